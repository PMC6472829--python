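# Methods

## Coordinates

Promoter positions use the biology convention: the first transcribed base
(the initiator A) is +1, its upstream neighbour is −1, and position 0 does
not exist.  Interval lengths therefore differ by one depending on whether
the interval straddles the TSS: −2..+33 covers 35 bases, −10..+40 covers
50.  All genomic file I/O (BED, bedGraph, MAF) is 0-based half-open; the
two systems meet only in `corepromoter.coords`, which owns the conversion
and refuses position 0 everywhere.

## Element matrices and thresholds

The element definitions follow the ElemeNT core promoter annotation
tool, whose exact numeric matrices are not publicly distributed.  The
packaged matrices are therefore **reconstructions**, shipped as replaceable data
(`data/pwms.meme`, MEME minimal format, with anchors/windows/thresholds in
`data/pwm_anchors.yaml`):

* Inr (Drosophila), TATA, MTE, BridgeII and DPE are consensus-degeneracy
  matrices (IUPAC-weighted columns, sharpened so that their information
  content resembles count-built matrices);
* BridgeI is count-built (pseudocount 0.1) from the six BridgeI site
  matches printed in the wild-type minimal promoters of *en*, *drm*,
  *Sema5c*, *Ppa*, *Cad74A* and *noc*;
* the mammalian Inr is a YYANWYY-weighted matrix.

Scoring is `sum log2(p / background)` in bits, uniform background by
default, case-insensitive, N scoring as the background-expected column
mean.  Only the sense strand is scanned: promoters are TSS-oriented.

Anchors and per-element thresholds (bits) were fixed once against the
packaged set of 28 experimentally characterized promoter variants, which
acts as the calibration anchor: *en*/*Cad74A* must call the mammalian initiator and
fail the Drosophila one, the other five genes the reverse or both; *opa*
must lack BridgeI; every mutant row must lose exactly its mutated element.

| element  | anchor/window | threshold | margin (pass / fail) |
|----------|---------------|-----------|----------------------|
| Inr_dros | −2..+4        | 3.0       | 4.41 / 0.59          |
| Inr_mamm | −2..+5        | 4.0       | 4.35 / —             |
| TATA     | search −40..−20 | 5.0     | (not in fixtures)    |
| BridgeI  | +18..+22      | 1.0       | 1.26 / −1.83         |
| BridgeII | +30..+33      | 3.0       | —                    |
| DPE      | +28..+33      | 1.0       | 1.53 / −3.45         |
| MTE      | +18..+29      | 4.0       | all WT below         |

All of these are configurable; the margins are narrow for BridgeI and DPE
because those elements are genuinely degenerate (the weakest fixture site
match sets the ceiling on the threshold).

The combined Inr–BridgeI–DPE model places the component log-odds columns at
their anchors inside −2..+33 and fills the remaining columns with zeros, so
spacer bases never contribute and additivity with the component scores is
exact.  The conventional score threshold for this model is 5 bits;
whether it applies per component or to the total is a free choice, and the
default applies
it to the combined total (per-component thresholds exist for annotation).
All seven wild-type promoters score above 5 with the appropriate initiator
variant (minimum ≈ 8.4 bits).

## Composition categories and enrichment

Categories partition transcripts with a most-specific-first rule list:
Inr+BridgeI+DPE ≻ TATA+Inr ≻ Inr+MTE ≻ Inr+DPE ≻ TATA_only ≻ Inr_only ≻
none_detected.  Either initiator variant satisfies an "Inr" requirement;
the Bridge-containing category demands the BridgeI hit, which is what
distinguishes it from Inr+MTE.  Broad-shape promoters are excluded; the
counting unit is the transcript, not the gene.

The enrichment test treats the genome as the population: for each category
a 1-df chi-square goodness-of-fit of the target's in/out split against the
genome proportion, Bonferroni-corrected over the number of categories.
Yates correction is off by default and a two-sample 2×2 variant is
available behind a flag.  With a degenerate expectation (genome proportion
0, nonzero observed) the test raises rather than reporting a spurious
infinity.

## Conservation test

The null distribution is built from 1000 35-bp windows placed uniformly at
random (with replacement) over all valid single-exon start positions,
pooled across exons — this weights each exon by its number of valid
placements.  An option to concatenate exons (windows may span junctions)
exists; single-exon placement is the default because sampling within the
gene exons, without junction windows, is the conservative reading of the
procedure.  The
summary is the sample SD (ddof = 1); when every resampled mean is identical
(forced placement) the SD is exactly 0 and the verdict requires exact
equality.  The promoter window is −2..+33; the upstream control is
−275..−241 — these exact coordinates are authoritative over the looser
description "200 bp away from the core promoter region" (they sit 200 bp
upstream of the −41 edge of a −40.. window).  Missing bases inside
any queried window are a hard error: the mean is the test statistic and
must never be computed on a silently shrunken window.

The verdict is |window_mean − resample_mean| ≤ 2·SD (multiplier
configurable).  Under the synthetic null (promoter bases drawn from the
exon score distribution) the within-band rate is ≈ 0.94–0.95 over 500
replicates — slightly under the two-sided normal mass because the band uses
the estimated mean and SD and overlapping windows correlate.

## Ortholog scan

Species windows come from MAF blocks: alignment columns are kept while the
reference coordinate lies within ±flank of the TSS, insertion columns
(reference gaps) attach to the preceding reference base, each species row
is de-gapped, and the anchor is recomputed as the count of that species'
non-gap bases preceding the TSS column.  A species not aligned at the TSS
column is omitted with a log note.  Distance is measured from the hit's
initiator A+1 column to the anchor; hits qualify with score strictly above
5 and distance ≤ 200, and the closest hit wins (ties: higher score, then
upstream).  Raising the threshold or tightening the distance can only
remove calls.

## Synthetic data

Generators are pure functions of their `SimulationConfig` (seed included);
identical configs give byte-identical output.

**Promoter population.**  Default composition proportions (Inr+BridgeI+DPE
0.08, TATA+Inr 0.10, Inr+MTE 0.08, Inr+DPE 0.12, TATA_only 0.08, Inr_only
0.24, none_detected 0.30) are design constants: real genome-wide
proportions depend on an external promoter database, so the defaults were
chosen once, guided by a power analysis, to be biologically plausible for
focused fly promoters (initiator-containing TATA-less classes dominant,
DPE-family common, TATA a minority): at the configured study size (285
targets, 2× enrichment) per-seed detection power exceeds 0.9 only when the
enriched category's genome-wide base rate is ≳ 7 %, so the default of 8 %
places the simulated study in a reliably detectable regime rather than at
the edge of significance.  Planted element sites are
drawn column-wise from the packaged matrices, rejection-truncated to score
at or above the element's calling threshold: a "planted" element that fails
its own definition would make the generator's truth label wrong by
construction.  Flanks are i.i.d. background (uniform by default,
configurable to AT-rich).  Elements sit at exact canonical anchors; a
jitter option shifts them to probe the strict spacing requirement (jittered
elements leave their canonical windows and stop being called).

**Conservation fixture.**  One synthetic gene on a star layout: exonic
bases score i.i.d. Normal(2, 1), intergenic Normal(0, 1) (both
configurable), with the promoter window re-drawn from the exon distribution
(optionally mean-shifted in null-SD units) or left at background.  Default
exon structure: 4 exons × 300 bp with 200-bp introns — enough placements
(≈ 1.1 k) that the resampled null is well mixed.

**Species alignment.**  A star phylogeny (no tree-aware substitution
model): one reference carrying the combined-model consensus at its centre,
`n_species` descendants with i.i.d. substitutions at rate 0.10, reduced by
the preservation factor 0.25 inside motif-informative columns for preserved
species; ablated species get the motif columns redrawn uniformly.  The
reference flanks are resampled until the planted site is the unique
qualifying window, and each species' mutation draw is repeated until its
exhaustively computed truth (any window with score > 5 within ±200 of the
anchor) matches its planted design — so the returned truth table is exact
by construction, and the pipeline's presence matrix is checked against it
for equality, not approximation.  No indels are simulated by the generator;
gap handling is exercised by hand-constructed alignment fixtures in the
tests.

What the passing tests do **not** show about real data: real promoter
populations have correlated flank composition, CpG/AT skews and positional
jitter that the generator omits; real phyloP tracks are not i.i.d. normal
within exons; and real alignments contain indels, rearrangements and
lineage structure that a star phylogeny with uniform substitution cannot
produce.  The calibration results bound the pipeline's behaviour under the
stated model, not under genomic reality.

## Numerical choices

* Scores are float64 bit-scores; scanner and oracle sum columns in the same
  order, so equality checks are exact.
* The ±2 SD band is closed (boundary values are inside).
* Bonferroni: `p_adj = min(1, p · k)`; flags use `p_adj < alpha` strictly.
* Hit selection ties (same distance): higher score, then smaller start.
* MEME files carry 6-decimal probabilities; the site sampler renormalises
  columns before drawing.

## Known limitations

* The packaged matrices are reconstructions; analyses against real genomes
  should load the user's own MEME matrices and anchors.
* BridgeI is intrinsically information-poor (~3.6 bits): at the calibrated
  threshold, ≈ 7 % of random 5-mers pass, which inflates the
  Inr+BridgeI+DPE category in both target and background (the enrichment
  test shares this bias on both sides by classifying the background through
  the same pipeline).
* The homolog branch accepts user-supplied gene-start windows only; no
  remote BLAST/database access exists anywhere in the package.
* Minus-strand MAF reference rows are not supported (reference windows are
  extracted on the + strand, as downloaded windows are TSS-oriented).
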