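# corepromoter

Analysis of *downstream core promoter elements* around CAGE-defined
transcription start sites, built for regulatory genomicists studying
TATA-less, DPE-dependent transcription in *Drosophila* — in particular the
promoters of Ftz/Ftz-F1 target genes, whose downstream region carries a
spacing-constrained combination of an initiator (Inr), the BridgeI element
and the DPE.

The package provides four connected analyses:

1. **TSS-anchored PWM annotation.** Position weight matrices for Inr
   (*Drosophila* TCAKTY-like and mammalian YYANWYY-like variants), TATA,
   BridgeI, BridgeII, MTE and DPE, each anchored to promoter coordinates
   (A+1 = +1, no position 0) with a canonical window (e.g. DPE at
   +28..+33).  Scoring is summed log2 odds against a background; a hit is a
   window scoring at or above the element's threshold inside its canonical
   window.  A combined 35-column Inr–BridgeI–DPE model spans −2..+33 with
   zero-scoring spacer columns, so its score is exactly the sum of the
   three component scores.
2. **Composition enrichment.** Each transcript is assigned to exactly one
   mutually exclusive composition category (Inr+BridgeI+DPE, TATA+Inr,
   Inr+MTE, Inr+DPE, TATA_only, Inr_only, none_detected) by a
   most-specific-first rule list.  A target gene set's category proportions
   are compared against genome-wide proportions with per-category 1-df
   chi-square goodness-of-fit tests, χ² = Σ (O−E)²/E over the in/out split,
   Bonferroni-corrected over categories.
3. **Exon-resampling conservation test.** The mean per-base conservation
   score (phyloP-style) of the −2..+33 window is compared to the
   distribution of means of 1000 random 35-bp windows placed inside the
   gene's exons; the null (exon-level conservation) stands if the window
   mean falls within ±2 SD of the resampled means.  A 35-bp upstream
   control window at −275..−241 is tested the same way.
4. **Multi-species ortholog scan.** Per-species promoter windows are
   extracted from MAF alignment blocks (±500 bp around the reference TSS)
   or supplied as gene-start-anchored FASTA windows (±1000 bp).  The
   combined model is slid over each de-gapped window; hits must score
   strictly above 5 bits with the initiator A+1 column within ±200 bp of
   the anchor, and the closest qualifying hit is the species' call.  Calls
   become a gene × species presence/absence matrix and a logo-ready
   position frequency matrix.

Seeded generators (`corepromoter.simulate`) produce synthetic inputs for
every stage — promoter populations with configurable composition
proportions, conservation tracks with exon structure, star-phylogeny
alignments with a planted combined motif — plus packaged fixtures of the
published minimal promoter variants (7 genes × 4 variants, window −10..+40)
and the published 40-species presence table.

## Worked example

```python
from corepromoter import load_promoter_variants, annotate, classify

variants = load_promoter_variants()
for gene in ["en", "opa"]:
    record = variants[(gene, "WT")]
    hits = annotate(record)
    print(gene, classify(hits))
    for h in hits:
        print(f"  {h.element_name:9s} {h.start:+d}..{h.end:+d}"
              f"  score={h.score:.2f}  {h.matched_seq}")
```

prints

```
en Inr+BridgeI+DPE
  Inr_mamm  -2..+5  score=5.54  CTAATTC
  BridgeI   +18..+22  score=5.59  CGATG
  DPE       +28..+33  score=8.17  AGACGT
  BridgeII  +30..+33  score=5.68  ACGT
opa Inr+DPE
  Inr_dros  -2..+4  score=10.03  TCAGTC
  DPE       +28..+33  score=3.80  AGTCTT
```

The *engrailed* promoter is annotated with a mammalian-type initiator,
BridgeI and DPE — the spacing-constrained combination — while *opa* carries
an initiator and DPE but no BridgeI, so it falls into the Inr+DPE category.
Scores are log2-odds sums in bits; each element is reported at its
canonical TSS-relative span.

The same stages are available from the command line
(`corepromoter annotate|classify|enrich|conserve|orthoscan|simulate|fixtures`);
`corepromoter simulate --kind alignment --seed 1 --out-dir out/` writes a
synthetic MAF plus its truth table, and `corepromoter orthoscan` scans it
back into a presence matrix.

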