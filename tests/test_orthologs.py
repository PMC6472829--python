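"""Species window extraction, combined-motif calls, presence matrix, PFM."""

import numpy as np
import pandas as pd
import pytest

from corepromoter import (
    PromoterInterval,
    SimulationConfig,
    build_pfm,
    build_presence_matrix,
    default_combined_model,
    extract_species_windows,
    gen_species_alignment,
    load_presence_table,
    scan_species,
)
from corepromoter.io import MafBlock, MafRow, read_maf
from corepromoter.orthologs import OrthologHit, SpeciesWindow
from corepromoter.pwm import MotifHit

from conftest import GENES


def toy_block(ref_text, other_text, ref_start=100, other_species="spB"):
    rows = (
        MafRow("dm6.chr2L", ref_start, len(ref_text.replace("-", "")), "+",
               10_000, ref_text),
        MafRow(f"{other_species}.scaf1", 0, len(other_text.replace("-", "")), "+",
               10_000, other_text),
    )
    return MafBlock(rows)


class TestExtraction:
    def test_identical_rows_identical_windows(self):
        text = "ACGTACGTACGTACGTACGT"
        block = toy_block(text, text)
        wins = extract_species_windows([block], "dm6", reference_tss=110, flank=5)
        assert len(wins) == 2
        a, b = wins
        assert a.sequence == b.sequence
        assert a.anchor == b.anchor == 5

    def test_insertion_shifts_anchor(self):
        # species B has a 3-base insertion upstream of the TSS column
        ref = "ACGT---ACGTACGT"
        spb = "ACGTGGGACGTACGT"
        block = toy_block(ref, spb)
        # reference coordinates: A=100..T=103, A=104...; TSS at 106
        wins = {w.species: w for w in extract_species_windows([block], "dm6", 106, flank=4)}
        # window keeps reference 102..110; four reference bases precede the TSS
        assert wins["dm6"].anchor == 4
        assert wins["spB"].anchor - wins["dm6"].anchor == 3

    def test_gapped_species_sequence_degapped(self):
        ref = "ACGTACGTAC"
        spb = "AC--ACG-AC"
        block = toy_block(ref, spb)
        wins = {w.species: w for w in extract_species_windows([block], "dm6", 104, flank=4)}
        assert "-" not in wins["spB"].sequence
        # de-gapping preserves the base multiset
        assert sorted(wins["spB"].sequence) == sorted("ACACGAC".upper()[:len(wins["spB"].sequence)])

    def test_species_absent_at_tss_omitted(self, caplog):
        ref = "ACGTACGTAC"
        spb = "ACGT------"
        block = toy_block(ref, spb)
        with caplog.at_level("INFO"):
            wins = extract_species_windows([block], "dm6", 107, flank=2)
        assert {w.species for w in wins} == {"dm6"}

    def test_missing_reference_raises(self):
        block = toy_block("ACGT", "ACGT")
        with pytest.raises(ValueError, match="reference species"):
            extract_species_windows([block], "nosuch", 102, flank=1)

    def test_window_bounded_by_flank(self):
        text = "A" * 400
        block = toy_block(text, text)
        wins = extract_species_windows([block], "dm6", 300, flank=100)
        assert all(len(w.sequence) <= 201 for w in wins)


@pytest.fixture(scope="module")
def model():
    return default_combined_model()


class TestScanSpecies:
    def consensus_window(self, model, rng, length=500, anchor=None):
        seq = rng.choice(list("ACGT"), size=length)
        anchor = length // 2 if anchor is None else anchor
        start = anchor - model.tss_column
        cols = np.argmax(model.log_odds, axis=1)
        informative = np.any(model.log_odds != 0.0, axis=1)
        for j in np.flatnonzero(informative):
            seq[start + j] = "ACGT"[cols[j]]
        return SpeciesWindow("sp", "g", "".join(seq), anchor)

    def test_planted_consensus_found_at_distance_zero(self, model):
        rng = np.random.default_rng(41)
        win = self.consensus_window(model, rng)
        oh = scan_species(win, model)
        assert oh is not None
        assert oh.distance_to_anchor == 0
        assert oh.hit.score > 5

    def test_closest_hit_wins(self, model):
        rng = np.random.default_rng(42)
        # plant two consensus copies at distances 150 and 30 from the anchor
        length, anchor = 800, 400
        seq = rng.choice(list("ACGT"), size=length)
        cols = np.argmax(model.log_odds, axis=1)
        informative = np.flatnonzero(np.any(model.log_odds != 0.0, axis=1))
        for dist in (150, 30):
            start = anchor + dist - model.tss_column
            for j in informative:
                seq[start + j] = "ACGT"[cols[j]]
        win = SpeciesWindow("sp", "g", "".join(seq), anchor)
        oh = scan_species(win, model)
        assert oh.distance_to_anchor == 30

    def test_hit_outside_distance_limit_ignored(self, model):
        rng = np.random.default_rng(43)
        win = self.consensus_window(model, rng, length=900, anchor=100)
        # planted at the anchor; move the anchor 350 bases downstream instead
        far = SpeciesWindow("sp", "g", win.sequence, 450)
        assert scan_species(far, model) is None
        assert scan_species(win, model) is not None

    def test_monotonic_in_threshold_and_distance(self, model):
        rng = np.random.default_rng(44)
        win = self.consensus_window(model, rng)
        base = scan_species(win, model, score_threshold=5, distance_limit=200)
        assert base is not None
        # a stricter scan can only keep or lose the call, never invent one
        for thr, lim in [(8, 200), (5, 50), (base.hit.score + 1, 200), (5, 0)]:
            stricter = scan_species(win, model, thr, lim)
            assert stricter is None or (
                stricter.hit.score > thr and stricter.distance_to_anchor <= lim
            )
        none_win = SpeciesWindow("sp", "g", "AC" * 250, 250)
        assert scan_species(none_win, model, 5, 200) is None


class TestPresenceMatrix:
    def test_all_none_gives_all_false(self):
        pm = build_presence_matrix({("g1", "s1"): None, ("g1", "s2"): None})
        assert not pm.values.any()

    def test_duplicate_cells_rejected(self):
        entries = [("g1", "s1", None), ("g1", "s1", None)]
        with pytest.raises(ValueError, match="duplicate"):
            build_presence_matrix(entries)

    def test_presence_fixture_rows(self):
        t2 = load_presence_table()
        assert list(t2.columns) == GENES
        assert t2.loc["Drosophila melanogaster"].all()
        for sp in ["Anopheles gambiae", "Apis mellifera", "Tribolium castaneum"]:
            assert not t2.loc[sp].any()
        assert t2.shape == (40, 7)  # 27 alignment species + 13 homolog species

    def test_round_trip(self, tmp_path):
        from corepromoter.io import read_presence_tsv, write_presence_tsv
        t2 = load_presence_table()
        path = tmp_path / "presence.tsv"
        write_presence_tsv(t2, path)
        again = read_presence_tsv(path)
        pd.testing.assert_frame_equal(t2, again)


class TestPfm:
    def _hit(self, seq, species="s", gene="g"):
        return OrthologHit(species, gene, MotifHit("combined", -2, 33, 10.0, seq), 0)

    def test_single_hit_one_hot(self):
        seq = "A" * 35
        pfm = build_pfm([self._hit(seq)])
        assert pfm.counts[:, 0].sum() == 35
        assert np.all(pfm.counts.sum(axis=1) == 1)

    def test_identical_hits_column_sums(self):
        seq = "ACGT" * 8 + "ACG"
        pfm = build_pfm([self._hit(seq, species=f"s{i}") for i in range(5)])
        assert np.all(pfm.counts.sum(axis=1) == 5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([self._hit("ACGT")])

    def test_wt_promoters_all_G_at_plus24(self, wt_records):
        # position +24 sits between BridgeI and DPE and is G in all seven genes
        hits = []
        for gene, rec in wt_records.items():
            s35 = rec.subsequence(PromoterInterval(-2, 33))
            hits.append(self._hit(s35.upper(), species="dmel", gene=gene))
        pfm = build_pfm(hits)
        from corepromoter.coords import to_string_index
        col = to_string_index(24, -2)
        assert pfm.base_fraction(col, "G") == 1.0


class TestSyntheticAlignmentRecovery:
    def test_presence_equals_generator_truth(self):
        model = default_combined_model()
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_species=8)
            blocks, truth, ref_tss = gen_species_alignment(cfg)
            wins = extract_species_windows(blocks, "dmel_sim", ref_tss, flank=500, gene="g")
            pm = build_presence_matrix(
                {("g", w.species): scan_species(w, model) for w in wins})
            assert pm["g"].to_dict() == truth

    def test_zero_substitution_rate_all_present(self):
        model = default_combined_model()
        cfg = SimulationConfig(seed=3, n_species=5, substitution_rate=0.0,
                               n_preserved=5)
        blocks, truth, ref_tss = gen_species_alignment(cfg)
        assert all(truth.values())
        block = blocks[0]
        assert all(r.text == block.rows[0].text for r in block.rows)

    def test_maf_round_trip(self, tmp_path):
        from corepromoter.io import write_maf
        cfg = SimulationConfig(seed=4, n_species=4)
        blocks, _, _ = gen_species_alignment(cfg)
        path = tmp_path / "aln.maf"
        write_maf(blocks, path)
        again = read_maf(path)
        assert again == blocks
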