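"""PWM construction, scoring, scanning, and the combined model."""

import numpy as np
import pytest

from corepromoter import (
    PromoterInterval,
    PromoterRecord,
    build_pwm,
    combine_pwms,
    scan,
    score_window,
)
from corepromoter.pwm import ALPHABET, PositionWeightMatrix

from conftest import GENES, random_record


def naive_score(pwm, seq):
    """Independent per-position table-lookup oracle."""
    total = 0.0
    lo = np.log2(pwm.probs / pwm.background)
    for j, base in enumerate(seq.upper()):
        if base == "N":
            total += float(pwm.background @ lo[j])
        else:
            total += float(lo[j, ALPHABET.index(base)])
    return total


class TestBuildPwm:
    def test_single_site_no_pseudocount_is_one_hot(self):
        pwm = build_pwm(["ACGT"], pseudocount=0)
        assert pwm.probs[0, 0] == 1.0 and pwm.probs[0, 1:].sum() == 0.0
        assert pwm.consensus == "ACGT"

    def test_pseudocounted_frequencies(self):
        pwm = build_pwm(["AA", "AC"], pseudocount=1)
        # column 2: A observed once in two sites -> (1+1)/(2+4)
        assert pwm.probs[1, 0] == pytest.approx(1 / 3)
        assert pwm.probs[0, 0] == pytest.approx(3 / 6)
        assert np.allclose(pwm.probs.sum(axis=1), 1)

    def test_background_matching_sites_score_zero(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0001)
        assert abs(score_window(pwm, "A")) < 1e-3
        pwm_exact = PositionWeightMatrix("flat", np.full((3, 4), 0.25))
        assert score_window(pwm_exact, "ACG") == 0.0

    def test_ragged_and_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])
        with pytest.raises(ValueError):
            build_pwm(["ACG", "AC"])

    def test_n_ignored_in_counts(self):
        pwm = build_pwm(["AN", "AN", "AC"], pseudocount=0)
        assert pwm.probs[1, 1] == pytest.approx(1.0)  # only the C counts


class TestScoring:
    def test_matches_naive_oracle_on_random_sequences(self, pwms):
        rng = np.random.default_rng(11)
        for name, pwm in pwms.items():
            for _ in range(20):
                seq = "".join(rng.choice(list("ACGTN"), size=pwm.width))
                assert score_window(pwm, seq) == pytest.approx(naive_score(pwm, seq), abs=1e-9)

    def test_consensus_maximises_score(self, pwms):
        rng = np.random.default_rng(12)
        for pwm in pwms.values():
            cmax = score_window(pwm, pwm.consensus)
            assert cmax == pytest.approx(pwm.max_score())
            for _ in range(10):
                seq = "".join(rng.choice(list("ACGT"), size=pwm.width))
                assert score_window(pwm, seq) <= cmax + 1e-12

    def test_case_insensitive(self, pwms):
        pwm = pwms["DPE"]
        assert score_window(pwm, "agacgt") == score_window(pwm, "AGACGT")

    def test_length_mismatch_rejected(self, pwms):
        with pytest.raises(ValueError):
            score_window(pwms["DPE"], "ACGT")


class TestScan:
    def test_equals_brute_force_oracle(self, pwms, thresholds):
        rng = np.random.default_rng(13)
        for _ in range(25):
            rec = random_record(rng, length=int(rng.integers(40, 200)))
            for name, pwm in pwms.items():
                thr = thresholds[name]
                hits = scan(pwm, rec, thr)
                expected = set()
                seq = rec.sequence.upper()
                for i in range(len(seq) - pwm.width + 1):
                    s = naive_score(pwm, seq[i : i + pwm.width])
                    if s >= thr:
                        expected.add(i)
                got = {hit.matched_seq for hit in hits}
                assert got == {seq[i : i + pwm.width] for i in expected}
                assert len(hits) == len(expected)
                assert [h.start for h in hits] == sorted(h.start for h in hits)

    def test_threshold_monotonicity(self, pwms):
        rng = np.random.default_rng(14)
        rec = random_record(rng, length=150)
        pwm = pwms["DPE"]
        previous = None
        for thr in [-5, -2, 0, 2, 5]:
            hits = {(h.start, h.matched_seq) for h in scan(pwm, rec, thr)}
            if previous is not None:
                assert hits <= previous
            previous = hits

    def test_short_sequence_warns_not_raises(self, pwms, caplog):
        rec = PromoterRecord("tiny", "ACG", PromoterInterval(1, 3))
        with caplog.at_level("WARNING"):
            assert scan(pwms["MTE"], rec, 0.0) == []
        assert "shorter" in caplog.text

    def test_en_bridgei_hit_at_18_22(self, pwms, thresholds, wt_records):
        hits = scan(pwms["BridgeI"], wt_records["en"], thresholds["BridgeI"],
                    positional_window=pwms["BridgeI"].canonical_window)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (18, 22)
        assert hits[0].matched_seq == "CGATG"

    def test_opa_has_no_bridgei(self, pwms, thresholds, wt_records):
        hits = scan(pwms["BridgeI"], wt_records["opa"], thresholds["BridgeI"],
                    positional_window=pwms["BridgeI"].canonical_window)
        assert hits == []

    def test_planted_consensus_is_top_hit(self, pwms):
        rng = np.random.default_rng(15)
        pwm = pwms["DPE"]
        flanks = "".join(rng.choice(list("ACGT"), size=94))
        seq = flanks[:40] + pwm.consensus + flanks[40:]
        rec = PromoterRecord("planted", seq, PromoterInterval(-50, 50))
        hits = scan(pwm, rec, -100)
        best = max(hits, key=lambda h: h.score)
        assert best.matched_seq == pwm.consensus
        assert best.start == -10  # string index 40 in a -50.. window


class TestCombinedModel:
    def test_span_and_width(self, pwms):
        model = combine_pwms(pwms["Inr_dros"], pwms["BridgeI"], pwms["DPE"])
        assert model.width == 35
        assert (model.span.start, model.span.end) == (-2, 33)

    def test_additivity_exact(self, pwms):
        rng = np.random.default_rng(16)
        for inr_name in ["Inr_dros", "Inr_mamm"]:
            inr, bri, dpe = pwms[inr_name], pwms["BridgeI"], pwms["DPE"]
            model = combine_pwms(inr, bri, dpe)
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            from corepromoter.coords import to_string_index
            off = {p.element_name: to_string_index(p.anchor, -2) for p in (inr, bri, dpe)}
            for i in range(0, 966, 7):
                s35 = seq[i : i + 35]
                total = sum(
                    score_window(p, s35[off[p.element_name] : off[p.element_name] + p.width])
                    for p in (inr, bri, dpe)
                )
                assert score_window(model, s35) == pytest.approx(total, abs=1e-9)

    def test_spacer_bases_are_free(self, pwms):
        inr, bri, dpe = pwms["Inr_dros"], pwms["BridgeI"], pwms["DPE"]
        model = combine_pwms(inr, bri, dpe)
        consensus_max = inr.max_score() + bri.max_score() + dpe.max_score()
        seq = list("A" * 35)
        from corepromoter.coords import to_string_index
        for p in (inr, bri, dpe):
            j = to_string_index(p.anchor, -2)
            seq[j : j + p.width] = p.consensus
        assert score_window(model, "".join(seq)) == pytest.approx(consensus_max)
        assert model.max_score() == pytest.approx(consensus_max)

    def test_overlapping_anchors_rejected(self, pwms):
        shifted = pwms["BridgeI"].with_anchor(-2)
        with pytest.raises(ValueError):
            combine_pwms(pwms["Inr_dros"], shifted, pwms["DPE"])

    def test_all_wt_promoters_pass_combined_threshold(self, pwms, wt_records):
        # the combined downstream model scores every wild-type promoter above 5
        for gene, rec in wt_records.items():
            inr = pwms["Inr_mamm"] if gene in ("en", "Cad74A") else pwms["Inr_dros"]
            model = combine_pwms(inr, pwms["BridgeI"], pwms["DPE"])
            s35 = rec.subsequence(PromoterInterval(-2, 33))
            assert score_window(model, s35) > 5.0
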