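import numpy as np
import pytest

from talechip.core import Genome, GenomicInterval, Peak, PeakSet, reverse_complement
from talechip.motifs import (MOTIF_LIBRARY, UNIFORM_BG, ConsensusMotif,
                             MotifClassTable, classify_peaks, consensus_to_pwm,
                             estimate_background, scan_peakset, scan_sequence,
                             score_by_motif_class, summit_coincident_subset,
                             summit_profile)

from oracles import naive_scan


class TestConsensusToPwm:
    def test_fixed_base_column_without_pseudocount(self):
        pwm = consensus_to_pwm(ConsensusMotif("m", "TGACTCA"), pseudocount=0.0)
        assert pwm.matrix[0].tolist() == [0, 0, 0, 1]  # T

    def test_degenerate_code_splits_uniformly(self):
        pwm = consensus_to_pwm(ConsensusMotif("m", "S"), pseudocount=0.0)
        assert pwm.matrix[0].tolist() == [0, 0.5, 0.5, 0]

    def test_wildcard_column_has_zero_log_odds(self):
        pwm = consensus_to_pwm(ConsensusMotif("m", "TXA"), pseudocount=0.1)
        assert np.allclose(pwm.log_odds[1], 0.0)

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            ConsensusMotif("bad", "TGAZ")

    def test_columns_sum_to_one(self):
        for motif in MOTIF_LIBRARY.values():
            pwm = consensus_to_pwm(motif)
            assert np.allclose(pwm.matrix.sum(axis=1), 1.0)


class TestScanSequence:
    def test_embedded_consensus_is_found(self, random_background):
        seq = random_background[:293] + "TGACTCA" + random_background[300:600]
        pwm = consensus_to_pwm(MOTIF_LIBRARY["AP1"])
        hits = scan_sequence(pwm, seq)
        assert any(h.start == 293 for h in hits)

    def test_reverse_complement_mirrors_hits(self, random_background):
        seq = random_background[:100] + "TGATGCAT" + random_background[110:400]
        pwm = consensus_to_pwm(MOTIF_LIBRARY["OCTA"])
        fwd = scan_sequence(pwm, seq)
        rev = scan_sequence(pwm, reverse_complement(seq))
        L, w = len(seq), pwm.width
        mirrored = {(L - w - h.start, {"+": "-", "-": "+"}[h.strand]) for h in rev}
        assert {(h.start, h.strand) for h in fwd} == mirrored

    def test_poly_a_has_no_ap1_hits(self):
        pwm = consensus_to_pwm(MOTIF_LIBRARY["AP1"])
        assert scan_sequence(pwm, "A" * 500) == []

    def test_threshold_p_one_hits_every_position_both_strands(self):
        pwm = consensus_to_pwm(MOTIF_LIBRARY["AP1"])
        seq = "ACGTACGTACGTACGTACGT"
        hits = scan_sequence(pwm, seq, p_threshold=1.0)
        assert len(hits) == 2 * (len(seq) - pwm.width + 1)

    def test_sequence_shorter_than_motif_yields_nothing(self):
        pwm = consensus_to_pwm(MOTIF_LIBRARY["DECA"])
        assert scan_sequence(pwm, "ACGT") == []

    def test_n_windows_are_skipped(self):
        pwm = consensus_to_pwm(MOTIF_LIBRARY["AP1"])
        seq = "TGANTCA" + "A" * 10  # N at index 3
        hits = scan_sequence(pwm, seq, p_threshold=1.0)
        assert hits and all(h.start > 3 for h in hits)
        assert scan_sequence(pwm, "NNNNNNNN") == []

    @pytest.mark.parametrize("motif", list(MOTIF_LIBRARY))
    def test_matches_exhaustive_oracle(self, motif, random_background):
        """Vectorised scanning equals plain per-position scoring on both
        strands, at a permissive threshold that yields many hits."""
        pwm = consensus_to_pwm(MOTIF_LIBRARY[motif])
        word = MOTIF_LIBRARY[motif].expansions()[0]
        bg = random_background[:2_000]
        seq = bg[:500] + word + bg[500 + len(word):1500] + word + bg[1500 + len(word):]
        p = 0.002
        threshold, _ = pwm.score_threshold(p)
        hits = scan_sequence(pwm, seq, p)
        expected = naive_scan(pwm.log_odds.tolist(), seq, threshold)
        assert {(h.strand, h.start) for h in hits} == expected
        assert len(expected) > 0


class TestThresholdCalibration:
    def test_attained_pvalue_matches_combinatorics(self):
        # AP-1 = TGASTCA: 2 exact words out of 4^7 under a uniform background
        pwm = consensus_to_pwm(MOTIF_LIBRARY["AP1"], UNIFORM_BG)
        threshold, attained = pwm.score_threshold(1e-4)
        assert attained == pytest.approx(2 / 4**7)
        assert threshold == pytest.approx(pwm.max_score(), abs=1e-6)

    def test_deca_reaches_requested_pvalue_regime(self):
        pwm = consensus_to_pwm(MOTIF_LIBRARY["DECA"], UNIFORM_BG)
        _, attained = pwm.score_threshold(1e-4)
        assert attained <= 1e-4


def _window_peakset(background, windows, width=300):
    """Build a genome of concatenated windows and one peak per window."""
    seq = "".join(windows)
    genome = Genome({"chrT": seq})
    peaks = []
    for i in range(len(windows)):
        start = i * width
        peaks.append(Peak(GenomicInterval("chrT", start, start + width),
                          start + width // 2, 10.0, f"w{i}"))
    return genome, PeakSet("windows", peaks)


class TestClassifyPeaks:
    def _background_windows(self, background, n, width=300):
        return [background[i * width:(i + 1) * width] for i in range(n)]

    def test_peak_with_both_motifs_counted_in_both_columns(self, random_background):
        wins = self._background_windows(random_background, 3)
        w = wins[0]
        wins[0] = w[:100] + "TGATGCAT" + w[108:150] + "TGACTCA" + w[157:]
        wins[1] = wins[1][:146] + "TGACTCA" + wins[1][153:]
        genome, ps = _window_peakset(random_background, wins)
        table = classify_peaks(ps, genome, "Meis1")
        rows = table.table.set_index("peak")
        assert bool(rows.loc["w0", "both"])
        assert bool(rows.loc["w1", "has_ap1"]) and not rows.loc["w1", "has_specific"]
        assert bool(rows.loc["w2", "neither"])
        assert table.counts["specific"] + table.counts["ap1"] == 3  # w0 in both

    def test_empty_peak_set(self, random_background):
        genome = Genome({"chrT": random_background[:1000]})
        table = classify_peaks(PeakSet("empty", []), genome, "Prep1")
        assert table.n == 0
        assert np.isnan(table.percentages["ap1"])

    def test_unknown_factor_rejected(self, random_background):
        genome = Genome({"chrT": random_background[:1000]})
        with pytest.raises(ValueError, match="factor"):
            classify_peaks(PeakSet("x", []), genome, "Hoxb4")

    def test_classification_is_strand_invariant(self, random_background):
        wins = self._background_windows(random_background, 4)
        wins[0] = wins[0][:140] + "TGATAAAT" + wins[0][148:]
        wins[2] = wins[2][:140] + "TGAGTCA" + wins[2][147:]
        genome, ps = _window_peakset(random_background, wins)
        fwd = classify_peaks(ps, genome, "Meis1")
        L = 4 * 300
        rc_genome = Genome({"chrT": reverse_complement(genome.fetch("chrT", 0, L))})
        rc_peaks = [Peak(GenomicInterval("chrT", L - p.end, L - p.start),
                         L - 1 - p.summit, p.score, p.name) for p in ps]
        rev = classify_peaks(PeakSet("rc", rc_peaks), genome=rc_genome, factor="Meis1")
        a = fwd.table.set_index("peak").sort_index()
        b = rev.table.set_index("peak").sort_index()
        assert (a == b).all().all()


class TestSummitProfile:
    def test_exact_summit_embedding_fills_central_bin(self, random_background):
        wins = self._windows_with_ap1(random_background, 10, jitter=None)
        genome, ps = _window_peakset(random_background, wins)
        hits = scan_peakset(ps, genome, ["AP1"])
        counts, edges = summit_profile(hits, window=150, bin_width=10)
        central = np.flatnonzero((edges[:-1] <= 0) & (edges[1:] > 0))[0]
        assert counts[central] == counts.sum() > 0

    def _windows_with_ap1(self, background, n, jitter, width=300, rng=None):
        wins = []
        for i in range(n):
            w = background[i * width:(i + 1) * width]
            offset = 0 if jitter is None else int(round(rng.normal(0, jitter)))
            # place so the hit midpoint (start + 3) sits at 150 + offset
            start = int(np.clip(147 + offset, 0, width - 7))
            wins.append(w[:start] + "TGACTCA" + w[start + 7:])
        return wins

    def test_jitter_sd_is_recovered(self, random_background):
        rng = np.random.default_rng(99)
        big_bg = random_background * 3
        wins = self._windows_with_ap1(big_bg, 2_000, jitter=20, rng=rng)
        genome, ps = _window_peakset(big_bg, wins)
        hits = scan_peakset(ps, genome, ["AP1"])
        dists = np.array([h.summit_distance for h in hits])
        assert abs(np.std(dists) - 20) < 3

    def test_mass_never_exceeds_hit_count(self, random_background):
        wins = self._windows_with_ap1(random_background, 5, jitter=None)
        genome, ps = _window_peakset(random_background, wins)
        hits = scan_peakset(ps, genome, ["AP1"])
        counts, _ = summit_profile(hits, window=50)
        assert counts.sum() <= len(hits)


class TestSummitCoincidentSubset:
    def _make(self, background, inserts):
        """inserts: list of (ap1_offset_from_mid or None, has_octa)."""
        width = 300
        wins = []
        for i, (ap1_off, octa) in enumerate(inserts):
            w = background[i * width:(i + 1) * width]
            if ap1_off is not None:
                start = 147 + ap1_off
                w = w[:start] + "TGACTCA" + w[start + 7:]
            if octa:
                w = w[:30] + "TGATGCAT" + w[38:]
            wins.append(w)
        return _window_peakset(background, wins)

    def test_inclusion_and_octa_exclusion(self, random_background):
        genome, ps = self._make(random_background,
                                [(0, False), (0, True), (None, False), (90, False)])
        subset = summit_coincident_subset(ps, genome, window=30)
        assert {p.name for p in subset} == {"w0"}

    def test_subset_shrinks_with_window(self, random_background):
        inserts = [(off, False) for off in (-25, -10, 0, 5, 18, 28)]
        genome, ps = self._make(random_background, inserts)
        wide = summit_coincident_subset(ps, genome, window=30)
        narrow = summit_coincident_subset(ps, genome, window=0)
        assert {p.name for p in narrow} <= {p.name for p in wide}
        assert len(narrow) < len(wide)


class TestScoreByMotifClass:
    def _table(self, flags):
        import pandas as pd
        rows = [(f"p{i}", s, a, s and a, not s and not a)
                for i, (s, a) in enumerate(flags)]
        return MotifClassTable("t", "Meis1", "OCTA", pd.DataFrame(
            rows, columns=["peak", "has_specific", "has_ap1", "both", "neither"]))

    def _peakset(self, scores):
        return PeakSet("t", [
            Peak(GenomicInterval("chr1", i * 1000, i * 1000 + 300),
                 i * 1000 + 150, s, f"p{i}") for i, s in enumerate(scores)])

    def test_type_i_error_rate_under_identical_distributions(self):
        rng = np.random.default_rng(7)
        reps, false_pos = 200, 0
        flags = [(True, False)] * 50 + [(False, True)] * 50
        table = self._table(flags)
        for _ in range(reps):
            ps = self._peakset(rng.lognormal(4, 0.5, size=100))
            res = score_by_motif_class(ps, table)
            if res["tests"]["specific_only_vs_ap1_only"]["p_value"] < 0.05:
                false_pos += 1
        # binomial(200, 0.05): mean 10, sd ~3.1
        assert 1 <= false_pos <= 25

    def test_shifted_class_is_detected(self):
        rng = np.random.default_rng(8)
        flags = [(True, False)] * 200 + [(False, True)] * 200
        table = self._table(flags)
        a = rng.normal(50, 10, size=200)
        b = rng.normal(60, 10, size=200)  # shift of 1 sd
        ps = self._peakset(np.abs(np.concatenate([a, b])))
        res = score_by_motif_class(ps, table)
        assert res["tests"]["specific_only_vs_ap1_only"]["p_value"] < 1e-6
        assert res["summaries"]["ap1_only"]["median"] > \
            res["summaries"]["specific_only"]["median"]

    def test_single_class_skips_tests_with_warning(self):
        table = self._table([(True, False)] * 5)
        ps = self._peakset([1, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="skipped"):
            res = score_by_motif_class(ps, table)
        assert res["tests"] == {}
        assert res["summaries"]["specific_only"]["n"] == 5


def test_background_estimation_is_strand_symmetric():
    bg = estimate_background(["AAAACCGG"])
    assert bg[0] == pytest.approx(bg[3])  # A vs T
    assert bg[1] == pytest.approx(bg[2])  # C vs G
    assert bg.sum() == pytest.approx(1.0)
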