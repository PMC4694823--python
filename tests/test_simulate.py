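import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from talechip.core import GeneModel
from talechip.motifs import MOTIF_LIBRARY
from talechip.simulate import (PROFILE_LEVELS, CellLineProfile, DESpec,
                               LandscapeSpec, MotifMix, PlacementIndex,
                               generate_expression, generate_genome,
                               generate_landscape, generate_marks,
                               standard_profiles)

SMALL_GENOME = dict(n_chrom=1, chrom_length=900_000, n_genes=30, seed=4,
                    margin=100_000, gene_length_range=(5_000, 15_000),
                    scrub_motifs=None)


@pytest.fixture(scope="module")
def small_world():
    genome, genes = generate_genome(**SMALL_GENOME)
    return genome, genes, PlacementIndex(genome, genes)


class TestGenerateGenome:
    def test_seed_determinism(self):
        g1, genes1 = generate_genome(**SMALL_GENOME)
        g2, genes2 = generate_genome(**SMALL_GENOME)
        assert g1.sequence("chr1") == g2.sequence("chr1")
        assert genes1 == genes2

    def test_gc_content_extremes(self):
        genome, _ = generate_genome(n_chrom=1, chrom_length=50_000, n_genes=2,
                                    gc_content=1.0, seed=1, margin=5_000,
                                    gene_length_range=(2_000, 4_000),
                                    scrub_motifs=None)
        assert set(genome.sequence("chr1")) == {"G", "C"}

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="place"):
            generate_genome(n_chrom=1, chrom_length=100_000, n_genes=50,
                            seed=1, gene_length_range=(5_000, 10_000))

    def test_genes_do_not_overlap_and_use_both_strands(self):
        _, genes = generate_genome(**SMALL_GENOME)
        ordered = sorted(genes, key=lambda g: g.interval.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.interval.end <= b.interval.start
        assert {g.strand for g in genes} == {"+", "-"}

    def test_background_scrubbing_removes_consensus_matches(self):
        genome, _ = generate_genome(n_chrom=1, chrom_length=200_000, n_genes=6,
                                    seed=9, margin=30_000,
                                    scrub_motifs=("OCTA", "DECA", "AP1"))
        seq = genome.sequence("chr1")
        from talechip.core import reverse_complement
        for name in ("OCTA", "DECA", "AP1"):
            for word in MOTIF_LIBRARY[name].expansions():
                assert word not in seq
                assert reverse_complement(word) not in seq


class TestGenerateLandscape:
    def test_zero_level_factor_yields_empty_set(self, small_world):
        genome, genes, placement = small_world
        spec = LandscapeSpec(peaks_per_unit_level=60, seed=4)
        landscape = generate_landscape(CellLineProfile.standard("ev"), spec,
                                       genome, genes, placement)
        assert len(landscape.peaksets["Prep1"]) == 0
        assert len(landscape.peaksets["Meis1"]) > 0

    def test_seed_determinism(self, small_world):
        genome, genes, placement = small_world
        spec = LandscapeSpec(peaks_per_unit_level=60, seed=4)
        profile = CellLineProfile.standard("WT")
        a = generate_landscape(profile, spec, genome, genes, placement)
        b = generate_landscape(profile, spec, genome, genes, placement)
        assert a.truth.equals(b.truth)
        assert [(p.chrom, p.start, p.summit, p.score) for p in a.peaksets["Meis1"]] == \
            [(p.chrom, p.start, p.summit, p.score) for p in b.peaksets["Meis1"]]

    def test_doubling_level_doubles_expected_count(self, small_world):
        """Mean peak-count ratio over 50 replicate landscapes is 2 within
        Poisson error."""
        genome, genes, placement = small_world
        lo, hi = [], []
        for rep in range(50):
            spec = LandscapeSpec(peaks_per_unit_level=60, seed=1000 + rep)
            a = generate_landscape(CellLineProfile("a", 1.0, 0.0), spec,
                                   genome, genes, placement)
            b = generate_landscape(CellLineProfile("b", 2.0, 0.0), spec,
                                   genome, genes, placement)
            lo.append(len(a.peaksets["Meis1"]))
            hi.append(len(b.peaksets["Meis1"]))
        ratio = np.mean(hi) / np.mean(lo)
        assert abs(ratio - 2.0) < 0.1

    def test_full_core_and_equal_levels_give_identical_positions(self, small_world):
        genome, genes, placement = small_world
        spec = LandscapeSpec(peaks_per_unit_level=60, core_fraction=1.0, seed=4)
        a = generate_landscape(CellLineProfile("a", 1.0, 0.0), spec, genome,
                               genes, placement)
        b = generate_landscape(CellLineProfile("b", 1.0, 0.0), spec, genome,
                               genes, placement)
        pos_a = {(p.chrom, p.summit) for p in a.peaksets["Meis1"]}
        pos_b = {(p.chrom, p.summit) for p in b.peaksets["Meis1"]}
        assert pos_a == pos_b and len(pos_a) == len(a.peaksets["Meis1"])

    def test_core_sites_shared_across_profiles(self, small_world):
        genome, genes, placement = small_world
        spec = LandscapeSpec(peaks_per_unit_level=60, core_fraction=0.9, seed=4)
        low = generate_landscape(CellLineProfile("low", 0.5, 0.0), spec,
                                 genome, genes, placement)
        high = generate_landscape(CellLineProfile("high", 3.0, 0.0), spec,
                                  genome, genes, placement)
        pos_low = {(p.chrom, p.summit) for p in low.peaksets["Meis1"]}
        pos_high = {(p.chrom, p.summit) for p in high.peaksets["Meis1"]}
        shared = len(pos_low & pos_high)
        assert shared / len(pos_low) >= 0.8

    def test_displacement_removes_ap1_extra_peaks(self, small_world):
        genome, genes, placement = small_world
        base = dict(peaks_per_unit_level=120, seed=4)
        spec_off = LandscapeSpec(**base)
        spec_on = LandscapeSpec(**base, displacement_fraction=0.8)
        profile = CellLineProfile("mp_like", 2.0, 4.0)
        off = generate_landscape(profile, spec_off, genome, genes, placement)
        on = generate_landscape(profile, spec_on, genome, genes, placement)
        def extra_ap1(landscape):
            t = landscape.truth
            return len(t[(t.factor == "Meis1") & ~t.is_core & (t.motif_class == "ap1")])
        assert extra_ap1(on) < extra_ap1(off)

    def test_motif_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotifMix(0.5, 0.5, 0.5, 0.5)


class TestGenerateMarks:
    def test_promoter_marks_are_near_tss(self, small_world):
        genome, genes, _ = small_world
        marks = generate_marks(genome, genes, seed=2)
        tss = np.sort(np.array([g.tss for g in genes]))
        for iv in marks["PolII"] + marks["H3K4me3"]:
            mid = (iv.start + iv.end) // 2
            assert np.abs(tss - mid).min() <= 1_500

    def test_determinism_and_bivalent_subset(self, small_world):
        genome, genes, _ = small_world
        m1 = generate_marks(genome, genes, seed=2)
        m2 = generate_marks(genome, genes, seed=2)
        assert m1 == m2
        assert set(map(tuple, ((iv.chrom, iv.start) for iv in m1["H3K27ac"]))) <= \
            set(map(tuple, ((iv.chrom, iv.start) for iv in m1["H3K4me1"])))

    def test_zero_enhancers(self, small_world):
        genome, genes, _ = small_world
        marks = generate_marks(genome, genes, seed=2, n_enhancers=0)
        assert marks["H3K4me1"] == [] and marks["H3K27ac"] == []


class TestGenerateExpression:
    GENES = [f"g{i:04d}" for i in range(1_000)]

    def test_fraction_up_one_makes_all_bound_de_positive(self):
        bound = set(self.GENES[:300])
        spec = DESpec(fraction_up=1.0, seed=3)
        df = generate_expression(self.GENES, bound, spec)
        bound_de = df[df.true_de & df.bound]
        assert len(bound_de) > 0
        assert (bound_de.log2fc > 0).all()

    def test_structure_fractions(self):
        bound = set(self.GENES[:500])
        spec = DESpec(fraction_de=0.3, fraction_bound_de=0.5, fraction_up=0.8, seed=3)
        df = generate_expression(self.GENES, bound, spec)
        n_de = df.true_de.sum()
        assert n_de == 300
        assert df[df.true_de & df.bound].shape[0] == 150
        up_frac = df[df.true_de & df.bound].true_up.mean()
        assert up_frac == pytest.approx(0.8, abs=0.01)

    def test_true_de_pvalues_are_stochastically_smaller(self):
        df = generate_expression(self.GENES, set(self.GENES[:300]), DESpec(seed=5))
        de_p = df.loc[df.true_de, "p_value"]
        null_p = df.loc[~df.true_de, "p_value"]
        assert de_p.median() < null_p.median()
        assert stats.mannwhitneyu(de_p, null_p, alternative="less").pvalue < 1e-20

    def test_zero_effect_makes_fold_changes_indistinguishable(self):
        """With effect_size = 0 and no directional bias, DE and non-DE
        log2FC distributions agree (KS p > 0.01 across replicate seeds)."""
        for seed in (11, 12, 13):
            spec = DESpec(effect_size=0.0, fraction_up=0.5, seed=seed)
            df = generate_expression(self.GENES, set(self.GENES[:300]), spec)
            res = stats.ks_2samp(df.loc[df.true_de, "log2fc"],
                                 df.loc[~df.true_de, "log2fc"])
            assert res.pvalue > 0.01

    def test_empty_gene_list(self):
        df = generate_expression([], set(), DESpec(seed=1))
        assert df.empty

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction_up"):
            generate_expression(self.GENES, set(), DESpec(fraction_up=1.5, seed=1))

    def test_accepts_gene_models(self):
        genes = [GeneModel(f"g{i}", __import__("talechip").GenomicInterval(
            "chr1", i * 1000, i * 1000 + 500), "+") for i in range(10)]
        df = generate_expression(genes, {"g1"}, DESpec(seed=1))
        assert set(df.gene_id) == {f"g{i}" for i in range(10)}


def test_standard_profiles_match_study_levels():
    levels = {p.name: (p.level_meis1, p.level_prep1) for p in standard_profiles()}
    assert levels == PROFILE_LEVELS
    assert levels["MP"] == (1.75, 4.2)
    assert levels["ev"] == (0.3, 0.0)
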