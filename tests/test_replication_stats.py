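"""Cumulative GC skew, ori/ter, GCSI, relative positions, conservation."""

import numpy as np
import pytest
from scipy import stats

from difscan.genome_io import Chromosome
from difscan.motif_profile import ScanHit
from difscan.replication_stats import (average_conservation, compare_positions,
                                       conservation_quantity, cumulative_skew,
                                       find_ori_ter, gcsi, position_variance,
                                       replichore_relative, skew_report,
                                       SkewReport)
from difscan.site_validation import DifPrediction
from difscan.synthetic_data import generate_skewed_genome
from .conftest import random_genome


def _chrom(seq, cid="c"):
    return Chromosome(cid, cid, ("", "", ""), seq)


class TestCumulativeSkew:
    def test_all_g(self):
        assert cumulative_skew(_chrom("GGGG")).tolist() == [-1, -2, -3, -4]

    def test_alternating(self):
        assert cumulative_skew(_chrom("GCGC")).tolist() == [-1, 0, -1, 0]

    def test_final_equals_c_minus_g(self, rng):
        for _ in range(50):
            seq = random_genome(rng, length=int(rng.integers(100, 2000)))
            final = cumulative_skew(_chrom(seq))[-1]
            assert final == seq.count("C") - seq.count("G")


class TestOriTer:
    def test_square_wave_positions(self):
        ori, ter = find_ori_ter(_chrom("G" * 500 + "C" * 500))
        assert (ori, ter) == (1000, 500)

    def test_rotation_equivariance(self, rng):
        seq = generate_skewed_genome(20_000, 0.5, 0.8, ori=5_000, rng=rng).sequence
        ori0, ter0 = find_ori_ter(_chrom(seq))
        L = len(seq)
        for _ in range(20):
            r = int(rng.integers(1, L))
            rotated = seq[r:] + seq[:r]
            ori, ter = find_ori_ter(_chrom(rotated))
            assert (ori - 1) % L == (ori0 - 1 - r) % L
            assert (ter - 1) % L == (ter0 - 1 - r) % L

    def test_programmed_ori_recovered(self, rng):
        L = 100_000
        chrom = generate_skewed_genome(L, 0.5, 1.0, ori=30_000, rng=rng)
        ori, ter = find_ori_ter(chrom)
        from difscan.replication_stats import circular_distance
        assert circular_distance(ori, 30_000, L) <= 0.01 * L
        assert circular_distance(ter, 30_000 + L // 2, L) <= 0.01 * L


class TestGcsi:
    def test_square_wave_calibration(self):
        value = gcsi(_chrom("G" * 500 + "C" * 500))
        assert value == pytest.approx(1.0, rel=0.02)

    def test_null_mostly_below_threshold(self, rng):
        below = sum(gcsi(_chrom(random_genome(rng, length=100_000))) < 0.05
                    for _ in range(20))
        assert below >= 19

    def test_monotone_in_skew_strength(self, rng):
        means = []
        for strength in (0.0, 0.2, 0.5, 1.0):
            vals = [gcsi(generate_skewed_genome(50_000, 0.5, strength,
                                                ori=10_000, rng=rng))
                    for _ in range(5)]
            means.append(np.mean(vals))
        assert means == sorted(means)

    def test_rotation_invariant(self, rng):
        seq = generate_skewed_genome(40_960, 0.5, 0.5, ori=9_999, rng=rng).sequence
        base = gcsi(_chrom(seq))
        r = 12_345
        assert gcsi(_chrom(seq[r:] + seq[:r])) == pytest.approx(base, rel=0.05)

    def test_short_sequence_window_reduction(self):
        assert gcsi(_chrom("G" * 50 + "C" * 50), windows=4096) == pytest.approx(1.0, rel=0.02)


class TestReplichoreRelative:
    def test_antipode_is_zero(self):
        assert replichore_relative(75_001, ori=25_001, L=100_000) == pytest.approx(0.0)

    def test_ori_is_hundred(self):
        assert replichore_relative(25_001, ori=25_001, L=100_000) == pytest.approx(100.0)

    def test_midway_is_fifty(self):
        assert replichore_relative(50_001, ori=25_001, L=100_000) == pytest.approx(50.0)


def _pred(cid, start):
    hit = ScanHit(cid, start, "+", "A" * 28, 12.0, 1e-9, 1e-4)
    return DifPrediction(hit=hit, status="validated")


def _skew(cid, L, ori, ter, g=0.5):
    return SkewReport(cid, L, ori, ter, g, g >= 0.05, 0, 0)


class TestComparePositions:
    def test_dif_at_ter_perfect_correlation(self):
        L = 100_000
        preds, skews = [], []
        for i, offset in enumerate((1000, 3000, 5000, 8000, 12000)):
            ori = 10_000
            ter = (ori - 1 + L // 2 + offset) % L + 1
            preds.append(_pred(f"c{i}", ter))
            skews.append(_skew(f"c{i}", L, ori, ter))
        comps, rho_pos, _ = compare_positions(preds, skews)
        assert rho_pos == pytest.approx(1.0)
        assert all(c.diff_percent_genome == pytest.approx(0.0) for c in comps)

    def test_low_gcsi_excluded(self):
        L = 100_000
        preds = [_pred(f"c{i}", 50_000) for i in range(4)]
        skews = [_skew(f"c{i}", L, 1, 50_000, g=0.5 if i < 2 else 0.01)
                 for i in range(4)]
        comps, rho, _ = compare_positions(preds, skews)
        assert len(comps) == 2
        assert np.isnan(rho)        # < 3 usable chromosomes

    def test_spearman_matches_rank_formula(self):
        """Hand-computed 5-pair example: rho = 1 - 6*sum(d^2)/(n(n^2-1))."""
        x = [10.0, 20.0, 30.0, 40.0, 50.0]
        y = [12.0, 25.0, 22.0, 48.0, 41.0]    # ranks 1,3,2,5,4 -> d2 sum = 4
        expected = 1 - 6 * 4 / (5 * 24)
        assert stats.spearmanr(x, y).statistic == pytest.approx(expected)
        L = 100_000
        preds, skews = [], []
        for i, (dif_off, ter_off) in enumerate(zip(x, y)):
            ori = 1
            ter = int(L // 2 + ter_off * 100)
            dif = int(L // 2 + dif_off * 100)
            preds.append(_pred(f"c{i}", dif))
            skews.append(_skew(f"c{i}", L, ori, ter))
        _, rho, _ = compare_positions(preds, skews)
        assert rho == pytest.approx(expected)


class TestConservation:
    def test_monomorphic_variance_2500(self):
        assert position_variance([100, 0, 0, 0]) == 2500.0

    def test_uniform_variance_zero(self):
        assert position_variance([25, 25, 25, 25]) == 0.0

    def test_two_base_split(self):
        assert position_variance([50, 50, 0, 0]) == pytest.approx(2500 / 3)

    def test_profile_bounds_and_extremes(self, rng):
        motifs = ["A" * 28, "T" * 28, "G" * 28, "C" * 28] * 25
        prof = conservation_quantity(motifs)
        assert np.allclose(prof.values, 0.0)
        prof = conservation_quantity(["A" * 28] * 100)
        assert np.allclose(prof.values, 100.0)
        motifs = [random_genome(rng, length=28) for _ in range(50)]
        prof = conservation_quantity(motifs)
        assert ((prof.values >= 0) & (prof.values <= 100)).all()

    def test_average_over_strains_linear(self):
        groups = [["A" * 28] * 10, ["A" * 14 + "C" * 14] * 10]
        avg = average_conservation(groups)
        per = [conservation_quantity(g).variances for g in groups]
        assert np.allclose(avg.variances, np.mean(per, axis=0))

    def test_xerd_arm_more_conserved_with_asymmetry(self):
        """Slower XerD-side evolution shows up as higher conservation."""
        from difscan.synthetic_data import CladeSpec, evolve_clade
        spec = CladeSpec(n_genera=8, genomes_per_genus=3, genome_length=10_000,
                         motif_sub_rate=0.08, xerD_arm_rate_factor=0.25,
                         random_seed=5)
        _, truth = evolve_clade(spec)
        motifs = [t.implant_sequence for t in truth.genomes.values() if t.implanted]
        prof = conservation_quantity(motifs)
        xerc_arm = prof.values[6:12].mean()     # positions 7-12
        xerd_arm = prof.values[16:22].mean()    # positions 17-22
        assert xerd_arm >= xerc_arm


def test_skew_report_flags_visibility(rng):
    strong = skew_report(generate_skewed_genome(50_000, 0.5, 0.8, ori=10_000, rng=rng))
    assert strong.skew_visible and strong.ori != strong.ter
    null = skew_report(_chrom(random_genome(rng, length=50_000)))
    assert not null.skew_visible
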