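"""Profile building, log-odds scoring, exact p-values, scanning, LOOCV."""

import itertools

import numpy as np
import pytest

from difscan._seq import revcomp
from difscan.genome_io import Chromosome
from difscan.motif_profile import (MotifProfile, TrainingSite, build_profile,
                                   loocv, scan, score_pvalue, score_window,
                                   _score_distribution, _survival,
                                   _int_threshold)
from difscan.seed_fuzzy import SEED_DIFS
from .conftest import random_genome

ECOLI = SEED_DIFS["Escherichia coli"]


def _mutate(motif, n, rng):
    out = list(motif)
    for i in rng.choice(len(motif), size=n, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _training(rng, n=10, subs=2):
    return [_mutate(ECOLI, subs, rng) for _ in range(n)]


class TestBuildProfile:
    def test_degenerate_single_sequence(self):
        prof = build_profile(["A" * 28], pseudocount=0.0)
        assert np.allclose(prof.emissions[:, 0], 1.0)
        assert np.allclose(prof.emissions[:, 1:], 0.0)

    def test_counting_two_sequences(self):
        a = "A" + "G" * 27
        c = "C" + "G" * 27
        prof = build_profile([a, c], pseudocount=0.0)
        assert prof.emissions[0].tolist() == [0.5, 0.5, 0.0, 0.0]
        assert prof.emissions[1].tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_pseudocount_arithmetic(self):
        # n=2, count(A)=2, pseudocount .5 -> (2+.5)/(2+4*.5) = 0.625
        prof = build_profile(["A" * 28, "A" * 28], pseudocount=0.5)
        assert prof.emissions[0, 0] == pytest.approx(0.625)

    def test_order_independent(self, rng):
        train = _training(rng)
        a = build_profile(train)
        b = build_profile(train[::-1])
        assert np.array_equal(a.emissions, b.emissions)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["ACGT"])

    def test_columns_sum_to_one(self, rng):
        prof = build_profile(_training(rng), pseudocount=0.5)
        assert np.allclose(prof.emissions.sum(axis=1), 1.0, atol=1e-9)


class TestScoreWindow:
    def test_degenerate_profile_56_bits(self):
        prof = build_profile(["A" * 28], pseudocount=0.0)
        assert score_window(prof, "A" * 28) == pytest.approx(56.0)

    def test_null_profile_zero_bits(self, rng):
        uniform = np.full((28, 4), 0.25)
        prof = MotifProfile(uniform, np.full(4, 0.25), 0.5)
        for _ in range(5):
            w = random_genome(rng, length=28)
            assert score_window(prof, w) == pytest.approx(0.0)

    def test_additivity_over_columns(self, rng):
        prof = build_profile(_training(rng))
        w = random_genome(rng, length=28)
        per_column = sum(
            float(np.log2(prof.emissions[j, "ACGT".index(w[j])] / 0.25))
            for j in range(28))
        assert score_window(prof, w) == pytest.approx(per_column)

    def test_n_unscoreable(self, rng):
        prof = build_profile(_training(rng))
        assert np.isnan(score_window(prof, "N" + "A" * 27))


def _toy_columns(rng, n_cols):
    """Random small emission matrix + background for oracle checks."""
    em = rng.dirichlet(np.ones(4), size=n_cols)
    bg = rng.dirichlet(np.ones(4) * 5)
    S = np.log2(em / bg[None, :])
    return S, bg


class TestScorePvalue:
    def test_extreme_thresholds(self, rng):
        prof = build_profile(_training(rng))
        assert score_pvalue(prof, -1e6) == pytest.approx(1.0)
        assert score_pvalue(prof, 1e6) == 0.0

    @pytest.mark.parametrize("n_cols", [4, 5, 6])
    def test_dp_matches_enumeration(self, rng, n_cols):
        """DP over discretized column scores equals brute-force enumeration."""
        grid = 1e-3
        S, bg = _toy_columns(rng, n_cols)
        pmf, lo = _score_distribution(S, bg, grid)
        sf = _survival(pmf)
        S_int = np.rint(S / grid).astype(np.int64)
        for threshold in (-3.0, -0.5, 0.0, 0.7, 2.0):
            t = _int_threshold(threshold, grid)
            idx = t - lo
            dp_p = 1.0 if idx <= 0 else (0.0 if idx >= len(sf) else sf[idx])
            brute = 0.0
            for word in itertools.product(range(4), repeat=n_cols):
                iscore = sum(S_int[j, b] for j, b in enumerate(word))
                if iscore >= t:
                    brute += np.prod([bg[b] for b in word])
            assert dp_p == pytest.approx(brute, abs=1e-9)

    def test_monotone_in_threshold(self, rng):
        prof = build_profile(_training(rng))
        ps = [score_pvalue(prof, t) for t in np.linspace(-10, 40, 26)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_full_window_space_mass_one(self, rng):
        """The DP pmf over all 28-mer windows integrates to 1."""
        prof = build_profile(_training(rng), pseudocount=0.5)
        from difscan.motif_profile import _score_matrix
        S = _score_matrix(prof, np.full(4, 0.25))
        pmf, _ = _score_distribution(S, np.full(4, 0.25), 1e-3)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_grid_refinement_stable(self, rng):
        """10x finer grid changes p-values by < 5% relative."""
        prof = build_profile(_training(rng), pseudocount=0.5)
        for threshold in (5.0, 10.0, 20.0):
            coarse = score_pvalue(prof, threshold, grid=1e-3)
            fine = score_pvalue(prof, threshold, grid=1e-4)
            assert fine == pytest.approx(coarse, rel=0.05)


class TestScan:
    def test_implant_is_top_hit(self, rng):
        train = _training(rng)
        prof = build_profile(train)
        seq = random_genome(rng, length=100_000)
        seq = seq[:60_000] + train[0] + seq[60_028:]
        hits = scan(prof, Chromosome("x", "x", ("", "", ""), seq))
        assert hits[0].start == 60_001
        assert hits[0].e_value == pytest.approx(hits[0].p_value * 2 * len(seq))

    def test_revcomp_swaps_strand_and_mirrors(self, rng):
        train = _training(rng)
        prof = build_profile(train)
        seq = random_genome(rng, length=20_000)
        seq = seq[:9_000] + train[0] + seq[9_028:]
        L = len(seq)
        fwd = scan(prof, Chromosome("x", "x", ("", "", ""), seq))[0]
        rev = scan(prof, Chromosome("y", "y", ("", "", ""), revcomp(seq)))[0]
        assert rev.strand == {"+": "-", "-": "+"}[fwd.strand]
        assert rev.start == L - fwd.start - 26
        assert rev.bit_score == pytest.approx(fwd.bit_score)

    def test_uniform_profile_no_hits_above_threshold(self, rng):
        """A profile equal to the background cannot produce significant hits."""
        uniform = MotifProfile(np.full((28, 4), 0.25), np.full(4, 0.25), 0.5)
        seq = random_genome(rng, length=10_000)
        hits = scan(uniform, Chromosome("x", "x", ("", "", ""), seq))
        # scores deviate from 0 only through the empirical background
        assert all(abs(h.bit_score) < 1.0 for h in hits)
        assert not any(h.bit_score >= 10.0 for h in hits)

    def test_short_chromosome_rejected(self, rng):
        prof = build_profile(_training(rng))
        with pytest.raises(ValueError):
            scan(prof, Chromosome("x", "x", ("", "", ""), "ACGT" * 5))

    def test_implant_recovery_rate(self, rng):
        """Implants up to 4 substitutions are the top hit in >=95/100 genomes."""
        train = _training(rng, n=12, subs=2)
        prof = build_profile(train)
        recovered = 0
        for _ in range(100):
            seq = random_genome(rng, length=100_000)
            pos = int(rng.integers(0, 100_000 - 28))
            implant = _mutate(ECOLI, int(rng.integers(0, 5)), rng)
            seq = seq[:pos] + implant + seq[pos + 28:]
            hits = scan(prof, Chromosome("x", "x", ("", "", ""), seq))
            if hits and hits[0].start == pos + 1:
                recovered += 1
        assert recovered >= 95


class TestSerialization:
    def test_tsv_round_trip_exact(self, rng, tmp_path):
        prof = build_profile(_training(rng), pseudocount=0.5,
                             training_ids=[("g1", "A" * 28)])
        path = tmp_path / "profile.tsv"
        prof.to_tsv(path)
        back = MotifProfile.from_tsv(path)
        assert np.array_equal(back.emissions, prof.emissions)
        assert np.array_equal(back.background, prof.background)
        assert back.pseudocount == prof.pseudocount
        assert back.training_ids == prof.training_ids


class TestLoocv:
    def _sites(self, rng, motifs):
        sites, chroms = [], {}
        for i, motif in enumerate(motifs):
            seq = random_genome(rng, length=30_000)
            pos = int(rng.integers(0, 30_000 - 28))
            seq = seq[:pos] + motif + seq[pos + 28:]
            cid = f"c{i}"
            chroms[cid] = Chromosome(cid, cid, ("", "", ""), seq)
            sites.append(TrainingSite(f"org{i}", cid, pos + 1, "+", motif))
        return sites, chroms

    def test_self_consistent_set_passes(self, rng):
        motifs = [ECOLI] * 10
        sites, chroms = self._sites(rng, motifs)
        results = loocv(sites, chroms)
        assert all(results.values())

    def test_unrelated_sequence_fails(self, rng):
        motifs = [_mutate(ECOLI, 2, rng) for _ in range(9)]
        motifs.append(random_genome(rng, length=28))   # adversarial
        sites, chroms = self._sites(rng, motifs)
        results = loocv(sites, chroms)
        assert not results["org9"]
        assert all(results[f"org{i}"] for i in range(9))

    def test_order_invariant(self, rng):
        motifs = [_mutate(ECOLI, 2, rng) for _ in range(6)]
        sites, chroms = self._sites(rng, motifs)
        a = loocv(sites, chroms)
        b = loocv(sites[::-1], chroms)
        assert a == b

    def test_too_small_rejected(self, rng):
        sites, chroms = self._sites(rng, [ECOLI])
        with pytest.raises(ValueError):
            loocv(sites, chroms)
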