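"""Windowed diversity/divergence statistics against brute-force enumeration."""

import numpy as np
import pytest

from loadscape import popgen

from conftest import random_matrix
from oracles import (
    brute_dxy,
    brute_hudson_fst,
    brute_pi,
    brute_spearman,
    brute_tajimas_d,
)


class TestPi:
    def test_monomorphic_window_is_zero(self):
        g = np.zeros((4, 10), dtype=np.int8)
        assert popgen.window_pi(g) == 0.0

    def test_two_diploids_one_fixed_difference(self):
        # alleles pooled: 0,0,1,1 -> 4 differing pairs of C(4,2)=6
        g = np.array([[0], [2]], dtype=np.int8)
        assert popgen.window_pi(g) == pytest.approx(4 / 6, abs=1e-15)

    def test_matches_bruteforce_with_missing(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_matrix(rng, n_samples=6, n_sites=50, missing_rate=0.15)
            assert popgen.window_pi(m.genotypes) == pytest.approx(
                brute_pi(m.genotypes), abs=1e-12
            )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, n_samples=8, n_sites=40)
        perm = rng.permutation(8)
        assert popgen.window_pi(m.genotypes) == pytest.approx(
            popgen.window_pi(m.genotypes[perm]), abs=1e-15
        )

    def test_fully_missing_site_changes_nothing(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, n_samples=6, n_sites=30, missing_rate=0.0)
        g = m.genotypes
        with_blank = np.hstack([g, np.full((6, 1), -1, dtype=np.int8)])
        assert popgen.window_pi(with_blank) == popgen.window_pi(g)

    def test_empty_window_undefined(self):
        assert np.isnan(popgen.window_pi(np.empty((4, 0), dtype=np.int8)))


class TestDxy:
    def test_identical_monomorphic_populations(self):
        g = np.zeros((3, 5), dtype=np.int8)
        assert popgen.window_dxy(g, g.copy()) == 0.0

    def test_fixed_difference_is_one(self):
        a = np.zeros((3, 1), dtype=np.int8)
        b = np.full((3, 1), 2, dtype=np.int8)
        assert popgen.window_dxy(a, b) == 1.0

    def test_matches_bruteforce_and_symmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = random_matrix(rng, n_samples=5, n_sites=40, missing_rate=0.1).genotypes
            b = random_matrix(rng, n_samples=4, n_sites=40, missing_rate=0.1).genotypes
            d = popgen.window_dxy(a, b)
            assert d == pytest.approx(brute_dxy(a, b), abs=1e-12)
            assert d == pytest.approx(popgen.window_dxy(b, a), abs=1e-15)


class TestFst:
    def test_equal_frequencies_near_zero(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.3, 0.7, 2000)
        a = rng.binomial(2, p, (30, 2000)).astype(np.int8)
        b = rng.binomial(2, p, (30, 2000)).astype(np.int8)
        assert abs(popgen.window_fst(a, b)) < 0.02

    def test_fixed_difference_is_one(self):
        a = np.zeros((4, 1), dtype=np.int8)
        b = np.full((4, 1), 2, dtype=np.int8)
        assert popgen.window_fst(a, b) == pytest.approx(1.0)

    def test_matches_independent_hudson(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            a = random_matrix(rng, n_samples=5, n_sites=100, missing_rate=0.05).genotypes
            b = random_matrix(rng, n_samples=5, n_sites=100, missing_rate=0.05).genotypes
            assert popgen.window_fst(a, b) == pytest.approx(
                brute_hudson_fst(a, b), abs=1e-10
            )


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        g = np.zeros((5, 20), dtype=np.int8)
        assert np.isnan(popgen.tajimas_d(g))

    def test_hand_computed_small_case(self):
        # 2 diploids = 4 haplotypes, 3 segregating sites, minor counts (1,1,2)
        g = np.array(
            [
                [1, 0, 2],
                [0, 1, 0],
            ],
            dtype=np.int8,
        )
        expected = brute_tajimas_d(g)
        assert popgen.tajimas_d(g) == pytest.approx(expected, abs=1e-12)
        # frozen value from direct evaluation of the 1989 constants
        assert popgen.tajimas_d(g) == pytest.approx(0.16766, abs=1e-4)

    def test_excludes_sites_with_missing_calls(self):
        rng = np.random.default_rng(15)
        g = rng.binomial(2, 0.4, (6, 60)).astype(np.int8)
        g[0, :5] = -1
        complete = g[:, 5:]
        assert popgen.tajimas_d(g) == pytest.approx(popgen.tajimas_d(complete), abs=1e-15)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            g = rng.binomial(2, rng.uniform(0.1, 0.9, 40), (7, 40)).astype(np.int8)
            d1, d2 = popgen.tajimas_d(g), brute_tajimas_d(g)
            if np.isnan(d2):
                assert np.isnan(d1)
            else:
                assert d1 == pytest.approx(d2, abs=1e-10)


class TestNormalCutoff:
    @pytest.mark.parametrize(
        "confidence,expected",
        [(0.5, 0.0), (0.99, 2.3263), (0.975, 1.96)],
    )
    def test_quantiles(self, confidence, expected):
        assert popgen.normal_cutoff(confidence) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            popgen.normal_cutoff(bad)


class TestLandscapeCorrelation:
    def test_perfect_correlations(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        r, _ = popgen.landscape_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _ = popgen.landscape_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_rank_and_pearson(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=20)
        b = rng.normal(size=20) + 0.5 * a
        r, _ = popgen.landscape_correlation(a, b)
        assert r == pytest.approx(brute_spearman(a, b), abs=1e-10)

    def test_nan_pairs_dropped(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        b = np.array([2.0, 1.0, 3.0, np.nan, 5.0, 4.0])
        r, _ = popgen.landscape_correlation(a, b)
        ok = np.array([0, 1, 4, 5])
        assert r == pytest.approx(brute_spearman(a[ok], b[ok]), abs=1e-10)

    def test_constant_vector_undefined(self):
        r, p = popgen.landscape_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(r)


class TestPropertyInvariants:
    """Randomized invariants checked with hypothesis (derandomized)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    genotype_arrays = hnp.arrays(
        dtype=np.int8,
        shape=st.tuples(st.integers(2, 8), st.integers(1, 30)),
        elements=st.sampled_from([-1, 0, 1, 2]),
    )

    @given(genotype_arrays)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pi_matches_bruteforce_and_bounds(self, g):
        pi = popgen.window_pi(g)
        expected = brute_pi(g)
        if np.isnan(expected):
            assert np.isnan(pi)
        else:
            assert pi == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= pi <= 1.0

    @given(genotype_arrays, genotype_arrays)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dxy_symmetric_and_bounded(self, a, b):
        n_sites = min(a.shape[1], b.shape[1])
        a, b = a[:, :n_sites], b[:, :n_sites]
        d_ab = popgen.window_dxy(a, b)
        d_ba = popgen.window_dxy(b, a)
        if np.isnan(d_ab):
            assert np.isnan(d_ba)
        else:
            assert d_ab == pytest.approx(d_ba, abs=1e-15)
            assert 0.0 <= d_ab <= 1.0

    @given(genotype_arrays)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_fully_missing_site_never_changes_pi(self, g):
        padded = np.hstack([g, np.full((g.shape[0], 1), -1, dtype=np.int8)])
        a, b = popgen.window_pi(g), popgen.window_pi(padded)
        assert (np.isnan(a) and np.isnan(b)) or a == b
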