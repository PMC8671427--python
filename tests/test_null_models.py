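"""Exact null pmfs checked against brute-force ensemble enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bibackbone.null_models import (
    EdgeNullDistribution,
    fcm_pmf,
    ffm_pmf,
    frm_pmf,
    poisson_binomial_pmf,
    sdsm_pmf,
    upper_tail,
)

ORACLE_TOL = 1e-12


def enumerate_pair_pmf(m, n, keep):
    """Overlap pmf of rows (0, 1) over all binary m x n matrices passing ``keep``."""
    counts = np.zeros(n + 1)
    for bits in itertools.product((0, 1), repeat=m * n):
        M = np.array(bits, dtype=np.int8).reshape(m, n)
        if keep(M):
            counts[int((M[0] & M[1]).sum())] += 1
    total = counts.sum()
    assert total > 0, "empty ensemble in oracle"
    return counts / total


class TestPoissonBinomial:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ([0.5, 0.5], [0.25, 0.5, 0.25]),
            ([1.0, 1.0, 0.0], [0, 0, 1, 0]),
            ([0.2, 0.3, 0.4], [0.336, 0.452, 0.188, 0.024]),
        ],
    )
    def test_known_values(self, probs, expected):
        assert poisson_binomial_pmf(probs) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            poisson_binomial_pmf([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_sums_to_one_with_correct_mean(self, probs):
        pmf = poisson_binomial_pmf(probs)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        mean = float(np.dot(np.arange(len(probs) + 1), pmf))
        assert mean == pytest.approx(sum(probs), abs=1e-9)


class TestFRM:
    def test_example_1_2_3(self):
        d = frm_pmf(1, 2, 3)
        assert d.pmf[0] == pytest.approx(1 / 3)
        assert d.pmf[1] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("r_j, n", [(0, 4), (2, 4), (4, 4)])
    def test_full_row_forces_overlap(self, r_j, n):
        d = frm_pmf(n, r_j, n)
        assert d.pmf[r_j] == pytest.approx(1.0)

    def test_zero_degree_point_mass(self):
        assert frm_pmf(0, 3, 5).pmf[0] == pytest.approx(1.0)

    def test_rejects_degree_above_n(self):
        with pytest.raises(ValueError):
            frm_pmf(5, 1, 4)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_oracle_all_degree_pairs(self, n):
        """Matches enumeration of matrices with both focal row sums fixed."""
        for r_i in range(n + 1):
            for r_j in range(n + 1):
                want = enumerate_pair_pmf(
                    2, n, lambda M: M[0].sum() == r_i and M[1].sum() == r_j
                )
                got = frm_pmf(r_i, r_j, n).pmf
                assert np.abs(got - want).max() < ORACLE_TOL

    def test_mean_identity(self):
        for r_i, r_j, n in [(2, 3, 6), (1, 1, 4), (4, 5, 9)]:
            assert frm_pmf(r_i, r_j, n).mean() == pytest.approx(r_i * r_j / n)


class TestFCM:
    def test_example_table1_columns(self):
        d = fcm_pmf([1, 1, 2], 3)
        assert d.pmf[1] == pytest.approx(1 / 3)
        assert d.pmf[0] == pytest.approx(2 / 3)

    def test_full_columns_point_mass(self):
        d = fcm_pmf([3, 3], 3)
        assert d.pmf[2] == pytest.approx(1.0)

    def test_weight_one_columns_point_mass_zero(self):
        d = fcm_pmf([1, 0, 1], 4)
        assert d.pmf[0] == pytest.approx(1.0)

    def test_rejects_single_agent(self):
        with pytest.raises(ValueError):
            fcm_pmf([1], 1)

    @pytest.mark.parametrize("m, n", [(2, 3), (3, 3), (4, 3), (3, 4)])
    def test_oracle_all_column_margins(self, m, n):
        """Matches enumeration of matrices with every column sum fixed."""
        for c in itertools.product(range(m + 1), repeat=n):
            want = enumerate_pair_pmf(m, n, lambda M: tuple(M.sum(axis=0)) == c)
            got = fcm_pmf(list(c), m).pmf
            assert np.abs(got - want).max() < ORACLE_TOL

    def test_mean_identity(self):
        c = np.array([2, 3, 1, 4])
        m = 5
        q = c * (c - 1) / (m * (m - 1))
        assert fcm_pmf(c, m).mean() == pytest.approx(q.sum())


class TestFFM:
    def test_example_2x2_f2(self):
        d = ffm_pmf(2, 2, 2)
        assert d.pmf[1] == pytest.approx(1 / 3)
        assert d.pmf[0] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("m, n", [(2, 4), (3, 3), (4, 2)])
    def test_boundary_fills(self, m, n):
        assert ffm_pmf(m, n, 0).pmf[0] == pytest.approx(1.0)
        assert ffm_pmf(m, n, m * n).pmf[n] == pytest.approx(1.0)

    def test_rejects_fill_out_of_range(self):
        with pytest.raises(ValueError):
            ffm_pmf(2, 3, 7)

    @pytest.mark.parametrize("m, n", [(2, 2), (2, 3), (3, 3), (2, 6), (4, 3), (6, 2)])
    def test_oracle_all_fills(self, m, n):
        """Matches enumeration of all matrices with exactly f ones, every f."""
        for f in range(m * n + 1):
            want = enumerate_pair_pmf(m, n, lambda M: M.sum() == f)
            got = ffm_pmf(m, n, f).pmf
            assert np.abs(got - want).max() < 1e-11

    def test_mean_identity(self):
        for m, n, f in [(3, 4, 5), (5, 3, 7), (4, 4, 9)]:
            want = n * (f * (f - 1)) / (m * n * (m * n - 1))
            assert ffm_pmf(m, n, f).mean() == pytest.approx(want, rel=1e-9)


class TestSDSM:
    def test_equal_probability_rows_are_binomial(self):
        n = 6
        d = sdsm_pmf(np.full(n, 0.5), np.full(n, 0.5))
        from scipy.stats import binom

        assert d.pmf == pytest.approx(binom.pmf(np.arange(n + 1), n, 0.25), abs=1e-12)

    def test_zero_row_point_mass(self):
        d = sdsm_pmf(np.zeros(4), np.full(4, 0.7))
        assert d.pmf[0] == pytest.approx(1.0)

    def test_table1_bicm_pair_zero_probability(self):
        """Pair (1,2) of the worked example: pmf(0) from the BiCM probabilities."""
        row = np.array([0.216, 0.216, 0.568])
        d = sdsm_pmf(row, row)
        want = (1 - 0.216**2) ** 2 * (1 - 0.568**2)
        assert d.pmf[0] == pytest.approx(want, abs=1e-12)
        assert d.pmf[0] == pytest.approx(0.6159, abs=5e-4)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            sdsm_pmf(np.full(3, 0.5), np.full(4, 0.5))

    def test_matches_bernoulli_simulation(self, rng):
        """Exact pmf within 3 standard errors of 1e5 Monte-Carlo cell fills."""
        n, draws = 8, 100_000
        pi = rng.random(n)
        pj = rng.random(n)
        Bi = rng.random((draws, n)) < pi
        Bj = rng.random((draws, n)) < pj
        overlaps = (Bi & Bj).sum(axis=1)
        emp = np.bincount(overlaps, minlength=n + 1) / draws
        exact = sdsm_pmf(pi, pj).pmf
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / draws)
        assert (np.abs(emp - exact) <= 3 * se + 1e-9).all()


class TestUpperTail:
    def test_zero_weight_is_one(self):
        d = frm_pmf(2, 2, 4)
        assert upper_tail(d, 0) == 1.0

    def test_frm_example(self):
        assert upper_tail(frm_pmf(1, 2, 3), 1) == pytest.approx(2 / 3)

    def test_beyond_support_is_zero(self):
        assert upper_tail(frm_pmf(1, 2, 3), 4) == 0.0

    def test_monotone_in_weight(self):
        d = fcm_pmf([2, 3, 2, 1], 4)
        tails = [upper_tail(d, w) for w in range(d.support_max + 2)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestDistributionValidation:
    def test_large_deviation_rejected(self):
        with pytest.raises(ValueError, match="formula error"):
            EdgeNullDistribution(2, np.array([0.5, 0.3, 0.1]), "FRM")

    def test_small_deviation_renormalized(self):
        pmf = np.array([0.5, 0.5 - 2e-10, 0.0])
        d = EdgeNullDistribution(2, pmf, "FRM")
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-15)
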