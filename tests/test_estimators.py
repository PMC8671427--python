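import numpy as np
import pytest

from bibackbone.core import BipartiteMatrix
from bibackbone.estimators import (
    enumerate_fixed_margin_matrices,
    estimate_bicm,
    estimate_glm,
    estimate_rcf,
    estimator_accuracy,
    exact_cell_probabilities,
    gale_ryser_feasible,
)
from conftest import TABLE1_BICM, TABLE1_EXACT, TABLE1_MARGINS


class TestEnumeration:
    def test_table1_has_five_members(self):
        members = enumerate_fixed_margin_matrices(*TABLE1_MARGINS)
        assert len(members) == 5
        for mb in members:
            assert mb.values.sum(axis=1).tolist() == [1, 1, 2]
            assert mb.values.sum(axis=0).tolist() == [1, 1, 2]
        # each member exactly once
        keys = {mb.values.tobytes() for mb in members}
        assert len(keys) == 5

    def test_forced_single_row(self):
        members = enumerate_fixed_margin_matrices([4], [1, 1, 1, 1])
        assert len(members) == 1
        assert members[0].values.tolist() == [[1, 1, 1, 1]]

    def test_forced_column(self):
        members = enumerate_fixed_margin_matrices([1, 1], [2, 0])
        assert len(members) == 1
        assert members[0].values.tolist() == [[1, 0], [1, 0]]

    def test_infeasible_margins_empty(self):
        assert enumerate_fixed_margin_matrices([3, 0], [1, 1, 0]) == []

    def test_cell_cap_enforced(self):
        with pytest.raises(ValueError, match="capped"):
            enumerate_fixed_margin_matrices([1] * 8, [1] * 8, cell_cap=30)

    def test_matches_brute_force_count(self):
        import itertools

        for r, c in [([2, 1], [1, 1, 1]), ([2, 2], [2, 1, 1]), ([1, 1, 2], [2, 2])]:
            m, n = len(r), len(c)
            brute = sum(
                1
                for bits in itertools.product((0, 1), repeat=m * n)
                if (lambda M: M.sum(1).tolist() == r and M.sum(0).tolist() == c)(
                    np.array(bits).reshape(m, n)
                )
            )
            assert len(enumerate_fixed_margin_matrices(r, c)) == brute


class TestGaleRyser:
    def test_feasible_and_not(self):
        assert gale_ryser_feasible([1, 1, 2], [1, 1, 2])
        assert not gale_ryser_feasible([3, 3], [1, 1, 1])  # degree exceeds rows
        assert not gale_ryser_feasible([2, 2], [1, 1, 1])  # unequal sums


class TestExactProbabilities:
    def test_table1_desired_probabilities(self):
        exact = exact_cell_probabilities(*TABLE1_MARGINS)
        assert exact.probs == pytest.approx(TABLE1_EXACT, abs=1e-12)
        assert exact.estimator == "exact"

    def test_two_by_two_symmetric(self):
        exact = exact_cell_probabilities([1, 1], [1, 1])
        assert exact.probs == pytest.approx(np.full((2, 2), 0.5))

    def test_forced_full_row(self):
        exact = exact_cell_probabilities([3, 1], [2, 1, 1])
        assert exact.probs[0] == pytest.approx([1.0, 1.0, 1.0])

    def test_margins_reproduced_exactly(self):
        exact = exact_cell_probabilities([2, 1, 1], [1, 2, 1])
        assert exact.probs.sum(axis=1) == pytest.approx([2, 1, 1])
        assert exact.probs.sum(axis=0) == pytest.approx([1, 2, 1])


class TestRCF:
    def test_table1_values(self, table1_matrix):
        p = estimate_rcf(table1_matrix)
        deg_sorted = table1_matrix.values.sum(axis=1)
        # row/col degree products over f=4
        r = table1_matrix.values.sum(axis=1)
        c = table1_matrix.values.sum(axis=0)
        want = np.clip(np.outer(r, c) / 4, 0, 1)
        assert p.probs == pytest.approx(want)

    def test_regular_matrix_constant(self):
        B = BipartiteMatrix(np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]]))
        p = estimate_rcf(B)
        assert p.probs == pytest.approx(np.full((3, 3), 2 / 3))

    def test_truncation_at_one(self):
        B = BipartiteMatrix(np.array([[1, 1, 1], [1, 0, 0]]))
        p = estimate_rcf(B)
        assert p.probs.max() == 1.0

    def test_empty_matrix_zero(self):
        B = BipartiteMatrix(np.zeros((2, 2), dtype=int))
        assert estimate_rcf(B).probs == pytest.approx(np.zeros((2, 2)))


class TestGLM:
    def test_constant_outcome_returns_constant(self):
        B = BipartiteMatrix(np.ones((2, 3), dtype=int))
        p = estimate_glm(B, "logit")
        assert p.probs == pytest.approx(np.ones((2, 3)))

    def test_lpm_matches_normal_equations(self, table1_matrix):
        """OLS on the 9 cells, recomputed by hand via the normal equations."""
        from bibackbone.core import degree_summary

        deg = degree_summary(table1_matrix)
        r = np.repeat(deg.agent_degrees, 3).astype(float)
        c = np.tile(deg.artifact_degrees, 3).astype(float)
        X = np.column_stack([np.ones(9), r, c])
        y = table1_matrix.values.ravel().astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        want = np.clip(X @ beta, 0, 1).reshape(3, 3)
        got = estimate_glm(table1_matrix, "linear").probs
        assert got == pytest.approx(want, abs=1e-10)

    def test_logit_probabilities_in_range(self, table1_matrix):
        p = estimate_glm(table1_matrix, "logit", interaction=True)
        assert (p.probs >= 0).all() and (p.probs <= 1).all()


class TestBiCM:
    def test_table1_probabilities(self):
        p = estimate_bicm(agent_degrees=[1, 1, 2], artifact_degrees=[1, 1, 2])
        assert p.probs == pytest.approx(TABLE1_BICM, abs=5e-4)

    def test_table1_row_sums(self):
        p = estimate_bicm(agent_degrees=[1, 1, 2], artifact_degrees=[1, 1, 2])
        assert p.probs.sum(axis=1) == pytest.approx([1, 1, 2], abs=1e-8)
        assert p.probs.sum(axis=0) == pytest.approx([1, 1, 2], abs=1e-8)

    def test_regular_margins_exact(self):
        p = estimate_bicm(agent_degrees=[2] * 4, artifact_degrees=[2] * 4)
        assert p.probs == pytest.approx(np.full((4, 4), 0.5), abs=1e-9)

    def test_margin_constraints_random(self, rng):
        B = BipartiteMatrix((rng.random((12, 15)) < 0.3).astype(int))
        from bibackbone.core import degree_summary

        deg = degree_summary(B)
        p = estimate_bicm(B)
        assert p.probs.sum(axis=1) == pytest.approx(deg.agent_degrees, abs=1e-7)
        assert p.probs.sum(axis=0) == pytest.approx(deg.artifact_degrees, abs=1e-7)

    def test_permutation_equivariance(self, rng):
        r, c = [3, 1, 2, 2], [2, 2, 2, 1, 1]
        p = estimate_bicm(agent_degrees=r, artifact_degrees=c).probs
        perm_r = [1, 3, 2, 0]
        perm_c = [4, 0, 1, 3, 2]
        p_perm = estimate_bicm(
            agent_degrees=np.array(r)[perm_r], artifact_degrees=np.array(c)[perm_c]
        ).probs
        assert p_perm == pytest.approx(p[np.ix_(perm_r, perm_c)], abs=1e-9)

    def test_degenerate_margins_peeled(self):
        # full row and empty column handled by fixing cells, not diverging
        p = estimate_bicm(agent_degrees=[3, 1, 1], artifact_degrees=[2, 2, 1, 0])
        assert p.probs[0, :3] == pytest.approx([1, 1, 1])
        assert p.probs[:, 3] == pytest.approx([0, 0, 0])
        assert p.probs.sum(axis=1) == pytest.approx([3, 1, 1], abs=1e-8)

    def test_sparse_limit_matches_rcf(self, rng):
        """In the sparse regime BiCM degenerates to the r_i c_k / f product."""
        for _ in range(5):
            B = BipartiteMatrix((rng.random((10, 10)) < 0.08).astype(int))
            from bibackbone.core import degree_summary

            deg = degree_summary(B)
            if deg.fill == 0 or np.outer(
                deg.agent_degrees, deg.artifact_degrees
            ).max() / max(deg.fill, 1) > 0.1:
                continue
            diff = np.abs(estimate_rcf(B).probs - estimate_bicm(B).probs).max()
            assert diff <= 0.02


class TestAccuracy:
    def test_table1_bicm_mad(self):
        exact = exact_cell_probabilities(*TABLE1_MARGINS)
        bicm = estimate_bicm(agent_degrees=[1, 1, 2], artifact_degrees=[1, 1, 2])
        assert estimator_accuracy(bicm, exact) == pytest.approx(0.028, abs=1e-3)

    def test_zero_for_identical(self):
        exact = exact_cell_probabilities([1, 1], [1, 1])
        assert estimator_accuracy(exact, exact) == 0.0

    def test_constant_shift(self):
        from bibackbone.estimators import ProbabilityMatrix

        exact = exact_cell_probabilities(*TABLE1_MARGINS)
        shifted = ProbabilityMatrix(np.clip(exact.probs + 0.1, 0, 1), "exact")
        assert estimator_accuracy(shifted, exact) == pytest.approx(0.1, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        a = exact_cell_probabilities([1, 1], [1, 1])
        b = exact_cell_probabilities(*TABLE1_MARGINS)
        with pytest.raises(ValueError):
            estimator_accuracy(a, b)


def test_accuracy_ordering_bicm_beats_interaction_logit():
    """Over enumerable ensembles with 2-4 rows/columns, mean MAD: BiCM <= Logit <= Logit-I."""
    from bibackbone.studies import run_study1

    result = run_study1(max_len=4, cell_cap=16)
    means = result.rows.groupby("estimator")["value"].mean()
    assert means["BiCM"] <= means["Logit"] + 1e-9
    assert means["Logit"] <= means["Logit-I"] + 1e-9
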