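"""Cell-filling probability estimators for the stochastic degree sequence model.

The SDSM needs an m x n matrix of probabilities p*_ik approximating
Pr(B*_ik = 1) over the ensemble of binary matrices with the observed row and
column sums.  This module provides:

* exhaustive enumeration of that ensemble (small margins only), giving the
  exact target probabilities;
* the RCF arithmetic estimator p*_ik = r_i c_k / f (Chung-Lu style);
* regression estimators fit over all cells — a linear probability model and
  logistic regressions with or without a margin-interaction term;
* the bipartite configuration model (BiCM), the maximum-entropy solution
  p_ik = x_i y_k / (1 + x_i y_k) whose multipliers reproduce both margins;
* the mean-absolute-difference accuracy metric comparing an estimator to the
  exact probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .core import BipartiteMatrix, degree_summary

__all__ = [
    "ProbabilityMatrix",
    "enumerate_fixed_margin_matrices",
    "exact_cell_probabilities",
    "estimate_rcf",
    "estimate_glm",
    "estimate_bicm",
    "estimator_accuracy",
]

ENUMERATION_CELL_CAP = 30
_CLIP = 1e-10


@dataclass(frozen=True)
class ProbabilityMatrix:
    """m x n matrix of cell-filling probabilities with estimator metadata."""

    probs: np.ndarray
    estimator: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("probability matrix must be 2-D")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", np.clip(p, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape


def gale_ryser_feasible(agent_degrees, artifact_degrees) -> bool:
    """Whether a binary matrix with the given row and column sums exists."""
    r = np.sort(np.asarray(agent_degrees, dtype=np.int64))[::-1]
    c = np.asarray(artifact_degrees, dtype=np.int64)
    if r.sum() != c.sum():
        return False
    if (r < 0).any() or (c < 0).any():
        return False
    if r.size and r[0] > c.size:
        return False
    if c.size and c.max(initial=0) > r.size:
        return False
    for k in range(1, r.size + 1):
        if r[:k].sum() > np.minimum(c, k).sum():
            return False
    return True


def enumerate_fixed_margin_matrices(
    agent_degrees,
    artifact_degrees,
    cell_cap: int = ENUMERATION_CELL_CAP,
) -> list[BipartiteMatrix]:
    """Every binary matrix with exactly the given margins, each exactly once.

    Columns are filled left to right, choosing the rows of each column in
    lexicographic order and pruning branches whose residual margins fail the
    Gale-Ryser condition.  Intended for small ensembles (cell count capped).
    """
    r = np.asarray(agent_degrees, dtype=np.int64)
    c = np.asarray(artifact_degrees, dtype=np.int64)
    m, n = r.size, c.size
    if m * n > cell_cap:
        raise ValueError(f"enumeration capped at {cell_cap} cells, got {m * n}")
    if not gale_ryser_feasible(r, c):
        return []

    out: list[BipartiteMatrix] = []
    mat = np.zeros((m, n), dtype=np.int8)

    def column_subsets(residual: np.ndarray, size: int) -> Iterator[tuple[int, ...]]:
        eligible = [i for i in range(m) if residual[i] > 0]
        from itertools import combinations

        yield from combinations(eligible, size)

    def fill(col: int, residual: np.ndarray) -> None:
        if col == n:
            out.append(BipartiteMatrix(mat.copy()))
            return
        for rows in column_subsets(residual, int(c[col])):
            residual[list(rows)] -= 1
            if gale_ryser_feasible(residual, c[col + 1 :]):
                mat[list(rows), col] = 1
                fill(col + 1, residual)
                mat[list(rows), col] = 0
            residual[list(rows)] += 1

    fill(0, r.copy())
    return out


def exact_cell_probabilities(
    agent_degrees, artifact_degrees, cell_cap: int = ENUMERATION_CELL_CAP
) -> ProbabilityMatrix:
    """Pr(B*_ik = 1) over the fixed-margin ensemble, by exhaustive enumeration."""
    members = enumerate_fixed_margin_matrices(agent_degrees, artifact_degrees, cell_cap)
    if not members:
        raise ValueError("margins are infeasible; ensemble is empty")
    stack = np.stack([mb.values for mb in members]).astype(np.float64)
    return ProbabilityMatrix(
        stack.mean(axis=0), "exact", {"ensemble_size": len(members)}
    )


def estimate_rcf(B: BipartiteMatrix) -> ProbabilityMatrix:
    """Arithmetic estimator p*_ik = r_i c_k / f, truncated into [0, 1]."""
    deg = degree_summary(B)
    if deg.fill == 0:
        return ProbabilityMatrix(np.zeros(B.shape), "RCF")
    p = np.outer(deg.agent_degrees, deg.artifact_degrees) / deg.fill
    return ProbabilityMatrix(np.clip(p, 0.0, 1.0), "RCF")


def _design(deg, interaction: bool) -> np.ndarray:
    r = np.repeat(deg.agent_degrees, deg.artifact_degrees.size).astype(np.float64)
    c = np.tile(deg.artifact_degrees, deg.agent_degrees.size).astype(np.float64)
    cols = [np.ones_like(r), r, c]
    if interaction:
        cols.append(r * c)
    return np.column_stack(cols)


def estimate_glm(
    B: BipartiteMatrix, link: str = "logit", interaction: bool = False
) -> ProbabilityMatrix:
    """Regression estimator over all m*n cells with margin predictors.

    ``link='linear'`` fits ordinary least squares and clips the predictions
    into [0, 1] (linear probability model, LPM); ``link='logit'`` fits a
    binomial GLM by maximum likelihood (Logit, or Logit-I with the
    interaction term r_i * c_k).
    """
    import statsmodels.api as sm

    if link not in ("linear", "logit"):
        raise ValueError("link must be 'linear' or 'logit'")
    deg = degree_summary(B)
    y = B.values.astype(np.float64).ravel()
    name = {
        ("linear", False): "LPM",
        ("linear", True): "LPM-I",
        ("logit", False): "Logit",
        ("logit", True): "Logit-I",
    }[(link, interaction)]
    if y.min() == y.max():  # constant outcome: degenerate fit
        return ProbabilityMatrix(np.full(B.shape, y[0]), name)
    X = _design(deg, interaction)
    if link == "linear":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        meta = {"coef": beta}
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
                pred = np.asarray(fit.mu)
                meta = {"coef": np.asarray(fit.params)}
            except Exception:  # perfect separation or singular design
                warnings.warn(f"{name} fit degenerate; falling back to cell mean")
                pred = np.full_like(y, y.mean())
                meta = {"coef": None}
        if (pred < _CLIP).any() or (pred > 1 - _CLIP).any():
            pred = np.clip(pred, _CLIP, 1 - _CLIP)
    return ProbabilityMatrix(
        np.clip(pred, 0.0, 1.0).reshape(B.shape), name, meta
    )


def _bicm_solve(r, c, tol, max_iter):
    """Damped fixed point on the multipliers, compressed over distinct degrees."""
    f = r.sum()
    ur, r_inv, r_cnt = np.unique(r, return_inverse=True, return_counts=True)
    uc, c_inv, c_cnt = np.unique(c, return_inverse=True, return_counts=True)
    x = ur / np.sqrt(f)
    y = uc / np.sqrt(f)
    for it in range(max_iter):
        xy = np.outer(x, y)
        # margin equation r_i = sum_k x y / (1+xy)  =>  x = r_i / sum_k y/(1+xy)
        x_new = ur / ((y[None, :] / (1.0 + xy)) * c_cnt).sum(axis=1)
        y_new = uc / ((x[:, None] / (1.0 + xy)) * r_cnt[:, None]).sum(axis=0)
        x = 0.5 * x + 0.5 * x_new
        y = 0.5 * y + 0.5 * y_new
        xy = np.outer(x, y)
        p = xy / (1.0 + xy)
        res_r = np.abs((p * c_cnt).sum(axis=1) - ur).max()
        res_c = np.abs((p * r_cnt[:, None]).sum(axis=0) - uc).max()
        res = max(res_r, res_c)
        if res <= tol:
            return x[r_inv], y[c_inv], res, it + 1
    # dense, near-degenerate margins can make the fixed point crawl; polish
    # with damped Newton on the log-multipliers.  The margin residual is the
    # gradient of the concave log-likelihood, so Newton converges
    # quadratically; the product gauge direction makes the Hessian singular,
    # which lstsq absorbs.
    z = np.log(np.concatenate([x, y]))
    nr = ur.size

    def residual(zv):
        xy = np.outer(np.exp(zv[:nr]), np.exp(zv[nr:]))
        p = xy / (1.0 + xy)
        return np.concatenate(
            [(p * c_cnt).sum(axis=1) - ur, (p * r_cnt[:, None]).sum(axis=0) - uc]
        ), p

    g, p = residual(z)
    for _ in range(100):
        res = np.abs(g).max()
        if res <= tol:
            break
        q = p * (1.0 - p)
        J = np.block(
            [
                [np.diag((q * c_cnt).sum(axis=1)), q * c_cnt],
                [(q * r_cnt[:, None]).T, np.diag((q * r_cnt[:, None]).sum(axis=0))],
            ]
        )
        step, *_ = np.linalg.lstsq(J, g, rcond=None)
        scale = 1.0
        for _ in range(30):
            g_new, p_new = residual(z - scale * step)
            if np.abs(g_new).max() < res:
                z = z - scale * step
                g, p = g_new, p_new
                break
            scale /= 2
        else:
            break
    res = np.abs(g).max()
    if res > tol:
        raise RuntimeError(
            f"BiCM solve did not converge (residual {res:.3e} after "
            f"{max_iter} fixed-point iterations and Newton polish)"
        )
    return np.exp(z[:nr])[r_inv], np.exp(z[nr:])[c_inv], res, max_iter


def estimate_bicm(
    B: BipartiteMatrix | None = None,
    tol: float = 1e-10,
    max_iter: int = 5000,
    agent_degrees=None,
    artifact_degrees=None,
) -> ProbabilityMatrix:
    """Bipartite configuration model: maximum-entropy p_ik = x_i y_k / (1 + x_i y_k).

    The positive multipliers x_i, y_k are chosen so the expected margins
    match the observed row and column sums within ``tol``.  Degenerate
    margins (empty or full rows/columns) are peeled off and fixed to 0/1
    before solving, since their multipliers diverge.  Accepts either a
    matrix or explicit degree sequences.
    """
    if B is not None:
        deg = degree_summary(B)
        r = deg.agent_degrees.astype(np.float64)
        c = deg.artifact_degrees.astype(np.float64)
    else:
        r = np.asarray(agent_degrees, dtype=np.float64)
        c = np.asarray(artifact_degrees, dtype=np.float64)
        if r.sum() != c.sum():
            raise ValueError("margin sums must agree")
    m, n = r.size, c.size
    probs = np.full((m, n), np.nan)
    row_active = np.ones(m, dtype=bool)
    col_active = np.ones(n, dtype=bool)
    r_eff, c_eff = r.copy(), c.copy()
    # peel degenerate margins iteratively: a full column forces a 1 in every
    # active row, shifting the effective row margins, and vice versa
    while True:
        n_act = int(col_active.sum())
        m_act = int(row_active.sum())
        changed = False
        for i in np.nonzero(row_active)[0]:
            if r_eff[i] <= 0:
                probs[i, col_active] = 0.0
                row_active[i] = False
                changed = True
            elif r_eff[i] >= n_act:
                probs[i, col_active] = 1.0
                row_active[i] = False
                c_eff[col_active] -= 1
                changed = True
        n_act = int(col_active.sum())
        m_act = int(row_active.sum())
        for k in np.nonzero(col_active)[0]:
            if c_eff[k] <= 0:
                probs[row_active, k] = 0.0
                col_active[k] = False
                changed = True
            elif c_eff[k] >= m_act:
                probs[row_active, k] = 1.0
                col_active[k] = False
                r_eff[row_active] -= 1
                changed = True
        if not changed:
            break
    meta: dict = {}
    if row_active.any() and col_active.any():
        ra = r_eff[row_active]
        ca = c_eff[col_active]
        x, yv, res, iters = _bicm_solve(ra, ca, tol, max_iter)
        xy = np.outer(x, yv)
        sub = xy / (1.0 + xy)
        probs[np.ix_(row_active, col_active)] = sub
        x_full = np.full(m, np.nan)
        y_full = np.full(n, np.nan)
        x_full[row_active] = x
        y_full[col_active] = yv
        meta = {"x": x_full, "y": y_full, "residual": res, "iterations": iters}
    probs = np.nan_to_num(probs, nan=0.0)
    return ProbabilityMatrix(probs, "BiCM", meta)


def estimator_accuracy(p: ProbabilityMatrix, exact: ProbabilityMatrix) -> float:
    """Mean absolute difference between estimated and exact cell probabilities."""
    if p.shape != exact.shape:
        raise ValueError("probability matrices must have the same shape")
    return float(np.abs(p.probs - exact.probs).mean())
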