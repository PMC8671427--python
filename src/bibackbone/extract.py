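"""Backbone extraction: null-model p-values, the significance rule, and alpha sweeps.

An edge (i, j) is kept in the backbone at significance level alpha when the
upper-tail probability Pr(P*_ij >= P_ij) under the chosen null is strictly
below alpha / 2 — the upper half of a two-tailed test at level alpha.  The
lower tail (significantly sparse pairs) is not extracted.

For the exact models the p-values are computed analytically (FFM and FCM
share one distribution across pairs; FRM is hypergeometric per degree pair;
SDSM is a Poisson-binomial per pair of probability rows).  FDSM p-values
come from curveball Monte-Carlo and can be reused across an alpha sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from . import _speed
from .core import Backbone, BipartiteMatrix, Projection, degree_summary, jaccard, project
from .estimators import ProbabilityMatrix, estimate_bicm, estimate_glm, estimate_rcf
from .fdsm import FdsmResult, fdsm_null
from .null_models import fcm_pmf, ffm_pmf

__all__ = [
    "AlphaSweepResult",
    "pvalue_matrix",
    "extract_backbone",
    "backbone_from_pvalues",
    "global_threshold",
    "sweep_alpha",
]

MODELS = ("FFM", "FRM", "FCM", "SDSM", "FDSM")

_ESTIMATORS = {
    "bicm": lambda B: estimate_bicm(B),
    "rcf": estimate_rcf,
    "lpm": lambda B: estimate_glm(B, "linear", False),
    "logit": lambda B: estimate_glm(B, "logit", False),
    "logit-i": lambda B: estimate_glm(B, "logit", True),
}


@dataclass(frozen=True)
class AlphaSweepResult:
    """Jaccard similarity to a reference backbone along a grid of alpha values."""

    alphas: np.ndarray
    jaccards: np.ndarray
    best_alpha: float
    best_jaccard: float


def resolve_probabilities(
    B: BipartiteMatrix, estimator: str | ProbabilityMatrix = "bicm"
) -> ProbabilityMatrix:
    """SDSM cell probabilities from an estimator tag or a precomputed matrix."""
    if isinstance(estimator, ProbabilityMatrix):
        return estimator
    key = str(estimator).lower()
    if key not in _ESTIMATORS:
        raise ValueError(
            f"unknown SDSM estimator {estimator!r}; choose from {sorted(_ESTIMATORS)}"
        )
    return _ESTIMATORS[key](B)


def pvalue_matrix(
    B: BipartiteMatrix,
    model: str,
    estimator: str | ProbabilityMatrix = "bicm",
    fdsm_result: FdsmResult | None = None,
    fdsm_config: dict | None = None,
) -> np.ndarray:
    """Upper-tail probabilities Pr(P*_ij >= P_ij) for every agent pair.

    Returns a symmetric m x m matrix with ones on the diagonal.
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    deg = degree_summary(B)
    P = project(B).weights
    m, n = B.shape
    W = P.copy()
    np.fill_diagonal(W, 0)

    if model == "FDSM":
        if fdsm_result is None:
            fdsm_result = fdsm_null(B, **(fdsm_config or {}))
        pv = fdsm_result.upper_tail_p.copy()
    elif model == "FRM":
        # hypergeometric sf is vectorized over the (r_i, r_j, w) triples
        r = deg.agent_degrees
        pv = hypergeom.sf(W - 1, n, r[:, None], r[None, :])
    elif model in ("FFM", "FCM"):
        dist = (
            ffm_pmf(m, n, deg.fill)
            if model == "FFM"
            else fcm_pmf(deg.artifact_degrees, m)
        )
        tail = np.concatenate((np.cumsum(dist.pmf[::-1])[::-1], [0.0]))
        pv = tail[np.minimum(W, dist.support_max + 1)]
    else:  # SDSM
        probs = resolve_probabilities(B, estimator)
        if probs.shape != B.shape:
            raise ValueError("probability matrix shape must match the biadjacency")
        pv = _speed.pb_upper_tail_pairs(
            np.ascontiguousarray(probs.probs), W.astype(np.int64)
        )
    pv = np.minimum(pv, 1.0)
    np.fill_diagonal(pv, 1.0)
    return pv


def backbone_from_pvalues(
    pvalues: np.ndarray,
    alpha: float,
    model: str,
    agent_labels: list[str] | None = None,
) -> Backbone:
    """Apply the retention rule Pr(P*_ij >= P_ij) < alpha / 2."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    edges = (pvalues < alpha / 2).astype(np.int8)
    edges = np.minimum(edges, edges.T)
    np.fill_diagonal(edges, 0)
    return Backbone(edges, model, alpha, list(agent_labels or []))


def extract_backbone(
    B: BipartiteMatrix,
    model: str,
    alpha: float,
    estimator: str | ProbabilityMatrix = "bicm",
    fdsm_result: FdsmResult | None = None,
    fdsm_config: dict | None = None,
) -> Backbone:
    """Extract the significance backbone of the projection of ``B``."""
    pv = pvalue_matrix(B, model, estimator, fdsm_result, fdsm_config)
    return backbone_from_pvalues(pv, alpha, model.upper(), B.agent_labels)


def global_threshold(P: Projection, T: int = 0) -> Backbone:
    """Keep every pair whose co-occurrence weight strictly exceeds ``T``."""
    if T < 0:
        raise ValueError("threshold must be nonnegative")
    edges = (P.weights > T).astype(np.int8)
    np.fill_diagonal(edges, 0)
    return Backbone(edges, "threshold", float(T), list(P.agent_labels))


def sweep_alpha(
    B: BipartiteMatrix,
    model: str,
    alpha_grid: np.ndarray,
    reference: Backbone,
    estimator: str | ProbabilityMatrix = "bicm",
    fdsm_result: FdsmResult | None = None,
    fdsm_config: dict | None = None,
) -> AlphaSweepResult:
    """Jaccard similarity to ``reference`` across a grid of significance levels.

    The null p-values do not depend on alpha, so they are computed once and
    thresholded per grid point.  Ties in the argmax resolve to the smallest
    alpha.
    """
    grid = np.asarray(alpha_grid, dtype=np.float64)
    if grid.size == 0 or (grid <= 0).any() or (grid >= 1).any():
        raise ValueError("alpha grid must be nonempty with values in (0, 1)")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("alpha grid must be strictly increasing")
    pv = pvalue_matrix(B, model, estimator, fdsm_result, fdsm_config)
    jaccards = np.empty(grid.size)
    for idx, alpha in enumerate(grid):
        bb = backbone_from_pvalues(pv, float(alpha), model.upper(), B.agent_labels)
        jaccards[idx] = jaccard(bb, reference)
    best_idx = int(np.argmax(jaccards))  # argmax takes the first (smallest) alpha
    return AlphaSweepResult(grid, jaccards, float(grid[best_idx]), float(jaccards[best_idx]))
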