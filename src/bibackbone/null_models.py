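"""Exact null distributions of the co-occurrence weight P*_ij.

Each ensemble fixes a different feature of the observed biadjacency matrix
and induces a distribution for the random co-occurrence count of a fixed
agent pair:

* FFM (fixed fill) — uniform over all m x n binary matrices with exactly f
  ones; the pair's overlap follows a distribution related to Jacobi
  polynomials, evaluated here by exact summation.
* FRM (fixed rows) — agent degrees fixed exactly; the overlap of two
  independent uniform artifact subsets of sizes r_i, r_j is hypergeometric.
* FCM (fixed columns) — artifact degrees fixed exactly; each column of
  weight c_k covers a fixed agent pair with probability
  c_k(c_k-1) / (m(m-1)), so the overlap is Poisson-binomial.
* SDSM (stochastic degree sequence) — independent Bernoulli cells with
  probabilities p*_ik; the overlap is Poisson-binomial with per-artifact
  probability p*_ik p*_jk.

The Poisson-binomial pmf is computed by exact sequential convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

__all__ = [
    "EdgeNullDistribution",
    "poisson_binomial_pmf",
    "frm_pmf",
    "fcm_pmf",
    "ffm_pmf",
    "sdsm_pmf",
    "upper_tail",
]

_SUM_WARN = 1e-12
_SUM_FAIL = 1e-9


@dataclass(frozen=True)
class EdgeNullDistribution:
    """Pmf of the random co-occurrence P*_ij on support {0..n} under a named ensemble."""

    support_max: int
    pmf: np.ndarray
    model: str
    pair: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=np.float64)
        if pmf.ndim != 1 or pmf.size != self.support_max + 1:
            raise ValueError("pmf must have length support_max + 1")
        if (pmf < -1e-15).any():
            raise ValueError("pmf entries must be nonnegative")
        pmf = np.clip(pmf, 0.0, None)
        dev = abs(pmf.sum() - 1.0)
        if dev > _SUM_FAIL:
            raise ValueError(f"pmf sums to 1 {dev:.3e} away from 1; formula error")
        if dev > _SUM_WARN:
            pmf = pmf / pmf.sum()
        object.__setattr__(self, "pmf", pmf)

    def mean(self) -> float:
        return float(np.dot(np.arange(self.support_max + 1), self.pmf))

    def var(self) -> float:
        t = np.arange(self.support_max + 1)
        mu = self.mean()
        return float(np.dot((t - mu) ** 2, self.pmf))


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(probs[k]) variables.

    Sequential convolution, O(n^2); returns a vector of length n + 1.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1:
        raise ValueError("probs must be a vector")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    n = probs.size
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for k, p in enumerate(probs):
        # after k+1 terms the support is 0..k+1
        pmf[1 : k + 2] = pmf[1 : k + 2] * (1.0 - p) + pmf[: k + 1] * p
        pmf[0] *= 1.0 - p
    return pmf


def frm_pmf(r_i: int, r_j: int, n: int) -> EdgeNullDistribution:
    """Overlap of two independent uniform artifact subsets of sizes r_i, r_j from n.

    Hypergeometric: pmf[t] = C(r_i, t) C(n - r_i, r_j - t) / C(n, r_j).
    """
    if not (0 <= r_i <= n and 0 <= r_j <= n):
        raise ValueError("degrees must lie in [0, n]")
    t = np.arange(n + 1)
    pmf = hypergeom.pmf(t, n, r_i, r_j)
    return EdgeNullDistribution(n, pmf, "FRM")


def fcm_pmf(artifact_degrees: np.ndarray, m: int) -> EdgeNullDistribution:
    """Pair overlap when artifact degrees are fixed and each column is placed uniformly.

    A column of weight c_k covers both members of a fixed agent pair with
    probability q_k = c_k (c_k - 1) / (m (m - 1)); the overlap is the
    Poisson-binomial sum of these indicators, identical for all pairs.
    """
    c = np.asarray(artifact_degrees, dtype=np.int64)
    if m < 2:
        raise ValueError("FCM requires at least two agents")
    if (c < 0).any() or (c > m).any():
        raise ValueError("artifact degrees must lie in [0, m]")
    q = c * (c - 1) / (m * (m - 1))
    return EdgeNullDistribution(c.size, poisson_binomial_pmf(q), "FCM")


def _log_binom(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def ffm_pmf(m: int, n: int, f: int) -> EdgeNullDistribution:
    """Pair overlap under the uniform ensemble of m x n binary matrices with f ones.

    Conditions on the number K of ones landing in the two focal rows, which
    is hypergeometric over the mn cells; given K, the K ones fall uniformly
    over the 2 x n focal block, and t both-covered columns with K - 2t
    singleton cells can be arranged C(n, t) C(n - t, K - 2t) 2^(K - 2t)
    ways.  Evaluated with log-binomials, O(n^2) overall; identical for all
    pairs.
    """
    if m < 2:
        raise ValueError("FFM requires at least two agents")
    if not (0 <= f <= m * n):
        raise ValueError("fill must lie in [0, m*n]")
    log_pmf = np.full(n + 1, -np.inf)
    ks = np.arange(0, min(2 * n, f) + 1)
    # log Pr(K ones in the focal 2n cells) — hypergeometric
    log_hyp = (
        _log_binom(2 * n, ks)
        + _log_binom((m - 2) * n, f - ks)
        - _log_binom(m * n, f)
    )
    for t in range(n + 1):
        valid = ks >= 2 * t
        if not valid.any():
            continue
        k_v = ks[valid]
        s = k_v - 2 * t  # singleton cells in the focal block
        log_arr = (
            _log_binom(n, t)
            + _log_binom(n - t, s)
            + s * np.log(2.0)
            - _log_binom(2 * n, k_v)
        )
        terms = log_hyp[valid] + log_arr
        if np.isneginf(terms).all():
            continue
        log_pmf[t] = logsumexp(terms)
    pmf = np.exp(log_pmf)
    return EdgeNullDistribution(n, pmf, "FFM")


def sdsm_pmf(p_row_i: np.ndarray, p_row_j: np.ndarray) -> EdgeNullDistribution:
    """Pair overlap when cells fill independently with probabilities p*_ik.

    Poisson-binomial with per-artifact probability p*_ik p*_jk.
    """
    pi = np.asarray(p_row_i, dtype=np.float64)
    pj = np.asarray(p_row_j, dtype=np.float64)
    if pi.shape != pj.shape or pi.ndim != 1:
        raise ValueError("probability rows must be vectors of equal length")
    if (pi < 0).any() or (pi > 1).any() or (pj < 0).any() or (pj > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return EdgeNullDistribution(pi.size, poisson_binomial_pmf(pi * pj), "SDSM")


def upper_tail(d: EdgeNullDistribution, w: int) -> float:
    """Pr(P*_ij >= w) under the distribution ``d``; equals 1 at w = 0."""
    if w < 0:
        raise ValueError("observed weight must be nonnegative")
    if w > d.support_max:
        return 0.0
    if w == 0:
        return 1.0
    # sum the (smaller) upper tail directly for accuracy at extreme weights
    return min(1.0, float(d.pmf[w:].sum()))
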