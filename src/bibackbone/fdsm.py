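"""Monte-Carlo fixed degree sequence model via curveball sampling.

The FDSM null fixes both degree sequences exactly; its edge-weight
distribution has no closed form and is approximated by sampling matrices
uniformly from the fixed-margin ensemble.  Sampling uses curveball trades:
pick two rows, pool the artifacts held by exactly one of them, and randomly
re-partition that pool between the rows, preserving every degree.  A single
Markov chain is run with a burn-in and a fixed number of trades between
retained samples; each retained sample is projected and compared against the
observed projection to accumulate empirical upper-tail p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _speed
from .core import BipartiteMatrix, project

__all__ = ["FdsmResult", "curveball_trade", "curveball_sample", "fdsm_null"]


@dataclass(frozen=True)
class FdsmResult:
    """Empirical FDSM null: counts and proportions of samples with P*_ij >= P_ij."""

    upper_tail_p: np.ndarray
    counts: np.ndarray
    samples_used: int
    seed: int
    edge_weight_samples: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def pair_distribution(self, i: int, j: int) -> np.ndarray:
        """Sampled co-occurrence weights for a tracked pair (i, j)."""
        key = (min(i, j), max(i, j))
        if key not in self.edge_weight_samples:
            raise KeyError(f"pair {key} was not tracked during sampling")
        return self.edge_weight_samples[key]


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def curveball_trade(
    B: BipartiteMatrix, row_a: int, row_b: int, rng: np.random.Generator
) -> BipartiteMatrix:
    """One curveball trade between two rows; every degree is preserved.

    The artifacts held by exactly one of the rows are pooled and randomly
    re-partitioned, keeping each row's count.  With no tradable artifacts the
    matrix is returned unchanged.
    """
    if row_a == row_b:
        raise ValueError("rows must be distinct")
    values = B.values.copy()
    ra, rb = values[row_a], values[row_b]
    only_a = np.nonzero((ra == 1) & (rb == 0))[0]
    only_b = np.nonzero((ra == 0) & (rb == 1))[0]
    if only_a.size == 0 or only_b.size == 0:
        return B
    pool = np.concatenate((only_a, only_b))
    rng.shuffle(pool)
    values[row_a, pool] = 0
    values[row_b, pool] = 0
    values[row_a, pool[: only_a.size]] = 1
    values[row_b, pool[only_a.size :]] = 1
    return BipartiteMatrix(values, list(B.agent_labels), list(B.artifact_labels))


def curveball_sample(
    B: BipartiteMatrix, n_trades: int, rng: np.random.Generator
) -> BipartiteMatrix:
    """Apply ``n_trades`` curveball trades between uniformly chosen row pairs."""
    if n_trades < 0:
        raise ValueError("n_trades must be nonnegative")
    if n_trades == 0:
        return B
    values = B.values.copy()
    _speed.curveball_trades(values, int(n_trades), _child_seed(rng))
    return BipartiteMatrix(values, list(B.agent_labels), list(B.artifact_labels))


def default_trades_per_sample(m: int) -> int:
    return 5 * m


def default_burn_in(m: int) -> int:
    return 10 * m


def fdsm_null(
    B: BipartiteMatrix,
    n_samples: int = 1000,
    trades_per_sample: int | None = None,
    burn_in: int | None = None,
    rng: np.random.Generator | int | None = None,
    track_pairs: list[tuple[int, int]] | None = None,
) -> FdsmResult:
    """Empirical FDSM upper-tail p-values from one thinned curveball chain.

    Parameters
    ----------
    n_samples : number of retained ensemble samples (1000 by default).
    trades_per_sample : trades between retained samples; default 5 * m.
    burn_in : trades before the first sample; default 10 * m.
    rng : Generator or integer seed; all randomness flows from it.
    track_pairs : agent pairs whose sampled weights are kept in full.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    m = B.n_agents
    if trades_per_sample is None:
        trades_per_sample = default_trades_per_sample(m)
    if burn_in is None:
        burn_in = default_burn_in(m)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seed = _child_seed(rng)
    chain_rng = np.random.default_rng(seed)

    P_obs = project(B).weights
    values = B.values.copy()
    counts = np.zeros((m, m), dtype=np.int64)
    tracked = {}
    if track_pairs:
        tracked = {
            (min(i, j), max(i, j)): np.empty(n_samples, dtype=np.int64)
            for i, j in track_pairs
        }

    _speed.curveball_trades(values, int(burn_in), _child_seed(chain_rng))
    fvals = values.astype(np.float64)
    for s in range(n_samples):
        _speed.curveball_trades(values, int(trades_per_sample), _child_seed(chain_rng))
        np.copyto(fvals, values)
        P_star = (fvals @ fvals.T).astype(np.int64)
        counts += P_star >= P_obs
        for (i, j), arr in tracked.items():
            arr[s] = P_star[i, j]

    np.fill_diagonal(counts, n_samples)
    upper = counts / n_samples
    return FdsmResult(upper, counts, n_samples, seed, tracked)
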