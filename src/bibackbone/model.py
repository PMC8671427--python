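"""Model/Results interface for backbone extraction.

`BipartiteBackbone` wraps a biadjacency matrix together with the choice of
null ensemble and, for the SDSM, the cell-probability estimator.  `fit()`
computes every pair's upper-tail p-value under that null and returns a
`BackboneResults` carrying the p-values, the retained edge set at the
requested significance level, and diagnostics; re-thresholding at other
levels reuses the fitted p-values.

Example
-------
>>> import numpy as np
>>> from bibackbone import BipartiteBackbone
>>> B = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 1]])
>>> res = BipartiteBackbone(B, null="frm").fit(alpha=0.1)
>>> res.backbone.n_edges
0
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Backbone, BipartiteMatrix, Projection, degree_summary, project
from .estimators import ProbabilityMatrix
from .extract import (
    MODELS,
    AlphaSweepResult,
    backbone_from_pvalues,
    pvalue_matrix,
    resolve_probabilities,
    sweep_alpha,
)
from .fdsm import FdsmResult, fdsm_null

__all__ = ["BipartiteBackbone", "BackboneResults"]


class BipartiteBackbone:
    """Significance-backbone model for a bipartite projection.

    Parameters
    ----------
    B : BipartiteMatrix or binary array-like
        Biadjacency matrix; rows are agents, columns artifacts.
    null : {'ffm', 'frm', 'fcm', 'sdsm', 'fdsm'}
        Null ensemble for the edge-weight test.
    estimator : str or ProbabilityMatrix
        SDSM cell-probability estimator ('bicm', 'rcf', 'lpm', 'logit',
        'logit-i') or a precomputed probability matrix.  Ignored by other
        nulls.
    fdsm_samples, fdsm_trades, fdsm_burn_in, seed
        Monte-Carlo controls for the FDSM null.
    """

    def __init__(
        self,
        B,
        null: str = "sdsm",
        estimator: str | ProbabilityMatrix = "bicm",
        fdsm_samples: int = 1000,
        fdsm_trades: int | None = None,
        fdsm_burn_in: int | None = None,
        seed: int | None = None,
    ) -> None:
        self.data = B if isinstance(B, BipartiteMatrix) else BipartiteMatrix(np.asarray(B))
        null_up = null.upper()
        if null_up not in MODELS:
            raise ValueError(f"unknown null {null!r}; choose from {MODELS}")
        self.null = null_up
        self.estimator = estimator
        self.fdsm_samples = fdsm_samples
        self.fdsm_trades = fdsm_trades
        self.fdsm_burn_in = fdsm_burn_in
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "BipartiteBackbone":
        """Build from a DataFrame whose index labels agents and columns artifacts."""
        B = BipartiteMatrix(
            frame.to_numpy(),
            [str(x) for x in frame.index],
            [str(x) for x in frame.columns],
        )
        return cls(B, **kwargs)

    @classmethod
    def from_edgelist(cls, pairs, **kwargs) -> "BipartiteBackbone":
        """Build from (agent, artifact) co-membership pairs."""
        frame = pd.DataFrame(pairs, columns=["agent", "artifact"])
        table = pd.crosstab(frame["agent"], frame["artifact"]).clip(upper=1)
        return cls.from_dataframe(table, **kwargs)

    def fit(self, alpha: float = 0.05) -> "BackboneResults":
        """Compute all pairwise p-values and threshold at ``alpha``."""
        fdsm_result = None
        if self.null == "FDSM":
            fdsm_result = fdsm_null(
                self.data,
                n_samples=self.fdsm_samples,
                trades_per_sample=self.fdsm_trades,
                burn_in=self.fdsm_burn_in,
                rng=self.seed,
            )
        probs = None
        if self.null == "SDSM":
            probs = resolve_probabilities(self.data, self.estimator)
        pv = pvalue_matrix(
            self.data,
            self.null,
            probs if probs is not None else self.estimator,
            fdsm_result=fdsm_result,
        )
        return BackboneResults(self, pv, alpha, fdsm_result, probs)


class BackboneResults:
    """Fitted backbone: p-values, retained edges, and diagnostics."""

    def __init__(
        self,
        model: BipartiteBackbone,
        pvalues: np.ndarray,
        alpha: float,
        fdsm_result: FdsmResult | None = None,
        probabilities: ProbabilityMatrix | None = None,
    ) -> None:
        self.model = model
        self.pvalues = pvalues
        self.alpha = alpha
        self.fdsm_result = fdsm_result
        self.probabilities = probabilities
        self.backbone = backbone_from_pvalues(
            pvalues, alpha, model.null, model.data.agent_labels
        )

    @property
    def projection(self) -> Projection:
        return project(self.model.data)

    def at_alpha(self, alpha: float) -> Backbone:
        """Re-threshold the fitted p-values at a different significance level."""
        return backbone_from_pvalues(
            self.pvalues, alpha, self.model.null, self.model.data.agent_labels
        )

    def sweep(self, alpha_grid, reference: Backbone) -> AlphaSweepResult:
        """Jaccard similarity to ``reference`` along an alpha grid (p-values reused)."""
        return sweep_alpha(
            self.model.data,
            self.model.null,
            alpha_grid,
            reference,
            estimator=self.probabilities
            if self.probabilities is not None
            else self.model.estimator,
            fdsm_result=self.fdsm_result,
        )

    def edges(self) -> pd.DataFrame:
        """Retained edges as a tidy frame with their p-values and weights."""
        P = self.projection.weights
        labels = self.model.data.agent_labels
        rows = [
            {
                "agent_i": labels[i],
                "agent_j": labels[j],
                "weight": int(P[i, j]),
                "pvalue": float(self.pvalues[i, j]),
            }
            for i, j in sorted(self.backbone.edge_set())
        ]
        return pd.DataFrame(rows, columns=["agent_i", "agent_j", "weight", "pvalue"])

    def summary(self) -> str:
        deg = degree_summary(self.model.data)
        m, n = self.model.data.shape
        bb = self.backbone
        lines = [
            "          Bipartite Projection Backbone",
            "=" * 48,
            f"Null ensemble:        {self.model.null}",
            f"Significance level:   alpha = {self.alpha:g} (rule: p < alpha/2)",
            f"Agents x artifacts:   {m} x {n}",
            f"Bipartite fill:       {deg.fill} ({deg.fill / (m * n):.4f} density)",
            f"Projection pairs:     {m * (m - 1) // 2}",
            f"Edges retained:       {bb.n_edges} ({bb.density:.4f} density)",
        ]
        if self.model.null == "SDSM" and self.probabilities is not None:
            meta = self.probabilities.metadata
            lines.append(f"SDSM estimator:       {self.probabilities.estimator}")
            if "residual" in meta:
                lines.append(f"BiCM margin residual: {meta['residual']:.2e}")
        if self.fdsm_result is not None:
            lines.append(f"FDSM samples:         {self.fdsm_result.samples_used}")
            lines.append(f"FDSM chain seed:      {self.fdsm_result.seed}")
        lines.append("=" * 48)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<BackboneResults null={self.model.null} alpha={self.alpha:g} "
            f"edges={self.backbone.n_edges}>"
        )
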