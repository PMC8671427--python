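"""Core containers and graph-level metrics for bipartite backbone analysis.

A bipartite network links *agents* (rows) to *artifacts* (columns) through a
binary biadjacency matrix ``B``.  Its projection ``P = B @ B.T`` counts, for
every pair of agents, the artifacts they share; the *backbone* is the binary
network that keeps only pairs whose co-occurrence count is statistically
significant under a chosen null ensemble.

This module holds the data types shared across the package plus the two
backbone-comparison metrics used throughout the simulation studies: the
Jaccard index between backbones' edge sets and the Newman-Girvan modularity
of a backbone with respect to a fixed node partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "BipartiteMatrix",
    "DegreeSummary",
    "Projection",
    "Backbone",
    "NodePartition",
    "project",
    "degree_summary",
    "jaccard",
    "modularity",
]


def _default_labels(prefix: str, count: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(count)]


@dataclass(frozen=True)
class BipartiteMatrix:
    """Binary m x n biadjacency matrix with agent (row) and artifact (column) labels."""

    values: np.ndarray
    agent_labels: list[str] = field(default_factory=list)
    artifact_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("biadjacency matrix must be 2-D with m, n >= 1")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(f"non-binary entry at cell ({bad[0]}, {bad[1]})")
        object.__setattr__(self, "values", values)
        m, n = values.shape
        agents = list(self.agent_labels) or _default_labels("a", m)
        artifacts = list(self.artifact_labels) or _default_labels("t", n)
        if len(agents) != m or len(artifacts) != n:
            raise ValueError("label lengths must match matrix dimensions")
        if len(set(agents)) != m or len(set(artifacts)) != n:
            raise ValueError("labels must be unique within each mode")
        object.__setattr__(self, "agent_labels", agents)
        object.__setattr__(self, "artifact_labels", artifacts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_agents(self) -> int:
        return self.values.shape[0]

    @property
    def n_artifacts(self) -> int:
        return self.values.shape[1]

    def transpose(self) -> "BipartiteMatrix":
        """Swap the agent and artifact modes."""
        return BipartiteMatrix(
            self.values.T.copy(), list(self.artifact_labels), list(self.agent_labels)
        )


@dataclass(frozen=True)
class DegreeSummary:
    """Row sums r_i, column sums c_k, and total fill f of a biadjacency matrix."""

    agent_degrees: np.ndarray
    artifact_degrees: np.ndarray
    fill: int

    def __post_init__(self) -> None:
        r = np.asarray(self.agent_degrees, dtype=np.int64)
        c = np.asarray(self.artifact_degrees, dtype=np.int64)
        object.__setattr__(self, "agent_degrees", r)
        object.__setattr__(self, "artifact_degrees", c)
        if r.sum() != self.fill or c.sum() != self.fill:
            raise ValueError("degree sums must both equal the fill")


@dataclass(frozen=True)
class Projection:
    """Symmetric agent-by-agent co-occurrence weights P = B @ B.T.

    The diagonal stores the agent degrees; downstream operations ignore it.
    """

    weights: np.ndarray
    agent_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("projection must be square")
        if not np.array_equal(w, w.T):
            raise ValueError("projection must be symmetric")
        object.__setattr__(self, "weights", w)
        labels = list(self.agent_labels) or _default_labels("a", w.shape[0])
        if len(labels) != w.shape[0]:
            raise ValueError("label length must match matrix dimension")
        object.__setattr__(self, "agent_labels", labels)

    @property
    def n_agents(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class Backbone:
    """Binary symmetric edge-retention matrix P' with zero diagonal."""

    edges: np.ndarray
    model: str
    alpha: float
    agent_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int8)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("backbone must be square")
        if not np.array_equal(e, e.T):
            raise ValueError("backbone must be symmetric")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("backbone entries must be 0/1")
        e = e.copy()
        np.fill_diagonal(e, 0)
        object.__setattr__(self, "edges", e)
        labels = list(self.agent_labels) or _default_labels("a", e.shape[0])
        if len(labels) != e.shape[0]:
            raise ValueError("label length must match matrix dimension")
        object.__setattr__(self, "agent_labels", labels)

    @property
    def n_agents(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.edges.sum()) // 2

    @property
    def density(self) -> float:
        m = self.n_agents
        possible = m * (m - 1) // 2
        return self.n_edges / possible if possible else 0.0

    def edge_set(self) -> set[tuple[int, int]]:
        """Unordered retained pairs as (i, j) index tuples with i < j."""
        ii, jj = np.nonzero(np.triu(self.edges, k=1))
        return {(int(i), int(j)) for i, j in zip(ii, jj)}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_agents))
        g.add_edges_from(self.edge_set())
        return g


@dataclass(frozen=True)
class NodePartition:
    """Assignment of each agent to a group identifier."""

    groups: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.groups)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("partition must be a nonempty vector")
        object.__setattr__(self, "groups", g)

    @property
    def n_agents(self) -> int:
        return self.groups.size

    def communities(self) -> list[set[int]]:
        return [
            set(np.nonzero(self.groups == label)[0].tolist())
            for label in np.unique(self.groups)
        ]


def project(B: BipartiteMatrix) -> Projection:
    """Project a bipartite matrix onto its agent mode, P = B @ B.T."""
    values = B.values.astype(np.int64)
    return Projection(values @ values.T, list(B.agent_labels))


def degree_summary(B: BipartiteMatrix) -> DegreeSummary:
    """Row sums, column sums, and fill of the biadjacency matrix."""
    r = B.values.sum(axis=1, dtype=np.int64)
    c = B.values.sum(axis=0, dtype=np.int64)
    return DegreeSummary(r, c, int(r.sum()))


def jaccard(b1: Backbone, b2: Backbone) -> float:
    """Jaccard index of two backbones' edge sets over unordered agent pairs.

    Two empty backbones are identical edge sets and score 1; an empty
    backbone against a nonempty one scores 0.
    """
    if b1.n_agents != b2.n_agents:
        raise ValueError("backbones must share the same agent set")
    e1 = np.triu(b1.edges, k=1).astype(bool)
    e2 = np.triu(b2.edges, k=1).astype(bool)
    union = int(np.sum(e1 | e2))
    if union == 0:
        return 1.0
    return int(np.sum(e1 & e2)) / union


def modularity(b: Backbone, part: NodePartition) -> float:
    """Newman-Girvan modularity Q of a backbone for a fixed agent partition.

    Q = sum_g [ L_g / L - (K_g / 2L)^2 ] over groups g, with L the total
    number of backbone edges, L_g the intra-group edges, and K_g the summed
    degree of group g.  An empty backbone returns 0 with a warning so that
    parameter sweeps never abort.
    """
    if b.n_agents != part.n_agents:
        raise ValueError("partition length must match agent count")
    if b.n_edges == 0:
        warnings.warn("modularity of an empty backbone is undefined; returning 0")
        return 0.0
    return float(nx.community.modularity(b.to_networkx(), part.communities()))


def backbone_from_edges(
    edge_list: Sequence[tuple[int, int]],
    n_agents: int,
    model: str = "manual",
    alpha: float = 0.0,
    agent_labels: Sequence[str] | None = None,
) -> Backbone:
    """Build a Backbone from unordered index pairs (convenience constructor)."""
    edges = np.zeros((n_agents, n_agents), dtype=np.int8)
    for i, j in edge_list:
        edges[i, j] = edges[j, i] = 1
    return Backbone(edges, model, alpha, list(agent_labels or []))
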