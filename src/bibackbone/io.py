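"""Reading biadjacency matrices and writing backbones.

Supported input formats:

* ``dense-csv`` — header row of artifact labels, first column of agent
  labels, 0/1 cells;
* ``edgelist-tsv`` — two tab-separated columns (agent, artifact), one
  co-membership per line; duplicates collapse with a warning;
* ``matrix-market`` — coordinate pattern/integer format with 1-based
  indices; any nonzero becomes a 1.

Backbones are written as a lexicographically ordered edge list or as a
dense CSV, with a comment header recording the model and significance
level.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import Backbone, BipartiteMatrix

__all__ = ["read_bipartite", "write_backbone", "read_backbone_edges", "FORMATS"]

FORMATS = ("dense-csv", "edgelist-tsv", "matrix-market")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "dense-csv"
    if suffix in (".tsv", ".txt"):
        return "edgelist-tsv"
    if suffix in (".mtx", ".mm"):
        return "matrix-market"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_bipartite(
    path, format: str | None = None, transpose: bool = False
) -> BipartiteMatrix:
    """Read a binary biadjacency matrix; rows are agents unless ``transpose``."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    if fmt == "dense-csv":
        frame = pd.read_csv(path, index_col=0)
        values = frame.to_numpy()
        bad = np.argwhere(~np.isin(values, (0, 1)))
        if bad.size:
            i, k = bad[0]
            raise ValueError(
                f"non-binary value at agent {frame.index[i]!r}, "
                f"artifact {frame.columns[k]!r}"
            )
        B = BipartiteMatrix(
            values, [str(x) for x in frame.index], [str(x) for x in frame.columns]
        )
    elif fmt == "edgelist-tsv":
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["agent", "artifact"], dtype=str,
            comment="#",
        )
        if frame.duplicated().any():
            warnings.warn("duplicate edges in edge list collapsed to single 1s")
            frame = frame.drop_duplicates()
        agents = sorted(frame["agent"].unique())
        artifacts = sorted(frame["artifact"].unique())
        a_idx = {a: i for i, a in enumerate(agents)}
        t_idx = {t: k for k, t in enumerate(artifacts)}
        values = np.zeros((len(agents), len(artifacts)), dtype=np.int8)
        for a, t in frame.itertuples(index=False):
            values[a_idx[a], t_idx[t]] = 1
        B = BipartiteMatrix(values, agents, artifacts)
    else:  # matrix-market
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = (np.asarray(mat) != 0).astype(np.int8)
        B = BipartiteMatrix(values)
    return B.transpose() if transpose else B


def write_backbone(b: Backbone, path, format: str = "edgelist-tsv") -> None:
    """Write a backbone with a comment header recording model and alpha."""
    path = Path(path)
    header = f"# backbone model={b.model} alpha={b.alpha:g} agents={b.n_agents}\n"
    if format == "edgelist-tsv":
        with open(path, "w") as fh:
            fh.write(header)
            pairs = sorted(
                (b.agent_labels[i], b.agent_labels[j]) for i, j in b.edge_set()
            )
            for a, c in pairs:
                fh.write(f"{a}\t{c}\n")
    elif format == "dense-csv":
        frame = pd.DataFrame(b.edges, index=b.agent_labels, columns=b.agent_labels)
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh)
    else:
        raise ValueError(f"unknown backbone format {format!r}")


def read_backbone_edges(path) -> list[tuple[str, str]]:
    """Read the (agent, agent) pairs of an edge-list backbone file."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, c = line.split("\t")
            pairs.append((a, c))
    return pairs
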