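"""Scripted replications of the four evaluation studies.

Each study is a configurable simulation harness returning a tidy table of
per-replicate metrics plus per-condition summaries:

1. accuracy of SDSM cell-probability estimators against exhaustive
   enumeration of small fixed-margin ensembles;
2. statistical power — how the SDSM significance level must be relaxed for
   its backbone to match an FDSM backbone at alpha = 0.05;
3. backbone similarity to FDSM across agent/artifact degree-distribution
   shapes;
4. recovery of a planted two-group community structure, measured by
   modularity of the extracted backbone against the planted partition.

Replicate counts and matrix sizes default to desk scale and scale up to the
full design purely through arguments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BipartiteMatrix, jaccard, modularity
from .estimators import (
    enumerate_fixed_margin_matrices,
    estimate_bicm,
    estimate_glm,
    estimate_rcf,
    estimator_accuracy,
    exact_cell_probabilities,
    gale_ryser_feasible,
)
from .extract import backbone_from_pvalues, pvalue_matrix, sweep_alpha
from .fdsm import fdsm_null
from .synthetic import (
    PlantedConfig,
    generate_bipartite,
    generate_gawc_like,
    generate_planted,
)

__all__ = [
    "StudyResult",
    "run_study1",
    "run_study2",
    "run_study3",
    "run_study4",
    "SHAPE_NAMES",
    "DEFAULT_ALPHA_GRID",
]

SHAPE_NAMES = ("right", "left", "uniform", "constant", "normal")
DEFAULT_ALPHA_GRID = np.round(np.arange(0.01, 0.3001, 0.005), 4)


@dataclass(frozen=True)
class StudyResult:
    """Tidy per-replicate rows and per-condition summary of one study run."""

    study: str
    rows: pd.DataFrame
    summary: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def _summarize(rows: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    grouped = rows.groupby(by + ["metric"], sort=False)["value"]
    out = grouped.agg(
        mean="mean",
        p10=lambda s: s.quantile(0.10),
        p90=lambda s: s.quantile(0.90),
        n="count",
    )
    return out.reset_index()


# ---------------------------------------------------------------- study 1


def margin_universe(max_len: int = 5, cell_cap: int = 25) -> list[tuple[tuple, tuple]]:
    """Feasible (agent margins, artifact margins) pairs with short sequences.

    Sequences have length 2..max_len, every degree in 1..len(other side) - 1
    (degenerate full/empty nodes excluded), equal sums, Gale-Ryser feasible,
    deduplicated up to row/column permutation by sorting descending.
    """
    pairs = []
    for m in range(2, max_len + 1):
        for n in range(2, max_len + 1):
            if m * n > cell_cap:
                continue
            rows_opts = [
                tuple(sorted(combo, reverse=True))
                for combo in itertools.combinations_with_replacement(
                    range(1, n), m
                )
            ]
            cols_opts = [
                tuple(sorted(combo, reverse=True))
                for combo in itertools.combinations_with_replacement(
                    range(1, m), n
                )
            ]
            for r in sorted(set(rows_opts)):
                for c in sorted(set(cols_opts)):
                    if sum(r) != sum(c):
                        continue
                    if gale_ryser_feasible(r, c):
                        pairs.append((r, c))
    return pairs


def run_study1(
    max_len: int = 5,
    cell_cap: int = 25,
    member_cap: int = 30,
    min_ensemble: int = 2,
) -> StudyResult:
    """Estimator accuracy over all enumerable short-margin ensembles.

    For every margin pair, the ensemble is enumerated exhaustively and each
    estimator's mean absolute difference from the exact cell probabilities
    is recorded.  Estimators that depend only on the margins (RCF, BiCM,
    LPM, Logit) are computed once; the interaction logit depends on the
    realized matrix, so its MAD is averaged over up to ``member_cap``
    evenly-spaced ensemble members.
    """
    records = []
    for r, c in margin_universe(max_len, cell_cap):
        members = enumerate_fixed_margin_matrices(r, c, cell_cap)
        if len(members) < min_ensemble:
            continue
        exact = exact_cell_probabilities(r, c, cell_cap)
        rep = members[0]
        estimates = {
            "RCF": estimate_rcf(rep),
            "LPM": estimate_glm(rep, "linear", False),
            "Logit": estimate_glm(rep, "logit", False),
            "BiCM": estimate_bicm(rep),
        }
        mads = {
            name: estimator_accuracy(est, exact) for name, est in estimates.items()
        }
        idx = np.unique(
            np.linspace(0, len(members) - 1, min(member_cap, len(members))).astype(int)
        )
        mads["Logit-I"] = float(
            np.mean(
                [
                    estimator_accuracy(
                        estimate_glm(members[i], "logit", True), exact
                    )
                    for i in idx
                ]
            )
        )
        for name, mad in mads.items():
            records.append(
                {
                    "agent_margins": str(list(r)),
                    "artifact_margins": str(list(c)),
                    "ensemble_size": len(members),
                    "estimator": name,
                    "metric": "mad",
                    "value": mad,
                }
            )
    rows = pd.DataFrame(records)
    return StudyResult("s1_accuracy", rows, _summarize(rows, ["estimator"]))


# ---------------------------------------------------------------- study 2


def run_study2(
    n_networks: int = 10,
    alpha_grid: np.ndarray | None = None,
    seed: int | None = None,
    fdsm_samples: int = 1000,
    fdsm_alpha: float = 0.05,
) -> StudyResult:
    """SDSM alpha sweep against FDSM backbones on right-tailed 196x100 networks."""
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_networks):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        B = generate_gawc_like(rep_rng)
        fdsm = fdsm_null(B, n_samples=fdsm_samples, rng=rep_rng)
        reference = backbone_from_pvalues(fdsm.upper_tail_p, fdsm_alpha, "FDSM")
        sweep = sweep_alpha(B, "SDSM", alpha_grid, reference)
        j_at_005 = float(
            sweep.jaccards[np.argmin(np.abs(np.asarray(alpha_grid) - 0.05))]
        )
        for metric, value in (
            ("best_alpha", sweep.best_alpha),
            ("best_jaccard", sweep.best_jaccard),
            ("jaccard_at_0.05", j_at_005),
        ):
            records.append(
                {"replicate": rep, "seed": rep_seed, "metric": metric, "value": value}
            )
    rows = pd.DataFrame(records)
    rows["condition"] = "gawc_like"
    return StudyResult("s2_power", rows, _summarize(rows, ["condition"]))


# ---------------------------------------------------------------- study 3


def run_study3(
    reps_per_condition: int = 10,
    alpha: float = 0.05,
    m: int = 100,
    n: int = 100,
    density: float = 0.1,
    agent_shapes=SHAPE_NAMES,
    artifact_shapes=SHAPE_NAMES,
    sdsm_alpha_grid: np.ndarray | None = None,
    seed: int | None = None,
    fdsm_samples: int = 1000,
) -> StudyResult:
    """Jaccard similarity of each exact-null backbone to the FDSM backbone.

    For every combination of agent and artifact degree shapes, generates
    networks, extracts FFM/FRM/FCM/SDSM backbones at ``alpha`` and an FDSM
    backbone at ``alpha``, and records the Jaccard of each alternative
    against FDSM.  When ``sdsm_alpha_grid`` is given, also sweeps the SDSM
    significance level and records the per-network best alpha and best
    Jaccard.
    """
    rng = np.random.default_rng(seed)
    records = []
    for a_shape in agent_shapes:
        for t_shape in artifact_shapes:
            for rep in range(reps_per_condition):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                rep_rng = np.random.default_rng(rep_seed)
                B = generate_bipartite(m, n, density, a_shape, t_shape, rep_rng)
                fdsm = fdsm_null(B, n_samples=fdsm_samples, rng=rep_rng)
                reference = backbone_from_pvalues(fdsm.upper_tail_p, alpha, "FDSM")
                base = {
                    "agent_shape": a_shape,
                    "artifact_shape": t_shape,
                    "replicate": rep,
                    "seed": rep_seed,
                }
                for model in ("FFM", "FRM", "FCM", "SDSM"):
                    pv = pvalue_matrix(B, model)
                    bb = backbone_from_pvalues(pv, alpha, model)
                    records.append(
                        {**base, "metric": f"jaccard_{model}", "value": jaccard(bb, reference)}
                    )
                    if model == "SDSM" and sdsm_alpha_grid is not None:
                        sweep = sweep_alpha(B, "SDSM", sdsm_alpha_grid, reference)
                        records.append(
                            {**base, "metric": "sdsm_best_alpha", "value": sweep.best_alpha}
                        )
                        records.append(
                            {**base, "metric": "sdsm_best_jaccard", "value": sweep.best_jaccard}
                        )
    rows = pd.DataFrame(records)
    return StudyResult(
        "s3_similarity", rows, _summarize(rows, ["agent_shape", "artifact_shape"])
    )


# ---------------------------------------------------------------- study 4


def run_study4(
    W_grid=(0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8),
    reps: int = 5,
    m: int = 200,
    n: int = 1000,
    density: float = 0.1,
    alpha: float = 0.05,
    sdsm_liberal_alpha: float = 0.13,
    seed: int | None = None,
    fdsm_samples: int = 1000,
    models=("FFM", "FRM", "FCM", "SDSM", "FDSM"),
) -> StudyResult:
    """Community recovery: modularity of backbones against a planted partition.

    Generates planted two-block matrices at each within-group fraction W,
    extracts backbones at ``alpha`` (plus SDSM at the liberal level), and
    records each backbone's Newman modularity with respect to the planted
    agent groups.
    """
    rng = np.random.default_rng(seed)
    records = []
    for W in W_grid:
        if not 0.5 <= W < 1:
            raise ValueError("W values must lie in [0.5, 1)")
    for W in W_grid:
        for rep in range(reps):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            rep_rng = np.random.default_rng(rep_seed)
            cfg = PlantedConfig(m, n, density, float(W))
            B, partition = generate_planted(cfg, "right", "right", rep_rng)
            base = {"W": float(W), "replicate": rep, "seed": rep_seed}
            for model in models:
                if model == "FDSM":
                    fdsm = fdsm_null(B, n_samples=fdsm_samples, rng=rep_rng)
                    pv = fdsm.upper_tail_p
                else:
                    pv = pvalue_matrix(B, model)
                bb = backbone_from_pvalues(pv, alpha, model)
                records.append(
                    {**base, "metric": f"Q_{model}", "value": modularity(bb, partition)}
                )
                if model == "SDSM":
                    bb_lib = backbone_from_pvalues(pv, sdsm_liberal_alpha, model)
                    records.append(
                        {
                            **base,
                            "metric": f"Q_SDSM_{sdsm_liberal_alpha:g}",
                            "value": modularity(bb_lib, partition),
                        }
                    )
    rows = pd.DataFrame(records)
    return StudyResult("s4_community", rows, _summarize(rows, ["W"]))
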