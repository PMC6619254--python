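"""Scoring detections against planted ground truth.

Confusion counts run over the unique off-diagonal edges (i < j) of the
positives matrix P and ground-truth mask T:

    TP = #(T=1 and P=1)    FP = #(T=0 and P=1)
    FN = #(T=1 and P=0)    TN = #(T=0 and P=0)

    sensitivity = TP / (TP + FN)      specificity = TN / (TN + FP)
    false positive rate = 1 - specificity

A family-wise error is the presence of one or more false-positive edges
anywhere in the matrix (indicator 0/1 per comparison); rates are means
over replicate comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import matrix_to_edge_vector
from .synthetic import GroundTruthMask


@dataclass
class ConfusionSummary:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def sensitivity(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.TN + self.FP
        return self.TN / denom if denom else float("nan")

    @property
    def false_positive_rate(self) -> float:
        return 1.0 - self.specificity

    @property
    def fwe_indicator(self) -> int:
        return int(self.FP >= 1)

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _as_mask_matrix(T: GroundTruthMask | np.ndarray) -> np.ndarray:
    return T.T if isinstance(T, GroundTruthMask) else np.asarray(T)


def confusion_counts(P: np.ndarray, T: GroundTruthMask | np.ndarray) -> ConfusionSummary:
    """Confusion counts of a binary positives matrix against ground truth.

    Both arguments are symmetric binary N x N matrices (or a
    :class:`~tfnbs.synthetic.GroundTruthMask`); counting is over the
    N(N-1)/2 unique edges, so TP+FP+FN+TN = N(N-1)/2.
    """
    Tm = _as_mask_matrix(T)
    P = np.asarray(P)
    if P.shape != Tm.shape:
        raise ValueError("positives matrix and ground truth differ in shape")
    p = matrix_to_edge_vector(P) != 0
    t = matrix_to_edge_vector(Tm) != 0
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return ConfusionSummary(TP=tp, FP=fp, FN=fn, TN=tn)


def per_component_sensitivity(P: np.ndarray, T: GroundTruthMask) -> list[float]:
    """Fraction of each ground-truth component's edges marked positive."""
    P = np.asarray(P)
    out = []
    for comp in T.components:
        hit = sum(1 for a, b in comp.edges if P[a, b])
        out.append(hit / comp.extent)
    return out


class SpuriousNeighborProbability(NamedTuple):
    linear: float  # expected-count approximation: candidate_edges * p
    exact: float   # 1 - (1 - p)^candidate_edges


def spurious_neighbor_probability(
    component_nodes: int,
    N: int,
    per_edge_prob: float,
    candidate_edges: int,
) -> SpuriousNeighborProbability:
    """Probability that a spurious suprathreshold edge touches a component.

    In a fully connected noisy matrix, each node of a true-effect
    component can be linked by chance to any of the other nodes, so a
    component spanning more nodes exposes more candidate edges on which
    an isolated noise effect would merge with it.  Given the per-edge
    probability of a spurious effect and the number of candidate
    neighbouring edges, returns the linear expected-count approximation
    ``candidate_edges * per_edge_prob`` (which grows linearly with the
    component's node count) alongside the exact complement probability.
    The candidate count is supplied by the caller, not derived.
    """
    if not 0.0 <= per_edge_prob <= 1.0:
        raise ValueError("per_edge_prob must be a probability")
    if candidate_edges < 0:
        raise ValueError("candidate_edges must be non-negative")
    if component_nodes < 1 or N < component_nodes:
        raise ValueError("need 1 <= component_nodes <= N")
    linear = candidate_edges * per_edge_prob
    exact = 1.0 - (1.0 - per_edge_prob) ** candidate_edges
    return SpuriousNeighborProbability(linear=linear, exact=exact)


def aggregate_grid(
    records: pd.DataFrame | Iterable[dict],
    grouping: Sequence[str],
) -> pd.DataFrame:
    """Mean test properties per parameter-grid cell.

    ``records`` holds one row per simulated comparison with at least the
    columns ``sensitivity``, ``specificity``, ``false_positive_rate``,
    ``fwe`` and ``fp`` plus the grouping keys (method, parameters,
    scenario...).  Returns one row per group with the arithmetic means,
    the number of replicates, and the mean FP count among comparisons
    with at least one false positive (NaN when none had any).
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no records to aggregate")

    rows = []
    for keys, grp in df.groupby(list(grouping), dropna=False):
        if grp.empty:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"empty group {keys}; omitted", stacklevel=2)
            continue
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(grouping, keys))
        row["n"] = len(grp)
        for col in ("sensitivity", "specificity", "false_positive_rate"):
            if col in grp:
                row[col] = float(grp[col].mean())
        if "fwe" in grp:
            row["fwe_rate"] = float(grp["fwe"].mean())
        if "fp" in grp:
            with_fp = grp.loc[grp["fp"] >= 1, "fp"]
            row["mean_fp_given_any"] = float(with_fp.mean()) if len(with_fp) else math.nan
        comp_cols = [c for c in grp.columns if c.startswith("comp_sens_")]
        for col in comp_cols:
            row[col] = float(grp[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)
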