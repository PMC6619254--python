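"""The threshold-free enhancement transform.

Every edge's raw statistic is replaced by an enhanced score

    score(i, j) = sum_h  e_h(i, j)^E * h^H        (optionally * dh)

where the sum runs over a ladder of thresholds h0, h0+dh, ... up to the
matrix maximum, and ``e_h(i, j)`` is the extent (edge count) of the
connected component containing edge (i, j) at threshold h (zero when the
edge is subthreshold).  ``E`` and ``H`` are the extension and height
enhancement exponents; ``dh`` is fixed at ``max(stat) / n_intervals``
from the observed statistic matrix and reused for all permuted matrices,
whose ladders run to their own maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import tfnbs_sweep
from .cohort import EdgeStatMatrix, edge_vector_to_matrix, triu_edges

#: tolerance deciding whether stat_max is itself a ladder rung
_LADDER_RTOL = 1e-12


@dataclass(frozen=True)
class TfnbsParams:
    """Enhancement parameters of the transform.

    Attributes
    ----------
    E
        Extension enhancement exponent (> 0).  Larger values reward
        membership in large connected components more strongly.
    H
        Height enhancement exponent (> 0).  Larger values weight strong
        statistics more heavily, making the test more conservative.
    h0
        Base of the thresholding ladder (default 0).
    n_intervals
        Number of ladder intervals used to derive ``dh`` from the observed
        statistic maximum (default 100, i.e. dh = max/100 and 101 rungs).
    multiply_dh
        Multiply accumulated scores by ``dh`` (integral normalisation).
        Off by default: ``dh`` is constant across the observed and all
        permuted matrices, so the factor cancels from every p value and
        the plain per-rung sum matches common threshold-free practice.
    """

    E: float
    H: float
    h0: float = 0.0
    n_intervals: int = 100
    multiply_dh: bool = False

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("enhancement exponents E and H must be positive")
        if self.h0 < 0:
            raise ValueError("ladder base h0 must be non-negative")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")


@dataclass
class ScoreMatrix:
    """Symmetric matrix of enhanced edge scores."""

    values: np.ndarray
    params: TfnbsParams
    dh_used: float

    @property
    def node_count(self) -> int:
        return self.values.shape[0]

    def edge_values(self) -> np.ndarray:
        iu = np.triu_indices(self.node_count, k=1)
        return self.values[iu]

    def max(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0


def compute_dh(stat: EdgeStatMatrix, n_intervals: int = 100) -> float:
    """Ladder interval: the statistic maximum divided by ``n_intervals``.

    Returns 0 for an all-zero matrix (degenerate input; a warning is
    emitted and any downstream transform yields all-zero scores).
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    mx = stat.max()
    if mx <= 0:
        warnings.warn(
            "all-zero statistic matrix: dh = 0 (degenerate input)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return mx / n_intervals


def threshold_ladder(stat_max: float, dh: float, h0: float = 0.0) -> np.ndarray:
    """Ascending ladder of thresholds ``h0, h0+dh, ...`` up to ``stat_max``.

    The top rung is the largest multiple of ``dh`` (offset by ``h0``) not
    exceeding ``stat_max``; a relative tolerance of 1e-12 makes
    ``stat_max`` itself a rung when it is an exact multiple, so an
    observed matrix with ``dh = max/100`` and ``h0 = 0`` is thresholded
    at exactly 101 steps.  A permuted matrix keeps the observed ``dh``
    and gets a ladder truncated or extended to its own maximum.
    """
    if dh <= 0:
        raise ValueError("dh must be positive (degenerate statistic matrix?)")
    if h0 < 0:
        raise ValueError("h0 must be non-negative")
    n_steps = int(np.floor((stat_max + _LADDER_RTOL * abs(stat_max) - h0) / dh))
    if n_steps < 0:
        return np.array([h0])
    return h0 + dh * np.arange(n_steps + 1, dtype=float)


def tfnbs_transform(stat: EdgeStatMatrix, params: TfnbsParams, dh: float) -> ScoreMatrix:
    """Apply the threshold-free enhancement to a raw statistic matrix.

    Scores are accumulated per edge per rung with an incremental
    union-find sweep; the result equals the naive computation that
    materialises the full ``N x N x t`` stack of per-threshold component
    extents.  An all-zero matrix or ``dh = 0`` yields all-zero scores.
    """
    n = stat.node_count
    mx = stat.max()
    if dh < 0:
        raise ValueError("dh must be non-negative")
    if dh == 0 or mx <= params.h0:
        return ScoreMatrix(np.zeros((n, n)), params=params, dh_used=dh)

    ii, jj = triu_edges(n)
    w = np.ascontiguousarray(stat.values[ii, jj], dtype=float)
    heights = threshold_ladder(mx, dh, params.h0)
    raw = tfnbs_sweep(
        ii.astype(np.int64),
        jj.astype(np.int64),
        w,
        heights,
        np.array([params.E], dtype=float),
        np.array([params.H], dtype=float),
        n,
    )[0]
    if params.multiply_dh:
        raw = raw * dh
    return ScoreMatrix(edge_vector_to_matrix(raw, n), params=params, dh_used=dh)
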