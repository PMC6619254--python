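"""Edge-wise two-group F statistics.

The group comparison at every edge is the one-way two-group GLM F test,
identical to the square of the pooled-variance two-sample t statistic,
with degrees of freedom ``(1, S - 2)``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .cohort import CohortStack, EdgeStatMatrix, edge_vector_to_matrix

# relative tolerance used to declare a within-group sum of squares zero
_ZERO_SS_RTOL = 1e-12


class FStatEngine:
    """Vectorised two-group F statistics over a fixed data matrix.

    Precomputes per-edge totals so that the statistic under any relabeling
    costs a single matrix-vector product; used heavily by the permutation
    engines where the same subjects are relabeled thousands of times.
    """

    def __init__(self, edge_data: np.ndarray):
        # edge_data: (S, m) per-subject edge values
        self.X = np.asarray(edge_data, dtype=float)
        self.S = self.X.shape[0]
        self._colsum = self.X.sum(axis=0)
        self._ss_tot = np.einsum("ij,ij->j", self.X, self.X)

    def f_values(self, labels: np.ndarray) -> np.ndarray:
        """F statistic per edge for a 0/1 label vector."""
        b = np.asarray(labels, dtype=float)
        n1 = b.sum()
        n0 = self.S - n1
        if n0 == 0 or n1 == 0:
            raise ValueError("both groups must be non-empty")
        sum1 = b @ self.X
        sum0 = self._colsum - sum1
        m0 = sum0 / n0
        m1 = sum1 / n1
        diff = m0 - m1
        bss = (n0 * n1 / self.S) * diff * diff
        wss = self._ss_tot - n0 * m0 * m0 - n1 * m1 * m1
        df2 = self.S - 2
        tol = _ZERO_SS_RTOL * np.maximum(self._ss_tot, 1.0)
        degenerate = wss <= tol
        with np.errstate(divide="ignore", invalid="ignore"):
            f = bss * df2 / wss
        if np.any(degenerate):
            # zero within-group variance: F := 0 if between-group variance is
            # also zero, else the largest finite statistic (keeps the
            # thresholding ladder finite)
            zero_between = bss <= tol
            f = np.where(degenerate & zero_between, 0.0, f)
            blown = degenerate & ~zero_between
            if np.any(blown):
                warnings.warn(
                    "zero within-group variance with non-zero group difference; "
                    "capping F at the largest finite value",
                    RuntimeWarning,
                    stacklevel=2,
                )
                f = np.where(blown, np.finfo(float).max, f)
        # guard against tiny negative values from cancellation
        return np.maximum(f, 0.0)


def group_f_statistics(cohort: CohortStack) -> EdgeStatMatrix:
    """Edge-wise two-group F statistics for a cohort.

    Returns an :class:`~tfnbs.cohort.EdgeStatMatrix` with degrees of
    freedom ``(1, S - 2)``.  Only the unique edges (i < j) are computed;
    the matrix is mirrored and the diagonal fixed at zero.
    """
    engine = FStatEngine(cohort.edge_data())
    f = engine.f_values(cohort.labels)
    return EdgeStatMatrix(
        edge_vector_to_matrix(f, cohort.node_count),
        df1=1,
        df2=cohort.n_subjects - 2,
    )


def f_threshold_to_p(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution at ``f``.

    Maps a component-defining F threshold onto its edge-wise p value;
    e.g. F = 4 with df (1, 198) corresponds to p ~ 0.0469.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if f < 0:
        raise ValueError("F statistics are non-negative")
    return float(stats.f.sf(f, df1, df2))
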