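"""Containers for subject-level connectivity data.

A cohort is a stack of per-subject symmetric ``N x N`` connectivity
matrices together with a binary group label per subject.  All inference
in this package operates on the ``N(N-1)/2`` unique off-diagonal edges;
the diagonal carries no connection and is ignored everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: maximum allowed asymmetry |M - M.T| in a subject matrix
SYMMETRY_TOL = 1e-9


def triu_edges(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the unique edges (i < j) of an ``n_nodes`` graph."""
    return np.triu_indices(n_nodes, k=1)


def edge_vector_to_matrix(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Expand a length ``N(N-1)/2`` edge vector into a symmetric zero-diagonal matrix.

    The vector is taken in row-major upper-triangle order, the same order
    produced by :func:`numpy.triu_indices`.
    """
    values = np.asarray(values, dtype=float)
    mat = np.zeros((n_nodes, n_nodes), dtype=float)
    iu = np.triu_indices(n_nodes, k=1)
    if values.shape != iu[0].shape:
        raise ValueError(
            f"expected {iu[0].size} edge values for {n_nodes} nodes, got {values.size}"
        )
    mat[iu] = values
    mat.T[iu] = values
    return mat


def matrix_to_edge_vector(mat: np.ndarray) -> np.ndarray:
    """Extract the upper-triangle (i < j) edge vector from a square matrix."""
    mat = np.asarray(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


@dataclass
class CohortStack:
    """Stack of per-subject connectivity matrices with binary group labels.

    Parameters
    ----------
    subjects
        Array of shape ``(S, N, N)``; each slice is a symmetric
        connectivity matrix.  Diagonals are ignored downstream.
    labels
        Integer array of shape ``(S,)`` with values 0 and 1 assigning each
        subject to one of two groups.  Both groups must be non-empty and
        ``S >= 4`` so that the two-group F statistic has positive
        denominator degrees of freedom.
    validate
        Skip the (O(S N^2)) invariant checks when False; used internally
        by the permutation engine where matrices are never modified.
    """

    subjects: np.ndarray
    labels: np.ndarray
    validate: bool = True
    _edge_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.validate:
            self._check_invariants()

    def _check_invariants(self) -> None:
        if self.subjects.ndim != 3 or self.subjects.shape[1] != self.subjects.shape[2]:
            raise ValueError("subjects must be a (S, N, N) stack of square matrices")
        if self.labels.shape != (self.subjects.shape[0],):
            raise ValueError("labels must supply exactly one group label per subject")
        values = set(np.unique(self.labels).tolist())
        if not values <= {0, 1}:
            raise ValueError(f"labels must be binary (0/1), got values {sorted(values)}")
        if len(values) != 2:
            raise ValueError("both groups must be non-empty")
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects for a two-group comparison")
        asym = np.abs(self.subjects - np.transpose(self.subjects, (0, 2, 1))).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"subject matrices must be symmetric within {SYMMETRY_TOL}; "
                f"max asymmetry {asym:g}"
            )

    @property
    def n_subjects(self) -> int:
        return self.subjects.shape[0]

    @property
    def node_count(self) -> int:
        return self.subjects.shape[1]

    @property
    def n_edges(self) -> int:
        n = self.node_count
        return n * (n - 1) // 2

    @property
    def group_sizes(self) -> tuple[int, int]:
        """(size of group 0, size of group 1)."""
        n1 = int(self.labels.sum())
        return self.n_subjects - n1, n1

    def edge_data(self) -> np.ndarray:
        """Per-subject edge values, shape ``(S, N(N-1)/2)`` in upper-triangle order."""
        if self._edge_cache is None:
            iu = np.triu_indices(self.node_count, k=1)
            self._edge_cache = np.ascontiguousarray(self.subjects[:, iu[0], iu[1]])
        return self._edge_cache

    def with_labels(self, labels: np.ndarray) -> "CohortStack":
        """Copy of the cohort with a different label vector (matrices shared)."""
        new = CohortStack(self.subjects, labels, validate=False)
        new._edge_cache = self._edge_cache
        return new


@dataclass
class EdgeStatMatrix:
    """Symmetric non-negative matrix of raw edge-wise group test statistics.

    Holds the F statistic of the two-group comparison at every unique edge
    together with its degrees of freedom ``(df1, df2)``.  The diagonal is
    fixed at zero.
    """

    values: np.ndarray
    df1: int
    df2: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("statistic matrix must be square")
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("statistic matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("statistic matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("F statistics must be non-negative")

    @property
    def node_count(self) -> int:
        return self.values.shape[0]

    def edge_values(self) -> np.ndarray:
        """Upper-triangle edge vector of the statistics."""
        return matrix_to_edge_vector(self.values)

    @classmethod
    def from_edge_values(cls, values: np.ndarray, n_nodes: int, df1: int, df2: int) -> "EdgeStatMatrix":
        return cls(edge_vector_to_matrix(values, n_nodes), df1=df1, df2=df2)

    def max(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0
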