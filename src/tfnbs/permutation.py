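"""Group-relabeling permutation inference for enhanced edge scores.

Statistical significance is established by shuffling group membership
across subjects: at each permutation the full raw statistic matrix is
recomputed from the relabeled cohort (preserving the topological
dependencies among edges) and re-enhanced.  Family-wise-corrected edge
p values compare each observed edge score with the null distribution of
the connectome-wide maximum score; uncorrected p values compare each
edge with its own null distribution.

Each permutation's labels are a deterministic function of
``(seed, perm_index)`` only, so results do not depend on execution
order and identical configurations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterator

import numpy as np

from ._kernels import tfnbs_sweep
from .cohort import CohortStack, EdgeStatMatrix, edge_vector_to_matrix, triu_edges
from .edge_stats import FStatEngine
from .transform import ScoreMatrix, TfnbsParams, threshold_ladder


@dataclass
class PValueMatrix:
    """Symmetric matrix of edge-wise permutation p values in (0, 1].

    The diagonal (no connection) is reported as 1.
    """

    values: np.ndarray
    correction: str  # "fwe" | "uncorrected"
    n_perm: int
    seed: int

    @property
    def node_count(self) -> int:
        return self.values.shape[0]

    def significant_edges(self, alpha: float = 0.05) -> np.ndarray:
        """Binary symmetric matrix of edges with p <= alpha."""
        sig = (self.values <= alpha).astype(int)
        np.fill_diagonal(sig, 0)
        return sig


@dataclass
class TfnbsInferenceResult:
    """Observed scores plus corrected and uncorrected permutation p values."""

    scores: ScoreMatrix
    fwe: PValueMatrix
    uncorrected: PValueMatrix
    null_max: np.ndarray  # null distribution of the connectome-wide maximum


def permutation_labels(labels: np.ndarray, seed: int, perm_index: int) -> np.ndarray:
    """Uniformly random relabeling preserving group sizes.

    Deterministic in ``(seed, perm_index)`` alone.
    """
    rng = np.random.default_rng((int(seed), int(perm_index)))
    return labels[rng.permutation(labels.shape[0])]


def permute_cohort_labels(cohort: CohortStack, seed: int, perm_index: int) -> CohortStack:
    """Cohort with permuted group labels; subject matrices untouched."""
    return cohort.with_labels(permutation_labels(cohort.labels, seed, perm_index))


def _exhaustive_labelings(labels: np.ndarray) -> Iterator[np.ndarray]:
    """All distinct assignments of the observed group sizes to subjects."""
    s = labels.shape[0]
    n1 = int(labels.sum())
    base = np.zeros(s, dtype=int)
    for chosen in combinations(range(s), n1):
        b = base.copy()
        b[list(chosen)] = 1
        yield b


def n_exhaustive_labelings(n_subjects: int, n_group1: int) -> int:
    return comb(n_subjects, n_group1)


def _edge_scores(f_edges, dh, params, ei, ej, n_nodes):
    mx = float(f_edges.max())
    if dh <= 0 or mx <= params.h0:
        return np.zeros(f_edges.shape[0])
    heights = threshold_ladder(mx, dh, params.h0)
    s = tfnbs_sweep(
        ei, ej, np.ascontiguousarray(f_edges), heights,
        np.array([params.E]), np.array([params.H]), n_nodes,
    )[0]
    return s * dh if params.multiply_dh else s


def tfnbs_inference(
    cohort: CohortStack,
    params: TfnbsParams,
    n_perm: int = 3000,
    seed: int = 0,
    exhaustive: bool = False,
) -> TfnbsInferenceResult:
    """Enhanced scores with FWE-corrected and uncorrected edge p values.

    With ``exhaustive=True`` every distinct group relabeling is
    enumerated (feasible only for small cohorts) and p values are exact
    counts over the enumeration, which includes the observed labeling.
    Otherwise ``n_perm`` simple random relabelings are drawn and
    p = (1 + r) / (1 + n_perm), where r counts permutations at least as
    extreme as the observation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = cohort.node_count
    ii, jj = triu_edges(n)
    ei = ii.astype(np.int64)
    ej = jj.astype(np.int64)
    engine = FStatEngine(cohort.edge_data())
    f_obs = engine.f_values(cohort.labels)
    mx = float(f_obs.max())
    dh = mx / params.n_intervals if mx > 0 else 0.0

    obs = _edge_scores(f_obs, dh, params, ei, ej, n)

    if exhaustive:
        label_iter = _exhaustive_labelings(cohort.labels)
        total = n_exhaustive_labelings(cohort.n_subjects, int(cohort.labels.sum()))
    else:
        label_iter = (
            permutation_labels(cohort.labels, seed, i) for i in range(1, n_perm + 1)
        )
        total = n_perm

    null_max = np.empty(total)
    unc_count = np.zeros(obs.shape[0])
    for idx, b in enumerate(label_iter):
        s_p = _edge_scores(engine.f_values(b), dh, params, ei, ej, n)
        null_max[idx] = s_p.max() if s_p.size else 0.0
        unc_count += s_p >= obs

    null_sorted = np.sort(null_max)
    ge_count = total - np.searchsorted(null_sorted, obs, side="left")
    if exhaustive:
        p_fwe = ge_count / total
        p_unc = unc_count / total
    else:
        p_fwe = (1.0 + ge_count) / (1.0 + total)
        p_unc = (1.0 + unc_count) / (1.0 + total)

    def _as_matrix(p, correction):
        m = edge_vector_to_matrix(p, n)
        np.fill_diagonal(m, 1.0)
        return PValueMatrix(m, correction=correction, n_perm=total, seed=seed)

    score_matrix = ScoreMatrix(edge_vector_to_matrix(obs, n), params=params, dh_used=dh)
    return TfnbsInferenceResult(
        scores=score_matrix,
        fwe=_as_matrix(p_fwe, "fwe"),
        uncorrected=_as_matrix(p_unc, "uncorrected"),
        null_max=null_max,
    )


def tfnbs_fwe_pvalues(
    cohort: CohortStack,
    params: TfnbsParams,
    n_perm: int = 3000,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[ScoreMatrix, PValueMatrix]:
    """Observed score matrix and max-statistic FWE-corrected edge p values."""
    res = tfnbs_inference(cohort, params, n_perm=n_perm, seed=seed, exhaustive=exhaustive)
    return res.scores, res.fwe


def tfnbs_uncorrected_pvalues(
    cohort: CohortStack,
    params: TfnbsParams,
    n_perm: int = 3000,
    seed: int = 0,
    exhaustive: bool = False,
) -> PValueMatrix:
    """Edge p values comparing each edge with its own null score distribution."""
    res = tfnbs_inference(cohort, params, n_perm=n_perm, seed=seed, exhaustive=exhaustive)
    return res.uncorrected
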