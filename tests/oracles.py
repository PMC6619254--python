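"""Independent reference implementations used only to check the package.

Deliberately naive: breadth-first search for components, a materialised
per-threshold score stack, and literal enumeration of relabelings.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def bfs_components(n_nodes: int, edges: list[tuple[int, int]]) -> list[frozenset[int]]:
    """Connected node sets of an edge list, by literal breadth-first search."""
    adj: dict[int, set[int]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[int] = set()
    comps = []
    for start in sorted(adj):
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        nodes = {start}
        while queue:
            cur = queue.pop(0)
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    nodes.add(nxt)
                    queue.append(nxt)
        comps.append(frozenset(nodes))
    return comps


def naive_stack_scores(
    stat: np.ndarray,
    E: float,
    H: float,
    dh: float,
    h0: float = 0.0,
    multiply_dh: bool = False,
) -> np.ndarray:
    """Enhanced scores by materialising the full N x N x t stack.

    At each ladder rung h the suprathreshold edge set is {w >= h} (an edge
    contributes at the rung equal to its own height); every member edge of
    a connected component of extent e receives e^E * h^H; the stack is
    summed over rungs.
    """
    n = stat.shape[0]
    mx = stat.max()
    if mx <= h0 or dh <= 0:
        return np.zeros((n, n))
    n_steps = int(np.floor((mx + 1e-12 * mx - h0) / dh))
    heights = h0 + dh * np.arange(n_steps + 1)
    ii, jj = np.triu_indices(n, k=1)
    w = stat[ii, jj]
    stack = np.zeros((len(heights), n, n))
    for t, h in enumerate(heights):
        if h <= 0:
            continue
        sel = w >= h - 1e-12 * h
        edges = list(zip(ii[sel].tolist(), jj[sel].tolist()))
        for nodes in bfs_components(n, edges):
            members = [(a, b) for a, b in edges if a in nodes]
            enh = float(len(members)) ** E * h ** H
            for a, b in members:
                stack[t, a, b] = enh
                stack[t, b, a] = enh
    out = stack.sum(axis=0)
    return out * dh if multiply_dh else out


def two_group_f(matrices: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Edge-wise F as the square of scipy's pooled-variance t statistic."""
    a = matrices[labels == 0]
    b = matrices[labels == 1]
    t = stats.ttest_ind(a, b, axis=0, equal_var=True).statistic
    f = np.nan_to_num(t, nan=0.0) ** 2
    np.fill_diagonal(f, 0.0)
    return f


def exhaustive_tfnbs_pvalues(
    matrices: np.ndarray,
    labels: np.ndarray,
    E: float,
    H: float,
    n_intervals: int = 100,
):
    """Exact enhanced-score p values by enumerating every relabeling.

    Returns (fwe_p, uncorrected_p) as edge matrices; the ladder interval
    dh comes from the observed statistic matrix and is reused for every
    relabeling, each ladder running to its own maximum.
    """
    n = matrices.shape[1]
    s = labels.shape[0]
    n1 = int(labels.sum())
    f_obs = two_group_f(matrices, labels)
    dh = f_obs.max() / n_intervals
    obs = naive_stack_scores(f_obs, E, H, dh)

    all_scores = []
    for chosen in combinations(range(s), n1):
        b = np.zeros(s, dtype=int)
        b[list(chosen)] = 1
        f_b = two_group_f(matrices, b)
        all_scores.append(naive_stack_scores(f_b, E, H, dh))

    total = len(all_scores)
    iu = np.triu_indices(n, k=1)
    fwe = np.ones((n, n))
    unc = np.ones((n, n))
    maxima = [sc.max() for sc in all_scores]
    for a, b in zip(*iu):
        o = obs[a, b]
        fwe[a, b] = fwe[b, a] = sum(1 for mx in maxima if mx >= o) / total
        unc[a, b] = unc[b, a] = sum(1 for sc in all_scores if sc[a, b] >= o) / total
    return fwe, unc
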