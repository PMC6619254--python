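"""Compiled inner loops for the threshold-ladder sweep.

The TFNBS score of every edge is a sum over a descending ladder of
thresholds.  Instead of recomputing connected components from scratch at
every rung (and materialising an ``N x N x t`` stack), the sweep walks
the ladder from the top down, inserting edges into a union-find forest
as they become suprathreshold; component extents are maintained
incrementally, so the whole ladder costs roughly one find() per
(suprathreshold edge, rung) pair.  Scores for several (E, H) parameter
combinations are accumulated in one pass, sharing the component
bookkeeping.

The result is contract-tested against a naive oracle that materialises
the full per-threshold stack with networkx components.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# relative tolerance for the inclusive suprathreshold comparison w >= h:
# an edge contributes at the rung equal to its own height (the upper limit
# of the enhancement integral is included)
_REL_TOL = 1e-12


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def tfnbs_sweep(ei, ej, w, heights, e_exponents, h_exponents, n_nodes):
    """Edge scores sum_h extent(h)^E * h^H for every (E, H) combination.

    Parameters
    ----------
    ei, ej : int64 arrays (m,)
        Edge endpoints.
    w : float64 array (m,)
        Raw statistic per edge.
    heights : float64 array (t,)
        Ascending ladder of thresholds (h0, h0+dh, ...).
    e_exponents, h_exponents : float64 arrays (k,)
        Extension/height enhancement exponents, paired per combination.
    n_nodes : int
        Number of graph nodes.

    Returns
    -------
    (k, m) float64 array of accumulated scores (not multiplied by dh).
    """
    m = w.shape[0]
    k = e_exponents.shape[0]
    scores = np.zeros((k, m))
    nh = heights.shape[0]
    if m == 0 or nh == 0:
        return scores

    order = np.argsort(-w)
    parent = np.arange(n_nodes)
    comp_edges = np.zeros(n_nodes, dtype=np.int64)
    stamp = np.full(n_nodes, -1, dtype=np.int64)
    root_val = np.zeros((n_nodes, k))
    h_pow = np.empty(k)

    ptr = 0
    for t in range(nh - 1, -1, -1):
        h = heights[t]
        if h <= 0.0:
            # height weighting h^H vanishes; nothing below contributes either
            break
        thr = h - _REL_TOL * h
        while ptr < m and w[order[ptr]] >= thr:
            e = order[ptr]
            ru = _find(parent, ei[e])
            rv = _find(parent, ej[e])
            if ru == rv:
                comp_edges[ru] += 1
            else:
                if comp_edges[ru] < comp_edges[rv]:
                    ru, rv = rv, ru
                parent[rv] = ru
                comp_edges[ru] += comp_edges[rv] + 1
            ptr += 1
        if ptr == 0:
            continue
        for c in range(k):
            h_pow[c] = h ** h_exponents[c]
        for q in range(ptr):
            e = order[q]
            r = _find(parent, ei[e])
            if stamp[r] != t:
                ext = float(comp_edges[r])
                for c in range(k):
                    root_val[r, c] = ext ** e_exponents[c] * h_pow[c]
                stamp[r] = t
            for c in range(k):
                scores[c, e] += root_val[r, c]
    return scores


@njit(cache=True)
def nbs_max_measures(ei, ej, w, threshold, n_nodes):
    """Largest component extent and excess intensity above a hard threshold.

    Uses the strict comparison ``w > threshold`` (the NBS component-defining
    threshold).  Intensity is measured as the sum of statistic excesses
    ``w - threshold`` over a component's edges, so isolated strong effects
    are not swamped by clusters of barely-suprathreshold noise edges.
    Returns ``(max_extent, max_excess_intensity)``; both are 0 when no edge
    is suprathreshold.
    """
    m = w.shape[0]
    parent = np.arange(n_nodes)
    comp_edges = np.zeros(n_nodes, dtype=np.int64)
    comp_sum = np.zeros(n_nodes)
    for e in range(m):
        if w[e] > threshold:
            ru = _find(parent, ei[e])
            rv = _find(parent, ej[e])
            if ru == rv:
                comp_edges[ru] += 1
                comp_sum[ru] += w[e] - threshold
            else:
                if comp_edges[ru] < comp_edges[rv]:
                    ru, rv = rv, ru
                parent[rv] = ru
                comp_edges[ru] += comp_edges[rv] + 1
                comp_sum[ru] += comp_sum[rv] + w[e] - threshold
    max_extent = 0
    max_intensity = 0.0
    for e in range(m):
        if w[e] > threshold:
            r = _find(parent, ei[e])
            if comp_edges[r] > max_extent:
                max_extent = comp_edges[r]
            if comp_sum[r] > max_intensity:
                max_intensity = comp_sum[r]
    return max_extent, max_intensity
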