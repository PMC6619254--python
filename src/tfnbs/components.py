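"""Connected components of suprathreshold edge sets.

Two edges are neighbours iff they share a node, so the components of a
thresholded statistic matrix are exactly the connected components of the
graph whose edge set is the suprathreshold edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cohort import EdgeStatMatrix


@dataclass
class Component:
    """One connected component of suprathreshold edges."""

    edges: list[tuple[int, int]]
    nodes: frozenset[int]
    intensity: float

    @property
    def extent(self) -> int:
        """Number of member edges."""
        return len(self.edges)


@dataclass
class ComponentSet:
    """All connected components of the edges exceeding a threshold."""

    threshold_h: float
    components: list[Component] = field(default_factory=list)

    def __iter__(self):
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    @property
    def total_extent(self) -> int:
        return sum(c.extent for c in self.components)


def suprathreshold_components(stat: EdgeStatMatrix, h: float) -> ComponentSet:
    """Connected components of the graph with edge set ``{(i,j): stat[i,j] > h}``.

    The comparison is strict, so ``h = 0`` on a non-negative F matrix
    selects exactly the non-zero edges.  Every suprathreshold edge belongs
    to exactly one component; a component's extent is its edge count and
    its intensity the sum of the raw statistic over its edges.
    """
    if h < 0:
        raise ValueError("threshold must be non-negative")
    values = stat.values
    n = values.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    w = values[ii, jj]
    sel = w > h
    ei = ii[sel]
    ej = jj[sel]
    ew = w[sel]

    graph = nx.Graph()
    graph.add_edges_from(zip(ei.tolist(), ej.tolist()))
    node_to_cid: dict[int, int] = {}
    raw: list[tuple[list[tuple[int, int]], set[int], float]] = []
    for cid, nodes in enumerate(nx.connected_components(graph)):
        raw.append(([], set(nodes), 0.0))
        for node in nodes:
            node_to_cid[node] = cid

    sums = [0.0] * len(raw)
    for a, b, wv in zip(ei.tolist(), ej.tolist(), ew.tolist()):
        cid = node_to_cid[a]
        raw[cid][0].append((a, b))
        sums[cid] += wv

    comps = [
        Component(edges=edges, nodes=frozenset(nodes), intensity=s)
        for (edges, nodes, _), s in zip(raw, sums)
    ]
    return ComponentSet(threshold_h=h, components=comps)


def component_membership_matrix(cs: ComponentSet, n_nodes: int) -> np.ndarray:
    """Symmetric integer matrix labelling each suprathreshold edge with its
    1-based component index (0 = edge in no component)."""
    mat = np.zeros((n_nodes, n_nodes), dtype=int)
    for idx, comp in enumerate(cs.components, start=1):
        for a, b in comp.edges:
            if a >= n_nodes or b >= n_nodes:
                raise ValueError("component node index exceeds matrix size")
            mat[a, b] = idx
            mat[b, a] = idx
    return mat
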