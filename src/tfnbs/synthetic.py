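"""Synthetic cohorts with planted connectivity effects.

The generator emulates a two-group connectome study: "healthy" subjects
whose 82 x 82 connectivity matrices contain iid standard normal noise,
and "disrupted" subjects identical except at a set of ground-truth edges
whose values are drawn with a negative mean (reduced connectivity).  The
planted mean shift divided by the unit noise standard deviation is the
contrast-to-noise ratio (CNR), equal to Cohen's d.

Ground-truth effects are organised into node-disjoint connected
components, either acyclic trees (random labeled trees; a path for the
"linear" growing-component regime) or clique-packed "cyclic" components
using the minimum number of nodes able to host the requested edge count.
The reference structure is five components of 20/7/3/1/1 edges (32 edges
on 82 nodes); mixed-CNR cohorts assign CNR 0.75/1/0.5/1/0.5 to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

from .cohort import CohortStack, triu_edges

#: reference component extents (edges per component)
DEFAULT_COMPONENT_SIZES = (20, 7, 3, 1, 1)
#: CNR per component in the mixed-CNR regime
MIXED_CNR_MAP = (0.75, 1.0, 0.5, 1.0, 0.5)

SCENARIOS = ("single_cnr", "mixed_cnr", "random_noise", "growing")
TOPOLOGIES = ("tree", "cyclic", "path")


@dataclass
class MaskComponent:
    edges: list[tuple[int, int]]
    nodes: frozenset[int]
    topology: str
    cnr: float | None = None

    @property
    def extent(self) -> int:
        return len(self.edges)


@dataclass
class GroundTruthMask:
    """Binary matrix of planted-effect edges with component metadata."""

    T: np.ndarray  # binary symmetric N x N
    components: list[MaskComponent] = field(default_factory=list)

    @property
    def node_count(self) -> int:
        return self.T.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.T.sum()) // 2


@dataclass
class ScenarioConfig:
    """Configuration of one simulated study regime."""

    scenario: str = "mixed_cnr"
    N: int = 82
    n_per_group: int = 100
    topology: str = "tree"
    cnr: float | None = None
    cnr_map: Sequence[float] = MIXED_CNR_MAP
    component_sizes: Sequence[int] = DEFAULT_COMPONENT_SIZES
    growing_sizes: Sequence[int] = tuple(range(4, 31, 2))
    growing_cnrs: Sequence[float] = (0.5, 0.75)
    growing_topologies: Sequence[str] = ("path", "cyclic")
    n_groups: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; expected one of {TOPOLOGIES}")
        if self.N < 2 or self.n_per_group < 2:
            raise ValueError("N and n_per_group must allow a two-group comparison")
        if any(s < 1 for s in self.component_sizes):
            raise ValueError("component sizes must be positive")


def minimal_clique_nodes(n_edges: int) -> int:
    """Smallest node count n with n(n-1)/2 >= n_edges (n >= 2)."""
    if n_edges < 1:
        raise ValueError("a component has at least one edge")
    n = 2
    while n * (n - 1) // 2 < n_edges:
        n += 1
    return n


def _component_node_demand(size: int, topology: str) -> int:
    if topology in ("tree", "path"):
        return size + 1
    return minimal_clique_nodes(size)


def _component_edges(size: int, topology: str, nodes: np.ndarray, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Edge list of one planted component on the given (global) node ids."""
    k = nodes.shape[0]
    if topology == "path":
        local = [(i, i + 1) for i in range(size)]
    elif topology == "tree":
        tree = nx.random_labeled_tree(k, seed=int(rng.integers(2**31)))
        local = list(tree.edges())
    else:  # cyclic: clique-packed, seeded order decides which edges to drop
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        order = rng.permutation(len(pairs))
        local = [pairs[o] for o in order[:size]]
    return [(int(nodes[a]), int(nodes[b])) for a, b in local]


def build_ground_truth(
    sizes: Sequence[int],
    topology: str,
    N: int = 82,
    seed: int = 0,
    cnrs: Sequence[float] | None = None,
) -> GroundTruthMask:
    """Planted-effect mask with node-disjoint components of the given extents.

    Tree components are uniformly random labeled trees on ``size + 1``
    freshly drawn nodes; path components are chains; cyclic components
    occupy the minimum node count able to host ``size`` edges, dropping
    surplus clique edges in seeded order.  Component node sets are drawn
    disjointly from the N nodes without replacement.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; expected one of {TOPOLOGIES}")
    if any(s < 1 for s in sizes):
        raise ValueError("component sizes must be >= 1")
    if cnrs is not None and len(cnrs) != len(sizes):
        raise ValueError("need one CNR per component")
    demands = [_component_node_demand(s, topology) for s in sizes]
    if sum(demands) > N:
        raise ValueError(
            f"components need {sum(demands)} nodes but the graph has only {N}"
        )

    rng = np.random.default_rng(seed)
    node_pool = rng.permutation(N)
    T = np.zeros((N, N), dtype=int)
    comps: list[MaskComponent] = []
    offset = 0
    for idx, (size, demand) in enumerate(zip(sizes, demands)):
        nodes = node_pool[offset:offset + demand]
        offset += demand
        edges = _component_edges(size, topology, nodes, rng)
        for a, b in edges:
            T[a, b] = 1
            T[b, a] = 1
        comps.append(
            MaskComponent(
                edges=edges,
                nodes=frozenset(int(x) for x in nodes),
                topology=topology,
                cnr=None if cnrs is None else float(cnrs[idx]),
            )
        )
    return GroundTruthMask(T=T, components=comps)


def empty_mask(N: int) -> GroundTruthMask:
    """All-zero mask (random-noise regime)."""
    return GroundTruthMask(T=np.zeros((N, N), dtype=int), components=[])


def _resolved_cnrs(mask: GroundTruthMask, config: ScenarioConfig) -> list[float]:
    out = []
    for idx, comp in enumerate(mask.components):
        if comp.cnr is not None:
            out.append(comp.cnr)
        elif config.scenario == "single_cnr" or config.scenario == "growing":
            if config.cnr is None:
                raise ValueError(f"scenario {config.scenario!r} needs config.cnr")
            out.append(float(config.cnr))
        elif config.scenario == "mixed_cnr":
            out.append(float(config.cnr_map[idx]))
        else:
            raise ValueError("random-noise scenario admits no planted components")
    return out


def simulate_cohort(mask: GroundTruthMask, config: ScenarioConfig, seed: int = 0) -> CohortStack:
    """Two-group cohort with the mask's effects planted in the second group.

    ``n_per_group`` healthy subjects (label 0) carry iid N(0, 1) edge
    values; ``n_per_group`` disrupted subjects (label 1) are identical
    except at ground-truth edges, drawn from N(-cnr, 1) with the CNR of
    the owning component.  Matrices are symmetric with zero diagonal.
    """
    N = config.N
    if mask.node_count != N:
        raise ValueError("mask and config disagree on the node count")
    rng = np.random.default_rng(seed)
    S = 2 * config.n_per_group
    ii, jj = triu_edges(N)
    m = ii.shape[0]
    vals = rng.standard_normal((S, m))

    if mask.components:
        col_of = np.full((N, N), -1, dtype=int)
        col_of[ii, jj] = np.arange(m)
        cnrs = _resolved_cnrs(mask, config)
        for comp, cnr in zip(mask.components, cnrs):
            cols = [col_of[min(a, b), max(a, b)] for a, b in comp.edges]
            vals[config.n_per_group:, cols] -= cnr

    subjects = np.zeros((S, N, N))
    subjects[:, ii, jj] = vals
    subjects[:, jj, ii] = vals
    labels = np.repeat([0, 1], config.n_per_group)
    return CohortStack(subjects, labels, validate=False)


def simulate_scenario(config: ScenarioConfig, seed: int | None = None) -> tuple[GroundTruthMask, CohortStack]:
    """Build the mask and one cohort for any non-growing scenario."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence((int(seed), 0))
    mask_seed, cohort_seed = (int(s % 2**31) for s in ss.generate_state(2))
    if config.scenario == "random_noise":
        mask = empty_mask(config.N)
    else:
        if config.scenario == "single_cnr":
            cnrs = [float(config.cnr)] * len(config.component_sizes)
        elif config.scenario == "mixed_cnr":
            cnrs = list(config.cnr_map[: len(config.component_sizes)])
        else:
            raise ValueError("use growing_component_suite for the growing scenario")
        mask = build_ground_truth(
            config.component_sizes, config.topology, config.N, mask_seed, cnrs=cnrs
        )
    return mask, simulate_cohort(mask, config, cohort_seed)


def growing_grid(config: ScenarioConfig) -> Iterator[tuple[int, float, str, int]]:
    """Enumerate (size, cnr, topology, group_index) of the growing regime.

    With the defaults this is 14 sizes x 2 CNRs x 2 topologies x 75
    groups = 4,200 planned comparisons.
    """
    for size in config.growing_sizes:
        for cnr in config.growing_cnrs:
            for topology in config.growing_topologies:
                for g in range(config.n_groups):
                    yield size, float(cnr), topology, g


def growing_component_suite(config: ScenarioConfig) -> Iterator[tuple[GroundTruthMask, CohortStack]]:
    """Stream of (mask, cohort) pairs over the growing-component grid.

    Each cohort plants a single component of the given size, CNR and
    topology ("linear" tree effects are path graphs).  Seeds derive from
    ``config.seed`` and the grid position only.
    """
    for k, (size, cnr, topology, _g) in enumerate(growing_grid(config)):
        ss = np.random.SeedSequence((int(config.seed), 1, k))
        mask_seed, cohort_seed = (int(s % 2**31) for s in ss.generate_state(2))
        mask = build_ground_truth([size], topology, config.N, mask_seed, cnrs=[cnr])
        yield mask, simulate_cohort(mask, config, cohort_seed)
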