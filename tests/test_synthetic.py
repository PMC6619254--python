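import networkx as nx
import numpy as np
import pytest

from tfnbs import (
    DEFAULT_COMPONENT_SIZES,
    MIXED_CNR_MAP,
    ScenarioConfig,
    build_ground_truth,
    growing_component_suite,
    growing_grid,
    simulate_cohort,
    simulate_scenario,
)
from tfnbs.synthetic import empty_mask, minimal_clique_nodes


@pytest.mark.parametrize("topology", ["tree", "cyclic"])
def test_reference_mask_has_32_edges_in_five_components(topology):
    mask = build_ground_truth(DEFAULT_COMPONENT_SIZES, topology, N=82, seed=0)
    assert mask.edge_count == 32
    assert len(mask.components) == 5
    assert [c.extent for c in mask.components] == [20, 7, 3, 1, 1]
    # node-disjoint components
    all_nodes = [n for c in mask.components for n in c.nodes]
    assert len(all_nodes) == len(set(all_nodes))
    # mask matrix is consistent with the edge lists
    assert mask.T.sum() == 2 * 32


def test_tree_components_are_trees():
    mask = build_ground_truth(DEFAULT_COMPONENT_SIZES, "tree", N=82, seed=3)
    for comp in mask.components:
        g = nx.Graph(comp.edges)
        assert len(comp.nodes) == comp.extent + 1
        assert nx.is_tree(g)


def test_cyclic_components_use_minimal_cliques():
    assert minimal_clique_nodes(3) == 3   # triangle
    assert minimal_clique_nodes(20) == 7  # C(7,2)=21 >= 20
    assert minimal_clique_nodes(30) == 9  # C(9,2)=36 >= 30
    mask = build_ground_truth([3, 20], "cyclic", N=82, seed=1)
    tri, big = mask.components
    assert len(tri.nodes) == 3 and tri.extent == 3
    assert len(big.nodes) == 7 and big.extent == 20
    assert len(nx.cycle_basis(nx.Graph(big.edges))) >= 1


def test_node_demand_exceeding_graph_is_rejected():
    with pytest.raises(ValueError, match="nodes"):
        build_ground_truth([20, 20], "tree", N=30, seed=0)


def test_cohort_reproducibility_and_shape():
    config = ScenarioConfig(scenario="mixed_cnr", N=20, n_per_group=6,
                            component_sizes=(3, 1), cnr_map=(0.75, 1.0))
    mask = build_ground_truth((3, 1), "tree", N=20, seed=5, cnrs=(0.75, 1.0))
    a = simulate_cohort(mask, config, seed=8)
    b = simulate_cohort(mask, config, seed=8)
    assert np.array_equal(a.subjects, b.subjects)
    assert a.subjects.shape == (12, 20, 20)
    assert np.array_equal(a.labels, np.repeat([0, 1], 6))
    asym = np.abs(a.subjects - a.subjects.transpose(0, 2, 1)).max()
    assert asym == 0
    assert np.all(a.subjects.diagonal(axis1=1, axis2=2) == 0)


def test_planted_effect_matches_configured_cnr():
    """Monte-Carlo moments: group mean difference -cnr, pooled sd 1."""
    config = ScenarioConfig(scenario="single_cnr", N=15, n_per_group=5000, cnr=1.0,
                            component_sizes=(5,))
    mask = build_ground_truth((5,), "tree", N=15, seed=2, cnrs=(1.0,))
    cohort = simulate_cohort(mask, config, seed=4)
    healthy = cohort.subjects[:5000]
    disrupted = cohort.subjects[5000:]
    for a, b in mask.components[0].edges:
        diff = disrupted[:, a, b].mean() - healthy[:, a, b].mean()
        assert diff == pytest.approx(-1.0, abs=0.05)
        assert disrupted[:, a, b].std() == pytest.approx(1.0, abs=0.05)
    # off-mask edge carries no effect
    off = [(i, j) for i in range(15) for j in range(i + 1, 15) if not mask.T[i, j]][0]
    diff = disrupted[:, off[0], off[1]].mean() - healthy[:, off[0], off[1]].mean()
    assert diff == pytest.approx(0.0, abs=0.06)


def test_random_noise_scenario_has_empty_mask():
    config = ScenarioConfig(scenario="random_noise", N=10, n_per_group=4)
    mask, cohort = simulate_scenario(config, seed=1)
    assert mask.edge_count == 0
    assert cohort.n_subjects == 8


def test_mixed_scenario_applies_cnr_map():
    config = ScenarioConfig(scenario="mixed_cnr", N=82, n_per_group=3)
    mask, _ = simulate_scenario(config, seed=0)
    assert [c.cnr for c in mask.components] == list(MIXED_CNR_MAP)


def test_growing_grid_enumerates_4200_comparisons():
    config = ScenarioConfig(scenario="growing", n_groups=75)
    grid = list(growing_grid(config))
    assert len(grid) == 4200  # 14 sizes x 2 CNRs x 2 topologies x 75 groups
    sizes = sorted({g[0] for g in grid})
    assert sizes == list(range(4, 31, 2))
    assert {g[1] for g in grid} == {0.5, 0.75}
    assert {g[2] for g in grid} == {"path", "cyclic"}


def test_growing_suite_first_items():
    config = ScenarioConfig(scenario="growing", N=40, n_per_group=4, n_groups=1,
                            growing_sizes=(4, 30), growing_cnrs=(0.5,),
                            growing_topologies=("path", "cyclic"))
    items = []
    suite = growing_component_suite(config)
    for _ in range(4):
        items.append(next(suite))
    path4 = items[0][0].components[0]
    assert path4.extent == 4 and len(path4.nodes) == 5
    assert nx.is_tree(nx.Graph(path4.edges))
    cyc30 = items[3][0].components[0]
    assert cyc30.extent == 30 and len(cyc30.nodes) == 9


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="scenario"):
        ScenarioConfig(scenario="bogus")
    with pytest.raises(ValueError, match="topology"):
        ScenarioConfig(topology="spiral")
    with pytest.raises(ValueError):
        simulate_cohort(empty_mask(10), ScenarioConfig(scenario="random_noise", N=12, n_per_group=4))
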