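"""Interaction-network construction and statistics."""

import networkx as nx
import numpy as np
import pytest

from liface import (
    EnergyParameters,
    HBond,
    WaterBridge,
    aggregate,
    build_graph,
    cluster_stats,
    edge_lifetimes,
    find_network_bridges,
    node_degree_distribution,
    node_strength,
)
from liface.geometry import LeafletAssignment
from liface.synth import EdgeSchedule, FixtureSpec, component_graph, generate_edge_schedule_trajectory
from liface.topology import Moiety


LEAF = LeafletAssignment(labels={0: 0, 1: 0, 2: 0, 3: 1}, n_leaflets=2)


def ll_bond(t, mol_a, mol_b):
    return HBond(t, 0, 1, 2, mol_a, mol_b, "lipid_lipid",
                 Moiety.ALPHA_RING, Moiety.ALPHA_RING)


def wb(t, a, b, orientation="horizontal"):
    la, lb = sorted((a, b))
    return WaterBridge(t, 99, la, lb, Moiety.ALPHA_RING, Moiety.ALPHA_RING,
                       orientation, "double_donor")


def test_energy_parameters_must_be_negative():
    with pytest.raises(ValueError, match="negative"):
        EnergyParameters(e_hbond=1.0)


def test_build_graph_counts_and_isolates():
    hb = [ll_bond(0.0, 0, 1), ll_bond(0.0, 0, 1), ll_bond(0.0, 1, 2)]
    bridges = [wb(0.0, 0, 1), wb(0.0, 0, 3, "vertical")]
    g = build_graph(hb, bridges, LEAF, 0, 0.0)
    assert set(g.nodes) == {0, 1, 2}  # all leaflet members, including isolates
    assert g.edges[0, 1]["n_hbond"] == 2
    assert g.edges[0, 1]["n_wb"] == 1
    assert g.edges[1, 2]["n_hbond"] == 1
    # the vertical bridge and cross-leaflet pairs never enter
    assert not g.has_edge(0, 3)


def test_build_graph_edge_type_filter():
    hb = [ll_bond(0.0, 0, 1)]
    bridges = [wb(0.0, 1, 2)]
    g_hb = build_graph(hb, bridges, LEAF, 0, 0.0, edge_types=("hbond",))
    assert g_hb.has_edge(0, 1) and not g_hb.has_edge(1, 2)
    g_wb = build_graph(hb, bridges, LEAF, 0, 0.0, edge_types=("wb",))
    assert g_wb.has_edge(1, 2) and not g_wb.has_edge(0, 1)
    with pytest.raises(ValueError, match="unknown edge types"):
        build_graph(hb, bridges, LEAF, 0, 0.0, edge_types=("zap",))


def test_build_graph_other_frame_ignored():
    g = build_graph([ll_bond(1.0, 0, 1)], [], LEAF, 0, 0.0)
    assert g.number_of_edges() == 0


def test_cluster_stats():
    g = component_graph([3, 1, 5], seed=1)
    n, sizes = cluster_stats(g)
    assert n == 3
    assert sizes == [1, 3, 5]
    assert sum(sizes) == g.number_of_nodes()


def _bridges_by_removal(g):
    base = nx.number_connected_components(g)
    out = set()
    for e in g.edges:
        h = g.copy()
        h.remove_edge(*e)
        if nx.number_connected_components(h) > base:
            out.add(frozenset(e))
    return out


def test_find_network_bridges_known_cases():
    path = nx.path_graph(5)
    assert {frozenset(e) for e in find_network_bridges(path)} == {
        frozenset(e) for e in path.edges
    }
    cycle = nx.cycle_graph(5)
    assert find_network_bridges(cycle) == []
    # cycle with a pendant edge: only the pendant is a bridge
    g = nx.cycle_graph(4)
    g.add_edge(3, 9)
    assert {frozenset(e) for e in find_network_bridges(g)} == {frozenset((3, 9))}
    # disconnected graph with isolates
    g2 = nx.union(nx.path_graph(3), nx.cycle_graph(range(10, 13)))
    g2.add_node(99)
    assert {frozenset(e) for e in find_network_bridges(g2)} == {
        frozenset((0, 1)), frozenset((1, 2))
    }


def test_find_network_bridges_matches_oracles(rng):
    for _ in range(30):
        n = int(rng.integers(2, 40))
        p = float(rng.uniform(0.02, 0.3))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        got = {frozenset(e) for e in find_network_bridges(g)}
        assert got == {frozenset(e) for e in nx.bridges(g)}
        assert got == _bridges_by_removal(g)


def test_node_degree_distribution():
    g = component_graph([3, 1], seed=0)  # degrees: 1,2,1,0
    dist = node_degree_distribution([g])
    assert dist.loc[0] == pytest.approx(0.25)
    assert dist.loc[1] == pytest.approx(0.5)
    assert dist.loc[2] == pytest.approx(0.25)
    assert dist.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="at least one graph"):
        node_degree_distribution([])


def test_node_strength_default_formula():
    g = nx.Graph()
    g.add_nodes_from([0, 1, 2])
    g.add_edge(0, 1, n_hbond=1, n_wb=1)
    g.add_edge(1, 2, n_hbond=2, n_wb=0)
    strengths, meta = node_strength(g)
    assert strengths[0] == pytest.approx(5.12 + 14.23, abs=1e-12)
    assert strengths[1] == pytest.approx(5.12 + 14.23 + 2 * 5.12, abs=1e-12)
    assert strengths[2] == pytest.approx(2 * 5.12, abs=1e-12)
    assert meta["formula"] == "sum_edges(n_hbond*|e_hbond| + n_wb*|e_wb|)"
    assert meta["lifetime_weighted"] is False


def test_node_strength_lifetime_weighted():
    g = nx.Graph()
    g.add_edge(0, 1, n_hbond=1, n_wb=2)
    strengths, meta = node_strength(g, lifetimes={"hbond": 3.0, "wb": 0.5})
    assert strengths[0] == pytest.approx(1 * 5.12 * 3.0 + 2 * 14.23 * 0.5, abs=1e-12)
    assert meta["lifetime_weighted"] is True
    assert "tau" in meta["formula"]


def make_series(on_frames, n_frames=6, dt=1.0, kind="hbond"):
    spec = FixtureSpec(n_nodes=4, n_frames=n_frames, dt=dt,
                       edge_schedules=(EdgeSchedule(0, 1, tuple(on_frames), kind),))
    graphs, man = generate_edge_schedule_trajectory(spec)
    return graphs, man


def test_edge_lifetimes_deterministic():
    graphs, man = make_series([0, 1, 2, 4])
    out = edge_lifetimes(graphs)
    assert man.schedule_runs == [3, 1]
    assert out["n_runs"] == 2
    assert out["mean"] == pytest.approx(2.0)  # (3+1)/2 frames * 1 ps
    assert out["sem"] == pytest.approx(np.std([3.0, 1.0], ddof=1) / np.sqrt(2))


def test_edge_lifetimes_gap_tolerance_spans():
    graphs, _ = make_series([0, 1, 2, 4])
    out = edge_lifetimes(graphs, gap_tolerance=1)
    # the 1-frame gap merges into a single run spanning frames 0..4
    assert out["n_runs"] == 1
    assert out["mean"] == pytest.approx(5.0)


def test_edge_lifetimes_respects_dt():
    graphs, _ = make_series([1, 2], dt=0.5)
    out = edge_lifetimes(graphs)
    assert out["mean"] == pytest.approx(2 * 0.5)
    with pytest.raises(ValueError, match="dt"):
        edge_lifetimes(graphs, dt=1.0)


def test_edge_lifetimes_nonuniform_spacing_rejected():
    graphs, _ = make_series([0, 1])
    graphs[2].graph["frame_time"] = 7.5
    with pytest.raises(ValueError, match="non-uniform"):
        edge_lifetimes(graphs)


def test_edge_lifetimes_type_subset():
    graphs, _ = make_series([0, 1, 2], kind="wb")
    assert edge_lifetimes(graphs, edge_types=("hbond",))["n_runs"] == 0
    assert edge_lifetimes(graphs, edge_types=("wb",))["n_runs"] == 1


def test_aggregate_cluster_averaging_examples():
    # frame 0: one connected leaflet (1 cluster) + one split leaflet (2) -> 1.5
    g_a = component_graph([4], seed=0)
    g_b = component_graph([2, 2], seed=1)
    g_b.graph["leaflet"] = 1
    series = aggregate([g_a, g_b])
    assert series.per_frame.loc[0.0, "n_clusters"] == pytest.approx(1.5)
    # {1,1,98} leaflet next to a fully connected one -> (3+1)/2 = 2
    g_c = component_graph([1, 1, 98], seed=2)
    g_d = component_graph([100], seed=3)
    g_d.graph["leaflet"] = 1
    series2 = aggregate([g_c, g_d])
    assert series2.per_frame.loc[0.0, "n_clusters"] == pytest.approx(2.0)
    assert series2.per_frame.loc[0.0, "largest_pct"] == pytest.approx((98 + 100) / 2)


def test_aggregate_summary_and_distribution():
    g_a = component_graph([4], seed=0)          # frame 0
    g_b = component_graph([2, 2], seed=1)
    g_b.graph["frame_time"] = 1.0               # frame 1
    series = aggregate([g_a, g_b])
    assert series.summary.loc["n_clusters", "mean"] == pytest.approx(1.5)
    assert series.summary.loc["n_clusters", "sd"] == pytest.approx(0.5)
    dist = series.cluster_size_distribution
    assert dist.loc[2] == pytest.approx(2 / 3)
    assert dist.loc[4] == pytest.approx(1 / 3)
    assert series.lifetimes["hbond"]["n_runs"] >= 1
    assert series.strength_meta["e_hbond"] == -5.12
    # per-head interaction counts: component_graph edges carry n_hbond=1
    assert series.per_frame.loc[0.0, "hbonds_per_head"] == pytest.approx(2 * 3 / 4)


def test_aggregate_empty_rejected():
    with pytest.raises(ValueError, match="at least one graph"):
        aggregate([])
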