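import itertools
import math

import networkx as nx
import numpy as np
import pytest

from phyllocore.diversity import DistanceMatrix
from phyllocore.similarity_network import (
    SimilarityMatrix,
    export_graph,
    find_critical_network,
    modularity_partition,
    network_distance_curve,
    sweep_thresholds,
    threshold_graph,
    to_similarity_matrix,
)
from phyllocore.synthetic_data import generate_block_similarity


def sim_from_pairs(labels, pairs: dict[tuple[str, str], int]) -> SimilarityMatrix:
    n = len(labels)
    values = np.full((n, n), 0, dtype=np.int64)
    np.fill_diagonal(values, 100)
    pos = {l: i for i, l in enumerate(labels)}
    for (a, b), s in pairs.items():
        values[pos[a], pos[b]] = values[pos[b], pos[a]] = s
    return SimilarityMatrix(list(labels), values)


def random_similarity(rng, n) -> SimilarityMatrix:
    values = rng.integers(0, 101, size=(n, n))
    values = np.triu(values, 1)
    values = values + values.T
    np.fill_diagonal(values, 100)
    return SimilarityMatrix([f"s{i}" for i in range(n)], values)


# ---------------------------------------------------------------------------
# similarity matrix construction
# ---------------------------------------------------------------------------

def test_to_similarity_matrix_closed_forms():
    d = np.array([[0, 0.0, 1.0, 1 / 3], [0, 0, 0, 0], [1, 0, 0, 0], [1 / 3, 0, 0, 0]])
    d = (d + d.T) / 2
    sim = to_similarity_matrix(DistanceMatrix(list("abcd"), d))
    assert sim.values[0, 1] == 100  # identical pair
    assert sim.values[0, 2] == 0  # maximally dissimilar
    assert sim.values[0, 3] == 67  # (1 - 1/3) * 100 = 66.67 -> 67


def test_to_similarity_matrix_rounding_conventions():
    d = np.array([[0, 0.075], [0.075, 0]])  # similarity 92.5
    dm = DistanceMatrix(["a", "b"], d)
    assert to_similarity_matrix(dm, "half_up").values[0, 1] == 93
    assert to_similarity_matrix(dm, "half_even").values[0, 1] == 92


def test_to_similarity_matrix_rejects_unnormalized():
    d = np.array([[0, 1.4], [1.4, 0]])
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        to_similarity_matrix(DistanceMatrix(["a", "b"], d))


# ---------------------------------------------------------------------------
# threshold graphs
# ---------------------------------------------------------------------------

def test_threshold_is_inclusive_at_the_worked_value():
    sim = sim_from_pairs(["a", "b"], {("a", "b"): 33})
    assert threshold_graph(sim, 33).has_edge("a", "b")
    assert not threshold_graph(sim, 34).has_edge("a", "b")


def test_threshold_graph_extremes():
    rng = np.random.default_rng(0)
    sim = random_similarity(rng, 6)
    complete = threshold_graph(sim, 0)
    assert complete.number_of_edges() == math.comb(6, 2)
    with pytest.raises(ValueError):
        threshold_graph(sim, 101)
    capped = sim_from_pairs(["a", "b", "c"], {("a", "b"): 99, ("a", "c"): 50})
    top = threshold_graph(capped, 100)
    assert top.number_of_edges() == 0
    assert set(top.nodes) == {"a", "b", "c"}  # isolated nodes retained


def test_sweep_nesting_and_telescoping(rng):
    for _ in range(10):
        sim = random_similarity(rng, rng.integers(3, 10))
        sweep = sweep_thresholds(sim)
        edges = [set(map(frozenset, g.edges())) for g in sweep.graphs]
        assert all(edges[t + 1] <= edges[t] for t in range(100))
        dropped = sum(len(edges[t] - edges[t + 1]) for t in range(100))
        assert dropped == len(edges[0]) - len(edges[100])


# ---------------------------------------------------------------------------
# distance curve + critical network
# ---------------------------------------------------------------------------

def test_distance_curve_flat_similarity_is_zero():
    sim = sim_from_pairs(["a", "b", "c"], {("a", "b"): 100, ("a", "c"): 100, ("b", "c"): 100})
    curve = network_distance_curve(sweep_thresholds(sim))
    assert np.all(curve == 0)


def test_distance_curve_hand_enumerated_single_drop():
    sim = sim_from_pairs(["a", "b", "c"], {("a", "b"): 50, ("a", "c"): 50, ("b", "c"): 50})
    curve = network_distance_curve(sweep_thresholds(sim))
    assert curve[50] == 1.0  # all three edges vanish between t=50 and t=51
    assert np.count_nonzero(curve) == 1


def test_distance_curve_telescoping_conservation(rng):
    sim = random_similarity(rng, 8)
    sweep = sweep_thresholds(sim)
    curve = network_distance_curve(sweep, method="consecutive")
    e0 = sweep.graphs[0].number_of_edges()
    e100 = sweep.graphs[100].number_of_edges()
    assert curve.sum() == pytest.approx((e0 - e100) / math.comb(8, 2))


def test_from_initial_curve_is_monotone(rng):
    sim = random_similarity(rng, 8)
    sweep = sweep_thresholds(sim)
    curve = network_distance_curve(sweep, method="from_initial")
    assert curve[0] == 0.0
    assert np.all(np.diff(curve) >= -1e-15)


def test_critical_network_unique_jump():
    sim = sim_from_pairs(
        ["a", "b", "c"], {("a", "b"): 70, ("a", "c"): 70, ("b", "c"): 70}
    )
    t_star, graph, degenerate = find_critical_network(sweep_thresholds(sim))
    assert t_star == 70 and not degenerate
    assert graph.number_of_edges() == 0  # sparser side of the drop


def test_critical_network_degenerate_flat_sweep():
    sim = sim_from_pairs(["a", "b"], {("a", "b"): 100})
    t_star, _, degenerate = find_critical_network(sweep_thresholds(sim))
    assert degenerate and t_star == 0


def test_critical_network_largest_step_matches_enumeration_oracle(rng):
    for _ in range(5):
        sim = random_similarity(rng, 9)
        sweep = sweep_thresholds(sim)
        t_star, _, _ = find_critical_network(sweep, method="consecutive")
        # oracle: brute-force edge symmetric-difference count per step
        edges = [set(map(frozenset, g.edges())) for g in sweep.graphs]
        drops = [len(edges[t] ^ edges[t + 1]) for t in range(100)]
        assert t_star == int(np.argmax(drops))


def test_planted_two_block_matrix_recovers_gap_threshold():
    sim = generate_block_similarity(10, 2, (94, 96), (49, 51), seed=42)
    t_star, graph, _ = find_critical_network(sweep_thresholds(sim))
    assert 51 < t_star + 1 <= 94
    comps = sorted(sorted(c) for c in nx.connected_components(graph))
    blocks = {}
    for label in sim.labels:
        blocks.setdefault(label.split("_")[0], []).append(label)
    assert comps == sorted(sorted(b) for b in blocks.values())


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def _partitions(collection):
    if len(collection) == 1:
        yield [collection]
        return
    first, rest = collection[0], collection[1:]
    for smaller in _partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1 :]
        yield [[first]] + smaller


def test_two_cliques_partition_matches_exhaustive_oracle():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    result = modularity_partition(g)
    assert result.Q == pytest.approx(0.5)
    # exhaustive search over all 4140 partitions of the 8 nodes
    best = max(
        nx.community.modularity(g, [set(p) for p in parts])
        for parts in _partitions(list(g.nodes))
    )
    assert result.Q == pytest.approx(best)
    communities = {}
    for node, comm in result.assignment.items():
        communities.setdefault(comm, set()).add(node)
    assert sorted(map(sorted, communities.values())) == [
        ["n0", "n1", "n2", "n3"],
        ["n4", "n5", "n6", "n7"],
    ]


def test_complete_graph_has_single_community():
    g = nx.complete_graph(5)
    result = modularity_partition(g)
    assert len(set(result.assignment.values())) == 1
    assert result.Q == pytest.approx(0.0)


def test_modularity_determinism_and_edgeless_degeneracy():
    g = nx.Graph()
    g.add_nodes_from("abc")
    degenerate = modularity_partition(g, seed=7)
    assert degenerate.degenerate and degenerate.Q == 0.0
    assert len(set(degenerate.assignment.values())) == 3
    h = nx.karate_club_graph()
    a = modularity_partition(h, algorithm="louvain", seed=5)
    b = modularity_partition(h, algorithm="louvain", seed=5)
    assert a.assignment == b.assignment and a.Q == b.Q


def test_partition_beats_trivial_single_community(rng):
    g = nx.gnp_random_graph(12, 0.3, seed=3)
    result = modularity_partition(g)
    trivial = nx.community.modularity(g, [set(g.nodes)])
    assert result.Q >= trivial


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def test_graphml_roundtrip_with_partition(tmp_path):
    g = nx.path_graph(3)
    g = nx.relabel_nodes(g, {0: "x", 1: "y", 2: "z"})
    partition = modularity_partition(g)
    path = tmp_path / "graph.graphml"
    export_graph(g, path, partition)
    back = nx.read_graphml(path)
    assert set(back.nodes) == {"x", "y", "z"}
    assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
    assert all("community" in back.nodes[n] for n in back.nodes)


def test_edgelist_export_of_edgeless_graph_is_header_only(tmp_path):
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    path = tmp_path / "edges.tsv"
    export_graph(g, path, format="edgelist_tsv")
    assert path.read_text() == "source\ttarget\tsimilarity\n"
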