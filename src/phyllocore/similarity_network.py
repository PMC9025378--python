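"""Integer sample-similarity networks, threshold sweeps and modularity.

A Bray-Curtis dissimilarity matrix is mapped to an integer similarity
matrix S = round((1 - BC) * 100), and one undirected graph is built per
integer threshold t = 0..100 by connecting every pair of samples with
S >= t.  The per-threshold network-distance curve locates the largest
structural change in that graph family; the network just past the
largest drop is taken as the *critical network*, the sparse structure
from which community (modularity) information is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .diversity import DistanceMatrix


@dataclass
class SimilarityMatrix:
    """Symmetric integer similarity matrix with entries in [0, 100]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("similarity values must be integers")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("similarity values must lie in [0, 100]")
        if not np.all(np.diag(self.values) == 100):
            raise ValueError("similarity diagonal must equal 100")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class ThresholdSweep:
    similarity: SimilarityMatrix
    thresholds: np.ndarray  # 0..100
    graphs: list[nx.Graph]  # one per threshold
    method: str | None = None
    distance_curve: np.ndarray | None = None  # filled by network_distance_curve


@dataclass
class Partition:
    assignment: dict[str, int]
    Q: float
    seed: int
    algorithm: str
    degenerate: bool = False


def to_similarity_matrix(
    dist: DistanceMatrix, rounding: str = "half_up"
) -> SimilarityMatrix:
    """Convert a [0,1] dissimilarity matrix to integer percent similarity.

    S(i,j) = round((1 - d(i,j)) * 100).  ``half_up`` rounds .5 upward
    (spreadsheet convention); ``half_even`` uses banker's rounding.
    """
    if dist.values.max() > 1 + 1e-12:
        raise ValueError("dissimilarities must lie in [0, 1]")
    sim = (1.0 - dist.values) * 100.0
    if rounding == "half_up":
        values = np.floor(sim + 0.5).astype(np.int64)
    elif rounding == "half_even":
        values = np.rint(sim).astype(np.int64)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    np.fill_diagonal(values, 100)
    return SimilarityMatrix(list(dist.labels), values)


def threshold_graph(sim: SimilarityMatrix, t: int) -> nx.Graph:
    """Graph with an edge for every pair with similarity >= t.

    All samples appear as nodes, so samples isolated at high thresholds
    are not silently dropped.  A pair whose similarity equals the
    threshold is connected (the comparison is >=).
    """
    if not 0 <= t <= 100:
        raise ValueError("threshold must lie in [0, 100]")
    g = nx.Graph(threshold=int(t))
    g.add_nodes_from(sim.labels)
    ii, jj = np.nonzero(np.triu(sim.values >= t, k=1))
    g.add_edges_from(
        (sim.labels[i], sim.labels[j], {"similarity": int(sim.values[i, j])})
        for i, j in zip(ii, jj)
    )
    return g


def sweep_thresholds(sim: SimilarityMatrix) -> ThresholdSweep:
    """Build the nested family of threshold graphs for t = 0..100."""
    thresholds = np.arange(101)
    graphs = [threshold_graph(sim, int(t)) for t in thresholds]
    return ThresholdSweep(sim, thresholds, graphs)


def _edge_set(g: nx.Graph) -> set[frozenset]:
    return {frozenset(e) for e in g.edges()}


def _reachability_pairs(g: nx.Graph) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for comp in nx.connected_components(g):
        comp = list(comp)
        for i in range(len(comp)):
            for j in range(i + 1, len(comp)):
                pairs.add(frozenset((comp[i], comp[j])))
    return pairs


def network_distance_curve(sweep: ThresholdSweep, method: str = "component") -> np.ndarray:
    """Per-threshold structural-change curve of the sweep.

    ``component`` (default): D(t) = |R(G_t) delta R(G_{t+1})| / C(n,2)
    for t = 0..99, where R(G) is the set of node pairs lying in the same
    connected component — the fraction of sample pairs whose mutual
    reachability collapses when the threshold is raised by one.  This is
    the percolation-style reading of network distance: individual edge
    losses inside a well-connected cluster score zero, while the step at
    which the network fragments into separate clusters scores the full
    weight of every pair it separates.

    ``consecutive``: the same construction on raw edge sets,
    D(t) = |E(G_t) delta E(G_{t+1})| / C(n,2).  ``from_initial``:
    D(t) = |E(G_0) delta E(G_t)| / C(n,2) for t = 0..100 (monotone).
    The curve is stored on the sweep together with the method tag.
    """
    n = sweep.similarity.n
    pairs = math.comb(n, 2)
    if pairs == 0:
        raise ValueError("need at least two samples")
    if method == "component":
        reach = [_reachability_pairs(g) for g in sweep.graphs]
        curve = np.array([len(reach[t] ^ reach[t + 1]) / pairs for t in range(100)])
    elif method == "consecutive":
        edge_sets = [_edge_set(g) for g in sweep.graphs]
        curve = np.array(
            [len(edge_sets[t] ^ edge_sets[t + 1]) / pairs for t in range(100)]
        )
    elif method == "from_initial":
        edge_sets = [_edge_set(g) for g in sweep.graphs]
        curve = np.array([len(edge_sets[0] ^ edge_sets[t]) / pairs for t in range(101)])
    else:
        raise ValueError(f"unknown method {method!r}")
    sweep.method = method
    sweep.distance_curve = curve
    return curve


def find_critical_network(
    sweep: ThresholdSweep, method: str = "component"
) -> tuple[int, nx.Graph, bool]:
    """Locate the most distant (critical) network of the sweep.

    Returns ``(t_star, graph, degenerate)`` where ``t_star`` is the
    threshold attaining the maximum of the distance curve (smallest such
    threshold on ties).  Under the step-wise methods (``component``,
    ``consecutive``) the critical graph is G_{t_star + 1}, the sparser
    network just after the largest structural drop; under
    ``from_initial`` it is G_{t_star}.  A flat all-zero curve is flagged
    degenerate and yields t_star = 0.
    """
    if sweep.distance_curve is None or sweep.method != method:
        network_distance_curve(sweep, method)
    curve = sweep.distance_curve
    assert curve is not None
    if np.all(curve == 0):
        return 0, sweep.graphs[0], True
    t_star = int(np.argmax(curve))  # argmax takes the first (smallest) maximum
    graph = sweep.graphs[t_star] if method == "from_initial" else sweep.graphs[t_star + 1]
    return t_star, graph, False


def modularity_partition(
    graph: nx.Graph, algorithm: str = "greedy", seed: int = 0
) -> Partition:
    """Community partition maximizing Newman-Girvan modularity heuristically.

    ``greedy`` uses agglomerative modularity maximization (deterministic);
    ``louvain`` uses the Louvain heuristic seeded for reproducibility.
    An edgeless graph degenerates to singleton communities with Q = 0.
    """
    if graph.number_of_edges() == 0:
        assignment = {node: i for i, node in enumerate(sorted(graph.nodes()))}
        return Partition(assignment, Q=0.0, seed=seed, algorithm=algorithm, degenerate=True)
    if algorithm == "greedy":
        communities = nx.community.greedy_modularity_communities(graph)
    elif algorithm == "louvain":
        communities = nx.community.louvain_communities(graph, seed=seed)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    assignment = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(graph, [set(c) for c in communities])
    return Partition(assignment, Q=float(q), seed=seed, algorithm=algorithm)


def export_graph(
    graph: nx.Graph,
    path: str | Path,
    partition: Partition | None = None,
    format: str = "graphml",
) -> None:
    """Write a graph as GraphML or a two-column TSV edge list.

    Node order is stabilized by sorting labels; the community id of a
    partition, when given, is attached as a node attribute.
    """
    out = nx.Graph()
    out.add_nodes_from(sorted(graph.nodes(), key=str))
    for u, v, data in graph.edges(data=True):
        # GraphML holds scalars only; flatten e.g. witness-sample lists
        clean = {
            k: (";".join(map(str, val)) if isinstance(val, (list, tuple, set)) else val)
            for k, val in data.items()
        }
        out.add_edge(u, v, **clean)
    if partition is not None:
        nx.set_node_attributes(out, partition.assignment, "community")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(out, path)
    elif format == "edgelist_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tsimilarity\n")
            for u, v in sorted((sorted((str(a), str(b))) for a, b in out.edges())):
                sim = out.edges[u, v].get("similarity", "")
                fh.write(f"{u}\t{v}\t{sim}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
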