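"""Within-species pocket-similarity graphs, community detection, and nulls.

A species' sparse pairwise alignment-score matrix becomes a weighted,
undirected graph after normalizing scores by the species maximum; the
unweighted companion keeps an edge only where the normalized score is
strictly greater than 0.1.  Singletons — pockets with no nonzero alignment
score to any other pocket — are defined on the raw scores, before
normalization and thresholding.  Communities are found with the Leiden
algorithm (CPM objective, resolution 0.01 by default, modularity
selectable); three null models are provided: degree-preserving rewiring,
uniform random graphs with matched node/edge counts, and symmetric
permutation of the score multiset.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import igraph as ig
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import linregress

from .model import SimilarityMatrix


@dataclass
class PocketGraph:
    """Weighted/unweighted views of one species' pocket-similarity graph."""

    species: str
    nodes: list[str]
    weighted_edges: list[tuple[str, str, float]]  # max-normalized scores in (0, 1]
    edge_threshold: float = 0.1
    normalization_max: float | None = None

    @property
    def unweighted_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, w in self.weighted_edges if w > self.edge_threshold]

    def to_networkx(self, weighted: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        if weighted:
            g.add_weighted_edges_from(self.weighted_edges)
        else:
            g.add_edges_from(self.unweighted_edges)
        return g

    def degree_sequence(self, weighted: bool = False) -> dict[str, int]:
        return dict(self.to_networkx(weighted=weighted).degree())


@dataclass
class ClusteringResult:
    """Partition of a species' pockets into communities and singletons.

    ``communities`` holds node sets of size >= 2.  ``singletons`` is every
    node not placed in a community; its provenance is tracked separately:
    ``alignment_singletons`` (no raw alignment score at all),
    ``threshold_isolated`` (scores present but all at or below the edge
    threshold), and ``partition_isolates`` (size-1 clusters emitted by the
    partitioner).  n_unique = |communities| + |singletons|.
    """

    species: str
    communities: list[frozenset[str]]
    singletons: frozenset[str]
    alignment_singletons: frozenset[str] = frozenset()
    threshold_isolated: frozenset[str] = frozenset()
    partition_isolates: frozenset[str] = frozenset()

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    @property
    def n_unique(self) -> int:
        return self.n_communities + self.n_singletons

    @property
    def largest_community(self) -> int:
        return max((len(c) for c in self.communities), default=0)

    @property
    def n_pockets(self) -> int:
        return sum(len(c) for c in self.communities) + self.n_singletons

    def singleton_fraction(self) -> float:
        return self.n_singletons / self.n_pockets if self.n_pockets else 0.0


def build_graph(sim: SimilarityMatrix, edge_threshold: float = 0.1) -> PocketGraph:
    """Normalize scores by the species maximum and build both graph views.

    The unweighted edge rule is strict: normalized score > ``edge_threshold``.
    An all-zero matrix yields a graph with no edges (normalization maximum
    undefined).
    """
    max_score = sim.max_score()
    if max_score == 0.0:
        return PocketGraph(sim.species, list(sim.pocket_ids), [], edge_threshold, None)
    coo = sp.triu(sim.scores, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row))
    edges = [
        (sim.pocket_ids[coo.row[k]], sim.pocket_ids[coo.col[k]], float(coo.data[k]) / max_score)
        for k in order
    ]
    return PocketGraph(sim.species, list(sim.pocket_ids), edges, edge_threshold, max_score)


def find_singletons(sim: SimilarityMatrix) -> frozenset[str]:
    """Pockets with no nonzero raw alignment score to any other pocket."""
    deg = sim.degrees()
    return frozenset(pid for pid, d in zip(sim.pocket_ids, deg) if d == 0)


def components_at_threshold(sim: SimilarityMatrix, raw_threshold: float) -> ClusteringResult:
    """Connected components of the graph with edges where raw score >= t.

    Size-1 components are counted with the singletons.
    """
    present = sim.scores > 0
    if raw_threshold > 0:
        adjacency = (sim.scores >= raw_threshold).multiply(present)
    else:
        adjacency = present
    n_comp, labels = connected_components(sp.csr_matrix(adjacency), directed=False)
    groups: dict[int, list[str]] = {}
    for pid, lab in zip(sim.pocket_ids, labels):
        groups.setdefault(int(lab), []).append(pid)
    communities = [frozenset(g) for g in groups.values() if len(g) >= 2]
    single = frozenset(g[0] for g in groups.values() if len(g) == 1)
    return ClusteringResult(
        species=sim.species,
        communities=communities,
        singletons=single,
        alignment_singletons=find_singletons(sim),
    )


def leiden_communities(
    graph: PocketGraph,
    resolution: float = 0.01,
    weighted: bool = False,
    objective: str = "CPM",
    seed: int = 0,
    alignment_singletons: frozenset[str] = frozenset(),
) -> ClusteringResult:
    """Leiden partition of the non-isolated subgraph.

    Degree-0 nodes are held out before partitioning and reported as
    singletons (split into alignment singletons vs threshold-isolated
    nodes); size-1 clusters emitted by Leiden are reported as partition
    isolates.  Seed-pinned for reproducibility.
    """
    g = graph.to_networkx(weighted=weighted)
    isolated = frozenset(n for n, d in g.degree() if d == 0)
    core_nodes = [n for n in graph.nodes if n not in isolated]
    communities: list[frozenset[str]] = []
    partition_isolates: set[str] = set()
    if core_nodes:
        index = {n: k for k, n in enumerate(core_nodes)}
        if weighted:
            edges = [
                (index[u], index[v]) for u, v, _ in graph.weighted_edges if u in index and v in index
            ]
            weights = [w for u, v, w in graph.weighted_edges if u in index and v in index]
        else:
            edges = [(index[u], index[v]) for u, v in graph.unweighted_edges]
            weights = None
        igg = ig.Graph(n=len(core_nodes), edges=edges)
        state = random.getstate()
        random.seed(seed)
        try:
            membership = igg.community_leiden(
                objective_function=objective,
                weights=weights,
                resolution=resolution,
                n_iterations=4,
            ).membership
        finally:
            random.setstate(state)
        groups: dict[int, list[str]] = {}
        for node, m in zip(core_nodes, membership):
            groups.setdefault(m, []).append(node)
        for g_nodes in groups.values():
            if len(g_nodes) >= 2:
                communities.append(frozenset(g_nodes))
            else:
                partition_isolates.add(g_nodes[0])
    align_single = alignment_singletons & isolated
    threshold_isolated = isolated - align_single
    singletons = frozenset(isolated | partition_isolates)
    communities.sort(key=lambda c: (-len(c), min(c)))
    return ClusteringResult(
        species=graph.species,
        communities=communities,
        singletons=singletons,
        alignment_singletons=frozenset(align_single),
        threshold_isolated=frozenset(threshold_isolated),
        partition_isolates=frozenset(partition_isolates),
    )


def cluster_similarity(
    sim: SimilarityMatrix,
    edge_threshold: float = 0.1,
    resolution: float = 0.01,
    weighted: bool = False,
    seed: int = 0,
) -> ClusteringResult:
    """Convenience path: build the graph, hold out singletons, run Leiden."""
    graph = build_graph(sim, edge_threshold=edge_threshold)
    return leiden_communities(
        graph,
        resolution=resolution,
        weighted=weighted,
        seed=seed,
        alignment_singletons=find_singletons(sim),
    )


# ---------------------------------------------------------------------------
# null models

def rewire_degree_preserving(graph: PocketGraph, n_swaps: int | None = None, seed: int = 0) -> PocketGraph:
    """Randomize the unweighted graph by double-edge swaps.

    The degree of every node is unchanged and no self-loops or multi-edges
    are introduced.  Default swap budget is 10 x |E| attempts (enough to mix
    the edge set); graphs with no valid swap are returned unchanged.
    """
    g = graph.to_networkx(weighted=False)
    n_edges = g.number_of_edges()
    if n_swaps is None:
        n_swaps = 10 * n_edges
    if n_edges >= 2 and g.number_of_nodes() >= 4 and n_swaps > 0:
        try:
            nx.double_edge_swap(g, nswap=n_swaps, max_tries=max(100, 20 * n_swaps), seed=seed)
        except nx.NetworkXError:
            pass  # swap attempts exhausted; degrees are preserved regardless
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    return PocketGraph(
        species=graph.species,
        nodes=list(graph.nodes),
        weighted_edges=[(u, v, 1.0) for u, v in edges],
        edge_threshold=graph.edge_threshold,
        normalization_max=graph.normalization_max,
    )


def random_graph_same_density(graph: PocketGraph, seed: int = 0) -> PocketGraph:
    """Uniform random graph with the same node and edge counts."""
    n = len(graph.nodes)
    m = len(graph.unweighted_edges)
    g = nx.gnm_random_graph(n, m, seed=seed)
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    return PocketGraph(
        species=graph.species,
        nodes=list(graph.nodes),
        weighted_edges=[(graph.nodes[u], graph.nodes[v], 1.0) for u, v in edges],
        edge_threshold=graph.edge_threshold,
        normalization_max=graph.normalization_max,
    )


def randomize_score_matrix(sim: SimilarityMatrix, seed: int = 0) -> SimilarityMatrix:
    """Permute the off-diagonal score multiset over uniformly random pairs,
    keeping the matrix symmetric.  The score multiset is preserved."""
    rng = np.random.default_rng(seed)
    n = sim.n_pockets
    values = sp.triu(sim.scores, k=1).tocoo().data.copy()
    n_pairs = n * (n - 1) // 2
    if len(values) > n_pairs:
        raise ValueError("more scores than available pairs")
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < len(values):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            pairs.add((min(int(i), int(j)), max(int(i), int(j))))
    ordered = sorted(pairs)
    rows = np.array([p[0] for p in ordered], dtype=int)
    cols = np.array([p[1] for p in ordered], dtype=int)
    rng.shuffle(values)
    scores = sp.coo_matrix((values, (rows, cols)), shape=(n, n))
    return SimilarityMatrix(sim.species, list(sim.pocket_ids), scores)


# ---------------------------------------------------------------------------
# cluster-size statistics

def cluster_size_histogram(result: ClusteringResult) -> dict[int, int]:
    """Frequency of each community size (singletons not included)."""
    hist: dict[int, int] = {}
    for c in result.communities:
        hist[len(c)] = hist.get(len(c), 0) + 1
    return dict(sorted(hist.items()))


def size_distribution_slope(hist: dict[int, int], bins_per_decade: int = 5) -> float:
    """Power-law slope of the community-size distribution.

    OLS of log(density) on log(size) after logarithmic binning of the
    histogram (density = count / bin width); raw per-size frequencies
    flatten the tail (many sizes observed exactly once) and bias the slope,
    so the standard log-binned estimator is used.  The negated slope is the
    size-distribution exponent.
    """
    sizes = np.array(sorted(s for s, f in hist.items() if f > 0), dtype=float)
    if len(sizes) < 3:
        raise ValueError("need at least 3 distinct sizes for a slope")
    counts = np.array([hist[int(s)] for s in sizes], dtype=float)
    lo, hi = sizes.min(), sizes.max()
    n_bins = max(3, int(np.ceil(np.log10(hi / lo) * bins_per_decade)))
    edges = np.geomspace(lo, hi * (1 + 1e-9), n_bins + 1)
    idx = np.clip(np.digitize(sizes, edges) - 1, 0, n_bins - 1)
    x, y = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        width = edges[b + 1] - edges[b]
        x.append(np.log(np.sqrt(edges[b] * edges[b + 1])))  # geometric bin center
        y.append(np.log(counts[mask].sum() / width))
    if len(x) < 3:
        raise ValueError("too few occupied bins for a slope")
    fit = linregress(x, y)
    return float(fit.slope)
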