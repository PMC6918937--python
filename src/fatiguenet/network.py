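"""Binary brain-network construction and small-world analysis.

A weighted mutual-information adjacency matrix is binarized either by an
absolute weight threshold (edge kept iff weight >= T) or by fixing the mean
degree K (keep the ``round(n*K/2)`` largest weights).  On the resulting
simple undirected graph this module computes

* the clustering coefficient ``C = mean_i 2 E_i / (K_i (K_i - 1))`` (nodes
  of degree < 2 contribute 0),
* the characteristic path length ``L``, the mean shortest-path distance in
  hops over ordered node pairs (reachable pairs only if the graph is
  disconnected, which is flagged),
* the small-world index ``sigma = (C / C_rand) / (L / L_rand)`` where
  ``C_rand, L_rand`` are ensemble means over degree-preserving random
  rewirings of the same graph (Maslov-Sneppen double-edge swaps).

``sigma > 1`` indicates clustering above, and path length near, that of
degree-matched random graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import WeightedAdjacency

__all__ = [
    "BinaryGraph",
    "SmallWorldResult",
    "ThresholdSweep",
    "binarize_by_threshold",
    "binarize_by_degree",
    "clustering_coefficient",
    "characteristic_path_length",
    "is_connected",
    "maslov_sneppen_rewire",
    "small_world",
    "threshold_sweep",
    "default_thresholds",
    "write_pajek",
    "write_graphml",
]


@dataclass(frozen=True)
class BinaryGraph:
    """Simple undirected graph over labelled nodes, stored as a boolean matrix."""

    adjacency: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if adj.shape[0] != len(self.labels):
            raise ValueError("label count must match adjacency size")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def from_edges(
        cls, labels: Sequence[str], edges: Iterable[tuple[str, str]]
    ) -> "BinaryGraph":
        labels = tuple(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=bool)
        for a, b in edges:
            i, j = idx[a], idx[b]
            if i == j:
                raise ValueError(f"self-loop on {a!r}")
            adj[i, j] = adj[j, i] = True
        return cls(adj, labels)

    @classmethod
    def from_networkx(cls, g) -> "BinaryGraph":
        import networkx as nx

        nodes = list(g.nodes())
        adj = nx.to_numpy_array(g, nodelist=nodes) > 0
        return cls(adj, tuple(str(v) for v in nodes))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from((self.labels[a], self.labels[b]) for a, b in zip(i, j))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    @property
    def isolated_nodes(self) -> tuple[str, ...]:
        deg = self.degrees
        return tuple(lab for lab, d in zip(self.labels, deg) if d == 0)


@dataclass(frozen=True)
class SmallWorldResult:
    """C, L, degree-matched null-ensemble means, and the small-world index."""

    C: float
    L: float
    C_rand: float
    L_rand: float
    sigma: Optional[float]
    n_nulls: int
    disconnected: bool = False

    def as_dict(self) -> dict:
        return {
            "C": self.C,
            "L": self.L,
            "C_rand": self.C_rand,
            "L_rand": self.L_rand,
            "sigma": self.sigma,
            "n_nulls": self.n_nulls,
            "disconnected": self.disconnected,
        }


@dataclass(frozen=True)
class ThresholdSweep:
    """Small-world metrics along an ascending list of binarization thresholds.

    ``results[i]`` is ``None`` where the graph at ``thresholds[i]`` has
    isolated nodes (such thresholds violate the no-isolated-node
    construction principle and are flagged, not computed).
    """

    thresholds: tuple[float, ...]
    results: tuple[Optional[SmallWorldResult], ...]
    isolated: tuple[bool, ...]
    edge_counts: tuple[int, ...]

    @property
    def valid_thresholds(self) -> tuple[float, ...]:
        return tuple(
            t for t, iso in zip(self.thresholds, self.isolated) if not iso
        )


def default_thresholds(
    lo: float = 0.15, hi: float = 0.35, step: float = 0.01
) -> tuple[float, ...]:
    """The default binarization sweep: 0.15 to 0.35 in steps of 0.01."""
    n = int(round((hi - lo) / step))
    return tuple(np.round(lo + step * np.arange(n + 1), 10))


def binarize_by_threshold(adj: WeightedAdjacency, threshold: float) -> BinaryGraph:
    """Edge (i, j) kept iff ``weight_ij >= threshold`` (ties survive).

    Isolated nodes are reported through :attr:`BinaryGraph.isolated_nodes`,
    not silently repaired: the no-isolated-node construction principle
    makes them a flagged outcome for the caller.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mat = adj.values >= threshold
    np.fill_diagonal(mat, False)
    return BinaryGraph(mat, adj.channels)


def binarize_by_degree(adj: WeightedAdjacency, k: float) -> BinaryGraph:
    """Keep the ``m = round(n * K / 2)`` largest weights as edges (mean degree K).

    Rounding is half-up (n = 19, K = 5 gives 48 edges).  Ties among equal
    weights are broken by lexicographic (i, j) node-index order, making the
    construction deterministic.
    """
    n = len(adj.channels)
    if k < 1:
        raise ValueError("mean degree K must be >= 1")
    m = int(np.floor(n * k / 2.0 + 0.5))
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ValueError(f"mean degree K={k} infeasible: needs {m} > {max_edges} edges")
    iu, ju = np.triu_indices(n, k=1)
    w = adj.values[iu, ju]
    # stable sort on -w keeps lexicographic (i, j) order within ties
    order = np.argsort(-w, kind="stable")[:m]
    mat = np.zeros((n, n), dtype=bool)
    mat[iu[order], ju[order]] = True
    return BinaryGraph(mat | mat.T, adj.channels)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean local clustering: fraction of a node's neighbour pairs that are linked.

    ``C_i = 2 E_i / (K_i (K_i - 1))`` for degree >= 2, else 0; ``C`` is the
    mean over all nodes.
    """
    if g.n_nodes < 1:
        raise ValueError("graph must have at least one node")
    a = g.adjacency.astype(float)
    deg = a.sum(axis=1)
    triangles2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * E_i per node
    denom = deg * (deg - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, triangles2 / denom, 0.0)
    return float(ci.mean())


def _hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by breadth-first boolean matrix expansion.

    Equivalent to per-source BFS (or Dijkstra with unit weights); the loop
    runs once per diameter step, which keeps it fast on the small dense
    graphs this pipeline produces.
    """
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj] = 1.0
    reached = adj | np.eye(n, dtype=bool)
    frontier = adj
    hops = 1
    while frontier.any():
        nxt = (frontier.astype(np.uint8) @ adj.astype(np.uint8) > 0) & ~reached
        hops += 1
        dist[nxt] = hops
        reached |= nxt
        frontier = nxt
    return dist


def _path_length(g: BinaryGraph) -> tuple[float, bool]:
    if g.n_edges == 0:
        raise ValueError("characteristic path length undefined for an edgeless graph")
    d = _hop_distances(g.adjacency)
    off = ~np.eye(g.n_nodes, dtype=bool)
    dists = d[off]
    finite = np.isfinite(dists)
    disconnected = not finite.all()
    return float(dists[finite].mean()), disconnected


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length (hops) over ordered pairs ``i != j``.

    Unweighted Dijkstra (equivalent to BFS).  If the graph is disconnected
    the mean runs over reachable pairs only; use :func:`is_connected` or
    :class:`SmallWorldResult.disconnected` to detect that situation.

    Raises
    ------
    ValueError
        If the graph has no edges (every distance infinite).
    """
    if g.n_nodes < 2:
        raise ValueError("graph must have at least two nodes")
    return _path_length(g)[0]


def is_connected(g: BinaryGraph) -> bool:
    if g.n_nodes == 0:
        return False
    n_comp, _ = connected_components(csr_matrix(g.adjacency), directed=False)
    return n_comp == 1


def maslov_sneppen_rewire(
    g: BinaryGraph,
    n_swaps: Optional[int] = None,
    seed: int = 0,
    max_attempt_factor: int = 100,
) -> BinaryGraph:
    """Degree-preserving randomization by double-edge swaps.

    Repeatedly picks two edges (a, b), (c, d) and proposes the exchange
    (a, d), (c, b) -- rejecting self-loops and multi-edges -- until
    ``n_swaps`` swaps are accepted (default ``10 * n_edges``, a standard
    mixing budget).  Every node's degree is invariant under the move, so
    the output has exactly the input's degree sequence and edge count.
    Deterministic given ``seed``.

    If the accepted-swap budget is unreachable (e.g. complete graphs or
    triangles admit no valid swap) the attempt cap ``max_attempt_factor *
    n_swaps`` is hit and the graph randomized so far is returned with a
    warning.

    Dense graphs (edge density > 1/2) are rewired through their complement:
    a double-edge swap on the complement preserves every original degree
    just as well, and proposal acceptance stays high, so near-complete
    graphs do not stall.  For the complete graph the complement is empty
    and the graph is returned unchanged (its degree sequence admits a
    single realization).
    """
    n = g.n_nodes
    density = g.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0
    complemented = density > 0.5
    if n_swaps is None:
        n_swaps = 10 * g.n_edges
    if complemented:
        comp = ~g.adjacency
        np.fill_diagonal(comp, False)
        work = BinaryGraph(comp, g.labels)
    else:
        work = g
    edges = work.edges
    m = len(edges)
    if m < 2:
        if not complemented:
            warnings.warn("fewer than two edges: nothing to rewire", stacklevel=2)
        return BinaryGraph(g.adjacency.copy(), g.labels)
    rng = np.random.default_rng(seed)
    edge_list: list[tuple[int, int]] = list(edges)
    edge_set = set(edge_list)

    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * n_swaps
    chunk = 1024
    while accepted < n_swaps and attempts < max_attempts:
        pairs = rng.integers(0, m, size=(chunk, 2)).tolist()
        flips = rng.integers(0, 2, size=chunk).tolist()
        for (e1, e2), flip in zip(pairs, flips):
            if accepted >= n_swaps or attempts >= max_attempts:
                break
            attempts += 1
            if e1 == e2:
                continue
            a, b = edge_list[e1]
            c, d = edge_list[e2]
            if flip:
                c, d = d, c
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            e_ad = (a, d) if a < d else (d, a)
            e_cb = (c, b) if c < b else (b, c)
            if e_ad in edge_set or e_cb in edge_set:
                continue
            edge_set.remove(edge_list[e1])
            edge_set.remove(edge_list[e2])
            edge_set.add(e_ad)
            edge_set.add(e_cb)
            edge_list[e1] = e_ad
            edge_list[e2] = e_cb
            accepted += 1
    adj = np.zeros_like(work.adjacency)
    if edge_list:
        idx = np.array(edge_list, dtype=np.int64)
        adj[idx[:, 0], idx[:, 1]] = True
        adj |= adj.T
    if accepted < n_swaps:
        warnings.warn(
            f"rewiring stopped after {attempts} attempts with {accepted}/{n_swaps} "
            "accepted swaps (graph admits few valid moves)",
            stacklevel=2,
        )
    if complemented:
        adj = ~adj
        np.fill_diagonal(adj, False)
    return BinaryGraph(adj, g.labels)


def small_world(
    g: BinaryGraph,
    n_nulls: int = 250,
    seed: int = 0,
    n_swaps: Optional[int] = None,
) -> SmallWorldResult:
    """Small-world index of ``g`` against a Maslov-Sneppen null ensemble.

    ``C_rand`` and ``L_rand`` are means over ``n_nulls`` independent
    degree-preserving rewirings (null i is seeded from ``seed`` and i, so
    the ensemble is reproducible).  ``sigma = (C/C_rand) / (L/L_rand)``;
    it is reported as ``None`` when ``C_rand = 0`` (triangle-free nulls
    leave the ratio undefined).
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    c = clustering_coefficient(g)
    length, disconnected = _path_length(g)
    c_nulls = np.empty(n_nulls)
    l_nulls = np.empty(n_nulls)
    any_null_disconnected = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unswappable graphs are handled below
        for i in range(n_nulls):
            child = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0])
            null = maslov_sneppen_rewire(g, n_swaps=n_swaps, seed=child)
            c_nulls[i] = clustering_coefficient(null)
            ln, disc = _path_length(null)
            l_nulls[i] = ln
            any_null_disconnected |= disc
    c_rand = float(c_nulls.mean())
    l_rand = float(l_nulls.mean())
    if c_rand > 0 and length > 0 and l_rand > 0:
        sigma = (c / c_rand) / (length / l_rand)
    else:
        sigma = None
    return SmallWorldResult(
        C=c,
        L=length,
        C_rand=c_rand,
        L_rand=l_rand,
        sigma=sigma,
        n_nulls=n_nulls,
        disconnected=disconnected or any_null_disconnected,
    )


def threshold_sweep(
    adj: WeightedAdjacency,
    thresholds: Optional[Sequence[float]] = None,
    n_nulls: int = 250,
    seed: int = 0,
    n_swaps: Optional[int] = None,
) -> ThresholdSweep:
    """Binarize at each threshold and compute small-world metrics.

    Thresholds whose graph has isolated nodes (or no edges) are marked and
    skipped, honouring the no-isolated-node construction principle.
    """
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    results: list[Optional[SmallWorldResult]] = []
    isolated: list[bool] = []
    counts: list[int] = []
    for t_idx, t in enumerate(thresholds):
        graph = binarize_by_threshold(adj, t)
        counts.append(graph.n_edges)
        if graph.isolated_nodes or graph.n_edges == 0:
            isolated.append(True)
            results.append(None)
            continue
        isolated.append(False)
        child = int(
            np.random.SeedSequence(seed, spawn_key=(1000 + t_idx,)).generate_state(1)[0]
        )
        results.append(small_world(graph, n_nulls=n_nulls, seed=child, n_swaps=n_swaps))
    return ThresholdSweep(
        thresholds=thresholds,
        results=tuple(results),
        isolated=tuple(isolated),
        edge_counts=tuple(counts),
    )


def write_pajek(g: BinaryGraph, path) -> None:
    """Export as a Pajek .net file (the format used by common graph viewers)."""
    import networkx as nx

    nx.write_pajek(g.to_networkx(), path)


def write_graphml(g: BinaryGraph, path) -> None:
    import networkx as nx

    nx.write_graphml(g.to_networkx(), path)
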