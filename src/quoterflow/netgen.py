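"""Network ensembles and structural metrics.

Generators cover the random-graph families used to probe how structure shapes
information flow: Erdős–Rényi (density), Barabási–Albert (degree hubs),
Watts–Strogatz (clustering), dichotomous configuration-model graphs (tunable
degree variance at fixed mean degree), and the two-block stochastic block
model (community structure).  A degree-preserving connected x-swap
randomizer lowers transitivity while fixing the degree sequence, and
Newman modularity / transitivity / summary metrics quantify the structure.

Graphs are plain :class:`networkx.Graph` objects with nodes ``0..N-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np

__all__ = [
    "DichotomousSpec",
    "SBMSpec",
    "NetworkMetrics",
    "generate_er",
    "generate_ba",
    "generate_ws",
    "generate_dichotomous",
    "generate_sbm",
    "xswap_randomize",
    "transitivity",
    "newman_modularity",
    "expected_sbm_modularity",
    "summary_metrics",
]


@dataclass(frozen=True)
class DichotomousSpec:
    """Two-degree configuration-model family: N/2 nodes of degree k1 and N/2
    of degree k2.  Mean degree μ = (k1+k2)/2; degree variance σ² = (k1−k2)²/4;
    k1/k2 = 1 recovers a random k-regular graph."""

    N: int
    k1: int
    k2: int

    def __post_init__(self):
        if self.N < 2 or self.N % 2:
            raise ValueError("N must be even and >= 2")
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("degrees must be >= 1")
        if max(self.k1, self.k2) >= self.N:
            raise ValueError("degrees must be < N for a simple graph")
        if (self.N // 2) * (self.k1 + self.k2) % 2:
            raise ValueError("stub sum N/2*(k1+k2) must be even")

    @property
    def mu(self) -> float:
        return (self.k1 + self.k2) / 2.0

    @property
    def sigma2(self) -> float:
        return (self.k1 - self.k2) ** 2 / 4.0

    @property
    def ratio(self) -> float:
        return min(self.k1, self.k2) / max(self.k1, self.k2)


@dataclass(frozen=True)
class SBMSpec:
    """Two equal planted blocks of size m = N/2 with within-block connection
    probability p0 and between-block probability p1."""

    N: int
    p0: float
    p1: float

    def __post_init__(self):
        if self.N < 2 or self.N % 2:
            raise ValueError("N must be even and >= 2")
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0):
            raise ValueError("connection probabilities must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.N // 2


@dataclass(frozen=True)
class NetworkMetrics:
    """Structural summary of a graph.

    ``density_pairs`` is M / C(N,2) (classic edge density); ``density_mn2``
    is M / N² (the density axis used for cross-network comparisons).  Both
    coexist because both appear in practice.
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    density_pairs: float
    density_mn2: float
    transitivity: float
    aspl: float
    modularity: float
    assortativity: float


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_er(N: int, k_avg: float, seed: Optional[int] = None) -> nx.Graph:
    """Erdős–Rényi graph G(N, p) with p = k_avg/(N−1)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not 0 <= k_avg <= N - 1:
        raise ValueError("k_avg must lie in [0, N-1]")
    return nx.fast_gnp_random_graph(N, k_avg / (N - 1), seed=seed)


def generate_ba(N: int, k_avg: int, seed: Optional[int] = None) -> nx.Graph:
    """Barabási–Albert graph grown with m = k_avg/2 links per arriving node.

    The first arrival links to all m seed nodes (resolving the degree-0 seed
    ambiguity); mean degree approaches k_avg for large N.  k_avg must be even.
    """
    if k_avg % 2 or k_avg < 2:
        raise ValueError("k_avg must be even and >= 2")
    m = k_avg // 2
    if N <= m:
        raise ValueError("N must exceed k_avg/2")
    return nx.barabasi_albert_graph(N, m, seed=seed)


def generate_ws(N: int, k: int, p_rewire: float, seed: Optional[int] = None) -> nx.Graph:
    """Watts–Strogatz ring lattice (k nearest neighbors) with each lattice
    edge rewired with probability ``p_rewire``; M = Nk/2 is preserved."""
    if k % 2:
        raise ValueError("k must be even")
    if k >= N:
        raise ValueError("k must be < N")
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError("p_rewire must lie in [0, 1]")
    return nx.watts_strogatz_graph(N, k, p_rewire, seed=seed)


def generate_dichotomous(spec: DichotomousSpec, seed: Optional[int] = None,
                         randomize_factor: int = 10) -> nx.Graph:
    """Simple connected graph with exactly N/2 nodes of degree k1 and N/2 of
    degree k2.

    Built deterministically by Havel–Hakimi (exact degrees, simple), repaired
    to a single component by degree-preserving cross-component rewiring, then
    randomized with ``randomize_factor * M`` connected x-swap attempts.
    """
    rng = np.random.default_rng(seed)
    m = spec.N // 2
    deg_seq = [spec.k1] * m + [spec.k2] * m
    if not nx.is_graphical(deg_seq):
        raise ValueError(f"degree sequence for {spec} is not graphical")
    g = nx.havel_hakimi_graph(deg_seq)
    _connect_components(g, rng)
    M = g.number_of_edges()
    g = xswap_randomize(g, n_swaps=randomize_factor * M,
                        seed=int(rng.integers(0, 2**31)))
    return g


def _connect_components(g: nx.Graph, rng: np.random.Generator) -> None:
    """Merge components in place by swapping one edge from each of two
    components: (a,b),(c,d) → (a,c),(b,d) keeps all degrees and is always
    simple across components."""
    comps = [list(c) for c in nx.connected_components(g)]
    while len(comps) > 1:
        e1 = _component_edge(g, comps[0], rng)
        e2 = _component_edge(g, comps[1], rng)
        if e1 is None or e2 is None:
            raise ValueError("cannot connect components without edges")
        (a, b), (c, d) = e1, e2
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, c)
        g.add_edge(b, d)
        comps = [list(c) for c in nx.connected_components(g)]


def _component_edge(g, comp, rng):
    comp = sorted(comp)
    order = rng.permutation(len(comp))
    for i in order:
        v = comp[i]
        nbrs = sorted(g.neighbors(v))
        if nbrs:
            return (v, nbrs[int(rng.integers(0, len(nbrs)))])
    return None


def generate_sbm(spec: SBMSpec, seed: Optional[int] = None):
    """Two-block planted-partition graph.

    Returns ``(graph, blocks)`` where blocks maps nodes 0..m-1 to ``"A"`` and
    m..N-1 to ``"B"``.
    """
    m = spec.m
    g = nx.stochastic_block_model(
        [m, m], [[spec.p0, spec.p1], [spec.p1, spec.p0]], seed=seed)
    g = nx.Graph(g)  # strip block-model metadata wrapper
    blocks = {v: ("A" if v < m else "B") for v in range(spec.N)}
    return g, blocks


# ---------------------------------------------------------------------------
# Degree-preserving randomization
# ---------------------------------------------------------------------------

def xswap_randomize(g: nx.Graph, n_swaps: int, seed: Optional[int] = None,
                    check_interval: int = 1) -> nx.Graph:
    """Randomize a connected graph by ``n_swaps`` attempted double edge swaps.

    Each attempt picks two distinct edges and exchanges endpoints
    ((a,b),(c,d) → (a,d),(c,b)); swaps creating self-loops or parallel edges
    are rejected, so the degree sequence and edge count are exactly
    preserved.  Connectivity is verified every ``check_interval`` accepted
    swaps and the offending batch is rolled back if the graph disconnected,
    so the result is always connected.  Attempts on swap-saturated graphs
    (e.g. complete graphs) are simply rejected, leaving the input unchanged.
    """
    if not nx.is_connected(g):
        raise ValueError("xswap_randomize requires a connected graph")
    if check_interval < 1:
        raise ValueError("check_interval must be >= 1")
    rng = np.random.default_rng(seed)
    h = g.copy()
    edges = [tuple(e) for e in h.edges]
    M = len(edges)
    if M < 2 or n_swaps == 0:
        return h
    undo: list[tuple[int, int, tuple, tuple]] = []  # (idx1, idx2, old_e1, old_e2)
    accepted_in_batch = 0
    for _ in range(int(n_swaps)):
        i, j = rng.integers(0, M, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        (p, q_), (r, s) = new1, new2
        if p == q_ or r == s:
            continue
        if h.has_edge(p, q_) or h.has_edge(r, s):
            continue
        if (p, q_) == (r, s) or (p, q_) == (s, r):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(p, q_)
        h.add_edge(r, s)
        undo.append((int(i), int(j), (a, b), (c, d)))
        edges[i] = new1
        edges[j] = new2
        accepted_in_batch += 1
        if accepted_in_batch >= check_interval:
            if nx.is_connected(h):
                undo.clear()
            else:
                for idx1, idx2, old1, old2 in reversed(undo):
                    h.remove_edge(*edges[idx1])
                    h.remove_edge(*edges[idx2])
                    h.add_edge(*old1)
                    h.add_edge(*old2)
                    edges[idx1] = old1
                    edges[idx2] = old2
                undo.clear()
            accepted_in_batch = 0
    if undo and not nx.is_connected(h):
        for idx1, idx2, old1, old2 in reversed(undo):
            h.remove_edge(*edges[idx1])
            h.remove_edge(*edges[idx2])
            h.add_edge(*old1)
            h.add_edge(*old2)
            edges[idx1] = old1
            edges[idx2] = old2
    return h


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def transitivity(g: nx.Graph) -> float:
    """Global transitivity T(G) = 3·N_triangles / N_triads; 0 for triad-free
    graphs (avoiding 0/0)."""
    return float(nx.transitivity(g))


def newman_modularity(g: nx.Graph, blocks: Mapping[int, object]) -> float:
    """Newman modularity Q = (1/2M)·Σij [aij − ki·kj/(2M)]·δ(ci, cj).

    Computed community-wise as Σc [Lc/M − (dc/2M)²] with Lc the edges inside
    community c and dc its degree sum; −1/2 ≤ Q ≤ 1.
    """
    M = g.number_of_edges()
    if M < 1:
        raise ValueError("modularity is undefined for an empty graph")
    unassigned = [v for v in g.nodes if v not in blocks]
    if unassigned:
        raise ValueError(f"nodes without community assignment: {unassigned[:5]}")
    internal: dict = {}
    deg_sum: dict = {}
    for v in g.nodes:
        deg_sum[blocks[v]] = deg_sum.get(blocks[v], 0) + g.degree(v)
    for u, v in g.edges:
        if blocks[u] == blocks[v]:
            internal[blocks[u]] = internal.get(blocks[u], 0) + 1
    two_m = 2.0 * M
    q = 0.0
    for c, dc in deg_sum.items():
        q += internal.get(c, 0) / M - (dc / two_m) ** 2
    return float(q)


def expected_sbm_modularity(spec: SBMSpec) -> float:
    """Expected Newman modularity of the planted two-block partition.

    For two equal blocks of size m, the expected within-edge fraction is
    (m−1)p0 / ((m−1)p0 + m·p1) and the degree-based null expectation is 1/2,
    giving ``Q = ((m−1)p0 − m·p1) / (2·((m−1)p0 + m·p1))``: 1/2 when p1 = 0
    (two disconnected modules) and → 0 when p0 = p1 with large m.
    """
    if spec.p0 == 0.0 and spec.p1 == 0.0:
        raise ValueError("expected modularity undefined for an empty SBM")
    m = spec.m
    within = (m - 1) * spec.p0
    between = m * spec.p1
    return float((within - between) / (2.0 * (within + between)))


def summary_metrics(g: nx.Graph, seed: Optional[int] = None,
                    largest_component_fallback: bool = False,
                    fast: bool = False) -> NetworkMetrics:
    """All-in-one structural summary.

    The modularity column uses a Louvain partition (each node starting in its
    own community).  ASPL requires connectivity; with
    ``largest_component_fallback`` it is computed on the largest component
    instead of raising.  Assortativity is NaN for regular graphs.  With
    ``fast=True`` the path/community/assortativity columns are skipped (NaN),
    leaving only the O(N+M) counting statistics.
    """
    N = g.number_of_nodes()
    M = g.number_of_edges()
    if N < 1:
        raise ValueError("graph must have at least one node")
    if fast:
        aspl = q = assort = float("nan")
    else:
        gc = g
        if not nx.is_connected(g):
            if not largest_component_fallback:
                raise ValueError("graph is disconnected; ASPL undefined "
                                 "(set largest_component_fallback=True)")
            gc = g.subgraph(max(nx.connected_components(g), key=len))
        aspl = float(nx.average_shortest_path_length(gc)) if gc.number_of_nodes() > 1 else 0.0
        if M >= 1:
            communities = nx.community.louvain_communities(g, seed=seed)
            blocks = {v: i for i, comm in enumerate(communities) for v in comm}
            q = newman_modularity(g, blocks)
        else:
            q = float("nan")
        try:
            assort = float(nx.degree_assortativity_coefficient(g))
        except (ZeroDivisionError, ValueError):
            assort = float("nan")
    return NetworkMetrics(
        n_nodes=N,
        n_edges=M,
        mean_degree=float(2.0 * M / N),
        density_pairs=float(M / (N * (N - 1) / 2)) if N > 1 else 0.0,
        density_mn2=float(M / N**2),
        transitivity=transitivity(g),
        aspl=aspl,
        modularity=q,
        assortativity=assort,
    )
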