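"""Tests of the network generators, x-swap randomizer and structural metrics."""

import itertools

import networkx as nx
import numpy as np
import pytest

import quoterflow as qf


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def test_er_degenerate_cases():
    assert qf.generate_er(10, 0, seed=1).number_of_edges() == 0
    assert qf.generate_er(10, 9, seed=1).number_of_edges() == 45
    with pytest.raises(ValueError):
        qf.generate_er(10, 12, seed=1)


def test_er_ensemble_mean_degree():
    """Mean degree over 100 draws matches the binomial expectation."""
    N, k = 1000, 20
    degs = [2 * qf.generate_er(N, k, seed=s).number_of_edges() / N
            for s in range(100)]
    # var of mean degree per draw ~ 2*k/N; 3 sigma over 100 draws
    se = np.sqrt(2 * k / N / 100)
    assert abs(np.mean(degs) - k) < 3 * se + 0.05


@pytest.mark.parametrize("N, k_avg, expected_m", [(100, 2, 99), (4, 2, 3)])
def test_ba_edge_counts(N, k_avg, expected_m):
    g = qf.generate_ba(N, k_avg, seed=2)
    assert g.number_of_edges() == expected_m
    assert nx.is_connected(g)


def test_ba_rejects_odd_mean_degree():
    with pytest.raises(ValueError):
        qf.generate_ba(100, 3, seed=1)


def test_ba_heavier_tail_than_er():
    """Preferential attachment grows hubs: mean max degree far exceeds ER's
    at the same size and density (50 seeds)."""
    max_ba = [max(d for _, d in qf.generate_ba(1000, 10, seed=s).degree())
              for s in range(50)]
    max_er = [max(d for _, d in qf.generate_er(1000, 10, seed=s).degree())
              for s in range(50)]
    assert np.mean(max_ba) > 2 * np.mean(max_er)
    assert np.mean(max_ba) > 50


def test_ws_lattice_transitivity_and_edge_conservation():
    g0 = qf.generate_ws(20, 4, 0.0, seed=3)
    # ring lattice closed form 3(k-2)/(4(k-1)) = 1/2 at k=4
    assert qf.transitivity(g0) == pytest.approx(0.5)
    assert g0.number_of_edges() == 40
    g1 = qf.generate_ws(20, 4, 0.1, seed=3)
    assert g1.number_of_edges() == 40
    with pytest.raises(ValueError):
        qf.generate_ws(20, 3, 0.1)


def test_ws_full_rewiring_reaches_random_transitivity():
    """At p=1 clustering falls to the random-graph level ~ k/N (100 seeds)."""
    N, k = 200, 6
    ts = [qf.transitivity(qf.generate_ws(N, k, 1.0, seed=s)) for s in range(100)]
    assert 0.5 * k / N < np.mean(ts) < 2.0 * k / N


def test_dichotomous_exact_degrees_and_variance():
    """Generated graphs carry exactly the prescribed degree histogram, so the
    sample degree variance equals (k1-k2)^2/4 identically."""
    for k1, k2, seed in [(16, 16, 4), (8, 24, 5), (4, 28, 6)]:
        spec = qf.DichotomousSpec(N=100, k1=k1, k2=k2)
        g = qf.generate_dichotomous(spec, seed=seed)
        degs = np.array([d for _, d in g.degree()])
        hist = dict(zip(*np.unique(degs, return_counts=True)))
        if k1 == k2:
            assert hist == {k1: 100}
        else:
            assert hist == {min(k1, k2): 50, max(k1, k2): 50}
        assert degs.var() == pytest.approx(spec.sigma2)
        assert nx.is_connected(g)


def test_dichotomous_spec_validation():
    with pytest.raises(ValueError):
        qf.DichotomousSpec(N=101, k1=4, k2=6)
    with pytest.raises(ValueError):
        qf.DichotomousSpec(N=10, k1=0, k2=4)
    spec = qf.DichotomousSpec(N=10, k1=2, k2=4)
    assert spec.mu == 3.0 and spec.sigma2 == 1.0 and spec.ratio == 0.5


def test_sbm_degenerate_and_expected_counts():
    g, blocks = qf.generate_sbm(qf.SBMSpec(N=100, p0=1.0, p1=0.0), seed=7)
    comps = list(nx.connected_components(g))
    assert sorted(len(c) for c in comps) == [50, 50]
    assert g.number_of_edges() == 2 * 50 * 49 // 2
    assert sorted(set(blocks.values())) == ["A", "B"]

    # within-block edge count matches its binomial expectation over 100 seeds
    spec = qf.SBMSpec(N=100, p0=0.5, p1=0.15)
    n_within = []
    for s in range(100):
        g, blocks = qf.generate_sbm(spec, seed=s)
        n_within.append(sum(1 for u, v in g.edges if blocks[u] == blocks[v]))
    n_pairs = 2 * 50 * 49 // 2
    expect = n_pairs * 0.5
    sigma = np.sqrt(n_pairs * 0.5 * 0.5 / 100)
    assert abs(np.mean(n_within) - expect) < 3 * sigma


# ---------------------------------------------------------------------------
# x-swap
# ---------------------------------------------------------------------------

def test_xswap_identity_cases():
    g = qf.generate_ws(30, 4, 0.0, seed=8)
    same = qf.xswap_randomize(g, n_swaps=0, seed=1)
    assert set(same.edges) == set(g.edges)
    k5 = nx.complete_graph(5)
    assert set(qf.xswap_randomize(k5, 500, seed=1).edges) == set(k5.edges)
    with pytest.raises(ValueError):
        qf.xswap_randomize(nx.empty_graph(4), 10, seed=1)


def test_xswap_preserves_degrees_and_connectivity_lowers_transitivity():
    """Over 20 seeds: identical sorted degree sequence and edge count, the
    result stays connected, and lattice transitivity strictly drops."""
    g = qf.generate_ws(100, 6, 0.0, seed=9)
    degs = sorted(d for _, d in g.degree())
    t0 = qf.transitivity(g)
    for s in range(20):
        h = qf.xswap_randomize(g, n_swaps=10 * g.number_of_edges(), seed=s,
                               check_interval=5)
        assert sorted(d for _, d in h.degree()) == degs
        assert h.number_of_edges() == g.number_of_edges()
        assert nx.is_connected(h)
        assert qf.transitivity(h) < t0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_transitivity_closed_forms():
    assert qf.transitivity(nx.complete_graph(3)) == 1.0
    assert qf.transitivity(nx.star_graph(4)) == 0.0
    k4e = nx.complete_graph(4)
    k4e.remove_edge(0, 1)
    assert qf.transitivity(k4e) == pytest.approx(0.75)  # 2 triangles, 8 triads


def _brute_transitivity(g):
    tri = sum(1 for a, b, c in itertools.combinations(g.nodes, 3)
              if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c))
    triads = sum(d * (d - 1) // 2 for _, d in g.degree())
    return 0.0 if triads == 0 else 3.0 * tri / triads


def _brute_modularity(g, blocks):
    m = g.number_of_edges()
    a = nx.to_numpy_array(g)
    k = a.sum(axis=1)
    nodes = list(g.nodes)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if blocks[u] == blocks[v]:
                q += a[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


def test_metric_oracles_on_small_random_graphs():
    """Transitivity and modularity agree with exhaustive enumeration on 100
    random graphs with N <= 12."""
    rng = np.random.default_rng(10)
    for trial in range(100):
        n = int(rng.integers(3, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)), seed=int(rng.integers(2**31)))
        assert qf.transitivity(g) == pytest.approx(_brute_transitivity(g), abs=1e-12)
        if g.number_of_edges() >= 1:
            blocks = {v: int(rng.integers(0, 3)) for v in g.nodes}
            assert qf.newman_modularity(g, blocks) == pytest.approx(
                _brute_modularity(g, blocks), abs=1e-12)


def test_modularity_closed_forms():
    g, blocks = qf.generate_sbm(qf.SBMSpec(N=100, p0=1.0, p1=0.0), seed=11)
    assert qf.newman_modularity(g, blocks) == pytest.approx(0.5)
    one_block = {v: 0 for v in g.nodes}
    assert qf.newman_modularity(g, one_block) == pytest.approx(0.0, abs=1e-12)
    c4 = nx.cycle_graph(4)
    assert qf.newman_modularity(c4, {0: 0, 1: 0, 2: 1, 3: 1}) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        qf.newman_modularity(nx.empty_graph(3), {0: 0, 1: 0, 2: 0})


def test_expected_sbm_modularity_limits_and_monte_carlo():
    assert qf.expected_sbm_modularity(qf.SBMSpec(N=100, p0=0.7, p1=0.0)) == 0.5
    assert abs(qf.expected_sbm_modularity(qf.SBMSpec(N=2000, p0=0.2, p1=0.2))) < 0.01
    with pytest.raises(ValueError):
        qf.expected_sbm_modularity(qf.SBMSpec(N=10, p0=0.0, p1=0.0))

    # Monte-Carlo oracle across a (p0, p1) grid: planted-partition modularity
    # of 200 sampled graphs per point, agreement within 2 standard errors.
    for p0, p1 in [(0.5, 0.15), (0.2, 0.2), (0.1, 0.3), (0.4, 0.05)]:
        spec = qf.SBMSpec(N=100, p0=p0, p1=p1)
        qs = []
        for s in range(200):
            g, blocks = qf.generate_sbm(spec, seed=1000 + s)
            if g.number_of_edges() == 0:
                continue
            qs.append(qf.newman_modularity(g, blocks))
        se = np.std(qs, ddof=1) / np.sqrt(len(qs))
        assert abs(np.mean(qs) - qf.expected_sbm_modularity(spec)) < 2 * se + 1e-3


def test_summary_metrics_complete_graph_and_fallback():
    m = qf.summary_metrics(nx.complete_graph(10), seed=1)
    assert m.transitivity == 1.0
    assert m.aspl == 1.0
    assert m.density_pairs == 1.0
    assert m.mean_degree == 9.0

    disconnected = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
    with pytest.raises(ValueError):
        qf.summary_metrics(disconnected, seed=1)
    m2 = qf.summary_metrics(disconnected, seed=1, largest_component_fallback=True)
    assert m2.aspl == 1.0
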