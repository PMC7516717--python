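"""Experiment orchestration: edge-level cross-entropy summaries, degree- and
block-conditional information flow, and the structural parameter sweeps
(density, degree heterogeneity, rewiring, x-swap, community structure,
vocabulary heterogeneity).

An "edge cross-entropy" h×(u|v) predicts ego v's stream from alter u's past;
both orientations of every undirected edge contribute, so a graph with M
edges yields up to 2M values.  Summaries (mean, variance, mean
predictability) are taken over exactly that set, optionally subsampled for
large graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import netgen
from .infoflow import cross_entropy, predictability
from .quoter import Corpus, QuoterConfig, simulate_quoter, zipf_vocabulary

__all__ = [
    "EdgeFlowStats",
    "BlockFlowStats",
    "ExperimentConfig",
    "edge_cross_entropies",
    "conditional_flow_by_degree",
    "block_flow_difference",
    "run_scenario",
    "load_experiment_config",
]

SCENARIOS = (
    "density_sweep",
    "dichotomous",
    "ws_rewiring",
    "xswap_compare",
    "sbm_blocks",
    "vocab_heterogeneity",
)


@dataclass
class EdgeFlowStats:
    """Directed-edge cross-entropies h×(alter→ego) and their summaries."""

    hx: dict
    pi: dict
    lengths: dict
    n_skipped: int

    @property
    def mean_hx(self) -> float:
        return float(np.mean(list(self.hx.values())))

    @property
    def var_hx(self) -> float:
        return float(np.var(list(self.hx.values())))

    @property
    def mean_pi(self) -> float:
        return float(np.mean(list(self.pi.values())))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-pair table: ego, alter, h_cross_bits, pi, TA, TB."""
        rows = [
            {"ego": ego, "alter": alter, "h_cross_bits": h,
             "pi": self.pi[(alter, ego)],
             "TA": self.lengths[(alter, ego)][0],
             "TB": self.lengths[(alter, ego)][1]}
            for (alter, ego), h in self.hx.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BlockFlowStats:
    """Within- vs between-block information flow; Δh× = between − within."""

    mean_within: float
    mean_between: float
    n_within: int
    n_between: int

    @property
    def delta_hx(self) -> float:
        return self.mean_between - self.mean_within


def _directed_edge_pairs(g: nx.Graph) -> list:
    pairs = []
    for u, v in g.edges:
        pairs.append((u, v))  # alter u predicts ego v
        pairs.append((v, u))
    return pairs


def edge_cross_entropies(
    g: nx.Graph,
    corpus: Corpus,
    pairs: Optional[Sequence] = None,
    max_pairs: Optional[int] = None,
    seed: Optional[int] = None,
) -> EdgeFlowStats:
    """Cross-entropy for both orientations of every edge (or given pairs).

    Pairs whose ego or alter stream is shorter than 2 words are skipped and
    counted.  ``max_pairs`` subsamples the pair list without replacement
    (seeded) to bound runtime on dense graphs.
    """
    if pairs is None:
        if g.number_of_edges() == 0:
            raise ValueError("graph has no edges; no pairs to estimate")
        pairs = _directed_edge_pairs(g)
    pairs = list(pairs)
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    z = corpus.vocabulary_size
    hx, pi, lengths = {}, {}, {}
    n_skipped = 0
    for alter, ego in pairs:
        src = corpus.streams[ego]
        tgt = corpus.streams[alter]
        if len(src) < 2 or len(tgt) < 2:
            n_skipped += 1
            continue
        est = cross_entropy(src, tgt)
        hx[(alter, ego)] = est.h_bits
        pi[(alter, ego)] = predictability(min(est.h_bits, np.log2(z)), z).pi
        lengths[(alter, ego)] = (len(src), len(tgt))
    if not hx:
        raise ValueError("no estimable pairs (all streams too short)")
    return EdgeFlowStats(hx=hx, pi=pi, lengths=lengths, n_skipped=n_skipped)


def conditional_flow_by_degree(stats: EdgeFlowStats, g: nx.Graph) -> pd.DataFrame:
    """Mean h× over directed edges grouped by (alter degree, ego degree)."""
    rows = [
        {"k_alter": g.degree(alter), "k_ego": g.degree(ego), "hx": h}
        for (alter, ego), h in stats.hx.items()
    ]
    df = pd.DataFrame(rows)
    out = (df.groupby(["k_alter", "k_ego"])
             .agg(mean_hx=("hx", "mean"), n=("hx", "size"))
             .reset_index())
    return out


def block_flow_difference(
    g: nx.Graph,
    blocks: Mapping[int, object],
    corpus: Corpus,
    mode: str = "edges",
    n_pairs: int = 200,
    max_pairs_per_class: Optional[int] = None,
    seed: Optional[int] = None,
) -> BlockFlowStats:
    """Average h× on within-block vs between-block pairs.

    ``mode="edges"`` (default) restricts to existing edges, both
    orientations; ``mode="sampled"`` draws ``n_pairs`` random ordered node
    pairs per category regardless of adjacency (the estimator does not
    require the pair to be linked).  ``max_pairs_per_class`` subsamples each
    class (seeded) to bound runtime on dense graphs.
    """
    if mode == "edges":
        pairs = _directed_edge_pairs(g)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        nodes = np.array(sorted(g.nodes))
        pairs = []
        while len(pairs) < 2 * n_pairs:
            u, v = rng.choice(nodes, size=2, replace=False)
            pairs.append((int(u), int(v)))
    else:
        raise ValueError("mode must be 'edges' or 'sampled'")
    within = [p for p in pairs if blocks[p[0]] == blocks[p[1]]]
    between = [p for p in pairs if blocks[p[0]] != blocks[p[1]]]
    if not within or not between:
        raise ValueError(
            "need both within- and between-block pairs; increase p1/p0 or "
            "use mode='sampled'")
    stats_w = edge_cross_entropies(g, corpus, pairs=within,
                                   max_pairs=max_pairs_per_class, seed=seed)
    stats_b = edge_cross_entropies(g, corpus, pairs=between,
                                   max_pairs=max_pairs_per_class, seed=seed)
    return BlockFlowStats(
        mean_within=stats_w.mean_hx,
        mean_between=stats_b.mean_hx,
        n_within=len(stats_w.hx),
        n_between=len(stats_b.hx),
    )


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """A declarative sweep: scenario id, a grid of graph parameters, quoter
    parameters, and a replicate count.  Replicates re-draw both the graph
    and the quoter randomness from seeds derived deterministically from
    ``seed`` via a SeedSequence.
    """

    scenario: str
    grid: list
    quoter: dict = field(default_factory=dict)
    replicates: int = 10
    seed: int = 0
    max_pairs: Optional[int] = 60

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _derived_seeds(base: int, *indices: int, n: int = 3):
    ss = np.random.SeedSequence([base, *indices])
    return [int(s % 2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def _quoter_cfg(params: dict, vocab=None, blocks=None) -> QuoterConfig:
    if vocab is None:
        vocab = zipf_vocabulary(params.get("z", 1000), params.get("alpha", 1.5))
    return QuoterConfig(
        q=params.get("q", 0.5),
        lam=params.get("lam", 3.0),
        steps_per_node=params.get("steps_per_node", 500),
        vocab=vocab,
        blocks=blocks,
        scheduling=params.get("scheduling", "random"),
    )


def _flow_row(g, corpus, cfg: ExperimentConfig, seed: int) -> dict:
    stats = edge_cross_entropies(g, corpus, max_pairs=cfg.max_pairs, seed=seed)
    return {
        "mean_hx": stats.mean_hx,
        "var_hx": stats.var_hx,
        "mean_pi": stats.mean_pi,
        "n_pairs": len(stats.hx),
        "n_edges": g.number_of_edges(),
        "density_mn2": g.number_of_edges() / g.number_of_nodes() ** 2,
    }


def run_scenario(cfg: ExperimentConfig) -> pd.DataFrame:
    """Execute a scenario grid; one row per (grid point, replicate)."""
    runner = {
        "density_sweep": _run_density_sweep,
        "dichotomous": _run_dichotomous,
        "ws_rewiring": _run_ws_rewiring,
        "xswap_compare": _run_xswap_compare,
        "sbm_blocks": _run_sbm_blocks,
        "vocab_heterogeneity": _run_vocab_heterogeneity,
    }[cfg.scenario]
    rows = []
    for gi, point in enumerate(cfg.grid):
        for rep in range(cfg.replicates):
            for row in runner(cfg, point, gi, rep):
                row.update({"replicate": rep, **{k: v for k, v in point.items()}})
                rows.append(row)
    return pd.DataFrame(rows)


def _run_density_sweep(cfg, point, gi, rep):
    g_seed, q_seed, s_seed = _derived_seeds(cfg.seed, gi, rep)
    model = point.get("model", "er")
    if model == "er":
        g = netgen.generate_er(point["N"], point["k_avg"], seed=g_seed)
    elif model == "ba":
        g = netgen.generate_ba(point["N"], point["k_avg"], seed=g_seed)
    else:
        raise ValueError(f"density_sweep model must be 'er' or 'ba', got {model!r}")
    corpus = simulate_quoter(g, _quoter_cfg(cfg.quoter), seed=q_seed)
    yield _flow_row(g, corpus, cfg, s_seed)


def _run_dichotomous(cfg, point, gi, rep):
    g_seed, q_seed, s_seed = _derived_seeds(cfg.seed, gi, rep)
    spec = netgen.DichotomousSpec(N=point["N"], k1=point["k1"], k2=point["k2"])
    g = netgen.generate_dichotomous(spec, seed=g_seed)
    corpus = simulate_quoter(g, _quoter_cfg(cfg.quoter), seed=q_seed)
    row = _flow_row(g, corpus, cfg, s_seed)
    row["degree_ratio"] = spec.ratio
    row["sigma2"] = spec.sigma2
    yield row


def _run_ws_rewiring(cfg, point, gi, rep):
    g_seed, q_seed, s_seed = _derived_seeds(cfg.seed, gi, rep)
    g = netgen.generate_ws(point["N"], point["k"], point["p_rewire"], seed=g_seed)
    corpus = simulate_quoter(g, _quoter_cfg(cfg.quoter), seed=q_seed)
    row = _flow_row(g, corpus, cfg, s_seed)
    row["transitivity"] = netgen.transitivity(g)
    yield row


def _run_xswap_compare(cfg, point, gi, rep):
    g_seed, q_seed, s_seed, x_seed = _derived_seeds(cfg.seed, gi, rep, n=4)
    g = netgen.generate_ws(point["N"], point["k"], point.get("p_rewire", 0.0),
                           seed=g_seed)
    swaps = point.get("n_swaps", 10 * g.number_of_edges())
    g_x = netgen.xswap_randomize(g, n_swaps=swaps, seed=x_seed,
                                 check_interval=point.get("check_interval", 10))
    for variant, graph in (("original", g), ("xswapped", g_x)):
        corpus = simulate_quoter(graph, _quoter_cfg(cfg.quoter), seed=q_seed)
        row = _flow_row(graph, corpus, cfg, s_seed)
        row["variant"] = variant
        row["transitivity"] = netgen.transitivity(graph)
        yield row


def _run_sbm_blocks(cfg, point, gi, rep):
    g_seed, q_seed, s_seed = _derived_seeds(cfg.seed, gi, rep)
    spec = netgen.SBMSpec(N=point["N"], p0=point["p0"], p1=point["p1"])
    g, blocks = netgen.generate_sbm(spec, seed=g_seed)
    corpus = simulate_quoter(g, _quoter_cfg(cfg.quoter), seed=q_seed)
    bstats = block_flow_difference(g, blocks, corpus,
                                  mode=point.get("pair_mode", "edges"),
                                  max_pairs_per_class=point.get("max_pairs_per_class"),
                                  seed=s_seed)
    yield {
        "mean_within": bstats.mean_within,
        "mean_between": bstats.mean_between,
        "delta_hx": bstats.delta_hx,
        "n_within": bstats.n_within,
        "n_between": bstats.n_between,
        "modularity": netgen.newman_modularity(g, blocks),
        "expected_modularity": netgen.expected_sbm_modularity(spec),
    }


def _run_vocab_heterogeneity(cfg, point, gi, rep):
    g_seed, q_seed, s_seed = _derived_seeds(cfg.seed, gi, rep)
    spec = netgen.SBMSpec(N=point["N"], p0=point["p0"], p1=point["p1"])
    g, blocks = netgen.generate_sbm(spec, seed=g_seed)
    z = cfg.quoter.get("z", 1000)
    vocab = {"A": zipf_vocabulary(z, point["alpha_A"]),
             "B": zipf_vocabulary(z, point["alpha_B"])}
    corpus = simulate_quoter(g, _quoter_cfg(cfg.quoter, vocab=vocab, blocks=blocks),
                             seed=q_seed)
    stats = edge_cross_entropies(g, corpus, max_pairs=cfg.max_pairs, seed=s_seed)
    by_pair: dict[str, list] = {"A->A": [], "A->B": [], "B->A": [], "B->B": []}
    for (alter, ego), h in stats.hx.items():
        by_pair[f"{blocks[alter]}->{blocks[ego]}"].append(h)
    row = {"modularity": netgen.newman_modularity(g, blocks)}
    for key, vals in by_pair.items():
        row[f"mean_hx_{key.replace('->', '_to_')}"] = (
            float(np.mean(vals)) if vals else float("nan"))
    yield row


def load_experiment_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ExperimentConfig(**raw)
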