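"""Plain-text I/O: edge lists, corpus TSV files, and deterministic toy
fixtures for exercising the match-length estimators.

Edge lists are whitespace-delimited two-column text, one undirected edge per
line, '#' comments allowed.  A corpus serializes as TSV lines
``node_id<TAB>timestep<TAB>word_id`` plus a JSON sidecar (``<path>.json``)
holding the generating configuration, the seed and the node list (so empty
streams survive the round trip).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np

from .infoflow import match_lengths_brute
from .quoter import Corpus, QuoterConfig, TextStream, zipf_vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "ToyFixture",
    "read_edgelist",
    "write_edgelist",
    "write_corpus",
    "read_corpus",
    "make_toy_fixture",
]


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_edgelist(path) -> nx.Graph:
    """Read a whitespace-delimited edge list into a simple undirected graph.

    Node ids are normalized to ``0..N-1`` (sorted by original id); the
    original→new map is kept in ``g.graph["node_relabeling"]``.  Self-loops
    and duplicate edges are dropped with a logged count; malformed lines
    raise with their line number.
    """
    edges = []
    raw_nodes = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node id") from exc
            raw_nodes.update((u, v))
            if u == v:
                n_self += 1
                continue
            edges.append((u, v))
    relabel = {orig: i for i, orig in enumerate(sorted(raw_nodes))}
    g = nx.Graph()
    g.add_nodes_from(range(len(relabel)))
    n_dup = 0
    for u, v in edges:
        a, b = relabel[u], relabel[v]
        if g.has_edge(a, b):
            n_dup += 1
        else:
            g.add_edge(a, b)
    if n_self or n_dup:
        logger.warning("read_edgelist(%s): dropped %d self-loops, %d duplicate edges",
                       path, n_self, n_dup)
    g.graph["node_relabeling"] = relabel
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    """Write one ``u v`` line per edge (0-based integer ids)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u} {v}\n")


# ---------------------------------------------------------------------------
# Corpus round trip
# ---------------------------------------------------------------------------

def _config_to_json(cfg: QuoterConfig) -> dict:
    vocab = cfg.vocab
    if isinstance(vocab, Mapping):
        vocab_json = {str(k): {"z": d.z, "alpha": d.alpha} for k, d in vocab.items()}
        blocks_json = {str(k): str(v) for k, v in cfg.blocks.items()}
    else:
        vocab_json = {"z": vocab.z, "alpha": vocab.alpha}
        blocks_json = None
    return {
        "q": cfg.q,
        "lam": cfg.lam,
        "steps_per_node": cfg.steps_per_node,
        "scheduling": cfg.scheduling,
        "seed": cfg.seed,
        "vocab": vocab_json,
        "blocks": blocks_json,
    }


def _config_from_json(d: dict) -> QuoterConfig:
    vj = d["vocab"]
    if "z" in vj:
        vocab = zipf_vocabulary(vj["z"], vj["alpha"])
        blocks = None
    else:
        vocab = {k: zipf_vocabulary(spec["z"], spec["alpha"]) for k, spec in vj.items()}
        blocks = {int(k): v for k, v in d["blocks"].items()}
    return QuoterConfig(q=d["q"], lam=d["lam"], steps_per_node=d["steps_per_node"],
                        vocab=vocab, blocks=blocks, scheduling=d["scheduling"],
                        seed=d["seed"])


def write_corpus(corpus: Corpus, path) -> None:
    """Serialize a corpus as TSV plus a JSON sidecar at ``<path>.json``."""
    path = Path(path)
    with open(path, "w") as fh:
        for node in sorted(corpus.streams):
            stream = corpus.streams[node]
            for w, t in zip(stream.words, stream.times):
                fh.write(f"{node}\t{t}\t{w}\n")
    sidecar = {
        "config": _config_to_json(corpus.config),
        "nodes": sorted(int(v) for v in corpus.graph.nodes),
        "edges": sorted([sorted(map(int, e)) for e in corpus.graph.edges]),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_corpus(path) -> Corpus:
    """Read a corpus TSV and its JSON sidecar back into a :class:`Corpus`.

    Raises if the sidecar is missing or if any node's timesteps decrease.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing corpus sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    cfg = _config_from_json(sidecar["config"])
    g = nx.Graph()
    g.add_nodes_from(sidecar["nodes"])
    g.add_edges_from(sidecar["edges"])
    words: dict[int, list[int]] = {v: [] for v in sidecar["nodes"]}
    times: dict[int, list[int]] = {v: [] for v in sidecar["nodes"]}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                node_s, t_s, w_s = line.split("\t")
                node, t, w = int(node_s), int(t_s), int(w_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed corpus row") from exc
            if times[node] and t < times[node][-1]:
                raise ValueError(f"{path}:{lineno}: timestep decreases for node {node}")
            words[node].append(w)
            times[node].append(t)
    streams = {v: TextStream(words=np.array(words[v], dtype=np.int64),
                             times=np.array(times[v], dtype=np.int64))
               for v in sidecar["nodes"]}
    return Corpus(streams=streams, config=cfg, graph=g)


# ---------------------------------------------------------------------------
# Toy fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyFixture:
    """Hand-built two-node corpus with brute-force-verified match ledgers.

    ``expected_ledgers[(u, v)]`` holds the Λt values for predicting ego v's
    stream from alter u's past.
    """

    graph: nx.Graph
    corpus: Corpus
    expected_ledgers: dict


def make_toy_fixture(kind: str) -> ToyFixture:
    """Deterministic two-node fixtures for the cross-entropy estimator.

    ``"copycat"``: node 1 writes an exact copy of node 0's earlier text, so
    matches are maximal under the end-of-sequence convention.
    ``"independent"``: disjoint vocabularies, so every Λt = 1 and
    ĥ× = log2(TB) exactly.  ``"staggered"``: interleaved timestamps where
    ignoring temporal precedence would change at least one Λt.
    """
    if kind == "copycat":
        b_words, b_times = [1, 2, 3, 1, 2], [1, 2, 3, 4, 5]
        a_words, a_times = [1, 2, 3, 1, 2], [6, 7, 8, 9, 10]
    elif kind == "independent":
        b_words, b_times = [4, 5, 6, 4, 5], [1, 2, 3, 4, 5]
        a_words, a_times = [1, 2, 3, 2, 1], [6, 7, 8, 9, 10]
    elif kind == "staggered":
        # node 0's later words (times 5, 7) are invisible to node 1's
        # positions written at times 4 and 6
        b_words, b_times = [7, 8, 9, 7], [1, 3, 5, 7]
        a_words, a_times = [7, 8, 9, 7], [2, 4, 6, 8]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    g = nx.Graph([(0, 1)])
    vocab = zipf_vocabulary(10, 1.0)
    cfg = QuoterConfig(q=0.5, lam=3.0, steps_per_node=5, vocab=vocab, seed=0)
    streams = {
        0: TextStream(words=np.array(b_words), times=np.array(b_times)),
        1: TextStream(words=np.array(a_words), times=np.array(a_times)),
    }
    corpus = Corpus(streams=streams, config=cfg, graph=g)
    ledgers = {}
    for alter, ego in ((0, 1), (1, 0)):
        src, tgt = streams[ego], streams[alter]
        ledgers[(alter, ego)] = match_lengths_brute(
            src.words, src.times, tgt.words, tgt.times)
    return ToyFixture(graph=g, corpus=corpus, expected_ledgers=ledgers)
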