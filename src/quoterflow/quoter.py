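"""The quoter model: networked nodes growing timestamped text streams.

At each of ``T = steps_per_node * N`` time steps one node (the ego) acts.
With probability ``q`` it quotes: it picks a neighbor (alter) uniformly at
random and copies a contiguous random segment of the alter's past text, of
Poisson(λ)-distributed length (clamped to the alter's current stream).
Otherwise (probability 1−q) it generates new content: Poisson(λ) words drawn
i.i.d. from its Zipf vocabulary distribution.  Every appended word carries
the current time step as its timestamp.

Vocabularies follow a Zipf law ``W(w) ∝ rank^(−α)`` over ``z`` words; a
per-block vocabulary map supports community-heterogeneous exponents, in which
case new content is drawn from the ego's own block distribution while quoting
copies verbatim regardless of block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import networkx as nx
import numpy as np

__all__ = [
    "VocabularyDistribution",
    "QuoterConfig",
    "TextStream",
    "Corpus",
    "zipf_vocabulary",
    "draw_words",
    "quote_segment",
    "simulate_quoter",
]


@dataclass(frozen=True)
class VocabularyDistribution:
    """Zipf rank-probability table over word ids ``1..z``.

    ``probs[r-1] = r^(−α) / H(z, α)`` with ``H(z, α) = Σ_{r=1}^{z} r^(−α)``.
    """

    z: int
    alpha: float
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.size != self.z:
            raise ValueError("probability table size must equal z")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        if np.any(np.diff(p) > 1e-15):
            raise ValueError("rank probabilities must be non-increasing")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "_cum", np.cumsum(p))

    @property
    def entropy_bits(self) -> float:
        """Shannon entropy of the vocabulary distribution in bits/word.

        Equals ``log2 H(z,α) + (α/H(z,α))·Σ r^(−α) log2 r``; this is the
        entropy rate of i.i.d. (q=0) text.
        """
        p = self.probs
        return float(-(p * np.log2(p)).sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` word ids (1-based) i.i.d. from the distribution."""
        if n == 0:
            return np.empty(0, dtype=np.int64)
        return np.searchsorted(self._cum, rng.random(n), side="right").astype(np.int64) + 1


def zipf_vocabulary(z: int, alpha: float) -> VocabularyDistribution:
    """Normalized Zipf vocabulary over ``z`` words with exponent ``alpha``."""
    if z < 2:
        raise ValueError("vocabulary size z must be >= 2")
    if alpha < 0:
        raise ValueError("Zipf exponent must be non-negative")
    ranks = np.arange(1, z + 1, dtype=float)
    w = ranks ** (-alpha)
    return VocabularyDistribution(z=z, alpha=alpha, probs=w / w.sum())


def draw_words(vocab: VocabularyDistribution, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(λ)-many i.i.d. draws from ``vocab`` (length 0 is allowed)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    return vocab.sample(int(rng.poisson(lam)), rng)


def quote_segment(alter_words, length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly positioned contiguous segment of an alter's past text.

    The requested ``length`` is clamped to the alter's current stream length;
    the start position is uniform among valid positions.  Raises on an empty
    alter stream (callers fall back to generating new content).
    """
    words = np.asarray(alter_words, dtype=np.int64)
    if words.size == 0:
        raise ValueError("cannot quote from an empty stream")
    L = min(int(length), words.size)
    if L == 0:
        return np.empty(0, dtype=np.int64)
    start = int(rng.integers(0, words.size - L + 1))
    return words[start:start + L]


@dataclass(frozen=True)
class TextStream:
    """Ordered (word id, time step) pairs produced by one node."""

    words: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.words, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.int64)
        if w.size != t.size:
            raise ValueError("words and times must have equal length")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        object.__setattr__(self, "words", w)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.words.size)


VocabSpec = Union[VocabularyDistribution, Mapping[object, VocabularyDistribution]]


@dataclass
class QuoterConfig:
    """Parameters of a quoter-model run.

    q
        Quote probability per action; q=0 disables copying entirely.
    lam
        Mean of the Poisson action length (words written or copied).
    steps_per_node
        Time-step multiplier; the run lasts ``steps_per_node * N`` steps so
        each node writes about ``steps_per_node * lam`` words.
    vocab
        A single :class:`VocabularyDistribution`, or a mapping from block
        label to distribution (requires ``blocks``).
    blocks
        Optional node → block label map used with a per-block vocabulary.
    scheduling
        ``"random"`` picks the acting node uniformly each step (default);
        ``"round_robin"`` cycles nodes deterministically.
    """

    q: float
    vocab: VocabSpec
    lam: float = 3.0
    steps_per_node: int = 1000
    blocks: Optional[Mapping[int, object]] = None
    scheduling: str = "random"
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.steps_per_node < 1:
            raise ValueError("steps_per_node must be >= 1")
        if self.scheduling not in ("random", "round_robin"):
            raise ValueError("scheduling must be 'random' or 'round_robin'")
        if isinstance(self.vocab, Mapping) and self.blocks is None:
            raise ValueError("a per-block vocabulary map requires blocks")


@dataclass
class Corpus:
    """One finished quoter run: a stream per node, plus provenance."""

    streams: dict[int, TextStream]
    config: QuoterConfig
    graph: nx.Graph

    @property
    def total_words(self) -> int:
        return sum(len(s) for s in self.streams.values())

    @property
    def vocabulary_size(self) -> int:
        vocab = self.config.vocab
        if isinstance(vocab, Mapping):
            return next(iter(vocab.values())).z
        return vocab.z


def _node_vocabs(g: nx.Graph, cfg: QuoterConfig) -> dict[int, VocabularyDistribution]:
    if isinstance(cfg.vocab, Mapping):
        missing = [v for v in g.nodes if v not in cfg.blocks]
        if missing:
            raise ValueError(f"nodes without block assignment: {missing[:5]}")
        return {v: cfg.vocab[cfg.blocks[v]] for v in g.nodes}
    return {v: cfg.vocab for v in g.nodes}


def simulate_quoter(g: nx.Graph, cfg: QuoterConfig, seed: Optional[int] = None) -> Corpus:
    """Run the quoter model on ``g`` for ``steps_per_node * N`` steps.

    Per-step draw order from the single seeded generator: acting node,
    quote-vs-new uniform, Poisson length; then, when quoting, alter index and
    segment start; when generating, the content words.  Runs are exactly
    reproducible from (graph, config, seed).

    An ego with no neighbors, or whose chosen alter has an empty stream,
    generates new content instead of quoting.  A Poisson length of 0 means
    the node writes nothing that step.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    if nodes != list(range(len(nodes))):
        raise ValueError("graph nodes must be labeled 0..N-1")
    N = len(nodes)
    T = cfg.steps_per_node * N

    vocabs = _node_vocabs(g, cfg)
    neighbors = {v: np.fromiter(g.neighbors(v), dtype=np.int64) for v in nodes}
    words_buf: dict[int, list[int]] = {v: [] for v in nodes}
    times_buf: dict[int, list[int]] = {v: [] for v in nodes}

    if cfg.scheduling == "random":
        actors = rng.integers(0, N, size=T)
    else:
        actors = np.resize(np.arange(N, dtype=np.int64), T)
    u_quote = rng.random(T)
    lengths = rng.poisson(cfg.lam, size=T)

    for step in range(1, T + 1):
        ego = int(actors[step - 1])
        L = int(lengths[step - 1])
        nbrs = neighbors[ego]
        new_words: np.ndarray
        if u_quote[step - 1] < cfg.q and nbrs.size > 0:
            alter = int(nbrs[rng.integers(0, nbrs.size)])
            alter_buf = words_buf[alter]
            if alter_buf:
                if L == 0:
                    continue
                Lq = min(L, len(alter_buf))
                start = int(rng.integers(0, len(alter_buf) - Lq + 1))
                new_words = np.asarray(alter_buf[start:start + Lq], dtype=np.int64)
            else:
                new_words = vocabs[ego].sample(L, rng)
        else:
            new_words = vocabs[ego].sample(L, rng)
        if new_words.size:
            words_buf[ego].extend(int(w) for w in new_words)
            times_buf[ego].extend([step] * new_words.size)

    streams = {
        v: TextStream(words=np.asarray(words_buf[v], dtype=np.int64),
                      times=np.asarray(times_buf[v], dtype=np.int64))
        for v in nodes
    }
    return Corpus(streams=streams, config=cfg, graph=g)
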