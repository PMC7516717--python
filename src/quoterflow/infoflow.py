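"""Nonparametric estimators of entropy rate, cross-entropy and predictability.

The estimators operate on timestamped integer word streams.  The entropy rate
of a stream is estimated from Lempel–Ziv match lengths against the stream's
own past (Kontoyiannis et al. 1998); the cross-entropy ``h×(A|B)`` of stream A
given stream B generalizes this by matching A's future against only those
words of B written *strictly before* each word of A (temporal precedence).
Lower cross-entropy means B's past carries more predictive information about
A — more information flow from B to A.

Predictability ``Π`` converts an entropy (bits/word) into the best achievable
next-word prediction accuracy permitted by Fano's inequality for a vocabulary
of ``z`` words.

All logarithms are base 2; entropies are in bits per word.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "MatchLedger",
    "CrossEntropyEstimate",
    "PredictabilityResult",
    "match_length",
    "match_lengths_brute",
    "entropy_rate",
    "cross_entropy",
    "predictability",
    "fano_bound",
]


# ---------------------------------------------------------------------------
# Match lengths
# ---------------------------------------------------------------------------

def match_length(source: Sequence[int], t: int, target_past: Sequence[int]) -> int:
    """Length of the shortest substring of ``source`` starting at ``t`` that is
    absent from ``target_past``.

    ``t`` is a 0-based position.  If every substring through the end of
    ``source`` occurs in ``target_past``, the end-of-sequence convention
    returns ``remaining_length + 1``.  An empty ``target_past`` gives 1 (the
    first word is trivially unseen).

    This is the straightforward quadratic scan; it doubles as the reference
    oracle for the fast kernel used by :func:`entropy_rate` and
    :func:`cross_entropy`.
    """
    src = list(source)
    past = list(target_past)
    if not 0 <= t < len(src):
        raise IndexError(f"position t={t} outside source of length {len(src)}")
    rem = len(src) - t
    c = len(past)
    best = 0
    for j in range(c):
        if past[j] != src[t]:
            continue
        length = 1
        while length < rem and j + length < c and past[j + length] == src[t + length]:
            length += 1
        if length > best:
            best = length
            if best == rem:
                break
    return best + 1


def match_lengths_brute(
    source_words: Sequence[int],
    source_times: Sequence[int],
    target_words: Sequence[int],
    target_times: Sequence[int],
) -> np.ndarray:
    """Cross-parsing match lengths Λt(A|B) by brute force, honoring strict
    temporal precedence: position ``t`` of the source may only match against
    target words with ``time < source_times[t]``."""
    target_times = np.asarray(target_times)
    out = np.empty(len(source_words), dtype=np.int64)
    for t in range(len(source_words)):
        cursor = int(np.searchsorted(target_times, source_times[t], side="left"))
        out[t] = match_length(source_words, t, target_words[:cursor])
    return out


@njit(cache=True)
def _match_lengths_kernel(source, target, cursors):  # pragma: no cover - numba
    TA = source.shape[0]
    out = np.empty(TA, dtype=np.int64)
    for t in range(TA):
        c = cursors[t]
        rem = TA - t
        best = 0
        for j in range(c):
            if target[j] != source[t]:
                continue
            length = 1
            while length < rem and j + length < c and target[j + length] == source[t + length]:
                length += 1
            if length > best:
                best = length
                if best == rem:
                    break
        out[t] = best + 1
    return out


def _as_int64(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=np.int64))


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchLedger:
    """Per-position match lengths underlying an entropy estimate."""

    lambdas: np.ndarray
    source_length: int
    target_length: int

    def __post_init__(self):
        lam = np.asarray(self.lambdas)
        if lam.size and (lam.min() < 1):
            raise ValueError("match lengths must be >= 1")


@dataclass(frozen=True)
class CrossEntropyEstimate:
    """Estimated cross-entropy in bits per word plus its match-length ledger."""

    h_bits: float
    ledger: MatchLedger


@dataclass(frozen=True)
class PredictabilityResult:
    """Largest predictability Π consistent with Fano's inequality."""

    pi: float
    z: int
    h_bits: float


# ---------------------------------------------------------------------------
# Entropy estimators
# ---------------------------------------------------------------------------

def _stream_arrays(stream):
    """Accept a TextStream-like object (``.words``/``.times``) or a plain
    sequence of words (times default to positions)."""
    if hasattr(stream, "words"):
        return _as_int64(stream.words), _as_int64(stream.times)
    words = _as_int64(stream)
    return words, np.arange(words.size, dtype=np.int64)


def entropy_rate(stream) -> float:
    """Match-length estimate ``ĥ = T·log2(T) / ΣΛt`` of a stream's entropy
    rate, where Λt is matched against the stream's own first ``t`` words.

    Converges to the true entropy rate for stationary ergodic sources.
    Requires a stream of length >= 2.
    """
    words, _ = _stream_arrays(stream)
    T = words.size
    if T < 2:
        raise ValueError("entropy_rate needs a stream of length >= 2")
    cursors = np.arange(T, dtype=np.int64)
    lambdas = _match_lengths_kernel(words, words, cursors)
    return float(T * np.log2(T) / lambdas.sum())


def cross_entropy(source, target) -> CrossEntropyEstimate:
    """Cross-entropy ``ĥ×(source|target) = TA·log2(TB) / Σt Λt`` with strict
    temporal precedence.

    Λt is the length of the shortest substring of the source starting at
    position ``t`` that does not appear among the target words written
    strictly before ``source.times[t]``.  Target words stamped at exactly the
    same time step are excluded from the matchable past.
    """
    s_words, s_times = _stream_arrays(source)
    t_words, t_times = _stream_arrays(target)
    if s_words.size < 1:
        raise ValueError("source stream is empty")
    if t_words.size < 2:
        raise ValueError("target stream must have length >= 2")
    cursors = np.searchsorted(t_times, s_times, side="left").astype(np.int64)
    lambdas = _match_lengths_kernel(s_words, t_words, cursors)
    h = float(s_words.size * np.log2(t_words.size) / lambdas.sum())
    ledger = MatchLedger(lambdas=lambdas, source_length=int(s_words.size),
                         target_length=int(t_words.size))
    return CrossEntropyEstimate(h_bits=h, ledger=ledger)


# ---------------------------------------------------------------------------
# Fano predictability
# ---------------------------------------------------------------------------

def fano_bound(pi: float, z: int) -> float:
    """Left-hand side of Fano's relation: ``h(Π) + (1−Π)·log2(z−1)``."""
    if pi <= 0.0 or pi >= 1.0:
        h2 = 0.0
    else:
        h2 = -pi * np.log2(pi) - (1.0 - pi) * np.log2(1.0 - pi)
    return float(h2 + (1.0 - pi) * np.log2(z - 1))


def predictability(h_bits: float, z: int) -> PredictabilityResult:
    """Largest Π solving ``h(Π) + (1−Π)·log2(z−1) = h_bits``.

    Π is the accuracy an ideal next-word predictor can reach given entropy
    ``h_bits`` over a vocabulary of ``z`` words: Π=1 at h=0 and Π=1/z at the
    uniform limit h=log2(z).  Estimates exceeding log2(z) (possible with
    finite samples) are clamped with a warning.
    """
    if z < 2:
        raise ValueError("vocabulary size z must be >= 2")
    if h_bits < 0:
        raise ValueError("entropy must be non-negative")
    h_max = float(np.log2(z))
    if h_bits > h_max:
        warnings.warn(
            f"entropy {h_bits:.4f} exceeds log2(z)={h_max:.4f}; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        h_bits = h_max
    if h_bits == 0.0:
        return PredictabilityResult(pi=1.0, z=z, h_bits=0.0)
    if h_bits == h_max:
        return PredictabilityResult(pi=1.0 / z, z=z, h_bits=h_bits)
    # fano_bound is decreasing on [1/z, 1]; the largest root lies there.
    pi = brentq(lambda p: fano_bound(p, z) - h_bits, 1.0 / z, 1.0, xtol=1e-12)
    return PredictabilityResult(pi=float(pi), z=z, h_bits=float(h_bits))
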