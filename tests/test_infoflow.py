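"""Unit and property tests for the match-length entropy estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quoterflow as qf
from quoterflow.infoflow import _match_lengths_kernel

from conftest import random_stream_pair


# ---------------------------------------------------------------------------
# match_length
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "source, t, past, expected",
    [
        # [1],[1,2] seen in past; [1,2,4] unseen
        ([1, 2, 4], 0, [1, 2, 3, 1, 2], 3),
        # first word unseen
        ([9, 1, 1], 0, [1, 2], 1),
        # [1] seen, source exhausted -> remaining+1
        ([1], 0, [1], 2),
        # empty past: first word trivially unseen
        ([5, 5], 0, [], 1),
        # interior position
        ([1, 2, 4], 1, [1, 2, 3, 1, 2], 2),
        # whole remainder seen -> remaining+1
        ([1, 2], 0, [3, 1, 2, 3], 3),
    ],
)
def test_match_length_examples(source, t, past, expected):
    assert qf.match_length(source, t, past) == expected


@settings(deadline=None, max_examples=200)
@given(
    source=st.lists(st.integers(1, 5), min_size=1, max_size=30),
    past=st.lists(st.integers(1, 5), min_size=0, max_size=30),
    data=st.data(),
)
def test_match_length_bounds(source, past, data):
    """1 <= match length <= remaining length + 1, for any position."""
    t = data.draw(st.integers(0, len(source) - 1))
    lam = qf.match_length(source, t, past)
    assert 1 <= lam <= len(source) - t + 1


def test_kernel_equals_brute_force():
    """The fast kernel reproduces the quadratic scan exactly on random
    timestamped pairs (the full 1000-instance sweep runs in acceptance)."""
    rng = np.random.default_rng(7)
    for _ in range(150):
        a, b = random_stream_pair(rng)
        brute = qf.match_lengths_brute(a.words, a.times, b.words, b.times)
        cursors = np.searchsorted(b.times, a.times, side="left").astype(np.int64)
        fast = _match_lengths_kernel(a.words, b.words, cursors)
        np.testing.assert_array_equal(brute, fast)


def test_temporal_precedence_future_permutation_invariant():
    """Permuting target words written at or after time(A_t) cannot change
    the match length at t — only B's strict past is matchable."""
    rng = np.random.default_rng(21)
    for _ in range(50):
        a, b = random_stream_pair(rng, z=5, max_len=40)
        lambdas = qf.match_lengths_brute(a.words, a.times, b.words, b.times)
        t = int(rng.integers(0, len(a)))
        cutoff = a.times[t]
        future = np.flatnonzero(b.times >= cutoff)
        if future.size < 2:
            continue
        permuted = b.words.copy()
        permuted[future] = permuted[rng.permutation(future)]
        lam_perm = qf.match_lengths_brute(a.words, a.times, permuted, b.times)
        assert lam_perm[t] == lambdas[t]


# ---------------------------------------------------------------------------
# entropy_rate
# ---------------------------------------------------------------------------

def test_entropy_rate_all_novel_words():
    """Every word new -> all match lengths 1 -> h = log2 T."""
    T = 64
    stream = np.arange(1, T + 1)
    assert qf.entropy_rate(stream) == pytest.approx(np.log2(T))


def test_entropy_rate_constant_stream_decreases_with_length():
    h500 = qf.entropy_rate(np.ones(500, dtype=int))
    h1000 = qf.entropy_rate(np.ones(1000, dtype=int))
    assert h1000 < h500 < 0.1


def test_entropy_rate_requires_two_words():
    with pytest.raises(ValueError):
        qf.entropy_rate(np.array([3]))


def test_entropy_rate_zipf_convergence(vocab_paper):
    """The i.i.d.-Zipf estimate moves toward the analytic entropy as T
    grows (seeded ensemble of 20 streams per length)."""
    rng = np.random.default_rng(3)
    h_true = vocab_paper.entropy_bits
    errs = {}
    for T in (1500, 12000):
        ests = [qf.entropy_rate(vocab_paper.sample(T, rng)) for _ in range(20)]
        errs[T] = abs(np.mean(ests) - h_true)
    assert errs[12000] < errs[1500]


# ---------------------------------------------------------------------------
# cross_entropy
# ---------------------------------------------------------------------------

def test_cross_entropy_matches_formula():
    """h = TA*log2(TB)/sum(Lambda) with the ledger the estimate reports."""
    rng = np.random.default_rng(5)
    a, b = random_stream_pair(rng, z=4, max_len=50)
    est = qf.cross_entropy(a, b)
    expected = len(a) * np.log2(len(b)) / est.ledger.lambdas.sum()
    assert est.h_bits == pytest.approx(expected)
    assert est.ledger.source_length == len(a)
    assert est.ledger.target_length == len(b)


def test_cross_entropy_self_copy_is_highly_predictable(vocab_paper):
    """A verbatim later copy of the target is far more predictable from the
    target's past than from its own past alone."""
    rng = np.random.default_rng(9)
    words = vocab_paper.sample(400, rng)
    b = qf.TextStream(words=words, times=np.arange(400))
    a = qf.TextStream(words=words, times=np.arange(400) + 1000)
    est = qf.cross_entropy(a, b)
    assert est.h_bits < 0.5 * qf.entropy_rate(a)


def test_cross_entropy_rejects_degenerate_streams():
    good = qf.TextStream(words=np.array([1, 2, 3]), times=np.array([1, 2, 3]))
    empty = qf.TextStream(words=np.array([], dtype=int), times=np.array([], dtype=int))
    short = qf.TextStream(words=np.array([1]), times=np.array([1]))
    with pytest.raises(ValueError):
        qf.cross_entropy(empty, good)
    with pytest.raises(ValueError):
        qf.cross_entropy(good, short)


def test_cross_entropy_is_directional():
    """Swapping ego and alter changes the ledger on asymmetric streams."""
    b = qf.TextStream(words=np.array([1, 2, 3, 4, 5]), times=np.array([1, 2, 3, 4, 5]))
    a = qf.TextStream(words=np.array([1, 2, 3, 9, 9]), times=np.array([6, 7, 8, 9, 10]))
    fwd = qf.cross_entropy(a, b)
    rev = qf.cross_entropy(b, a)
    assert fwd.h_bits != rev.h_bits
    assert not np.array_equal(fwd.ledger.lambdas, rev.ledger.lambdas)


# ---------------------------------------------------------------------------
# predictability
# ---------------------------------------------------------------------------

def test_predictability_limits():
    assert qf.predictability(0.0, 1000).pi == 1.0
    assert qf.predictability(float(np.log2(1000)), 1000).pi == pytest.approx(
        0.001, abs=1e-9)


def test_predictability_round_trip_and_monotone():
    """fano_bound(predictability(h)) == h, and Pi decreases as h grows."""
    z = 1000
    hs = np.linspace(0.05, np.log2(z) - 0.05, 25)
    pis = [qf.predictability(float(h), z).pi for h in hs]
    for h, pi in zip(hs, pis):
        assert qf.fano_bound(pi, z) == pytest.approx(h, abs=1e-6)
    assert all(p1 > p2 for p1, p2 in zip(pis, pis[1:]))


def test_predictability_clamps_above_log2z():
    with pytest.warns(RuntimeWarning):
        res = qf.predictability(np.log2(1000) + 0.5, 1000)
    assert res.pi == pytest.approx(0.001)


def test_predictability_rejects_bad_inputs():
    with pytest.raises(ValueError):
        qf.predictability(-0.1, 1000)
    with pytest.raises(ValueError):
        qf.predictability(1.0, 1)
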