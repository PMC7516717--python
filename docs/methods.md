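# Methods

This note documents the models implemented in `quoterflow`, the estimators
and their numerical conventions, the design decisions taken where the
procedures admit more than one reasonable reading, and the limits of what
the synthetic experiments can show.

## The quoter model

The simulation operates on a simple undirected graph with nodes `0..N−1`.
Time advances in `T = steps_per_node · N` discrete steps. At each step:

1. **Scheduling.** One node (the ego) is chosen uniformly at random
   (default), or deterministically in rotation (`scheduling="round_robin"`).
   Random scheduling is the default because the target behavior is that
   each node generates *approximately* `steps_per_node · λ` words, i.e.
   per-node action counts are stochastic. Both disciplines are implemented;
   estimates are insensitive to the choice at the scales used here.
2. **Action.** With probability `q` the ego quotes: it picks an alter
   uniformly among its graph neighbors and copies a contiguous segment of
   the alter's *current* stream, of Poisson(λ)-distributed length, start
   position uniform among valid positions. Otherwise (probability `1−q`)
   it writes Poisson(λ) fresh words sampled i.i.d. from its vocabulary
   distribution.
3. **Timestamping.** Every appended word carries the global step index.

Conventions that keep the dynamics well-posed:

- A drawn Poisson length of 0 means the node writes nothing that step
  (no resampling; the Poisson is taken at face value).
- A requested quote length is clamped to the alter's current stream length
  (a segment of past text cannot exceed it).
- If the ego has no neighbors, or its chosen alter has not yet written
  anything, the ego generates fresh content instead. Isolated nodes
  therefore behave exactly as `q = 0` nodes.
- One seeded NumPy generator drives the whole run. The per-step draw order
  (actor, quote-vs-new uniform, length; then alter index and segment start
  when quoting, or content words when writing) is fixed, so a run is exactly
  reproducible from (graph, config, seed).

**Vocabulary.** Words are ranks `1..z` with Zipf probabilities
`W(r) = r^(−α)/H(z,α)`, `H(z,α) = Σ_{r=1}^{z} r^(−α)`. The study conditions
are `z = 1000` and `α = 1.5` (typical of social-media text), with `q = 1/2`
and `λ = 3`; `steps_per_node = 1000` makes each stream ≈ 3000 words, long
enough for the entropy estimators to stabilize. A per-block vocabulary map
(block label → distribution) models community-level dynamic heterogeneity:
fresh content comes from the ego's own block distribution while quoting
copies verbatim across blocks.

## Entropy, cross-entropy, predictability

The entropy rate of a stream is estimated as `ĥ = T·log2(T)/Σ_t Λ_t`, where
`Λ_t` is the length of the shortest substring starting at position `t` that
does not occur in the stream's own first `t` words. The cross-entropy of
stream A given stream B generalizes this:
`ĥ×(A|B) = T_A·log2(T_B)/Σ_t Λ_t(A|B)`, with `Λ_t` matched only against the
words of B whose timestamps are **strictly earlier** than `time(A_t)`
(same-step words are excluded; temporal precedence is the point of the
measure). All logarithms are base 2; entropies are bits per word.

Numerical conventions:

- **End-of-sequence.** If every substring through the end of the source
  occurs in the matchable past, `Λ_t = (remaining length) + 1` — the
  standard convention for match-length estimators, and the one under which
  a verbatim copy yields the maximal possible `ΣΛ`.
- **Empty past.** `Λ_t = 1` (the first word is trivially unseen); not an
  error.
- **Implementation.** The production path is an `O(T_A·T_B)` scan compiled
  with numba; its contract is bit-exact equality with the quadratic
  pure-Python reference scan (`match_length` / `match_lengths_brute`), which
  the test suite enforces on a thousand random timestamped instances.
- **Fano predictability.** `Π` is the largest root of
  `h2(Π) + (1−Π)·log2(z−1) = h` on `[1/z, 1]`, found by Brent's method to
  `1e−12` (the left-hand side is strictly decreasing there, with value
  `log2 z` at `1/z` and `0` at `1`). `h = 0` maps to `Π = 1` and
  `h = log2 z` to `Π = 1/z` exactly. Inputs above `log2 z` — possible for
  finite-sample estimates — are clamped with a warning rather than
  rejected.

**Finite-sample bias (known limitation).** Match-length estimators converge
slowly — the error decays roughly like `log log T / log T` — and on a
heavy-tailed `z = 1000` vocabulary the longest-match statistics are further
inflated by rare long coincidences. In practice, i.i.d.-Zipf text at
`T ≈ 3000` words measures around 3.4 bits/word against an analytic Shannon
entropy of 4.21 bits/word (about 20 % low), with the gap closing only
logarithmically as `T` grows; the convergence test demonstrates the
monotone approach. Comparisons in this package are therefore *relative*:
all structural results compare cross-entropies estimated at the same `T`,
where the common bias cancels, and no result depends on reading `ĥ×` as an
unbiased absolute entropy.

## Contagion baselines

Dynamics are continuous-time and event-driven (Gillespie): every
susceptible–infected edge transmits at rate β and every infected node
recovers at rate γ, so rates such as β = 20 are meaningful (they are not
per-step probabilities). `⌈init_frac·N⌉` initial infecteds are drawn
without replacement (defaults: β = 20, γ = 1, init_frac = 0.05).

The complex-contagion variant multiplies a susceptible node's total
infection rate `β·(# infected neighbors)` by an indicator that the
*fraction of all neighbors currently infected* is at least φ, re-evaluated
at every event. The denominator is the node's full degree (not its
non-recovered neighborhood) — the standard reading of "proportion of
infected neighbors". A small epsilon (`1e−9`) guards the fraction-threshold
comparison against binary-float artifacts (e.g. `0.18 × 50` exceeding 9 by
one ulp). φ = 0 reduces to plain SIR through the identical code path, so
runs agree bitwise for a shared seed. The headline observable is the peak
outbreak size `max_t |I(t)|`; the final size is recorded as well. With
γ = 0 and no admissible transmission the process is absorbing and the
simulation stops (prevalence then does not return to zero).

## Network ensembles and metrics

- **ER**: `G(N, p)` with `p = ⟨k⟩/(N−1)`. Used as generated, possibly
  disconnected — the quoter simulation tolerates isolated nodes — since the
  density sweeps define the ensemble by `p`, not by a connectivity repair.
- **BA**: growth with `m = ⟨k⟩/2` edges per arriving node; the seeding
  ambiguity (initial nodes have no edges, so degree-proportional choice is
  undefined for the first arrival) is resolved by letting the first arrival
  link to all `m` seeds, giving exactly `M = m(N−m)` edges.
- **WS**: ring lattice with `k` nearest neighbors, each lattice edge
  rewired with probability `p`; edge count `Nk/2` preserved.
- **Dichotomous**: exactly `N/2` nodes of degree `k1` and `N/2` of degree
  `k2` (mean `(k1+k2)/2`, variance `(k1−k2)²/4`). Built by Havel–Hakimi on
  the exact degree sequence, repaired to a single component by
  degree-preserving cross-component rewiring, then randomized by `10·M`
  connected double-edge-swap attempts. This yields exact degrees and
  connectivity by construction, avoiding the rejection loops of stub
  matching.
- **SBM**: two planted blocks of size `m = N/2` with within/between
  connection probabilities `p0`/`p1`.
- **x-swap**: repeated double edge swaps `(a,b),(c,d) → (a,d),(c,b)`;
  swaps creating self-loops or parallel edges are rejected (so degrees and
  `M` are exact invariants), and connectivity is checked every
  `check_interval` accepted swaps with batch rollback on failure. The swap
  budget counts *attempts*, so swap-saturated graphs (complete graphs)
  terminate unchanged.

Metrics: transitivity `T(G) = 3·N_triangles/N_triads` with `T = 0` for
triad-free graphs (avoiding 0/0); Newman modularity
`Q = Σ_c [L_c/M − (d_c/2M)²]`, equivalent to the adjacency-matrix double
sum; both edge-density conventions (`M/C(N,2)` for descriptive tables,
`M/N²` for cross-network density axes) are computed and labeled. Summary
partitions for the modularity column come from networkx's Louvain
implementation. The closed-form expected modularity of the two-block SBM
is derived as the expected within-edge fraction minus the symmetric null
term 1/2:

    E[Q] = ((m−1)·p0 − m·p1) / (2·((m−1)·p0 + m·p1))

which gives 1/2 for `p1 = 0`, tends to 0 for `p0 = p1` at large `m`, and is
validated against Monte-Carlo planted-partition modularity within two
standard errors across a `(p0, p1)` grid. (This form replaces a garbled
printed expression; the limits and the Monte-Carlo oracle pin it down.)

## Experiments and summary statistics

An edge cross-entropy `h×(u|v)` predicts ego `v` from alter `u`; both
orientations of every edge enter the summary set, so means and variances
are over up to `2M` directed values (population variance, `ddof = 0`).
Pairs with a stream shorter than two words are skipped and counted. Block
summaries (`Δh× = ⟨h×(between)⟩ − ⟨h×(within)⟩`) default to existing edges,
matching the within-/between-*edge* framing; a sampled mode draws arbitrary
ordered node pairs instead, since the estimator does not require adjacency
(both modes are exposed because the between-community measurements admit
either reading). On dense graphs the pair set can be subsampled without
replacement (seeded) to bound runtime.

Replicated scenarios (`run_scenario`) re-draw both the graph and the quoter
randomness per replicate, with all seeds derived from a single base seed
via a `SeedSequence`, so sweeps are exactly reproducible.

**Problem sizes.** The structural experiments in the test suite run at
desk scale, chosen once: `N = 200` for ER/BA/WS and dichotomous ensembles,
`N = 100` for the SBM (matching the study's own SBM size),
`steps_per_node` of 250–300 for direction checks (streams of ~750–900
words), 25–40 replicates per grid point, and 80–300 estimated pairs per
graph. Pilot noise measurements showed these scales resolve every
directional effect by several standard errors, except the anti-community
`Δh× > 0` effect, which is intrinsically weak (~0.001 bits) and gets the
largest replicate and pair budgets. The word-volume and estimator-baseline
checks run at the full study scale (`steps_per_node = 1000`,
~3000 words/node).

## What the synthetic experiments do and do not show

The generator *is* the study system: conclusions are about the quoter
model on synthetic graph ensembles, under an idealized Zipf vocabulary,
undirected reciprocal ties, uniform alter choice, and a single global `q`.
Passing tests establish the structural phenomenology of this model —
density-inhibited flow, hub-driven variance, clustering effects, weak long
ties — not properties of real social-media text, which has syntax,
burstiness, topic drift, directed and weighted relationships, and
vocabulary sizes the match-length estimator handles with substantial
finite-sample bias. Real-network analyses are supported through the
edge-list loader, but network provenance, weighting, and preprocessing are
the user's responsibility.

Other known limitations: per-edge heterogeneous quote probabilities and
directed quoting are out of scope; transfer/causation-entropy style
multi-alter measures are not implemented; the x-swap comparison cannot
isolate transitivity from the path-length/modularity/assortativity changes
it simultaneously induces — that confound is a property of the method, not
of this implementation.
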