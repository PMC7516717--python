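"""Information flow within vs between planted communities.

On a two-block SBM, edges bridging the blocks ("long ties") carry less
predictive information than within-block edges: delta h_x > 0, a
weakness-of-long-ties effect — without any social-reinforcement mechanism.
"""

import numpy as np

import quoterflow as qf

vocab = qf.zipf_vocabulary(1000, 1.5)
for p0, p1 in [(0.40, 0.05), (0.20, 0.20), (0.10, 0.30)]:
    spec = qf.SBMSpec(N=100, p0=p0, p1=p1)
    deltas, qs = [], []
    for r in range(15):
        g, blocks = qf.generate_sbm(spec, seed=10 * r)
        cfg = qf.QuoterConfig(q=0.5, lam=3.0, steps_per_node=250, vocab=vocab)
        corpus = qf.simulate_quoter(g, cfg, seed=10 * r + 1)
        bs = qf.block_flow_difference(g, blocks, corpus, seed=r)
        deltas.append(bs.delta_hx)
        qs.append(qf.newman_modularity(g, blocks))
    print(f"p0={p0:.2f} p1={p1:.2f}: Q={np.mean(qs):+.3f}  "
          f"delta h_x = {np.mean(deltas):+.4f} bits "
          f"(between minus within, 15 runs)")
# delta h_x grows with modularity and, with enough replicates, its ensemble
# mean stays (weakly) positive even in the anti-community regime Q < 0.
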