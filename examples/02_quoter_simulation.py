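"""Run the quoter model and inspect the text streams it generates.

Each node acts ~steps_per_node times, writing Poisson(lam) words per action
either freshly from its Zipf vocabulary (prob 1-q) or by quoting a random
segment of a neighbor's past text (prob q).
"""

import numpy as np

import quoterflow as qf

g = qf.generate_er(50, 6, seed=1)
vocab = qf.zipf_vocabulary(1000, 1.5)
cfg = qf.QuoterConfig(q=0.5, lam=3.0, steps_per_node=1000, vocab=vocab)
corpus = qf.simulate_quoter(g, cfg, seed=2)

lengths = np.array([len(s) for s in corpus.streams.values()])
print(f"nodes: {len(corpus.streams)}, total words: {corpus.total_words}")
print(f"words per node: mean {lengths.mean():.0f} (expected ~ steps*lam = 3000), "
      f"min {lengths.min()}, max {lengths.max()}")
s0 = corpus.streams[0]
print(f"node 0 starts: words {s0.words[:8].tolist()} at steps {s0.times[:8].tolist()}")
# Word ids are Zipf ranks (1 = most frequent); timestamps are the global
# simulation steps at which each word was written.
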