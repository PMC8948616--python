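"""Replicate sampling: missing-value handling as on-the-fly data augmentation.

Each emitted training vector draws every metabolite value uniformly from
the observed replicate pool of its biological condition, so missing
entries never need filling and each draw is a fresh recombination.
"""

import numpy as np

import metabodl as m

train, _ = m.generate_dataset(m.SynthConfig(seed=1))
# a few metabolites are below detection in all replicates of some strain;
# those have no pool to sample from and are dropped
train = m.drop_unpoolable_features(train)
sampler = m.ReplicateSampler(train, rng=np.random.default_rng(0))

draws = sampler.draw_batch(["class_0"] * 5)
print("five sampled vectors for strain class_0, first 4 metabolites:")
print(np.round(draws[:, :4], 3))
print("each column's values all come from class_0's observed replicate pool;")

pool = train.values[np.asarray(train.replicate_group) == "class_0"][:, 0]
pool = pool[~np.isnan(pool)]
many = sampler.draw_batch(["class_0"] * 10_000)[:, 0]
print(f"pool for metabolite met_0: {np.round(sorted(pool), 3)}")
print(f"empirical mean over 10k draws {many.mean():.3f} vs pool mean {pool.mean():.3f}")
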