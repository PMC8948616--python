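"""Cast metabolite levels to mass-action-ratio (MAR) features.

A MAR is the reaction quotient Gamma = prod(products^p) / prod(reactants^r)
of a metabolic reaction.  Reactions with under 50% measured metabolites
are dropped, unmeasured species get fixed defaults, and ratios are clipped
to [1e-3, 1e3].
"""

import numpy as np

import metabodl as m

train, _ = m.generate_dataset(m.SynthConfig(seed=2))
train = m.drop_unpoolable_features(train)  # sampling needs non-empty pools
network = m.generate_network(train.feature_ids, n_reactions=30,
                             participants_per_reaction=4,
                             fraction_unmeasured=0.25, seed=2)

mar_table = m.build_mar_features(train, network, rng=np.random.default_rng(0))
print(f"input:  {train.n_samples} samples x {train.n_features} metabolites")
print(f"output: {mar_table.n_samples} samples x {mar_table.n_features} reactions "
      f"(of {len(network)} in the network; low-coverage reactions dropped)")
print(f"MAR range: [{mar_table.values.min():.2e}, {mar_table.values.max():.2e}] "
      "(clipped to [1e-3, 1e3])")
print("first sample, first 5 reactions:", np.round(mar_table.values[0, :5], 4))
print("a MAR >> 1 means product levels dominate; << 1 means reactant levels dominate")
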