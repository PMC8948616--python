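"""Preprocess a metabolite table: biomass normalization, imputation, transforms.

Generates a small synthetic study (7 strains x 3 replicates, 100
metabolites, below-detection-limit missingness), then walks the standard
preprocessing chain and prints what each step does to the values.
"""

import numpy as np

import metabodl as m

train, test = m.generate_dataset(m.SynthConfig(seed=0))
print(f"train: {train.n_samples} samples x {train.n_features} metabolites, "
      f"{train.n_missing} values below detection limit")

# divide out per-sample culture amount (gDW)
train_bn = m.biomass_normalize(train)
print(f"biomass range {train.biomass.min():.2f}-{train.biomass.max():.2f} gDW; "
      "values divided per sample")

# fill missing values with the within-replicate-group mean
filled = m.impute_fill(train_bn, "mean")
print(f"after mean fill: {filled.n_missing} missing values remain")

# offline log2 + min-max projection, parameters frozen on the training split
state = m.fit_transform(filled, "LogTransProj", "Off")
projected = m.apply_transform(filled, state)
print(f"LogTransProj output range: [{projected.values.min():.3f}, "
      f"{projected.values.max():.3f}]  (unit interval by construction)")

# clipped log10 fold change relative to the first strain
fc_state = m.fit_transform(filled, "FCLog", "Off", base=10, control_group="class_0")
fc = m.apply_transform(filled, fc_state)
print(f"FCLog10 output range: [{fc.values.min():.3f}, {fc.values.max():.3f}]; "
      f"{np.mean(np.abs(fc.values) >= 1):.1%} of values clipped at +/-1")
print("values near 0 = at control level; +1 = >=10x up; -1 = >=10x down")
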