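"""Synthetic metabolomics data with realistic statistical structure.

The generator emulates the features of targeted metabolomics feature
tables that drive preprocessing behaviour:

* log-normal metabolite levels spanning several orders of magnitude;
* class effects as log-fold shifts on a subset of features;
* a low-rank factor structure (metabolite levels are highly correlated);
* multiplicative per-feature batch effects, with the test split acquired
  under an independent batch multiplier (two-instrument acquisition);
* replicate noise;
* left-censoring: values below the detection limit become missing (the
  dominant missingness mechanism in metabolomics), plus an optional small
  missing-completely-at-random fraction for imputer testing;
* per-sample biomass that multiplies all measured values;
* class imbalance via per-class replicate counts.

Defaults mirror a small targeted study: 7 classes (strains), 3 replicates
each, 100 metabolites.  A companion generator emits random reaction
networks over the measured features so the mass-action-ratio pipeline and
its coverage filter can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable, Reaction, ReactionNetwork

__all__ = ["SynthConfig", "generate_dataset", "generate_network"]


@dataclass
class SynthConfig:
    n_classes: int = 7
    replicates_per_class: int | list[int] = 3
    test_replicates_per_class: int | list[int] = 3
    n_metabolites: int = 100
    log_mean_loc: float = 0.0     # natural-log location of per-feature baselines
    log_mean_scale: float = 2.0   # spread of baselines across features (orders of magnitude)
    class_effect_fraction: float = 0.3   # fraction of features shifted per class
    class_effect_scale: float = 1.5      # log-fold-shift scale (several-fold to ~10x shifts)
    n_factors: int = 3
    factor_scale: float = 0.4     # loading scale of the low-rank correlation structure
    batch_log_sd: float = 0.5     # per-feature batch log-multiplier SD (0 = no batch effect)
    replicate_noise_log_sd: float = 0.25
    detection_limit: float = 0.05  # measured values below become missing
    mcar_fraction: float = 0.0
    biomass_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_metabolites < 1:
            raise ValueError("counts must be >= 1")
        if self.detection_limit < 0:
            raise ValueError("detection limit must be >= 0")
        for v in (self.log_mean_scale, self.class_effect_scale, self.batch_log_sd,
                  self.replicate_noise_log_sd, self.biomass_log_sd):
            if v < 0:
                raise ValueError("scales must be >= 0")

    def _reps(self, split: str) -> list[int]:
        reps = self.replicates_per_class if split == "train" else self.test_replicates_per_class
        if isinstance(reps, int):
            return [reps] * self.n_classes
        if len(reps) != self.n_classes:
            raise ValueError("per-class replicate list must have n_classes entries")
        return list(reps)


def generate_dataset(cfg: SynthConfig) -> tuple[FeatureTable, FeatureTable]:
    """Generate (train, test) feature tables; deterministic given the seed.

    Values are ``exp(baseline + class shift + batch + factor*loading +
    replicate noise) * biomass``; entries below the detection limit are set
    missing.  Train and test carry independent per-feature batch
    multipliers when ``batch_log_sd > 0``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_metabolites

    base = rng.normal(cfg.log_mean_loc, cfg.log_mean_scale, size=p)
    loadings = rng.normal(0.0, cfg.factor_scale, size=(cfg.n_factors, p))
    shifts = np.zeros((cfg.n_classes, p))
    for c in range(cfg.n_classes):
        hit = rng.random(p) < cfg.class_effect_fraction
        shifts[c, hit] = rng.normal(0.0, cfg.class_effect_scale, size=int(hit.sum()))

    batch_names = ("long_gradient", "short_gradient")
    tables = []
    for split, batch_name in zip(("train", "test"), batch_names):
        if cfg.batch_log_sd > 0:
            # acquisition batches differ both in overall sensitivity (shared
            # across features) and feature-specifically
            batch_shift = rng.normal(0.0, cfg.batch_log_sd) + rng.normal(
                0.0, cfg.batch_log_sd, size=p
            )
        else:
            batch_shift = np.zeros(p)
        reps = cfg._reps(split)
        rows, sample_ids, labels, groups, batches = [], [], [], [], []
        for c, n_rep in enumerate(reps):
            label = f"class_{c}"
            for r in range(n_rep):
                factors = rng.normal(0.0, 1.0, size=cfg.n_factors)
                noise = rng.normal(0.0, cfg.replicate_noise_log_sd, size=p)
                logv = base + shifts[c] + batch_shift + factors @ loadings + noise
                rows.append(logv)
                sample_ids.append(f"{split}_{label}_rep{r}")
                labels.append(label)
                groups.append(label)
                batches.append(batch_name)
        biomass = np.exp(rng.normal(0.0, cfg.biomass_log_sd, size=len(rows)))
        X = np.exp(np.asarray(rows)) * biomass[:, None]
        X[X < cfg.detection_limit] = np.nan
        if cfg.mcar_fraction > 0:
            X[rng.random(X.shape) < cfg.mcar_fraction] = np.nan
        tables.append(FeatureTable(
            sample_ids=sample_ids,
            feature_ids=[f"met_{j}" for j in range(p)],
            values=X,
            labels=labels,
            replicate_group=groups,
            batch=batches,
            biomass=biomass,
        ))
    return tables[0], tables[1]


def generate_network(
    feature_ids: list[str],
    n_reactions: int = 20,
    participants_per_reaction: int = 4,
    fraction_unmeasured: float = 0.0,
    seed: int = 0,
) -> ReactionNetwork:
    """Random reaction network over measured features plus unmeasured species.

    ``fraction_unmeasured`` controls the expected measured coverage of each
    reaction (coverage = 1 - fraction_unmeasured), so the 50% coverage
    filter can be exercised on both sides of the threshold.  Deterministic
    given the seed.
    """
    if participants_per_reaction < 2:
        raise ValueError("reactions need at least 2 participants")
    rng = np.random.default_rng(seed)
    feature_ids = list(feature_ids)
    reactions = []
    unmeasured_counter = 0
    for i in range(n_reactions):
        n_unmeasured = int(np.round(fraction_unmeasured * participants_per_reaction))
        n_measured = participants_per_reaction - n_unmeasured
        mets = list(rng.choice(feature_ids, size=n_measured, replace=False))
        for _ in range(n_unmeasured):
            mets.append(f"unmeasured_{unmeasured_counter}")
            unmeasured_counter += 1
        mets = list(rng.permutation(mets))
        k = max(1, min(len(mets) - 1, int(rng.integers(1, len(mets)))))
        coefs = rng.choice([1.0, 1.0, 2.0], size=len(mets))
        reactions.append(Reaction(
            id=f"rxn_{i}",
            reactants={m: c for m, c in zip(mets[:k], coefs[:k])},
            products={m: c for m, c in zip(mets[k:], coefs[k:])},
        ))
    return ReactionNetwork(reactions=reactions)
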