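"""Mass-action-ratio (MAR) features from a stoichiometric reaction network.

A MAR is the thermodynamic reaction quotient

    Gamma = prod_i P_i^{p_i} / prod_j R_j^{r_j}

over a reaction's products P (coefficients p) and reactants R
(coefficients r).  Casting metabolite levels to MARs changes the feature
space from measured metabolites to network reactions, and — because a
single replicate is drawn per metabolite when computing each ratio —
doubles as a sampling-based missing-value treatment.

Species not measured in the table receive fixed defaults: the common
inorganic species carry literature estimates (phosphate 1.0, water
55.0e-3, dihydrogen 34.0, dioxygen 55.0, carbon dioxide 1.4, proton 1.0),
and any other unmeasured participant defaults to 1.0.  Computed MARs are
clipped to [1e-3, 1e3], and reactions whose measured-metabolite coverage
is below 50% are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable, Reaction, ReactionNetwork
from .preprocess import ReplicateSampler

__all__ = ["MarConfig", "compute_mar", "reaction_coverage", "build_mar_features", "MarSampler"]

#: default levels for the six special unmeasured species, by alias
SPECIES_DEFAULTS = {
    "pi": 1.0, "phosphate": 1.0,
    "h2o": 55.0e-3, "water": 55.0e-3,
    "h2": 34.0, "dihydrogen": 34.0,
    "o2": 55.0, "oxygen": 55.0,
    "co2": 1.4, "carbon_dioxide": 1.4,
    "h": 1.0, "hydrogen": 1.0, "h+": 1.0,
}


@dataclass
class MarConfig:
    defaults: dict[str, float] = field(default_factory=lambda: dict(SPECIES_DEFAULTS))
    generic_default: float = 1.0
    clip_low: float = 1e-3
    clip_high: float = 1e3
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if not self.clip_low < self.clip_high:
            raise ValueError("clip_low must be < clip_high")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.generic_default <= 0 or any(v <= 0 for v in self.defaults.values()):
            raise ValueError("all default levels must be positive")


def compute_mar(reaction: Reaction, levels: dict[str, float], cfg: MarConfig | None = None) -> float:
    """Clipped mass-action ratio of one reaction given metabolite levels.

    Every participant must resolve to a positive level — measured, a named
    default, or the generic default.
    """
    cfg = cfg or MarConfig()
    log_g = 0.0
    for met, coef in reaction.products.items():
        log_g += coef * np.log(_level(met, levels, cfg))
    for met, coef in reaction.reactants.items():
        log_g -= coef * np.log(_level(met, levels, cfg))
    return float(np.clip(np.exp(log_g), cfg.clip_low, cfg.clip_high))


def _level(met: str, levels: dict[str, float], cfg: MarConfig) -> float:
    if met in levels:
        v = levels[met]
        if not v > 0:
            raise ValueError(f"non-positive level for metabolite {met!r}: {v}")
        return v
    v = cfg.defaults.get(met.lower(), cfg.generic_default)
    if not v > 0:
        raise ValueError(f"non-positive default for metabolite {met!r}")
    return v


def reaction_coverage(reaction: Reaction, measured: set[str]) -> float:
    """Fraction of a reaction's participants present in ``measured``.

    Species with fixed defaults count as unmeasured: the coverage filter
    asks how much of the reaction is informed by data.
    """
    parts = reaction.participants
    if not parts:
        return 0.0
    return len(parts & measured) / len(parts)


def _retained(network: ReactionNetwork, measured: set[str], cfg: MarConfig) -> list[Reaction]:
    # strictly-below-threshold reactions are omitted; the boundary is kept
    return [r for r in network if reaction_coverage(r, measured) >= cfg.min_coverage]


class MarSampler:
    """On-the-fly MAR feature sampler for training loops.

    Each emitted vector draws one replicate per metabolite (uniformly over
    the observed pool of the requested replicate group) and computes the
    clipped MAR of every retained reaction.  The retained reaction set
    depends only on the measured feature ids, never on sample values.
    """

    def __init__(
        self,
        table: FeatureTable,
        network: ReactionNetwork,
        cfg: MarConfig | None = None,
        rng: np.random.Generator | int = 0,
    ):
        self.cfg = cfg or MarConfig()
        measured = set(table.feature_ids)
        self.reactions = _retained(network, measured, self.cfg)
        if not self.reactions:
            raise ValueError(
                "no reaction meets the measured-metabolite coverage threshold "
                f"({self.cfg.min_coverage:.0%}); lower min_coverage or measure more species"
            )
        self.table = table
        self.sampler = ReplicateSampler(table, rng=rng)
        self.feature_ids = [r.id for r in self.reactions]

        # exponent matrix over [measured features | unmeasured participants]
        extra = sorted({m for r in self.reactions for m in r.participants} - measured)
        self._n_meas = len(table.feature_ids)
        col = {m: i for i, m in enumerate(table.feature_ids)}
        col.update({m: self._n_meas + i for i, m in enumerate(extra)})
        E = np.zeros((len(self.reactions), len(col)))
        for i, r in enumerate(self.reactions):
            for met, coef in r.products.items():
                E[i, col[met]] += coef
            for met, coef in r.reactants.items():
                E[i, col[met]] -= coef
        self._E = E
        self._default_log = np.array(
            [np.log(self.cfg.defaults.get(m.lower(), self.cfg.generic_default)) for m in extra]
        )

    def draw_batch(self, groups: list[str]) -> np.ndarray:
        levels = self.sampler.draw_batch(groups)
        if np.any(levels <= 0):
            raise ValueError("replicate pools must contain positive levels for MARs")
        logs = np.concatenate(
            [np.log(levels), np.tile(self._default_log, (len(groups), 1))], axis=1
        )
        mars = np.exp(logs @ self._E.T)
        return np.clip(mars, self.cfg.clip_low, self.cfg.clip_high)

    @property
    def groups(self):
        return self.sampler.groups


def build_mar_features(
    table: FeatureTable,
    network: ReactionNetwork,
    cfg: MarConfig | None = None,
    rng: np.random.Generator | int = 0,
) -> FeatureTable:
    """Materialize one MAR feature table (one replicate draw per sample).

    Output features are the retained reaction ids; sample metadata carries
    over unchanged.  The number of features per sample changes from the
    number of measured metabolites to the number of retained reactions.
    """
    ms = MarSampler(table, network, cfg=cfg, rng=rng)
    X = ms.draw_batch(list(table.replicate_group))
    return table.with_values(X, feature_ids=ms.feature_ids)
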