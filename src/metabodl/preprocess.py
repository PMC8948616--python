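"""Biomass normalization, missing-value handling and the transformation catalog.

Missing values in metabolomics tables mostly arise from metabolites falling
below the instrument limit of detection in some replicates but not others.
Four treatments are provided:

* ``impute_fill`` — substitute zero, or the within-replicate-group mean;
* ``impute_em`` — EM-fitted multivariate-normal conditional means on
  log-values, averaged over bootstrap-resampled fits;
* ``ReplicateSampler`` — on-the-fly "Sampling": each feature of an emitted
  training example is drawn uniformly from the observed replicate pool of
  its biological condition.

The transformation catalog (None, Proj, LogTransProj, StandProj,
LogTransStandProj, FCLogX) is applied either offline (``Off``), with all
parameters fitted on the training split and frozen, or online (``On``) on a
sample-per-sample basis.  FCLogX is the clipped log-fold-change relative to
a control condition: ``clip(log_X((x+eps)/(ref+eps)), -1, 1)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import FeatureTable

__all__ = [
    "biomass_normalize",
    "impute_fill",
    "impute_em",
    "poolable_features",
    "drop_unpoolable_features",
    "ReplicateSampler",
    "TransformState",
    "fit_transform",
    "apply_transform",
    "TRANSFORM_METHODS",
    "FC_BASES",
]

TRANSFORM_METHODS = (
    "None", "Proj", "LogTransProj", "StandProj", "LogTransStandProj", "FCLog",
)
#: supported fold-change bases
FC_BASES = (2, 10, 20, 100)

EPSILON = 1e-9  # additive safety for every log in this module


# ---------------------------------------------------------------------------
# biomass normalization
# ---------------------------------------------------------------------------

def biomass_normalize(table: FeatureTable) -> FeatureTable:
    """Divide every value by its sample's biomass (e.g. gram dry weight).

    The missingness pattern is unchanged.  Raises ``ValueError`` if biomass
    is absent.
    """
    if table.biomass is None:
        raise ValueError("biomass_normalize requires a biomass column for every sample")
    return table.with_values(table.values / table.biomass[:, None])


# ---------------------------------------------------------------------------
# simple imputation
# ---------------------------------------------------------------------------

def impute_fill(table: FeatureTable, method: str = "zero") -> FeatureTable:
    """Fill missing values with zero, or the within-replicate-group mean.

    For ``mean``, a (group, feature) pair with no observed value at all
    falls back to the global feature mean with a warning; if the feature is
    entirely missing, a ``ValueError`` lists the offending pairs.
    """
    X = table.values.copy()
    mask = np.isnan(X)
    if method == "zero":
        X[mask] = 0.0
        return table.with_values(X)
    if method != "mean":
        raise ValueError(f"unknown fill method {method!r}")

    groups = np.asarray(table.replicate_group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_mean = np.nanmean(X, axis=0)
    bad_pairs = []
    for g in np.unique(groups):
        rows = groups == g
        sub = X[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gmean = np.nanmean(sub, axis=0)
        hole = np.isnan(sub)
        need_fallback = np.isnan(gmean) & hole.any(axis=0)
        for j in np.where(need_fallback)[0]:
            if np.isnan(global_mean[j]):
                bad_pairs.append((g, table.feature_ids[j]))
            else:
                warnings.warn(
                    f"replicate group {g!r} has no observed value for feature "
                    f"{table.feature_ids[j]!r}; falling back to the global feature mean"
                )
                gmean[j] = global_mean[j]
        sub[hole] = np.broadcast_to(gmean, sub.shape)[hole]
        X[rows] = sub
    if bad_pairs:
        raise ValueError(f"features entirely missing, cannot mean-fill: {bad_pairs}")
    return table.with_values(X)


# ---------------------------------------------------------------------------
# EM multivariate-normal imputation with bootstrap averaging
# ---------------------------------------------------------------------------

def _em_mvn(X: np.ndarray, ridge: float, max_iter: int, tol: float):
    """Fit a multivariate normal to data with NaN holes by EM.

    Returns ``(mu, sigma)``.  Raises ``RuntimeError`` on non-convergence,
    reporting the last relative log-likelihood change.
    """
    n, p = X.shape
    miss = np.isnan(X)
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[~np.isfinite(var) | (var <= 0)] = 1.0
    sigma = np.diag(var) + ridge * np.eye(p)

    last_ll = -np.inf
    rel = np.inf
    for _ in range(max_iter):
        Xf = X.copy()
        cc_sum = np.zeros((p, p))  # accumulated conditional covariances
        ll = 0.0
        for i in range(n):
            m = miss[i]
            if not m.any():
                o = ~m
                d = X[i] - mu
                L = np.linalg.cholesky(sigma)
                sol = np.linalg.solve(L, d)
                ll += -0.5 * (sol @ sol) - np.log(np.diag(L)).sum() - 0.5 * p * np.log(2 * np.pi)
                continue
            o = ~m
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            Smm = sigma[np.ix_(m, m)]
            L = np.linalg.cholesky(Soo)
            d = X[i, o] - mu[o]
            sol = np.linalg.solve(L, d)
            ll += -0.5 * (sol @ sol) - np.log(np.diag(L)).sum() - 0.5 * o.sum() * np.log(2 * np.pi)
            W = np.linalg.solve(L.T, np.linalg.solve(L, Smo.T)).T  # Smo @ Soo^-1
            Xf[i, m] = mu[m] + W @ d
            cond_cov = Smm - W @ Smo.T
            idx = np.where(m)[0]
            cc_sum[np.ix_(idx, idx)] += cond_cov
        mu = Xf.mean(axis=0)
        D = Xf - mu
        sigma = (D.T @ D + cc_sum) / n + ridge * np.eye(p)

        if np.isfinite(last_ll):
            rel = abs(ll - last_ll) / (abs(last_ll) + 1e-12)
            if rel < tol:
                return mu, sigma
        last_ll = ll
    raise RuntimeError(
        f"EM did not converge within {max_iter} iterations "
        f"(last relative log-likelihood change {rel:.3e})"
    )


def _conditional_fill(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    out = X.copy()
    for i in range(X.shape[0]):
        m = np.isnan(X[i])
        if not m.any():
            continue
        o = ~m
        Soo = sigma[np.ix_(o, o)]
        Smo = sigma[np.ix_(m, o)]
        out[i, m] = mu[m] + Smo @ np.linalg.solve(Soo, X[i, o] - mu[o])
    return out


def impute_em(
    table: FeatureTable,
    m: int = 5,
    seed: int = 0,
    log_transform: bool = True,
    ridge: float = 1e-3,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> FeatureTable:
    """EM-with-bootstrap multivariate-normal imputation.

    The model class mirrors classical EM/bootstrap multiple-imputation
    programs: a multivariate normal on (by default) log-transformed values,
    fitted by EM with a small ridge on the covariance, refitted on ``m``
    bootstrap resamples; each missing entry is replaced by the average of
    the conditional means across the ``m`` fits.  Deterministic given
    ``seed``.  Features with zero observed values must be excluded first.
    """
    if table.n_samples < 2:
        raise ValueError("impute_em requires at least 2 samples")
    X = table.values.copy()
    mask = np.isnan(X)
    if not mask.any():
        return table.with_values(X)
    if mask.all(axis=0).any():
        bad = [table.feature_ids[j] for j in np.where(mask.all(axis=0))[0]]
        raise ValueError(f"features with zero observed values must be excluded: {bad}")

    Z = np.log(X + EPSILON) if log_transform else X
    rng = np.random.default_rng(seed)
    n = Z.shape[0]
    acc = np.zeros_like(Z)
    for _ in range(m):
        for _attempt in range(20):
            rows = rng.integers(0, n, size=n)
            Zb = Z[rows]
            if not np.isnan(Zb).all(axis=0).any():
                break
        else:
            Zb = Z  # bootstrap kept producing empty features; fall back to full data
        mu, sigma = _em_mvn(Zb, ridge=ridge, max_iter=max_iter, tol=tol)
        acc += _conditional_fill(Z, mu, sigma)
    Zfill = Z.copy()
    Zfill[mask] = (acc / m)[mask]
    Xout = np.exp(Zfill) - EPSILON if log_transform else Zfill
    Xout[~mask] = X[~mask]
    return table.with_values(Xout)


def poolable_features(*tables: FeatureTable) -> np.ndarray:
    """Mask of features with >= 1 observed value in every replicate group.

    Sampling-based treatments require non-empty (group, feature) pools;
    features failing this in any of the given tables are masked out.
    """
    keep = np.ones(tables[0].n_features, dtype=bool)
    for table in tables:
        groups = np.asarray(table.replicate_group)
        for g in np.unique(groups):
            keep &= (~np.isnan(table.values[groups == g])).any(axis=0)
    return keep


def drop_unpoolable_features(*tables: FeatureTable) -> tuple[FeatureTable, ...]:
    """The given tables restricted to their jointly poolable features."""
    keep = poolable_features(*tables)
    out = tuple(
        t.with_values(t.values[:, keep],
                      [f for f, k in zip(t.feature_ids, keep) if k])
        for t in tables
    )
    return out if len(out) > 1 else out[0]


# ---------------------------------------------------------------------------
# replicate sampling ("Sampling" imputation)
# ---------------------------------------------------------------------------

class ReplicateSampler:
    """On-the-fly replicate sampling view of a feature table.

    For each requested replicate group, every feature value of the emitted
    vector is drawn uniformly and independently from that group's observed
    values for the feature.  Draws are independent across features and
    across requests, which both fills missing values and acts as a data
    augmentation: the emitted vectors are recombinations of observed
    replicate measurements.

    Raises at construction if any (group, feature) pool is empty.
    """

    def __init__(self, table: FeatureTable, rng: np.random.Generator | int = 0):
        self.table = table
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        groups = np.asarray(table.replicate_group)
        self.groups = list(dict.fromkeys(groups))  # stable order of appearance
        self._pools: dict[str, np.ndarray] = {}
        self._counts: dict[str, np.ndarray] = {}
        empties = []
        for g in self.groups:
            sub = table.values[groups == g]  # (reps, features)
            counts = (~np.isnan(sub)).sum(axis=0)
            for j in np.where(counts == 0)[0]:
                empties.append((g, table.feature_ids[j]))
            # pack observed values to the top so row k < counts[j] is valid
            packed = np.full_like(sub, np.nan)
            for j in range(sub.shape[1]):
                obs = sub[~np.isnan(sub[:, j]), j]
                packed[: obs.size, j] = obs
            self._pools[g] = packed
            self._counts[g] = counts
        if empties:
            raise ValueError(f"(group, feature) pairs with no observed value: {empties}")

    def draw(self, group: str) -> np.ndarray:
        """One complete feature vector for ``group``."""
        return self.draw_batch([group])[0]

    def draw_batch(self, groups: list[str]) -> np.ndarray:
        """A (len(groups), n_features) matrix of independent draws."""
        p = self.table.n_features
        out = np.empty((len(groups), p))
        for i, g in enumerate(groups):
            counts = self._counts[g]
            idx = (self.rng.random(p) * counts).astype(int)
            out[i] = self._pools[g][idx, np.arange(p)]
        return out

    def materialize(self) -> FeatureTable:
        """A single complete realization of the whole table (one draw per sample)."""
        X = self.draw_batch(list(self.table.replicate_group))
        return self.table.with_values(X)


# ---------------------------------------------------------------------------
# transformation catalog
# ---------------------------------------------------------------------------

@dataclass
class TransformState:
    """Frozen parameters of a fitted transformation.

    Off-mode parameters are fitted on the training split only and applied
    unchanged to test data; On mode computes per-sample statistics at
    application time and stores nothing data-dependent.
    """

    method: str = "None"
    mode: str = "Off"
    base: float = 10.0
    epsilon: float = EPSILON
    feat_min: np.ndarray | None = None  # Proj family, Off: min after any log/stand step
    feat_max: np.ndarray | None = None
    feat_mean: np.ndarray | None = None  # Stand family, Off (population std)
    feat_std: np.ndarray | None = None
    control_ref: np.ndarray | None = None  # FCLog: per-feature control-group mean

    def to_json(self, path) -> None:
        payload = {}
        for k, v in self.__dict__.items():
            payload[k] = v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TransformState":
        with open(path) as fh:
            payload = json.load(fh)
        for k in ("feat_min", "feat_max", "feat_mean", "feat_std", "control_ref"):
            if payload.get(k) is not None:
                payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


def _proj(X, lo, hi):
    span = hi - lo
    out = np.full_like(X, 0.5)  # constant feature: direction-free midpoint
    ok = span > 0
    out[..., ok] = (X[..., ok] - lo[..., ok]) / span[..., ok]
    return out


def _row_proj(X):
    lo = X.min(axis=-1, keepdims=True)
    hi = X.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.full_like(X, 0.5)
    rows = (span > 0).ravel()
    out[rows] = (X[rows] - lo[rows]) / span[rows]
    return out


def fit_transform(
    train: FeatureTable | np.ndarray,
    method: str = "None",
    mode: str = "Off",
    base: float = 10.0,
    control_group: str | None = None,
) -> TransformState:
    """Fit a :class:`TransformState` on training data.

    ``train`` must contain no missing values (impute or sample first).  For
    the Proj family in Off mode, min/max are computed after any log /
    standardization step; standardization uses the population (n) standard
    deviation.  FCLog stores the per-feature mean of the designated control
    replicate group.
    """
    if method not in TRANSFORM_METHODS:
        raise ValueError(f"unknown transform {method!r}; choose from {TRANSFORM_METHODS}")
    if mode not in ("On", "Off"):
        raise ValueError("mode must be 'On' or 'Off'")

    if isinstance(train, FeatureTable):
        X = train.values
        groups = np.asarray(train.replicate_group)
    else:
        X = np.asarray(train, dtype=float)
        groups = None
    if np.isnan(X).any():
        raise ValueError("training data contains missing values; impute or sample first")

    st = TransformState(method=method, mode=mode, base=float(base))
    if method == "None":
        return st
    if method == "FCLog":
        if base not in FC_BASES:
            raise ValueError(f"fold-change base must be one of {FC_BASES}")
        if control_group is None or groups is None:
            raise ValueError("FCLog requires a FeatureTable and a control_group")
        rows = groups == control_group
        if not rows.any():
            raise ValueError(f"control group {control_group!r} not present in training data")
        ref = X[rows].mean(axis=0)
        st.control_ref = np.maximum(ref, 0.0)  # floored; epsilon added at apply time
        return st
    if mode == "On":
        return st

    Z = X
    if method in ("LogTransProj", "LogTransStandProj"):
        Z = np.log2(Z + st.epsilon)
    if method in ("StandProj", "LogTransStandProj"):
        st.feat_mean = Z.mean(axis=0)
        st.feat_std = Z.std(axis=0)  # population std
        std = np.where(st.feat_std > 0, st.feat_std, 1.0)
        Z = (Z - st.feat_mean) / std
    st.feat_min = Z.min(axis=0)
    st.feat_max = Z.max(axis=0)
    return st


def apply_transform(x: FeatureTable | np.ndarray, state: TransformState):
    """Apply a fitted transformation to a table or value array.

    Off-mode Proj-family outputs are clipped to [0, 1] (test values may
    fall outside the train-fitted bounds); FCLog outputs are clipped to
    [-1, 1].  Returns the same kind of object it was given.
    """
    table = x if isinstance(x, FeatureTable) else None
    X = np.asarray(table.values if table is not None else x, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[None, :]
    eps = state.epsilon
    method, mode = state.method, state.mode

    if method == "None":
        Z = X.copy()
    elif method == "FCLog":
        if state.control_ref is None:
            raise ValueError("FCLog state is not fitted")
        ratio = (X + eps) / (state.control_ref + eps)
        Z = np.clip(np.log(ratio) / np.log(state.base), -1.0, 1.0)
    else:
        Z = X.copy()
        if method in ("LogTransProj", "LogTransStandProj"):
            Z = np.log2(Z + eps)
        if mode == "On":
            if method in ("StandProj", "LogTransStandProj"):
                mu = Z.mean(axis=-1, keepdims=True)
                sd = Z.std(axis=-1, keepdims=True)
                Z = (Z - mu) / np.where(sd > 0, sd, 1.0)
            Z = _row_proj(Z)
        else:
            if state.feat_min is None:
                raise ValueError(f"Off-mode {method} state is not fitted")
            if method in ("StandProj", "LogTransStandProj"):
                std = np.where(state.feat_std > 0, state.feat_std, 1.0)
                Z = (Z - state.feat_mean) / std
            Z = np.clip(_proj(Z, state.feat_min, state.feat_max), 0.0, 1.0)

    if squeeze:
        Z = Z[0]
    if table is not None:
        return table.with_values(Z)
    return Z
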