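"""Config-driven sweeps over preprocessing x model x loss combinations.

A grid names lists of options for every preprocessing and modelling
choice; it expands to a Cartesian product of fully specified runs, each
with a human-readable name built from the field's nomenclature (e.g.
``Concs / BN / Sampling / FCLog10 / classify``) and a per-run seed derived
deterministically from the run name and the master seed.  Replicate runs
aggregate to mean +/- SD summary tables with min-max scaled loss columns,
sorted and truncated like the bar-chart summaries such sweeps feed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import FeatureTable
from .mars import MarConfig, MarSampler
from .models import (
    ClassifierSpec, LatentSpec, TrainConfig, SamplingBatcher,
    train_classifier, train_reconstruction,
)
from .preprocess import (
    ReplicateSampler, apply_transform, biomass_normalize, drop_unpoolable_features,
    fit_transform, impute_em, impute_fill,
)
from .synthetic import SynthConfig, generate_dataset, generate_network

__all__ = ["ExperimentGrid", "RunConfig", "expand_grid", "run_single", "run_grid", "aggregate"]

IMPUTATION_METHODS = ("FillZero", "FillMean", "ImputedAmelia", "Sampling", "MARs")
TRANSFORM_NAMES = {
    "None": ("None", "Off", 10),
    "OnProj": ("Proj", "On", 10),
    "OffProj": ("Proj", "Off", 10),
    "OnLogTransProj": ("LogTransProj", "On", 10),
    "OffLogTransProj": ("LogTransProj", "Off", 10),
    "OnStandProj": ("StandProj", "On", 10),
    "OffStandProj": ("StandProj", "Off", 10),
    "OnLogTransStandProj": ("LogTransStandProj", "On", 10),
    "OffLogTransStandProj": ("LogTransStandProj", "Off", 10),
    "FCLog2": ("FCLog", "Off", 2),
    "FCLog10": ("FCLog", "Off", 10),
    "FCLog20": ("FCLog", "Off", 20),
    "FCLog100": ("FCLog", "Off", 100),
}


@dataclass
class RunConfig:
    name: str
    level: str
    biomass_normalize: bool
    imputation: str
    transform: str
    task: str                      # classify | reconstruct | joint
    loss: str                      # XEntropy | MSE | MAE | MAPE
    n_continuous: int
    n_discrete: int
    supervision_fraction: float
    replicate: int
    seed: int
    iterations: int | None = None


@dataclass
class ExperimentGrid:
    """Lists of options; every combination expands to one run per replicate."""

    levels: list[str] = field(default_factory=lambda: ["Concs"])
    biomass_normalize: list[bool] = field(default_factory=lambda: [False])
    imputation: list[str] = field(default_factory=lambda: ["Sampling"])
    transform: list[str] = field(default_factory=lambda: ["FCLog10"])
    task: list[str] = field(default_factory=lambda: ["classify"])
    loss: list[str] = field(default_factory=lambda: ["MSE"])
    latent: list[tuple[int, int]] = field(default_factory=lambda: [(4, 4)])
    supervision_fraction: list[float] = field(default_factory=lambda: [0.0])
    n_replicates: int = 3
    master_seed: int = 0
    iterations: int | None = None
    n_classes: int | None = None   # needed to validate supervised latent sizes


def derive_seed(name: str, master_seed: int) -> int:
    """Stable per-run seed: hash of the run name folded with the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def expand_grid(grid: ExperimentGrid) -> list[RunConfig]:
    """Cartesian expansion; incompatible combinations are skipped with a warning."""
    runs = []
    for level, bn, imp, trans, task, loss, (nc, nd), sup in itertools.product(
        grid.levels, grid.biomass_normalize, grid.imputation, grid.transform,
        grid.task, grid.loss, grid.latent, grid.supervision_fraction,
    ):
        if imp not in IMPUTATION_METHODS:
            raise ValueError(f"unknown imputation {imp!r}")
        if trans not in TRANSFORM_NAMES:
            raise ValueError(f"unknown transform {trans!r}")
        if task == "classify" and loss != "XEntropy":
            loss = "XEntropy"  # classification always trains with cross-entropy
        if task in ("reconstruct", "joint") and loss == "XEntropy":
            warnings.warn(f"skipping {task} run with XEntropy reconstruction loss")
            continue
        if task == "joint" and sup > 0 and grid.n_classes is not None and nd != grid.n_classes:
            warnings.warn(
                f"skipping supervised joint run: n_discrete {nd} != n_classes {grid.n_classes}"
            )
            continue
        base = f"{level}{'BN' if bn else ''} / {imp} / {trans} / {task}"
        if task != "classify":
            base += f" / {loss} / {nc}C{nd}D"
            if sup > 0:
                base += f" / sup{sup:g}"
        if any(r.name.startswith(base + " / rep") for r in runs):
            continue  # classification collapses the loss dimension to XEntropy
        for rep in range(grid.n_replicates):
            name = f"{base} / rep{rep}"
            runs.append(RunConfig(
                name=name, level=level, biomass_normalize=bn, imputation=imp,
                transform=trans, task=task, loss=loss, n_continuous=nc,
                n_discrete=nd, supervision_fraction=sup, replicate=rep,
                seed=derive_seed(name, grid.master_seed), iterations=grid.iterations,
            ))
    seen = set()
    for r in runs:
        if r.name in seen:
            raise ValueError(f"duplicate run name {r.name!r}")
        seen.add(r.name)
    return runs


# ---------------------------------------------------------------------------
# pipeline assembly for one run
# ---------------------------------------------------------------------------

def _labels_to_codes(labels, classes):
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[l] for l in labels])


def run_single(
    run: RunConfig,
    train: FeatureTable,
    test: FeatureTable,
    network=None,
    control_group: str | None = None,
    log_path=None,
) -> dict:
    """Execute one fully specified run and return a flat result record.

    Preprocessing follows the run config: optional biomass normalization,
    the chosen missing-value treatment (sampling-based treatments emit
    fresh draws every batch), and the chosen transformation with Off
    parameters fitted on the training split only.
    """
    method, mode, base = TRANSFORM_NAMES[run.transform]
    if run.biomass_normalize:
        train = biomass_normalize(train)
        test = biomass_normalize(test)
    train, test = drop_unpoolable_features(train, test)
    if control_group is None:
        control_group = sorted(set(train.replicate_group))[0]

    classes = sorted(set(train.labels) | set(test.labels))
    y_train = _labels_to_codes(train.labels, classes)
    y_test = _labels_to_codes(test.labels, classes)
    rng_seed = run.seed

    # --- assemble the training batch source and the fixed evaluation arrays
    if run.imputation in ("Sampling", "MARs"):
        if run.imputation == "MARs":
            if network is None:
                raise ValueError("MARs imputation requires a reaction network")
            sampler = MarSampler(train, network, rng=np.random.default_rng(rng_seed))
            test_sampler = MarSampler(test, network, rng=np.random.default_rng(rng_seed + 1))
        else:
            sampler = ReplicateSampler(train, rng=np.random.default_rng(rng_seed))
            test_sampler = ReplicateSampler(test, rng=np.random.default_rng(rng_seed + 1))
        fit_table = sampler.table.with_values(
            sampler.draw_batch(list(sampler.table.replicate_group)),
            feature_ids=getattr(sampler, "feature_ids", sampler.table.feature_ids),
        )
        state = fit_transform(fit_table, method, mode, base, control_group=control_group)
        batcher = SamplingBatcher(sampler, labels=y_train, transform_state=state)
        X_train_eval = apply_transform(fit_table.values, state)
        # evaluation inputs are themselves sampled; average predictions over
        # several draws so a single unlucky recombination does not dominate
        test_eval_draws = [
            apply_transform(test_sampler.draw_batch(list(test.replicate_group)), state)
            for _ in range(16)
        ]
        X_test_eval = test_eval_draws[0]
    else:
        if run.imputation == "FillZero":
            train_i, test_i = impute_fill(train, "zero"), impute_fill(test, "zero")
        elif run.imputation == "FillMean":
            train_i, test_i = impute_fill(train, "mean"), impute_fill(test, "mean")
        else:  # ImputedAmelia: EM multivariate-normal with bootstrap averaging
            train_i = impute_em(train, seed=rng_seed)
            test_i = impute_em(test, seed=rng_seed + 1)
        state = fit_transform(train_i, method, mode, base, control_group=control_group)
        X_train_eval = apply_transform(train_i.values, state)
        X_test_eval = apply_transform(test_i.values, state)
        test_eval_draws = [X_test_eval]
        batcher = None

    cfg = TrainConfig(iterations=run.iterations, seed=rng_seed,
                      supervision_fraction=run.supervision_fraction)
    record = {
        "name": run.name, "task": run.task, "imputation": run.imputation,
        "transform": run.transform, "loss": run.loss, "replicate": run.replicate,
        "seed": run.seed,
    }
    record["config"] = " / ".join(run.name.split(" / ")[:-1])

    if run.task == "classify":
        spec = ClassifierSpec(n_inputs=X_train_eval.shape[1], n_outputs=len(classes))
        data = batcher if batcher is not None else (X_train_eval, y_train)
        result = train_classifier(data, spec, cfg, test_data=(X_test_eval, y_test))
        pred_train = result.model.predict(X_train_eval)
        record["train_accuracy"] = float(np.mean(pred_train == y_train))
        mean_logits = np.mean([result.model.logits(Xd) for Xd in test_eval_draws], axis=0)
        record["test_accuracy"] = float(np.mean(np.argmax(mean_logits, axis=1) == y_test))
    else:
        supervision = "none"
        if run.task == "joint":
            supervision = "full" if run.supervision_fraction >= 1 else (
                "semi" if run.supervision_fraction > 0 else "none"
            )
        latent = LatentSpec(n_continuous=run.n_continuous, n_discrete=run.n_discrete)
        data = batcher if batcher is not None else (X_train_eval, y_train)
        result = train_reconstruction(
            data, latent, cfg, loss_kind=run.loss, supervision=supervision,
            test_data=(X_test_eval, y_test), n_classes=len(classes) if supervision != "none" else None,
        )
        for k, v in result.test_report.values.items():
            record[f"test_{k}"] = v

    record["iterations_to_min_loss"] = result.iterations_to_min_loss
    record["min_loss"] = result.min_loss
    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({k: v for k, v in record.items()}) + "\n")
    return record


def run_grid(
    grid: ExperimentGrid,
    synth_cfg: SynthConfig | None = None,
    train: FeatureTable | None = None,
    test: FeatureTable | None = None,
    network=None,
    log_path=None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Expand and execute a grid; returns one result row per run.

    Data are either supplied directly or generated per replicate from
    ``synth_cfg`` (each replicate re-generates with a derived seed, so
    replicate variation covers both data and training stochasticity).
    Runs are independent and share no mutable state; ``n_jobs > 1``
    executes them in a process pool with identical results.
    """
    runs = expand_grid(grid)
    if "MARs" in grid.imputation and network is None and train is None:
        synth_cfg = synth_cfg or SynthConfig()
        network = generate_network(
            [f"met_{j}" for j in range(synth_cfg.n_metabolites)],
            n_reactions=max(20, synth_cfg.n_metabolites // 2),
            seed=grid.master_seed,
        )
    cache: dict[int, tuple[FeatureTable, FeatureTable]] = {}

    def _data_for(run: RunConfig):
        if train is not None and test is not None:
            return train, test
        scfg = synth_cfg or SynthConfig()
        data_seed = derive_seed(f"data-rep{run.replicate}", grid.master_seed)
        if data_seed not in cache:
            cache[data_seed] = generate_dataset(
                SynthConfig(**{**asdict(scfg), "seed": data_seed})
            )
        return cache[data_seed]

    if n_jobs > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(run_single)(run, *_data_for(run), network=network)
            for run in runs
        )
        if log_path is not None:
            with open(log_path, "a") as fh:
                for rec in rows:
                    fh.write(json.dumps(rec) + "\n")
    else:
        rows = [
            run_single(run, *_data_for(run), network=network, log_path=log_path)
            for run in runs
        ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(
    results: pd.DataFrame,
    sort_key: str,
    ascending: bool = False,
    top_k: int | None = None,
    scale_columns: tuple = ("iterations_to_min_loss", "min_loss"),
) -> pd.DataFrame:
    """Mean +/- SD across replicates per configuration, scaled and ranked.

    ``scale_columns`` are min-max scaled to [0, 1] across configurations
    (constant columns map to 0).  The table is sorted on the mean of
    ``sort_key`` and truncated to ``top_k`` rows.
    """
    numeric = [c for c in results.columns
               if c not in ("name", "config", "replicate", "seed")
               and pd.api.types.is_numeric_dtype(results[c])]
    grouped = results.groupby("config")[numeric]
    summary = grouped.mean().add_suffix("_mean").join(
        grouped.std(ddof=0).add_suffix("_sd")
    ).reset_index()
    for col in scale_columns:
        c = f"{col}_mean"
        if c in summary.columns:
            lo, hi = summary[c].min(), summary[c].max()
            summary[f"{col}_scaled"] = 0.0 if hi == lo else (summary[c] - lo) / (hi - lo)
    key = f"{sort_key}_mean" if f"{sort_key}_mean" in summary.columns else sort_key
    summary = summary.sort_values(key, ascending=ascending, kind="mergesort").reset_index(drop=True)
    if top_k is not None:
        summary = summary.head(top_k)
    return summary


def plot_summary(summary: pd.DataFrame, value_col: str, out_path=None):
    """Horizontal bar chart of a summary column with SD error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sd_col = value_col.replace("_mean", "_sd")
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(summary) + 1))
    ax.barh(summary["config"], summary[value_col],
            xerr=summary[sd_col] if sd_col in summary.columns else None)
    ax.set_xlabel(value_col)
    ax.invert_yaxis()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
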