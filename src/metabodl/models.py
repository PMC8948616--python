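"""Classifier and (joint) variational-autoencoder networks.

All architectures are small, fixed, single-hidden-layer feedforward
networks, implemented directly in NumPy with explicit forward/backward
passes and a hand-rolled ADAM optimizer:

* classifier — inputs -> 8 hidden (leaky ReLU, slope 0.01) -> class
  logits, trained with cross-entropy, ADAM alpha 1e-4;
* VAE / JVAE — encoder inputs -> 16 hidden -> (mu, logvar[, logits]);
  the continuous latent uses the Gaussian reparameterization trick, the
  discrete latent the Concrete (Gumbel-softmax) relaxation; decoder latent
  -> 16 hidden -> reconstruction; ADAM alpha 1e-5.

Shared training machinery: He weight initialization, zero biases, batch
size 64, global gradient-norm clipping at 10, and a linear KL ("beta")
ramp from 0 to 1 over 2.5e4 iterations.  Supervision attaches a
cross-entropy loss to the discrete logits, applied per batch with
probability equal to the supervision fraction.  Every source of
randomness flows from the config seed, so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    MetricReport,
    classification_metrics,
    mean_similarity_report,
    reconstruction_loss,
)

__all__ = [
    "ClassifierSpec", "LatentSpec", "TrainConfig",
    "init_network", "beta_schedule",
    "reparameterize_gaussian", "reparameterize_concrete",
    "Classifier", "JointVAE", "TrainResult",
    "train_classifier", "train_reconstruction",
]


# ---------------------------------------------------------------------------
# specs and config
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    n_inputs: int
    n_outputs: int
    n_hidden: int = 8
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.n_outputs < 2:
            raise ValueError("classifier needs at least 2 output classes")


@dataclass
class LatentSpec:
    """Latent architecture: nC Gaussian nodes + nD Concrete (one-hot) nodes."""

    n_continuous: int
    n_discrete: int = 0
    n_hidden: int = 16
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.n_continuous + self.n_discrete < 1:
            raise ValueError("latent space must have at least one node")


@dataclass
class TrainConfig:
    """Training schedule; ``None`` fields resolve to per-task defaults.

    Defaults: 1e5 iterations (2e5 for semi-supervised reconstruction),
    learning rate 1e-4 for classification and 1e-5 for reconstruction.
    """

    iterations: int | None = None
    batch_size: int = 64
    learning_rate: float | None = None
    gradient_clip: float = 10.0
    beta_ramp_iters: int = 25_000
    beta_max: float = 1.0
    supervision_fraction: float = 0.0
    classification_loss_weight: float = 1.0
    concrete_temperature: float = 0.5
    eval_every: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.supervision_fraction <= 1:
            raise ValueError("supervision_fraction must lie in [0, 1]")
        if self.concrete_temperature <= 0 or self.gradient_clip <= 0:
            raise ValueError("temperature and gradient clip must be positive")


DEFAULT_ITERATIONS = 100_000
DEFAULT_ITERATIONS_SEMI = 200_000
DEFAULT_LR_CLASSIFIER = 1e-4
DEFAULT_LR_RECONSTRUCTION = 1e-5


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def _he(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


def init_network(spec: ClassifierSpec | LatentSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """He-initialized parameters (weights N(0, 2/fan_in), biases 0)."""
    rng = np.random.default_rng(seed)
    if isinstance(spec, ClassifierSpec):
        return {
            "W1": _he(rng, spec.n_inputs, spec.n_hidden),
            "b1": np.zeros(spec.n_hidden),
            "W2": _he(rng, spec.n_hidden, spec.n_outputs),
            "b2": np.zeros(spec.n_outputs),
        }
    raise TypeError("init_network expects a ClassifierSpec; JointVAE initializes itself")


def beta_schedule(iteration: int, ramp_iters: int, beta_max: float = 1.0) -> float:
    """Linear KL-weight ramp: 0 at iteration 0, ``beta_max`` from ``ramp_iters`` on."""
    if ramp_iters <= 0:
        return beta_max
    return beta_max * min(iteration / ramp_iters, 1.0)


def reparameterize_gaussian(mu, logvar, rng: np.random.Generator):
    """``mu + exp(logvar/2) * eps`` with standard-normal ``eps``."""
    mu = np.asarray(mu, dtype=float)
    eps = rng.standard_normal(mu.shape)
    return mu + np.exp(np.asarray(logvar, dtype=float) / 2.0) * eps


def reparameterize_concrete(logits, temperature: float, rng: np.random.Generator):
    """Concrete/Gumbel-softmax sample: ``softmax((logits + G)/T)``."""
    z = np.asarray(logits, dtype=float)
    u = rng.random(z.shape)
    gumbel = -np.log(-np.log(u + 1e-30) + 1e-30)
    return _softmax((z + gumbel) / temperature)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _lrelu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _lrelu_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, 1.0, slope)


def _clip_global(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so the global norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] *= scale
        return max_norm
    return total


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# batch sources
# ---------------------------------------------------------------------------

class ArrayBatcher:
    """Batches drawn with replacement from fixed (X, y) arrays."""

    def __init__(self, X: np.ndarray, y: np.ndarray | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = None if y is None else np.asarray(y)

    def draw(self, n: int, rng: np.random.Generator):
        idx = rng.integers(0, self.X.shape[0], size=n)
        return self.X[idx], (None if self.y is None else self.y[idx])


class SamplingBatcher:
    """Batches emitted by a replicate (or MAR) sampler, one fresh draw each.

    ``sampler`` needs ``draw_batch(groups)``; rows of the underlying table
    are chosen uniformly, their replicate groups define the pools, and an
    optional transform state is applied to every emitted batch.
    """

    def __init__(self, sampler, labels=None, transform_state=None):
        self.sampler = sampler
        self.groups = list(sampler.table.replicate_group)
        self.labels = None if labels is None else np.asarray(labels)
        self.state = transform_state

    def draw(self, n: int, rng: np.random.Generator):
        idx = rng.integers(0, len(self.groups), size=n)
        X = self.sampler.draw_batch([self.groups[i] for i in idx])
        if self.state is not None:
            from .preprocess import apply_transform
            X = apply_transform(X, self.state)
        return X, (None if self.labels is None else self.labels[idx])


def _as_batcher(data):
    if hasattr(data, "draw"):
        return data
    if isinstance(data, tuple):
        return ArrayBatcher(*data)
    return ArrayBatcher(np.asarray(data))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: object
    trace: dict[str, list] = field(default_factory=dict)
    train_report: MetricReport | None = None
    test_report: MetricReport | None = None

    @property
    def iterations_to_min_loss(self) -> int:
        """Iteration of the minimum recorded evaluation loss (cadence 100)."""
        losses = self.trace.get("eval_loss") or self.trace.get("loss")
        if not losses:
            return 0
        return int(self.trace["iteration"][int(np.argmin(losses))])

    @property
    def min_loss(self) -> float:
        losses = self.trace.get("eval_loss") or self.trace.get("loss")
        return float(np.min(losses)) if losses else float("nan")

    def trace_frame(self):
        import pandas as pd
        return pd.DataFrame(self.trace)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class Classifier:
    """Single-hidden-layer softmax classifier."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        self.params = init_network(spec, seed)

    def logits(self, X: np.ndarray) -> np.ndarray:
        p, s = self.params, self.spec
        h = _lrelu(X @ p["W1"] + p["b1"], s.leaky_slope)
        return h @ p["W2"] + p["b2"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(X), axis=-1)

    def _loss_grads(self, X, y):
        p, s = self.params, self.spec
        a1 = X @ p["W1"] + p["b1"]
        h = _lrelu(a1, s.leaky_slope)
        logits = h @ p["W2"] + p["b2"]
        q = _softmax(logits)
        n = X.shape[0]
        loss = -float(np.mean(np.log(q[np.arange(n), y] + 1e-30)))
        dl = q.copy()
        dl[np.arange(n), y] -= 1.0
        dl /= n
        grads = {
            "W2": h.T @ dl, "b2": dl.sum(0),
        }
        dh = dl @ p["W2"].T * _lrelu_grad(a1, s.leaky_slope)
        grads["W1"] = X.T @ dh
        grads["b1"] = dh.sum(0)
        return loss, grads


def train_classifier(
    train_data,
    spec: ClassifierSpec,
    cfg: TrainConfig,
    test_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainResult:
    """Train the classifier with cross-entropy loss.

    ``train_data`` is either ``(X, y)`` arrays (y as integer class codes)
    or any batch source with ``draw(n, rng) -> (X, y)``, e.g. a
    :class:`SamplingBatcher` emitting fresh replicate draws.  The trace
    records the training loss, post-clip gradient norm and (when a test
    set is given) the held-out loss every ``cfg.eval_every`` iterations.
    """
    iters = cfg.iterations if cfg.iterations is not None else DEFAULT_ITERATIONS
    lr = cfg.learning_rate if cfg.learning_rate is not None else DEFAULT_LR_CLASSIFIER
    rng = np.random.default_rng(cfg.seed)
    batcher = _as_batcher(train_data)
    model = Classifier(spec, seed=cfg.seed)
    opt = _Adam(model.params, lr)
    trace = {"iteration": [], "loss": [], "grad_norm": []}
    if test_data is not None:
        trace["eval_loss"] = []

    for it in range(iters):
        X, y = batcher.draw(cfg.batch_size, rng)
        loss, grads = model._loss_grads(X, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        gnorm = _clip_global(grads, cfg.gradient_clip)
        opt.step(model.params, grads)
        if it % cfg.eval_every == 0:
            trace["iteration"].append(it)
            trace["loss"].append(loss)
            trace["grad_norm"].append(gnorm)
            if test_data is not None:
                Xt, yt = test_data
                lt, _ = model._loss_grads(np.asarray(Xt, dtype=float), np.asarray(yt))
                trace["eval_loss"].append(lt)

    result = TrainResult(model=model, trace=trace)
    if hasattr(batcher, "X") and batcher.y is not None:
        pred = model.predict(batcher.X)
        result.train_report = classification_metrics(batcher.y, pred, split="train")
    if test_data is not None:
        Xt, yt = test_data
        result.test_report = classification_metrics(
            np.asarray(yt), model.predict(np.asarray(Xt, dtype=float)), split="test"
        )
    return result


# ---------------------------------------------------------------------------
# (joint) variational autoencoder
# ---------------------------------------------------------------------------

class JointVAE:
    """VAE (continuous latent) or JVAE (continuous + discrete latent).

    The encoder output splits into mean and log-variance encodings (and
    logit encodings when ``n_discrete > 0``); the decoder consumes the
    concatenated latent sample.  Deterministic encodings (``mu``,
    ``softmax(logits)``) are used for evaluation and traversal decoding.
    """

    def __init__(self, n_inputs: int, latent: LatentSpec, seed: int = 0):
        self.n_inputs = n_inputs
        self.latent = latent
        rng = np.random.default_rng(seed)
        nC, nD, H = latent.n_continuous, latent.n_discrete, latent.n_hidden
        nL = nC + nD
        p = {
            "We1": _he(rng, n_inputs, H), "be1": np.zeros(H),
            "Wd1": _he(rng, nL, H), "bd1": np.zeros(H),
            "Wd2": _he(rng, H, n_inputs), "bd2": np.zeros(n_inputs),
        }
        if nC > 0:
            p["Wmu"] = _he(rng, H, nC); p["bmu"] = np.zeros(nC)
            p["Wlv"] = _he(rng, H, nC); p["blv"] = np.zeros(nC)
        if nD > 0:
            p["Wlg"] = _he(rng, H, nD); p["blg"] = np.zeros(nD)
        self.params = p

    # -- deterministic paths -------------------------------------------------
    def encode(self, X: np.ndarray):
        p, s = self.params, self.latent
        h = _lrelu(X @ p["We1"] + p["be1"], s.leaky_slope)
        mu = h @ p["Wmu"] + p["bmu"] if s.n_continuous else np.zeros((X.shape[0], 0))
        lv = h @ p["Wlv"] + p["blv"] if s.n_continuous else np.zeros((X.shape[0], 0))
        lg = h @ p["Wlg"] + p["blg"] if s.n_discrete else np.zeros((X.shape[0], 0))
        return mu, lv, lg

    def decode(self, z: np.ndarray) -> np.ndarray:
        p, s = self.params, self.latent
        z = np.atleast_2d(np.asarray(z, dtype=float))
        h = _lrelu(z @ p["Wd1"] + p["bd1"], s.leaky_slope)
        return h @ p["Wd2"] + p["bd2"]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction through the mean latent encoding."""
        mu, _, lg = self.encode(np.asarray(X, dtype=float))
        parts = [mu] + ([_softmax(lg)] if self.latent.n_discrete else [])
        return self.decode(np.concatenate(parts, axis=1))

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        if not self.latent.n_discrete:
            raise ValueError("no discrete latent nodes to classify with")
        _, _, lg = self.encode(np.asarray(X, dtype=float))
        return np.argmax(lg, axis=-1)

    # -- training step -------------------------------------------------------
    def _step(self, X, y, beta, cfg: TrainConfig, loss_kind: str, rng, apply_ce: bool):
        p, s = self.params, self.latent
        nC, nD = s.n_continuous, s.n_discrete
        B = X.shape[0]
        slope = s.leaky_slope
        T = cfg.concrete_temperature

        # encoder forward
        ae = X @ p["We1"] + p["be1"]
        he = _lrelu(ae, slope)
        mu = he @ p["Wmu"] + p["bmu"] if nC else np.zeros((B, 0))
        lv = he @ p["Wlv"] + p["blv"] if nC else np.zeros((B, 0))
        lg = he @ p["Wlg"] + p["blg"] if nD else np.zeros((B, 0))

        # latent samples
        if nC:
            eps = rng.standard_normal(mu.shape)
            std = np.exp(lv / 2.0)
            zc = mu + std * eps
        else:
            zc = mu
        if nD:
            u = rng.random(lg.shape)
            gumbel = -np.log(-np.log(u + 1e-30) + 1e-30)
            zd = _softmax((lg + gumbel) / T)
            z = np.concatenate([zc, zd], axis=1)
        else:
            z = zc

        # decoder forward
        ad = z @ p["Wd1"] + p["bd1"]
        hd = _lrelu(ad, slope)
        xhat = hd @ p["Wd2"] + p["bd2"]

        # losses
        diff = xhat - X
        D = X.shape[1]
        if loss_kind == "MSE":
            recon = float(np.mean(diff**2))
            dxhat = 2.0 * diff / (B * D)
        elif loss_kind == "MAE":
            recon = float(np.mean(np.abs(diff)))
            dxhat = np.sign(diff) / (B * D)
        elif loss_kind == "MAPE":
            w = 100.0 / (np.abs(X) + 1e-9)
            recon = float(np.mean(np.abs(diff) * w))
            dxhat = np.sign(diff) * w / (B * D)
        else:
            raise ValueError(f"unknown loss kind {loss_kind!r}")

        klc = float(-0.5 * np.sum(1 + lv - mu**2 - np.exp(lv)) / B) if nC else 0.0
        if nD:
            q = _softmax(lg)
            a = np.log(q + 1e-30) + np.log(nD)
            kld = float(np.sum(q * a) / B)
        else:
            kld = 0.0

        ce = 0.0
        if apply_ce and nD:
            qce = _softmax(lg)
            ce = -float(np.mean(np.log(qce[np.arange(B), y] + 1e-30)))

        loss = recon + beta * (klc + kld) + cfg.classification_loss_weight * ce

        # ---- backward ----
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dhd = dxhat @ p["Wd2"].T
        grads["Wd2"] = hd.T @ dxhat
        grads["bd2"] = dxhat.sum(0)
        dad = dhd * _lrelu_grad(ad, slope)
        grads["Wd1"] = z.T @ dad
        grads["bd1"] = dad.sum(0)
        dz = dad @ p["Wd1"].T
        dzc, dzd = dz[:, :nC], dz[:, nC:]

        dmu = np.zeros_like(mu)
        dlv = np.zeros_like(lv)
        dlg = np.zeros_like(lg)
        if nC:
            dmu += dzc
            dlv += dzc * 0.5 * std * eps
            dmu += beta * mu / B
            dlv += beta * 0.5 * (np.exp(lv) - 1.0) / B
        if nD:
            # concrete reparameterization: z_d = softmax(u), du = J_softmax^T dz_d
            dot = (dzd * zd).sum(axis=1, keepdims=True)
            dlg += zd * (dzd - dot) / T
            # categorical KL to uniform
            qa = (q * a).sum(axis=1, keepdims=True)
            dlg += beta * q * (a - qa) / B
            if apply_ce:
                dce = qce.copy()
                dce[np.arange(B), y] -= 1.0
                dlg += cfg.classification_loss_weight * dce / B

        dhe = np.zeros_like(he)
        if nC:
            grads["Wmu"] = he.T @ dmu
            grads["bmu"] = dmu.sum(0)
            grads["Wlv"] = he.T @ dlv
            grads["blv"] = dlv.sum(0)
            dhe += dmu @ p["Wmu"].T + dlv @ p["Wlv"].T
        if nD:
            grads["Wlg"] = he.T @ dlg
            grads["blg"] = dlg.sum(0)
            dhe += dlg @ p["Wlg"].T
        dae = dhe * _lrelu_grad(ae, slope)
        grads["We1"] = X.T @ dae
        grads["be1"] = dae.sum(0)

        parts = {"recon": recon, "kl_continuous": klc, "kl_discrete": kld, "xentropy": ce}
        return loss, grads, parts


def train_reconstruction(
    train_data,
    latent_spec: LatentSpec,
    cfg: TrainConfig,
    loss_kind: str = "MSE",
    supervision: str = "none",
    test_data: tuple[np.ndarray, np.ndarray | None] | None = None,
    n_classes: int | None = None,
) -> TrainResult:
    """Train a VAE/JVAE for reconstruction, optionally with supervision.

    The optimized objective is ``reconstruction + beta(t) * KL`` with the
    linear beta ramp, plus — for ``supervision`` "full" or "semi" — a
    cross-entropy loss on the discrete logits applied per batch with
    probability 1 or ``cfg.supervision_fraction``.  When supervised, the
    number of discrete nodes must equal the number of class labels.

    ``train_data`` is ``(X, y)`` (y may be ``None`` when unsupervised) or a
    batch source; ``test_data`` an optional held-out ``(X, y)``.  Returns
    the trained model, the training trace (loss components, post-clip
    gradient norm, cross-entropy application count) and final similarity /
    classification reports.
    """
    if supervision not in ("none", "semi", "full"):
        raise ValueError("supervision must be 'none', 'semi' or 'full'")
    if supervision != "none":
        if latent_spec.n_discrete == 0:
            raise ValueError("supervised training requires discrete latent nodes")
        if n_classes is not None and latent_spec.n_discrete != n_classes:
            raise ValueError(
                f"supervised training requires n_discrete ({latent_spec.n_discrete}) "
                f"to equal the number of class labels ({n_classes})"
            )
    frac = {"none": 0.0, "full": 1.0}.get(supervision, cfg.supervision_fraction)
    iters = cfg.iterations
    if iters is None:
        iters = DEFAULT_ITERATIONS_SEMI if supervision == "semi" else DEFAULT_ITERATIONS
    lr = cfg.learning_rate if cfg.learning_rate is not None else DEFAULT_LR_RECONSTRUCTION

    rng = np.random.default_rng(cfg.seed)
    batcher = _as_batcher(train_data)
    probe, _ = batcher.draw(1, np.random.default_rng(cfg.seed))
    model = JointVAE(probe.shape[1], latent_spec, seed=cfg.seed)
    opt = _Adam(model.params, lr)
    trace = {
        "iteration": [], "loss": [], "recon": [], "kl_continuous": [],
        "kl_discrete": [], "xentropy": [], "grad_norm": [], "beta": [],
    }
    if test_data is not None:
        trace["eval_loss"] = []
    ce_applied = 0

    for it in range(iters):
        X, y = batcher.draw(cfg.batch_size, rng)
        beta = beta_schedule(it, cfg.beta_ramp_iters, cfg.beta_max)
        apply_ce = frac > 0 and y is not None and rng.random() < frac
        if apply_ce:
            ce_applied += 1
        loss, grads, parts = model._step(X, y, beta, cfg, loss_kind, rng, apply_ce)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        gnorm = _clip_global(grads, cfg.gradient_clip)
        opt.step(model.params, grads)
        if it % cfg.eval_every == 0:
            trace["iteration"].append(it)
            trace["loss"].append(loss)
            trace["grad_norm"].append(gnorm)
            trace["beta"].append(beta)
            for k, v in parts.items():
                trace[k].append(v)
            if test_data is not None:
                Xt = np.asarray(test_data[0], dtype=float)
                trace["eval_loss"].append(
                    reconstruction_loss(model.reconstruct(Xt), Xt, loss_kind)
                )

    trace["ce_applied_total"] = [ce_applied]
    result = TrainResult(model=model, trace=trace)
    if hasattr(batcher, "X"):
        Xtr = batcher.X
        result.train_report = mean_similarity_report(model.reconstruct(Xtr), Xtr, split="train")
    if test_data is not None:
        Xt = np.asarray(test_data[0], dtype=float)
        result.test_report = mean_similarity_report(model.reconstruct(Xt), Xt, split="test")
        yt = test_data[1]
        if supervision != "none" and yt is not None:
            cls = classification_metrics(np.asarray(yt), model.predict_labels(Xt), split="test")
            result.test_report.values.update(cls.values)
    return result
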