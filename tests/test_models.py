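"""Network initialization, schedules, reparameterization and training loops."""

import numpy as np
import pytest

import metabodl as m
from metabodl.models import JointVAE, _clip_global


# ---------------------------------------------------------------------------
# initialization and schedules
# ---------------------------------------------------------------------------

def test_he_init_deterministic_and_zero_biases():
    spec = m.ClassifierSpec(n_inputs=10, n_outputs=3)
    a = m.init_network(spec, seed=4)
    b = m.init_network(spec, seed=4)
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])
    assert np.all(a["b1"] == 0) and np.all(a["b2"] == 0)


def test_he_init_variance_matches_fan_in():
    spec = m.ClassifierSpec(n_inputs=100, n_outputs=100)
    params = m.init_network(spec, seed=0)
    var = params["W1"].var()
    assert abs(var - 2 / 100) < 0.2 * 2 / 100


@pytest.mark.parametrize("it, expected", [(0, 0.0), (12_500, 0.5), (25_000, 1.0), (50_000, 1.0)])
def test_beta_ramp(it, expected):
    assert m.beta_schedule(it, 25_000) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# reparameterization
# ---------------------------------------------------------------------------

def test_gaussian_reparam_zero_variance_limit(rng):
    mu = np.array([1.5, -2.0])
    z = m.reparameterize_gaussian(mu, np.full(2, -1e10), rng)
    np.testing.assert_allclose(z, mu)


def test_gaussian_reparam_moments():
    rng = np.random.default_rng(0)
    z = np.array([m.reparameterize_gaussian([0.0], [0.0], rng)[0] for _ in range(5000)])
    assert abs(z.mean()) < 0.05 and abs(z.std() - 1.0) < 0.05


def test_concrete_sums_to_one(rng):
    z = m.reparameterize_concrete(rng.normal(0, 1, (30, 5)), 0.5, rng)
    np.testing.assert_allclose(z.sum(axis=-1), 1.0, atol=1e-12)
    assert np.all(z > 0)


def test_concrete_low_temperature_approaches_one_hot():
    logits = np.array([0.1, 2.0, -1.0])
    rng_a = np.random.default_rng(5)
    rng_b = np.random.default_rng(5)
    soft = m.reparameterize_concrete(logits, 1.0, rng_a)
    hard = m.reparameterize_concrete(logits, 1e-3, rng_b)  # same Gumbel noise
    assert hard[np.argmax(soft)] == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# classifier training
# ---------------------------------------------------------------------------

def _blobs(rng, n_per=60, p=20, sep=3.0):
    X = np.vstack([rng.normal(0, 1, (n_per, p)), rng.normal(sep, 1, (n_per, p))])
    y = np.repeat([0, 1], n_per)
    idx = rng.permutation(len(y))
    return X[idx], y[idx]


def test_classifier_learns_separable_blobs():
    rng = np.random.default_rng(0)
    X, y = _blobs(rng)
    cfg = m.TrainConfig(iterations=5000, seed=0)
    res = m.train_classifier((X[:80], y[:80]), m.ClassifierSpec(20, 2), cfg,
                             test_data=(X[80:], y[80:]))
    assert res.test_report["AccuracyMCMicro"] >= 0.95


def test_classifier_at_chance_on_permuted_labels():
    rng = np.random.default_rng(1)
    X, y = _blobs(rng)
    y_perm = rng.permutation(y)
    cfg = m.TrainConfig(iterations=3000, seed=0)
    res = m.train_classifier((X[:80], y_perm[:80]), m.ClassifierSpec(20, 2), cfg,
                             test_data=(X[80:], y_perm[80:]))
    assert abs(res.test_report["AccuracyMCMicro"] - 0.5) <= 0.2


def test_zero_iterations_gives_untrained_network_empty_trace(rng):
    X, y = _blobs(rng, n_per=10)
    cfg = m.TrainConfig(iterations=0, seed=0)
    res = m.train_classifier((X, y), m.ClassifierSpec(20, 2), cfg)
    assert res.trace["iteration"] == []
    init = m.init_network(m.ClassifierSpec(20, 2), seed=0)
    np.testing.assert_array_equal(res.model.params["W1"], init["W1"])


def test_gradient_clipping_bounds_norm():
    grads = {"a": np.full(100, 5.0), "b": np.full(100, -5.0)}
    norm = _clip_global(grads, 10.0)
    assert norm == pytest.approx(10.0)
    total = np.sqrt(sum(np.sum(g * g) for g in grads.values()))
    assert total == pytest.approx(10.0)


def test_trace_gradient_norms_never_exceed_clip():
    rng = np.random.default_rng(2)
    X, y = _blobs(rng, n_per=20)
    cfg = m.TrainConfig(iterations=500, seed=0, eval_every=10)
    res = m.train_classifier((X, y * 0 + rng.integers(0, 2, len(y))),
                             m.ClassifierSpec(20, 2), cfg)
    assert max(res.trace["grad_norm"]) <= 10.0 + 1e-9


def test_training_is_bit_deterministic():
    rng = np.random.default_rng(3)
    X, y = _blobs(rng, n_per=15)
    cfg = m.TrainConfig(iterations=400, seed=11)
    a = m.train_classifier((X, y), m.ClassifierSpec(20, 2), cfg)
    b = m.train_classifier((X, y), m.ClassifierSpec(20, 2), cfg)
    assert a.trace["loss"] == b.trace["loss"]
    for k in a.model.params:
        np.testing.assert_array_equal(a.model.params[k], b.model.params[k])


def test_non_finite_loss_aborts():
    X = np.full((10, 4), 1e308)  # overflows the first matmul -> NaN loss
    y = np.zeros(10, dtype=int)
    cfg = m.TrainConfig(iterations=50, seed=0)
    with pytest.raises(FloatingPointError):
        m.train_classifier((X, y), m.ClassifierSpec(4, 2), cfg)


# ---------------------------------------------------------------------------
# reconstruction training
# ---------------------------------------------------------------------------

def _vae_data(rng, n=120, p=8):
    t = rng.random(n)  # one latent factor
    X = np.outer(t, rng.random(p)) + 0.02 * rng.normal(0, 1, (n, p))
    return np.clip(X, 0, 1)


def test_vae_improves_over_untrained_reconstruction():
    rng = np.random.default_rng(4)
    X = _vae_data(rng)
    spec = m.LatentSpec(n_continuous=1)
    cfg = m.TrainConfig(iterations=20_000, seed=0, learning_rate=1e-3, beta_max=0.0)
    res = m.train_reconstruction((X, None), spec, cfg, loss_kind="MSE",
                                 test_data=(X, None))
    untrained = JointVAE(X.shape[1], spec, seed=0)
    d0 = np.linalg.norm(untrained.reconstruct(X) - X, axis=1).mean()
    d1 = np.linalg.norm(res.model.reconstruct(X) - X, axis=1).mean()
    assert d1 * 10 <= d0


def test_vae_loss_decreases_with_beta_zero():
    rng = np.random.default_rng(5)
    X = _vae_data(rng, n=60)
    cfg = m.TrainConfig(iterations=4000, seed=0, learning_rate=1e-3, beta_max=0.0)
    res = m.train_reconstruction((X, None), m.LatentSpec(1), cfg)
    losses = np.array(res.trace["loss"])
    smoothed = np.convolve(losses, np.ones(5) / 5, mode="valid")
    assert smoothed[-1] < smoothed[0]


@pytest.mark.parametrize("supervision, expected", [("none", 0), ("full", None)])
def test_supervision_fraction_controls_ce_applications(supervision, expected, rng):
    X = np.clip(rng.random((30, 6)), 0, 1)
    y = rng.integers(0, 3, 30)
    cfg = m.TrainConfig(iterations=200, seed=0)
    res = m.train_reconstruction((X, y), m.LatentSpec(1, 3), cfg,
                                 supervision=supervision, n_classes=3)
    count = res.trace["ce_applied_total"][0]
    assert count == (200 if expected is None else 0)


def test_supervision_requires_matching_discrete_nodes(rng):
    X = rng.random((10, 4))
    y = rng.integers(0, 3, 10)
    with pytest.raises(ValueError, match="equal the number of class labels"):
        m.train_reconstruction((X, y), m.LatentSpec(1, 4),
                               m.TrainConfig(iterations=10), supervision="full", n_classes=3)
    with pytest.raises(ValueError, match="discrete"):
        m.train_reconstruction((X, y), m.LatentSpec(2, 0),
                               m.TrainConfig(iterations=10), supervision="full", n_classes=3)


def test_supervised_jvae_recovers_labels():
    """With class-matched discrete nodes and full supervision the discrete
    argmax must recover labels on well-separated 3-class data."""
    rng = np.random.default_rng(6)
    centers = np.array([[0.1] * 10, [0.5] * 10, [0.9] * 10])
    X = np.vstack([rng.normal(c, 0.05, (40, 10)) for c in centers])
    y = np.repeat([0, 1, 2], 40)
    cfg = m.TrainConfig(iterations=30_000, seed=0)
    res = m.train_reconstruction((X, y), m.LatentSpec(1, 3), cfg,
                                 supervision="full", test_data=(X, y), n_classes=3)
    acc = np.mean(res.model.predict_labels(X) == y)
    assert acc >= 0.9


def test_reconstruction_training_deterministic(rng):
    X = np.clip(rng.random((40, 5)), 0, 1)
    cfg = m.TrainConfig(iterations=300, seed=21)
    a = m.train_reconstruction((X, None), m.LatentSpec(2, 2), cfg)
    b = m.train_reconstruction((X, None), m.LatentSpec(2, 2), cfg)
    assert a.trace["loss"] == b.trace["loss"]
    for k in a.model.params:
        np.testing.assert_array_equal(a.model.params[k], b.model.params[k])


def test_iterations_to_min_loss_uses_eval_cadence(rng):
    X, y = _blobs(rng, n_per=15)
    cfg = m.TrainConfig(iterations=1000, seed=0, eval_every=100)
    res = m.train_classifier((X, y), m.ClassifierSpec(20, 2), cfg, test_data=(X, y))
    assert res.iterations_to_min_loss % 100 == 0
    assert 0 <= res.iterations_to_min_loss < 1000
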