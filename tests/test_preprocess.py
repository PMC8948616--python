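"""Biomass normalization, imputation, replicate sampling and transforms."""

import numpy as np
import pytest
from scipy import stats

import metabodl as m
from metabodl.preprocess import EPSILON, ReplicateSampler, TransformState

from conftest import random_table


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

def test_biomass_normalize_divides_and_preserves_missingness(small_table):
    out = m.biomass_normalize(small_table)
    assert out.values[1, 0] == pytest.approx(2.0 / 2.0)
    assert out.values[0, 1] == pytest.approx(10.0 / 1.0)
    assert np.isnan(out.values[1, 1]) and np.isnan(out.values[3, 2])
    assert out.n_missing == small_table.n_missing


def test_biomass_one_is_identity(small_table):
    table = small_table
    table.biomass[:] = 1.0
    out = m.biomass_normalize(table)
    np.testing.assert_array_equal(out.values, table.values)


def test_biomass_missing_is_hard_error(rng):
    table = random_table(rng)
    table.biomass = None
    with pytest.raises(ValueError, match="biomass"):
        m.biomass_normalize(table)


# ---------------------------------------------------------------------------
# fill imputation
# ---------------------------------------------------------------------------

def test_zero_fill(small_table):
    out = m.impute_fill(small_table, "zero")
    assert out.n_missing == 0
    assert out.values[1, 1] == 0.0
    assert out.values[0, 0] == 1.0  # observed values untouched


def test_mean_fill_uses_replicate_group_mean():
    table = m.FeatureTable(
        sample_ids=["a", "b", "c"], feature_ids=["f"],
        values=np.array([[1.0], [np.nan], [3.0]]),
        labels=["x", "x", "x"], replicate_group=["g", "g", "g"],
    )
    out = m.impute_fill(table, "mean")
    assert out.values[1, 0] == pytest.approx(2.0)


def test_fill_identity_when_complete(rng):
    table = random_table(rng, missing=0.0)
    for method in ("zero", "mean"):
        np.testing.assert_array_equal(m.impute_fill(table, method).values, table.values)


def test_mean_fill_falls_back_to_global_mean_with_warning():
    table = m.FeatureTable(
        sample_ids=["a", "b", "c"], feature_ids=["f"],
        values=np.array([[np.nan], [np.nan], [6.0]]),
        labels=["x", "x", "y"], replicate_group=["g1", "g1", "g2"],
    )
    with pytest.warns(UserWarning, match="global"):
        out = m.impute_fill(table, "mean")
    assert out.values[0, 0] == pytest.approx(6.0)


# ---------------------------------------------------------------------------
# EM imputation
# ---------------------------------------------------------------------------

def _lognormal_bivariate(rng, n=200, rho=0.9):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    Z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return np.exp(Z)


def test_em_beats_mean_fill_on_correlated_data():
    """Conditional-mean imputation exploits the rho=0.9 correlation that
    group-mean filling ignores, so its error must be lower on MCAR holes."""
    rng = np.random.default_rng(42)
    X = _lognormal_bivariate(rng)
    mask = rng.random(X.shape) < 0.10
    mask[0] = False  # keep at least one fully observed row
    table = m.FeatureTable(
        sample_ids=[f"s{i}" for i in range(len(X))], feature_ids=["f1", "f2"],
        values=np.where(mask, np.nan, X),
        labels=["l"] * len(X), replicate_group=["g"] * len(X),
    )
    em = m.impute_em(table, m=5, seed=0)
    mean = m.impute_fill(table, "mean")
    rmse_em = np.sqrt(np.mean((np.log(em.values[mask]) - np.log(X[mask])) ** 2))
    rmse_mean = np.sqrt(np.mean((np.log(mean.values[mask]) - np.log(X[mask])) ** 2))
    assert rmse_em < rmse_mean


def test_em_identity_without_missing(rng):
    table = random_table(rng, missing=0.0)
    np.testing.assert_array_equal(m.impute_em(table, seed=1).values, table.values)


def test_em_deterministic_given_seed(rng):
    table = random_table(rng, n=30, p=3, missing=0.15)
    a = m.impute_em(table, m=3, seed=7).values
    b = m.impute_em(table, m=3, seed=7).values
    np.testing.assert_array_equal(a, b)
    c = m.impute_em(table, m=1, seed=7).values
    hole = np.isnan(table.values)
    assert not np.array_equal(a[hole], c[hole])  # m changes the average
    np.testing.assert_array_equal(a[~hole], c[~hole])


def test_em_rejects_fully_missing_feature():
    table = m.FeatureTable(
        sample_ids=["a", "b"], feature_ids=["f1", "f2"],
        values=np.array([[1.0, np.nan], [2.0, np.nan]]),
        labels=["x", "x"], replicate_group=["g", "g"],
    )
    with pytest.raises(ValueError, match="zero observed"):
        m.impute_em(table, seed=0)


# ---------------------------------------------------------------------------
# replicate sampling
# ---------------------------------------------------------------------------

def test_sampler_values_come_from_pool(small_table):
    s = ReplicateSampler(small_table, rng=0)
    draws = s.draw_batch(["ga"] * 50)
    assert set(draws[:, 0]) <= {1.0, 2.0}
    assert set(draws[:, 1]) == {10.0}  # single observed value -> always 10.0


def test_sampler_empty_pool_is_construction_error():
    table = m.FeatureTable(
        sample_ids=["a", "b"], feature_ids=["f"],
        values=np.array([[np.nan], [np.nan]]),
        labels=["x", "y"], replicate_group=["g1", "g2"],
    )
    with pytest.raises(ValueError, match="no observed value"):
        ReplicateSampler(table)


def test_sampler_mean_converges_to_pool_mean():
    table = m.FeatureTable(
        sample_ids=["a", "b"], feature_ids=["f"],
        values=np.array([[0.0], [1.0]]),
        labels=["x", "x"], replicate_group=["g", "g"],
    )
    s = ReplicateSampler(table, rng=3)
    draws = s.draw_batch(["g"] * 10_000)
    assert abs(draws.mean() - 0.5) < 0.02


def test_sampler_reproducible_and_uniform(small_table):
    a = ReplicateSampler(small_table, rng=9).draw_batch(["gb"] * 100)
    b = ReplicateSampler(small_table, rng=9).draw_batch(["gb"] * 100)
    np.testing.assert_array_equal(a, b)

    # chi-square goodness of fit of the marginal against the uniform pool
    table = m.FeatureTable(
        sample_ids=list("abc"), feature_ids=["f"],
        values=np.array([[1.0], [2.0], [3.0]]),
        labels=["x"] * 3, replicate_group=["g"] * 3,
    )
    draws = ReplicateSampler(table, rng=11).draw_batch(["g"] * 10_000)[:, 0]
    counts = [np.sum(draws == v) for v in (1.0, 2.0, 3.0)]
    assert stats.chisquare(counts).pvalue > 0.01


# ---------------------------------------------------------------------------
# transformation catalog
# ---------------------------------------------------------------------------

def test_proj_fixture():
    st = m.fit_transform(np.array([[2.0], [4.0], [6.0]]), "Proj", "Off")
    assert st.feat_min[0] == 2 and st.feat_max[0] == 6
    out = m.apply_transform(np.array([[2.0], [4.0], [6.0]]), st)
    np.testing.assert_allclose(out.ravel(), [0, 0.5, 1])


def test_stand_population_convention():
    st = m.fit_transform(np.array([[1.0], [3.0]]), "StandProj", "Off")
    assert st.feat_mean[0] == pytest.approx(2.0)
    assert st.feat_std[0] == pytest.approx(1.0)  # population (n) std


def test_fclog_identities(small_table):
    ref = 5.0
    train = m.FeatureTable(
        sample_ids=["a", "b"], feature_ids=["f"],
        values=np.array([[ref], [ref]]),
        labels=["ctl", "ctl"], replicate_group=["ctl", "ctl"],
    )
    st = m.fit_transform(train, "FCLog", "Off", base=100, control_group="ctl")
    assert st.control_ref[0] == pytest.approx(5.0)
    x = np.array([[ref], [100 * ref], [10_000 * ref]])
    np.testing.assert_allclose(m.apply_transform(x, st).ravel(), [0.0, 1.0, 1.0], atol=1e-8)

    st10 = m.fit_transform(train, "FCLog", "Off", base=10, control_group="ctl")
    assert m.apply_transform(np.array([[ref / 10]]), st10)[0, 0] == pytest.approx(-1.0, abs=1e-7)


def test_fclog_requires_control_group(small_table):
    with pytest.raises(ValueError, match="control"):
        m.fit_transform(m.impute_fill(small_table, "zero"), "FCLog", "Off", base=10)


def test_constant_feature_projects_to_half():
    st = m.fit_transform(np.array([[3.0], [3.0]]), "Proj", "Off")
    assert m.apply_transform(np.array([[3.0]]), st)[0, 0] == 0.5


@pytest.mark.parametrize("method", ["Proj", "LogTransProj", "StandProj", "LogTransStandProj"])
@pytest.mark.parametrize("mode", ["On", "Off"])
def test_proj_family_outputs_in_unit_interval(rng, method, mode):
    train = np.exp(rng.normal(0, 2, (12, 6)))
    test = np.exp(rng.normal(0, 2, (8, 6)))
    st = m.fit_transform(train, method, mode)
    out = m.apply_transform(test, st)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_fclog_outputs_in_clip_interval(rng):
    table = random_table(rng, n=10, p=5)
    st = m.fit_transform(table, "FCLog", "Off", base=10, control_group="g0")
    out = m.apply_transform(np.exp(rng.normal(0, 4, (20, 5))), st)
    assert out.min() >= -1.0 and out.max() <= 1.0


@pytest.mark.parametrize("method, base", [
    ("None", 10), ("Proj", 10), ("LogTransProj", 10),
    ("StandProj", 10), ("LogTransStandProj", 10), ("FCLog", 10),
])
def test_off_transforms_are_monotone_per_feature(rng, method, base):
    table = random_table(rng, n=12, p=4)
    st = m.fit_transform(table, method, "Off", base=base, control_group="g0")
    lo = np.exp(rng.normal(0, 1, (6, 4)))
    hi = lo * (1 + rng.random((6, 4)))
    assert np.all(m.apply_transform(hi, st) >= m.apply_transform(lo, st) - 1e-12)


def test_biomass_cancels_in_fold_change(rng):
    """Sample and control sharing one biomass factor leave FCLog unchanged:
    the fold change absorbs culture-amount differences exactly."""
    table = random_table(rng, n=8, p=3)
    st = m.fit_transform(table, "FCLog", "Off", base=10, control_group="g0")
    x = np.exp(rng.normal(0, 1, (4, 3)))
    c = 3.7
    scaled = table.with_values(table.values * c)
    scaled.biomass = np.full(8, c)
    st_scaled = m.fit_transform(m.biomass_normalize(scaled), "FCLog", "Off",
                                base=10, control_group="g0")
    np.testing.assert_allclose(
        m.apply_transform(x, st), m.apply_transform(x, st_scaled), rtol=1e-6
    )


def test_transform_state_round_trips_through_json(tmp_path, rng):
    table = random_table(rng, n=10, p=3)
    st = m.fit_transform(table, "LogTransStandProj", "Off")
    path = tmp_path / "state.json"
    st.to_json(path)
    back = TransformState.from_json(path)
    x = np.exp(rng.normal(0, 1, (5, 3)))
    np.testing.assert_array_equal(m.apply_transform(x, st), m.apply_transform(x, back))


def test_fit_rejects_missing_values(small_table):
    with pytest.raises(ValueError, match="missing"):
        m.fit_transform(small_table, "Proj", "Off")
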