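"""ST-GPR stages: model enumeration, mixed-effects fitting, ensemble
weights, space-time smoothing weights, GP conditioning and draw sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import delivloc as dl
from delivloc.stgpr import (
    STGPRConfig,
    amplitude_estimate,
    fit_linear_mixed,
    holdout_rmse,
    matern52,
    sample_draws,
    substream,
)


# ---------------------------------------------------------------- ensemble


def test_enumerate_models_counts():
    assert len(dl.enumerate_models(["a", "b", "c"], 3)) == 8
    assert len(dl.enumerate_models(["a"], 1)) == 2
    specs = dl.enumerate_models(["a", "b", "c", "d"], 2)
    assert len(specs) == 11
    assert specs[0] == ()
    assert specs == dl.enumerate_models(["d", "c", "b", "a"], 2)  # deterministic


def _fake_data(hierarchy, rng, beta=(2.0, 3.0), sigma=0.0, region_sd=0.0, n_per=10):
    rows = []
    for _, loc in hierarchy.locations.iterrows():
        u_reg = rng.normal(0, region_sd) if region_sd else 0.0
        for i in range(n_per):
            x = rng.normal()
            rows.append(
                {
                    "location_id": loc["location_id"],
                    "region_id": loc["region_id"],
                    "super_region_id": loc["super_region_id"],
                    "source_id": f"{loc['location_id']}_{i % 3}",
                    "year": 2000 + i,
                    "x": x,
                    "y": beta[0] + beta[1] * x + u_reg + rng.normal(0, sigma),
                }
            )
    return pd.DataFrame(rows)


def test_mixed_model_noiseless_recovery(small_hierarchy):
    data = _fake_data(small_hierarchy, np.random.default_rng(0))
    model = fit_linear_mixed(("x",), data, small_hierarchy)
    assert model.fe_params["Intercept"] == pytest.approx(2.0, abs=1e-5)
    assert model.fe_params["x"] == pytest.approx(3.0, abs=1e-5)
    pred = model.predict(data)
    assert np.allclose(pred, data["y"], atol=1e-4)


def test_mixed_model_intercept_only_constant(small_hierarchy):
    data = _fake_data(small_hierarchy, np.random.default_rng(1), beta=(4.2, 0.0))
    model = fit_linear_mixed((), data, small_hierarchy)
    grid = data.head(5)
    assert np.allclose(model.predict(grid), 4.2, atol=1e-5)


def test_mixed_model_simulated_slope_recovery(small_hierarchy):
    rng = np.random.default_rng(42)
    data = _fake_data(small_hierarchy, rng, beta=(1.0, 2.5), sigma=0.5,
                      region_sd=1.0, n_per=90)
    model = fit_linear_mixed(("x",), data, small_hierarchy)
    # 3 sd of the slope's standard error at this n is well under 0.15
    assert model.fe_params["x"] == pytest.approx(2.5, abs=0.15)


def test_mixed_model_errors(small_hierarchy):
    data = _fake_data(small_hierarchy, np.random.default_rng(2), n_per=2)
    data["x2"] = data["x"]  # collinear copy
    with pytest.raises(ValueError, match="rank"):
        fit_linear_mixed(("x", "x2"), data, small_hierarchy)
    with pytest.raises(ValueError, match="insufficient"):
        fit_linear_mixed(("x",), data.head(3), small_hierarchy)


def test_holdout_rmse_zero_for_perfect_model(small_hierarchy):
    data = _fake_data(small_hierarchy, np.random.default_rng(3))
    rmse = holdout_rmse(("x",), data, small_hierarchy, n_folds=5, seed=0)
    assert rmse == pytest.approx(0.0, abs=1e-5)


def test_holdout_rmse_approaches_sigma(small_hierarchy):
    sigma = 0.8
    data = _fake_data(small_hierarchy, np.random.default_rng(4),
                      beta=(1.0, 0.0), sigma=sigma, n_per=120)
    rmse = holdout_rmse((), data, small_hierarchy, n_folds=5, seed=0)
    assert rmse == pytest.approx(sigma, rel=0.2)


def test_ensemble_weights_values_and_properties():
    assert np.allclose(dl.ensemble_weights([1.0, 1.0]), [0.5, 0.5])
    assert np.allclose(dl.ensemble_weights([1.0, 3.0]), [0.75, 0.25])
    w = dl.ensemble_weights([0.0, 1.0, 0.0])
    assert np.allclose(w, [0.5, 0.0, 0.5])


@given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=20))
@settings(deadline=None)
def test_ensemble_weights_invariants(rmses):
    w = dl.ensemble_weights(rmses)
    assert abs(w.sum() - 1.0) < 1e-12
    order = np.argsort(rmses)
    assert np.all(np.diff(w[order]) <= 1e-12)  # anti-monotone in rmse
    perm = np.random.default_rng(0).permutation(len(rmses))
    w_perm = dl.ensemble_weights(np.asarray(rmses)[perm])
    assert np.allclose(w_perm, w[perm])


def test_stage1_predict_weighted_average(small_hierarchy):
    class Stub:
        def __init__(self, value):
            self.value = value

        def predict(self, frame):
            return np.full(len(frame), self.value)

    grid = small_hierarchy.locations.assign(year=2005)
    assert np.allclose(dl.stage1_predict([Stub(0.0), Stub(1.0)], [0.25, 0.75], grid), 0.75)
    assert np.allclose(dl.stage1_predict([Stub(0.4)], [1.0], grid), 0.4)


# ------------------------------------------------------- smoothing weights


def test_time_weight_closed_form():
    assert dl.time_weight(0, 1.0, 9) == pytest.approx(1.0)
    assert dl.time_weight(4, 1.0, 9) == pytest.approx((1 - 0.4) ** 3)
    assert dl.time_weight(9, 1.0, 9) > 0
    w = dl.time_weight(np.arange(10), 0.5, 9)
    assert np.all(np.diff(w) < 0)  # strictly decreasing


def test_space_weight_tiers(small_hierarchy):
    z = 0.9
    assert dl.space_weight("A1", "A1", z, small_hierarchy) == pytest.approx(z)
    assert dl.space_weight("A1", "A2", z, small_hierarchy) == pytest.approx(z * 0.1)
    assert dl.space_weight("A1", "B1", z, small_hierarchy) == pytest.approx(z * 0.01)
    assert dl.space_weight("A1", "C1", z, small_hierarchy) == 0.0
    with pytest.raises(KeyError):
        dl.space_weight("A1", "nope", z, small_hierarchy)


def _grid(hierarchy, years):
    return pd.DataFrame(
        [
            {"location_id": l, "year": int(y), "stage1": 0.0}
            for l in hierarchy.location_ids
            for y in years
        ]
    )


def test_stage2_no_data_returns_stage1(small_hierarchy):
    grid = _grid(small_hierarchy, range(2000, 2005))
    data = pd.DataFrame(columns=["location_id", "year", "y"])
    out = dl.stage2_smooth(grid, data, STGPRConfig(), small_hierarchy)
    assert np.allclose(out["stage2"], out["stage1"])


def test_stage2_single_datum_full_residual(small_hierarchy):
    grid = _grid(small_hierarchy, [2003])
    data = pd.DataFrame({"location_id": ["A1"], "year": [2003], "y": [0.5]})
    out = dl.stage2_smooth(grid, data, STGPRConfig(), small_hierarchy)
    row = out[(out["location_id"] == "A1") & (out["year"] == 2003)]
    assert row["stage2"].iloc[0] == pytest.approx(0.5)


def test_stage2_equal_weight_residual_mean(small_hierarchy):
    # two same-country same-year data with residuals +0.4 and 0.0
    grid = _grid(small_hierarchy, [2003])
    data = pd.DataFrame(
        {"location_id": ["A1", "A1"], "year": [2003, 2003], "y": [0.4, 0.0]}
    )
    out = dl.stage2_smooth(grid, data, STGPRConfig(), small_hierarchy)
    row = out[(out["location_id"] == "A1") & (out["year"] == 2003)]
    assert row["stage2"].iloc[0] == pytest.approx(0.2)


def test_stage2_different_super_region_untouched(small_hierarchy):
    grid = _grid(small_hierarchy, [2003])
    data = pd.DataFrame({"location_id": ["A1"], "year": [2003], "y": [1.0]})
    out = dl.stage2_smooth(grid, data, STGPRConfig(), small_hierarchy)
    c1 = out[out["location_id"] == "C1"]
    assert np.allclose(c1["stage2"], c1["stage1"])


# ------------------------------------------------------------ GP stage


def test_amplitude_estimate_properties():
    assert amplitude_estimate([0.3, 0.3, 0.3]) == pytest.approx(0.05)  # floor
    rng = np.random.default_rng(11)
    r = rng.standard_normal(10_000)
    assert amplitude_estimate(r) == pytest.approx(1.0, rel=0.05)
    big = amplitude_estimate(2 * r)
    assert big == pytest.approx(2 * amplitude_estimate(r), rel=1e-9)


def _brute_force_gp(years, prior, ty, y, v, eta, ell):
    """Independent oracle: direct dense conditioning via explicit inverse."""
    K = eta**2 * matern52(years[:, None] - years[None, :], ell)
    if len(ty) == 0:
        return prior.copy(), K
    Kdd = eta**2 * matern52(ty[:, None] - ty[None, :], ell) + np.diag(v)
    Kgd = eta**2 * matern52(years[:, None] - ty[None, :], ell)
    inv = np.linalg.inv(Kdd)
    m_at = np.interp(ty, years, prior)
    mean = prior + Kgd @ inv @ (y - m_at)
    cov = K - Kgd @ inv @ Kgd.T
    return mean, cov


def test_gp_no_data_returns_prior():
    years = np.arange(1995, 2024, dtype=float)
    prior = np.sin(years / 5.0)
    mean, cov = dl.gp_posterior(years, prior, [], [], [], eta=1.3, length_scale=5.0)
    assert np.allclose(mean, prior)
    assert np.allclose(np.diag(cov), 1.3**2)


def test_gp_interpolates_precise_datum():
    years = np.arange(2000, 2011, dtype=float)
    prior = np.zeros_like(years)
    mean, cov = dl.gp_posterior(
        years, prior, [2005.0], [0.7], [1e-10], eta=1.0, length_scale=5.0
    )
    i = 5
    assert mean[i] == pytest.approx(0.7, abs=1e-6)
    assert cov[i, i] < 1e-6


def test_gp_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    years = np.arange(1995, 2024, dtype=float)
    for _ in range(25):
        n = rng.integers(1, 21)
        ty = np.sort(rng.choice(years, size=n, replace=True))
        y = rng.normal(0, 1, n)
        v = rng.uniform(0.01, 1.0, n)
        eta = rng.uniform(0.1, 2.0)
        ell = rng.uniform(1.0, 10.0)
        prior = rng.normal(0, 1) + rng.normal(0, 0.1) * (years - 2000)
        mean, cov = dl.gp_posterior(years, prior, ty, y, v, eta, ell)
        mean_o, cov_o = _brute_force_gp(years, prior, ty, y, v, eta, ell)
        assert np.max(np.abs(mean - mean_o)) < 1e-8
        assert np.max(np.abs(cov - cov_o)) < 1e-8
        # posterior variance never exceeds the prior variance
        assert np.all(np.diag(cov) <= eta**2 + 1e-10)


def test_gp_posterior_moves_toward_new_datum():
    years = np.arange(2000, 2011, dtype=float)
    prior = np.zeros_like(years)
    base, _ = dl.gp_posterior(years, prior, [2002.0], [0.4], [0.05], 0.5, 5.0)
    more, _ = dl.gp_posterior(
        years, prior, [2002.0, 2008.0], [0.4, 1.0], [0.05, 1e-4], 0.5, 5.0
    )
    i = 8
    assert abs(more[i] - 1.0) < abs(base[i] - 1.0)


def test_sample_draws_reproducible_and_consistent():
    years = np.arange(2000, 2011, dtype=float)
    mean = np.linspace(-1, 1, len(years))
    cov = 0.04 * matern52(years[:, None] - years[None, :], 4.0)
    d1 = sample_draws(mean, cov, 50, substream(9, "draws"))
    d2 = sample_draws(mean, cov, 50, substream(9, "draws"))
    assert np.array_equal(d1, d2)
    assert d1.shape == (len(years), 50)
    assert np.all((d1 > 0) & (d1 < 1))

    # zero covariance: every draw is the (back-transformed) mean
    d0 = sample_draws(mean, np.zeros_like(cov), 7, substream(1, "x"))
    assert np.allclose(d0, dl.from_model_space(mean)[:, None])


def test_sample_draws_variance_matches_posterior():
    rng = substream(5, "mc")
    mean = np.zeros(4)
    var = np.array([0.3, 0.1, 0.05, 0.6])
    d = sample_draws(mean, np.diag(var), 100_000, rng)
    y = np.log(d / (1 - d))
    assert np.allclose(y.var(axis=1), var, rtol=0.03)


def test_substream_independence_and_determinism():
    a = substream(3, "folds").integers(0, 1000, 5)
    b = substream(3, "folds").integers(0, 1000, 5)
    c = substream(3, "draws").integers(0, 1000, 5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
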