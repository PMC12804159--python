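"""Three-stage spatiotemporal Gaussian process regression (ST-GPR).

Produces, for one indicator, a complete country-year time series with
posterior draws over the full estimation period, even where data are sparse
or absent, by borrowing strength across the location hierarchy and time:

1. **Ensemble prior** — linear mixed-effects models (nested random
   intercepts for super-region, region and location) are fit for every
   covariate subset; out-of-sample RMSE from source-level cross-validation
   weights them into an ensemble prediction.
2. **Space-time residual smoothing** — residuals between the data and the
   ensemble prediction are averaged into each country-year with weights
   that decay in time and step down across hierarchy tiers (same country,
   same region, same super-region).
3. **Gaussian process regression** — per country, a GP over years with the
   smoothed series as prior mean, a Matérn-5/2 kernel, amplitude set from
   the stage-1/stage-2 disagreement (pooled by region), and the data's
   sampling variance as noise, yields a posterior mean, covariance and
   seeded multivariate-normal draws, back-transformed to proportions.

All modelling happens on the clamped-logit scale defined in
:mod:`delivloc.prep`.
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .prep import from_model_space

logger = logging.getLogger(__name__)

__all__ = [
    "Hierarchy",
    "STGPRConfig",
    "enumerate_models",
    "fit_linear_mixed",
    "FittedMixedModel",
    "holdout_rmse",
    "ensemble_weights",
    "stage1_predict",
    "time_weight",
    "space_weight",
    "stage2_smooth",
    "amplitude_estimate",
    "matern52",
    "gp_posterior",
    "sample_draws",
    "run_stgpr",
    "substream",
]


def substream(root_seed: int, *names: str) -> np.random.Generator:
    """Named, reproducible child RNG derived from a single root seed."""
    key = tuple(
        int.from_bytes(name.encode("utf-8").ljust(4, b"\0")[:4], "little")
        for name in names
    )
    return np.random.default_rng(np.random.SeedSequence(int(root_seed), spawn_key=key))


@dataclass(frozen=True)
class Hierarchy:
    """Location hierarchy (country -> region -> super-region) plus births.

    ``locations``: DataFrame with location_id, region_id, super_region_id.
    ``births``: DataFrame with location_id, year, births (live births).
    """

    locations: pd.DataFrame
    births: pd.DataFrame

    def __post_init__(self) -> None:
        loc = self.locations
        if loc["location_id"].duplicated().any():
            raise ValueError("duplicate location_id in hierarchy")
        if loc[["region_id", "super_region_id"]].isna().any().any():
            raise ValueError("every location needs a region and super-region")
        if (self.births["births"] < 0).any():
            raise ValueError("births must be non-negative")

    @property
    def location_ids(self) -> list[str]:
        return list(self.locations["location_id"])

    def region_of(self, location_id: str) -> str:
        return self._maps()[0][location_id]

    def super_region_of(self, location_id: str) -> str:
        return self._maps()[1][location_id]

    def _maps(self):
        # tiny, rebuilt on demand; frozen dataclass keeps no cache
        reg = dict(zip(self.locations["location_id"], self.locations["region_id"]))
        sup = dict(zip(self.locations["location_id"], self.locations["super_region_id"]))
        return reg, sup


@dataclass(frozen=True)
class STGPRConfig:
    """ST-GPR hyperparameters (all exposed, defaults are package choices).

    lambda_time: exponent of the time-weight decay (larger = faster decay).
    zeta_space: share of smoothing weight kept in the same country; the
        remainder steps down by (1-zeta) per hierarchy tier.
    gp_scale_years: Matérn-5/2 length-scale in years.
    gp_amplitude_mult: multiplier on the MAD-based GP amplitude.
    amplitude_floor: minimum GP amplitude (logit scale).
    n_draws: posterior draws per location-year.
    n_folds: source-level cross-validation folds for ensemble weights.
    max_covariates: largest covariate subset in the ensemble (None = all).
    """

    lambda_time: float = 0.5
    zeta_space: float = 0.9
    gp_scale_years: float = 5.0
    gp_amplitude_mult: float = 1.0
    amplitude_floor: float = 0.05
    n_draws: int = 1000
    seed: int = 0
    n_folds: int = 10
    max_covariates: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.zeta_space < 1:
            raise ValueError("zeta_space must lie in (0, 1)")
        for name in ("lambda_time", "gp_scale_years", "gp_amplitude_mult",
                     "amplitude_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_draws < 1 or self.n_folds < 2:
            raise ValueError("need n_draws >= 1 and n_folds >= 2")


# ---------------------------------------------------------------------------
# stage 1: covariate ensemble


def enumerate_models(covariates: list[str], max_covs: int | None = None) -> list[tuple[str, ...]]:
    """All covariate subsets of size <= max_covs, plus intercept-only.

    Deterministic order: by subset size, then lexicographically; the
    intercept-only model (empty tuple) comes first.
    """
    if not covariates:
        raise ValueError("need at least one covariate")
    if len(set(covariates)) != len(covariates):
        raise ValueError("duplicate covariate names")
    names = sorted(covariates)
    k = len(names) if max_covs is None else min(max_covs, len(names))
    specs: list[tuple[str, ...]] = [()]
    for size in range(1, k + 1):
        specs.extend(itertools.combinations(names, size))
    return specs


_VC_RE = re.compile(r"C\((?:region_id|location_id)\)\[(.+?)\]")


class FittedMixedModel:
    """Linear mixed model with nested random intercepts, with prediction.

    Prediction for any location-year is fixed effects plus the sum of the
    available estimated random intercepts (super-region, region, location);
    unseen groups contribute zero.
    """

    def __init__(self, spec, fe_params, u_super, u_region, u_location):
        self.spec = tuple(spec)
        self.fe_params = fe_params  # pd.Series, index Intercept + covariates
        self.u_super = u_super
        self.u_region = u_region
        self.u_location = u_location

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        yhat = np.full(len(frame), float(self.fe_params.get("Intercept", 0.0)))
        for name in self.spec:
            yhat += float(self.fe_params[name]) * frame[name].to_numpy(dtype=float)
        yhat += np.array([self.u_super.get(s, 0.0) for s in frame["super_region_id"]])
        yhat += np.array([self.u_region.get(r, 0.0) for r in frame["region_id"]])
        yhat += np.array([self.u_location.get(l, 0.0) for l in frame["location_id"]])
        return yhat


def fit_linear_mixed(
    spec: tuple[str, ...], data: pd.DataFrame, hierarchy: Hierarchy
) -> FittedMixedModel:
    """Fit y ~ covariates with nested random intercepts.

    ``data`` carries y (model space), the covariate columns, and
    location_id/region_id/super_region_id. Raises on rank-deficient designs
    and on fewer data points than fixed effects + 2.
    """
    spec = tuple(spec)
    n, k = len(data), len(spec) + 1
    if n < k + 2:
        raise ValueError(f"insufficient data: n={n} for {k} fixed effects")
    exog = np.column_stack(
        [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in spec]
    )
    if np.linalg.matrix_rank(exog) < k:
        raise ValueError("rank-deficient design")

    df = data.copy()
    single_super = df["super_region_id"].nunique() < 2
    single_region = df["region_id"].nunique() < 2
    formula = "y ~ " + (" + ".join(spec) if spec else "1")
    vc = {}
    if not single_region:
        vc["region"] = "0 + C(region_id)"
    vc["location"] = "0 + C(location_id)"
    groups = "super_region_id" if not single_super else None

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        if groups is None:
            # one super-region: absorb it into the intercept, keep the rest
            df["_one"] = 1
            model = smf.mixedlm(formula, df, groups="_one", re_formula="0", vc_formula=vc)
        else:
            model = smf.mixedlm(formula, df, groups=groups, re_formula="1", vc_formula=vc)
        try:
            result = model.fit(reml=True, method="lbfgs", maxiter=200)
            if result.fe_params.isna().any():
                result = None
        except (np.linalg.LinAlgError, ValueError):
            result = None

    if result is None:
        # numerically singular mixed fit: fall back to the fixed-effects OLS
        # solution with zero random intercepts (poor models are then
        # down-weighted by their out-of-sample RMSE)
        logger.warning("mixed model fit failed for spec %s; using OLS fallback", spec)
        coef, *_ = np.linalg.lstsq(exog, data["y"].to_numpy(dtype=float), rcond=None)
        fe = pd.Series(coef, index=["Intercept", *spec])
        return FittedMixedModel(spec, fe, {}, {}, {})

    fe = result.fe_params
    u_super: dict[str, float] = {}
    u_region: dict[str, float] = {}
    u_location: dict[str, float] = {}
    for group, effects in result.random_effects.items():
        for name, value in effects.items():
            m = _VC_RE.search(str(name))
            if m is not None:
                target = u_region if "region_id" in str(name) else u_location
                if abs(value) > 0 or m.group(1) not in target:
                    target[m.group(1)] = target.get(m.group(1), 0.0) + float(value)
            elif groups is not None:
                u_super[group] = float(value)
    return FittedMixedModel(spec, fe, u_super, u_region, u_location)


def _fold_assignment(sources: list, n_folds: int, rng: np.random.Generator) -> dict:
    order = list(np.array(sorted(map(str, sources)))[rng.permutation(len(sources))])
    return {src: i % n_folds for i, src in enumerate(order)}


def holdout_rmse(
    spec: tuple[str, ...],
    data: pd.DataFrame,
    hierarchy: Hierarchy,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Out-of-sample RMSE with folds that partition sources.

    All data from one source share a fold so the <=5 cohorts of a survey
    never straddle the train/test split. Squared errors are pooled across
    folds before the root.
    """
    if n_folds < 2:
        raise ValueError("need at least two folds")
    sources = sorted(map(str, data["source_id"].unique()))
    if len(sources) < 2:
        raise ValueError("need at least two sources to cross-validate")
    folds = _fold_assignment(sources, min(n_folds, len(sources)), substream(seed, "folds"))
    fold_of = data["source_id"].astype(str).map(folds)
    sq_errors: list[np.ndarray] = []
    for f in sorted(set(folds.values())):
        train = data[fold_of != f]
        test = data[fold_of == f]
        if train.empty:
            raise ValueError("a fold leaves no training data")
        if test.empty:
            continue
        model = fit_linear_mixed(spec, train, hierarchy)
        pred = model.predict(test)
        sq_errors.append((test["y"].to_numpy(dtype=float) - pred) ** 2)
    pooled = np.concatenate(sq_errors)
    return float(np.sqrt(pooled.mean()))


def ensemble_weights(rmses) -> np.ndarray:
    """Inverse-RMSE weights, normalised to one.

    Zero-RMSE (perfect) models take the full weight, split equally among
    themselves.
    """
    r = np.asarray(rmses, dtype=float)
    if r.size == 0:
        raise ValueError("empty rmse list")
    if np.any(r < 0):
        raise ValueError("rmse must be non-negative")
    zero = r == 0
    if zero.any():
        w = np.where(zero, 1.0 / zero.sum(), 0.0)
        return w
    inv = 1.0 / r
    return inv / inv.sum()


def stage1_predict(
    models: list[FittedMixedModel], weights, grid: pd.DataFrame
) -> np.ndarray:
    """Ensemble (weighted-average) prediction over a location-year grid."""
    w = np.asarray(weights, dtype=float)
    if len(models) != w.size:
        raise ValueError("weights must align with models")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to one")
    pred = np.zeros(len(grid))
    for model, wi in zip(models, w):
        pred += wi * model.predict(grid)
    return pred


# ---------------------------------------------------------------------------
# stage 2: space-time residual smoothing


def time_weight(dt, lambda_time: float, dt_max: int) -> np.ndarray:
    """Cubed time weight (1 - (dt/(1+dt_max))^lambda)^3; 1 at dt=0."""
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("dt must be non-negative")
    return (1.0 - (dt / (1.0 + dt_max)) ** lambda_time) ** 3


def space_weight(
    target: str, source: str, zeta_space: float, hierarchy: Hierarchy
) -> float:
    """Tiered spatial weight: zeta within country, stepping down by tier."""
    reg, sup = hierarchy._maps()
    for loc in (target, source):
        if loc not in reg:
            raise KeyError(f"unknown location {loc!r}")
    if target == source:
        return zeta_space
    if reg[target] == reg[source]:
        return zeta_space * (1.0 - zeta_space)
    if sup[target] == sup[source]:
        return zeta_space * (1.0 - zeta_space) ** 2
    return 0.0


def stage2_smooth(
    stage1: pd.DataFrame,
    data: pd.DataFrame,
    config: STGPRConfig,
    hierarchy: Hierarchy,
) -> pd.DataFrame:
    """Add space-time-weighted data residuals to the stage-1 prediction.

    ``stage1``: location_id, year, stage1 (model space) over the full grid.
    ``data``: location_id, year, y. For each target location-year, every
    datum's weight is its time weight (normalised within its country)
    times its hierarchy-tier weight split equally across the tier's
    contributing countries. Locations with no weight anywhere return the
    stage-1 value unchanged.

    Returns ``stage1`` with an added ``stage2`` column.
    """
    out = stage1.copy()
    s1_lookup = {
        (l, int(y)): v
        for l, y, v in zip(stage1["location_id"], stage1["year"], stage1["stage1"])
    }
    d_loc = data["location_id"].to_numpy()
    d_year = data["year"].to_numpy(dtype=int)
    d_resid = data["y"].to_numpy(dtype=float) - np.array(
        [s1_lookup[(l, int(y))] for l, y in zip(d_loc, d_year)]
    )

    reg, sup = hierarchy._maps()

    stage2 = np.empty(len(out))
    for i, (target, year) in enumerate(zip(out["location_id"], out["year"])):
        tiers = np.array(
            [
                0 if s == target else (1 if reg[s] == reg[target] else (2 if sup[s] == sup[target] else 3))
                for s in d_loc
            ]
        )
        usable = tiers < 3
        if not usable.any():
            stage2[i] = s1_lookup[(target, int(year))]
            continue
        dt = np.abs(d_year - int(year))
        dt_max = int(dt[usable].max())
        tw = time_weight(dt, config.lambda_time, dt_max)

        z = config.zeta_space
        tier_w = {0: z, 1: z * (1 - z), 2: z * (1 - z) ** 2}
        omega = np.zeros(len(d_loc))
        for tier in (0, 1, 2):
            in_tier = usable & (tiers == tier)
            if not in_tier.any():
                continue
            countries = set(d_loc[in_tier])
            for c in countries:
                sel = in_tier & (d_loc == c)
                tw_sum = tw[sel].sum()
                if tw_sum > 0:
                    omega[sel] = tier_w[tier] / len(countries) * tw[sel] / tw_sum
        total = omega.sum()
        if total <= 0:
            stage2[i] = s1_lookup[(target, int(year))]
        else:
            stage2[i] = s1_lookup[(target, int(year))] + float(
                (omega * d_resid).sum() / total
            )
    out["stage2"] = stage2
    return out


# ---------------------------------------------------------------------------
# stage 3: Gaussian process regression


def amplitude_estimate(stage2_residuals, gp_amplitude_mult: float = 1.0,
                       floor: float = 0.05) -> float:
    """GP amplitude from the stage-1/stage-2 disagreement.

    Robust scale: 1.4826 * MAD of the differences, times the configured
    multiplier, floored so the prior never collapses to certainty.
    """
    r = np.asarray(stage2_residuals, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one residual")
    mad = np.median(np.abs(r - np.median(r)))
    return float(max(gp_amplitude_mult * 1.4826 * mad, floor))


def matern52(d, length_scale: float) -> np.ndarray:
    """Matérn-5/2 correlation as a function of distance."""
    x = np.sqrt(5.0) * np.abs(np.asarray(d, dtype=float)) / length_scale
    return (1.0 + x + x**2 / 3.0) * np.exp(-x)


def _solve_psd(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        c = sla.cho_factor(mat, lower=True)
    except np.linalg.LinAlgError:
        c = sla.cho_factor(mat + 1e-10 * np.eye(len(mat)), lower=True)
    return sla.cho_solve(c, rhs)


def gp_posterior(
    years,
    prior_mean,
    data_years,
    data_y,
    data_var,
    eta: float,
    length_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """GP conditioning over a year grid with a Matérn-5/2 kernel.

    Prior mean is the stage-2 series on ``years``; observations carry
    heteroskedastic noise ``data_var``. With no data the prior mean and
    covariance (eta^2 on the diagonal) are returned. Raises if the noisy
    kernel matrix is not positive definite after a 1e-10 jitter retry.
    """
    years = np.asarray(years, dtype=float)
    m = np.asarray(prior_mean, dtype=float)
    if years.shape != m.shape:
        raise ValueError("prior mean must align with the year grid")
    if eta <= 0 or length_scale <= 0:
        raise ValueError("kernel parameters must be positive")
    K_grid = eta**2 * matern52(years[:, None] - years[None, :], length_scale)
    ty = np.asarray(data_years, dtype=float)
    if ty.size == 0:
        return m.copy(), K_grid

    y = np.asarray(data_y, dtype=float)
    v = np.asarray(data_var, dtype=float)
    if np.any(v <= 0):
        raise ValueError("data variances must be positive")
    m_at_data = np.interp(ty, years, m)
    K_dd = eta**2 * matern52(ty[:, None] - ty[None, :], length_scale) + np.diag(v)
    K_gd = eta**2 * matern52(years[:, None] - ty[None, :], length_scale)

    alpha = _solve_psd(K_dd, y - m_at_data)
    mean = m + K_gd @ alpha
    cov = K_grid - K_gd @ _solve_psd(K_dd, K_gd.T)
    cov = (cov + cov.T) / 2.0
    return mean, cov


def sample_draws(
    mean: np.ndarray,
    cov: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multivariate-normal draws (model space), back-transformed to shares.

    Returns an array of shape (len(mean), n_draws) of proportions in (0,1).
    Raises if the covariance is not PSD after jitter.
    """
    cov = np.asarray(cov, dtype=float)
    n = len(mean)
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    chol = None
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    if chol is None:
        raise np.linalg.LinAlgError("covariance not PSD after jitter")
    z = rng.standard_normal((n, int(n_draws)))
    y = np.asarray(mean, dtype=float)[:, None] + chol @ z
    return from_model_space(y)


# ---------------------------------------------------------------------------
# orchestration for one indicator


@dataclass
class STGPRResult:
    """Full output of one indicator's ST-GPR run."""

    indicator: str
    grid: pd.DataFrame  # location_id, year, stage1, stage2, gp_mean, gp_sd
    draws: dict[str, np.ndarray]  # location_id -> (n_years, n_draws) shares
    years: np.ndarray
    weights: np.ndarray
    specs: list[tuple[str, ...]]
    rmses: np.ndarray


def run_stgpr(
    indicator: str,
    data: pd.DataFrame,
    covariates: pd.DataFrame,
    hierarchy: Hierarchy,
    config: STGPRConfig,
    years: np.ndarray,
) -> STGPRResult:
    """Run all three ST-GPR stages for one indicator.

    ``data``: location_id, year, y, var_y, source_id (model space,
    already restricted to included location-years). ``covariates``: wide
    frame location_id, year, one column per covariate.
    """
    cov_names = [
        c for c in covariates.columns if c not in ("location_id", "year")
    ]
    grid = covariates.merge(hierarchy.locations, on="location_id", how="left")
    grid = grid[grid["year"].isin(years)].copy()
    data = data.merge(covariates, on=["location_id", "year"], how="left").merge(
        hierarchy.locations, on="location_id", how="left"
    )

    specs = enumerate_models(cov_names, config.max_covariates)
    rmses = np.array(
        [
            holdout_rmse(spec, data, hierarchy, config.n_folds,
                         seed=config.seed)
            for spec in specs
        ]
    )
    weights = ensemble_weights(rmses)
    models = [fit_linear_mixed(spec, data, hierarchy) for spec in specs]
    grid["stage1"] = stage1_predict(models, weights, grid)

    grid = stage2_smooth(grid[["location_id", "year", "stage1"]], data, config, hierarchy)

    # amplitude from stage1-stage2 disagreement, pooled by region; measured
    # at location-years with data, where the smoothing stage actually had
    # residuals to correct (cells far from any datum have near-zero
    # corrections and would dilute the scale)
    grid = grid.merge(hierarchy.locations, on="location_id", how="left")
    data_cells = set(zip(data["location_id"], data["year"].astype(int)))
    at_data = grid[
        [
            (l, int(y)) in data_cells
            for l, y in zip(grid["location_id"], grid["year"])
        ]
    ]
    fallback_diffs = (
        at_data["stage2"] - at_data["stage1"] if len(at_data) else
        grid["stage2"] - grid["stage1"]
    )
    eta_by_region = {}
    for region, sub in grid.groupby("region_id"):
        sub_data = at_data[at_data["region_id"] == region]
        diffs = (
            sub_data["stage2"] - sub_data["stage1"]
            if len(sub_data)
            else fallback_diffs
        )
        eta_by_region[region] = amplitude_estimate(
            diffs, config.gp_amplitude_mult, config.amplitude_floor
        )

    grid = grid.reset_index(drop=True)
    draws: dict[str, np.ndarray] = {}
    gp_mean = np.empty(len(grid))
    gp_sd = np.empty(len(grid))
    for loc, sub in grid.groupby("location_id", sort=True):
        sub = sub.sort_values("year")
        idx = sub.index
        d = data[data["location_id"] == loc]
        mean, cov = gp_posterior(
            years,
            sub["stage2"].to_numpy(),
            d["year"].to_numpy(dtype=float),
            d["y"].to_numpy(dtype=float),
            d["var_y"].to_numpy(dtype=float),
            eta_by_region[hierarchy.region_of(loc)],
            config.gp_scale_years,
        )
        gp_mean[idx] = mean
        gp_sd[idx] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        rng = substream(config.seed, "draws", indicator, str(loc))
        draws[str(loc)] = sample_draws(mean, cov, config.n_draws, rng)

    grid["gp_mean"] = gp_mean
    grid["gp_sd"] = gp_sd
    return STGPRResult(
        indicator=indicator,
        grid=grid[["location_id", "year", "stage1", "stage2", "gp_mean", "gp_sd"]],
        draws=draws,
        years=np.asarray(years),
        weights=weights,
        specs=specs,
        rmses=rmses,
    )
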