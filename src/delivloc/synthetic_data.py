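"""Fully synthetic world with known ground truth for the whole pipeline.

Real inputs to this kind of analysis (survey microdata such as DHS/MICS,
a location hierarchy with live births, covariates, and an externally
modelled in-facility envelope) are restricted-access; this module generates
a statistical stand-in with the same shape so that every stage can be
exercised against a known truth:

* a hierarchy of super-regions / regions / countries with live births;
* smooth true five-category compositions per country-year, built as
  softmax of logistic latent trends with region- and country-level shifts
  (facility share rises over the period, mixes differ by region);
* covariates that are noisy monotone transforms of the facility latent;
* an envelope supplied as draws: the true in-facility share perturbed with
  logit-normal noise, mimicking an externally estimated input;
* multi-survey microdata with a ~45-label response-dialect catalogue,
  5-year recall windows, partial level/sector information, caesarean flags
  (hospitals have distinctly higher caesarean rates, which is what lets the
  caesarean-sorting step recover otherwise ambiguous labels), and
  log-normal survey weights.

Everything is reproducible bit-for-bit from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .stgpr import Hierarchy, substream

__all__ = [
    "SimulationConfig",
    "SyntheticWorld",
    "DIALECT_CATALOGUE",
    "simulate_truth",
    "simulate_covariates",
    "simulate_envelope",
    "simulate_survey",
    "simulate_world",
    "emit_fixtures",
    "read_fixtures",
]

TRUTH_CATEGORIES = ("pub_hosp", "priv_hosp", "pub_low", "priv_low", "non_facility")

# label pools by generator class; all resolve through the default rulebook
DIALECT_CATALOGUE: dict[str, tuple[str, ...]] = {
    "pub_hosp": (
        "government hospital", "district hospital", "regional hospital",
        "referral hospital", "provincial hospital", "teaching hospital",
        "national hospital", "military hospital", "central hospital",
    ),
    "nonprofit_hosp": ("mission hospital", "ngo hospital", "church hospital"),
    "priv_hosp": ("private hospital", "private maternity hospital", "private polyclinic"),
    "pub_low": (
        "government health centre", "public health centre",
        "government health post", "public health post",
        "government dispensary", "public dispensary",
        "government clinic", "public clinic",
    ),
    "nonprofit_low": ("mission health centre", "ngo clinic", "church dispensary"),
    "priv_low": ("private clinic", "private health centre", "private doctor", "nursing home"),
    "hosp_sector_unknown": ("hospital", "general hospital"),
    "low_sector_unknown": ("health centre", "health post", "dispensary", "birthing centre"),
    "level_unknown": ("clinic", "medical facility", "health facility", "other facility"),
    "csec_resolvable_hosp": ("maternity unit",),
    "csec_resolvable_low": ("delivery unit",),
    "non_facility": (
        "home", "own home", "parents' home", "enroute", "on the way", "in transit", "tba",
    ),
    "unknown": ("no response", "don't know", "other", "missing"),
}

# latent logistic trend parameters per category:
# (baseline, amplitude, midpoint year, width in years)
_TREND = {
    "pub_hosp": (-0.5, 2.2, 2008.0, 7.0),
    "priv_hosp": (-2.0, 1.5, 2012.0, 8.0),
    "pub_low": (-0.8, 0.8, 2005.0, 8.0),
    "priv_low": (-3.2, 0.5, 2012.0, 8.0),
    "non_facility": (0.8, -1.2, 2008.0, 8.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults define the study-sized synthetic world."""

    n_super_regions: int = 2
    n_regions_per: int = 2
    n_countries_per: int = 5
    year_start: int = 1995
    year_end: int = 2023
    n_surveys_per_country: int = 3
    births_per_survey: int = 2000
    unknown_level_rate: float = 0.02
    unknown_sector_rate: float = 0.07
    missing_rate: float = 0.005
    nonprofit_label_rate: float = 0.10
    csec_rate_hospital: float = 0.15
    csec_rate_lower: float = 0.03
    region_effect_scale: float = 0.5
    country_effect_scale: float = 0.4
    midpoint_jitter_years: float = 4.0
    covariate_noise: float = 0.3
    envelope_noise: float = 0.1
    n_envelope_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("unknown_level_rate", "unknown_sector_rate", "missing_rate",
                     "csec_rate_hospital", "csec_rate_lower"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.csec_rate_hospital <= self.csec_rate_lower:
            raise ValueError("hospitals are defined by caesarean capability: "
                             "csec_rate_hospital must exceed csec_rate_lower")
        if self.year_end <= self.year_start:
            raise ValueError("need year_end > year_start")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_countries(self) -> int:
        return self.n_super_regions * self.n_regions_per * self.n_countries_per


@dataclass
class SyntheticWorld:
    """All generated inputs plus the ground truth."""

    config: SimulationConfig
    hierarchy: Hierarchy
    covariates: pd.DataFrame  # wide: location_id, year, <covariate columns>
    truth: pd.DataFrame  # location_id, year, five categories + hosp/low/envelope
    envelope: pd.DataFrame  # wide: location_id, year, draw_1..draw_N
    microdata: pd.DataFrame


def _make_hierarchy(config: SimulationConfig, rng: np.random.Generator) -> Hierarchy:
    rows = []
    for s in range(config.n_super_regions):
        for r in range(config.n_regions_per):
            for c in range(config.n_countries_per):
                rows.append(
                    {
                        "location_id": f"C{s}{r}{c}",
                        "region_id": f"R{s}{r}",
                        "super_region_id": f"S{s}",
                    }
                )
    locations = pd.DataFrame(rows)
    base = np.exp(rng.normal(np.log(2e5), 0.8, size=len(locations))).astype(int) + 1000
    births = pd.DataFrame(
        [
            {"location_id": loc, "year": int(y), "births": int(b)}
            for loc, b in zip(locations["location_id"], base)
            for y in np.arange(config.year_start, config.year_end + 1)
        ]
    )
    return Hierarchy(locations, births)


def simulate_truth(config: SimulationConfig, hierarchy: Hierarchy | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """True compositions: softmax of logistic latents with nested shifts.

    Year-to-year changes stay below a few percentage points by construction
    (latent slopes bounded by amplitude / (4 * width)).
    """
    rng = rng if rng is not None else substream(config.seed, "trut")
    hierarchy = hierarchy if hierarchy is not None else _make_hierarchy(
        config, substream(config.seed, "hier")
    )
    years = config.years.astype(float)
    cats = TRUTH_CATEGORIES

    region_shift = {
        (reg, cat): rng.normal(0.0, config.region_effect_scale)
        for reg in hierarchy.locations["region_id"].unique()
        for cat in cats
    }
    rows = []
    for _, loc in hierarchy.locations.iterrows():
        latents = np.zeros((len(cats), len(years)))
        for k, cat in enumerate(cats):
            base, amp, mid, width = _TREND[cat]
            mid = mid + rng.normal(0.0, config.midpoint_jitter_years)
            shift = region_shift[(loc["region_id"], cat)] + rng.normal(
                0.0, config.country_effect_scale
            )
            latents[k] = base + shift + amp * expit((years - mid) / width)
        comp = np.exp(latents - latents.max(axis=0))
        comp /= comp.sum(axis=0)
        for j, year in enumerate(config.years):
            row = {"location_id": loc["location_id"], "year": int(year)}
            row.update({cat: comp[k, j] for k, cat in enumerate(cats)})
            row["hosp"] = row["pub_hosp"] + row["priv_hosp"]
            row["low"] = row["pub_low"] + row["priv_low"]
            row["envelope"] = 1.0 - row["non_facility"]
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_covariates(truth: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Covariates as noisy monotone transforms of the true facility latent."""
    rng = rng if rng is not None else substream(config.seed, "covs")
    lat = logit(np.clip(truth["envelope"].to_numpy(), 1e-6, 1 - 1e-6))
    n = len(truth)
    s = config.covariate_noise
    out = truth[["location_id", "year"]].copy()
    out["dev_index"] = 1.0 * lat + s * rng.standard_normal(n)
    out["urban_frac"] = expit(0.5 * lat + s * rng.standard_normal(n))
    out["anc_proxy"] = 0.8 * lat + s * rng.standard_normal(n)
    out["sba_proxy"] = 1.2 * lat + s * rng.standard_normal(n)
    return out


def simulate_envelope(truth: pd.DataFrame, config: SimulationConfig,
                      n_draws: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Envelope draws: true in-facility share with logit-normal noise.

    Each location-year gets a perturbed centre plus per-draw noise of the
    same scale, emulating an externally estimated input whose uncertainty
    is honest about its own error.
    """
    rng = rng if rng is not None else substream(config.seed, "envl")
    n_draws = int(n_draws or config.n_envelope_draws)
    centre = logit(np.clip(truth["envelope"].to_numpy(), 1e-6, 1 - 1e-6))
    centre = centre + config.envelope_noise * rng.standard_normal(len(centre))
    draws = expit(
        centre[:, None]
        + config.envelope_noise * rng.standard_normal((len(centre), n_draws))
    )
    draw_frame = pd.DataFrame(
        draws, columns=[f"draw_{d + 1}" for d in range(n_draws)]
    )
    return pd.concat(
        [truth[["location_id", "year"]].reset_index(drop=True), draw_frame], axis=1
    )


def _facility_labels(level: str, sector: str, n: int, config: SimulationConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw response labels for n facility births of one true category."""
    labels = np.empty(n, dtype=object)
    u = rng.random(n)
    lvl_amb = u < config.unknown_level_rate
    sec_amb = (~lvl_amb) & (u < config.unknown_level_rate + config.unknown_sector_rate)
    specific = ~(lvl_amb | sec_amb)

    # level-ambiguous: half generic, half resolvable only by caesarean rate
    n_amb = int(lvl_amb.sum())
    if n_amb:
        generic = rng.random(n_amb) < 0.5
        pool_csec = DIALECT_CATALOGUE[
            "csec_resolvable_hosp" if level == "hospital" else "csec_resolvable_low"
        ]
        amb_labels = np.where(
            generic,
            rng.choice(DIALECT_CATALOGUE["level_unknown"], size=n_amb),
            rng.choice(pool_csec, size=n_amb),
        )
        labels[lvl_amb] = amb_labels

    n_sec = int(sec_amb.sum())
    if n_sec:
        pool = DIALECT_CATALOGUE[
            "hosp_sector_unknown" if level == "hospital" else "low_sector_unknown"
        ]
        labels[sec_amb] = rng.choice(pool, size=n_sec)

    n_spec = int(specific.sum())
    if n_spec:
        if sector == "public":
            nfp = rng.random(n_spec) < config.nonprofit_label_rate
            pub_pool = DIALECT_CATALOGUE["pub_hosp" if level == "hospital" else "pub_low"]
            nfp_pool = DIALECT_CATALOGUE[
                "nonprofit_hosp" if level == "hospital" else "nonprofit_low"
            ]
            labels[specific] = np.where(
                nfp, rng.choice(nfp_pool, size=n_spec), rng.choice(pub_pool, size=n_spec)
            )
        else:
            pool = DIALECT_CATALOGUE["priv_hosp" if level == "hospital" else "priv_low"]
            labels[specific] = rng.choice(pool, size=n_spec)
    return labels


_CAT_LEVEL_SECTOR = {
    "pub_hosp": ("hospital", "public"),
    "priv_hosp": ("hospital", "private"),
    "pub_low": ("lower", "public"),
    "priv_low": ("lower", "private"),
}


def simulate_survey(
    truth: pd.DataFrame,
    location_id: str,
    interview_year: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    source_id: str | None = None,
) -> pd.DataFrame:
    """One survey: births in the 5-year recall window with dialect labels."""
    if interview_year - 5 < config.year_start:
        raise ValueError("recall window extends before the first modelled year")
    source_id = source_id or f"{location_id}_SVY{interview_year}"
    birth_years = np.arange(interview_year - 4, interview_year + 1)
    per_year = rng.multinomial(config.births_per_survey, np.full(5, 0.2))

    t = truth[truth["location_id"] == location_id].set_index("year")
    frames = []
    for year, n_births in zip(birth_years, per_year):
        if n_births == 0:
            continue
        probs = np.array([t.loc[int(year), c] for c in TRUTH_CATEGORIES])
        counts = rng.multinomial(int(n_births), probs / probs.sum())
        for cat, n_cat in zip(TRUTH_CATEGORIES, counts):
            if n_cat == 0:
                continue
            if cat == "non_facility":
                labels = rng.choice(DIALECT_CATALOGUE["non_facility"], size=n_cat)
                csec_rate = 0.0
            else:
                level, sector = _CAT_LEVEL_SECTOR[cat]
                labels = _facility_labels(level, sector, int(n_cat), config, rng)
                csec_rate = (
                    config.csec_rate_hospital if level == "hospital"
                    else config.csec_rate_lower
                )
            missing = rng.random(int(n_cat)) < config.missing_rate
            if missing.any():
                labels = labels.copy()
                labels[missing] = rng.choice(
                    DIALECT_CATALOGUE["unknown"], size=int(missing.sum())
                )
            frames.append(
                pd.DataFrame(
                    {
                        "location_id": location_id,
                        "source_id": source_id,
                        "interview_year": int(interview_year),
                        "birth_year": int(year),
                        "response_label": labels,
                        "weight": np.exp(rng.normal(0.0, 0.3, size=int(n_cat))),
                        "csec": (rng.random(int(n_cat)) < csec_rate).astype(int),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_world(config: SimulationConfig = SimulationConfig(),
                   n_envelope_draws: int | None = None) -> SyntheticWorld:
    """Generate the complete synthetic world from the configured seed."""
    hierarchy = _make_hierarchy(config, substream(config.seed, "hier"))
    truth = simulate_truth(config, hierarchy)
    covariates = simulate_covariates(truth, config)
    envelope = simulate_envelope(truth, config, n_envelope_draws)

    surveys = []
    candidates = np.arange(config.year_start + 5, config.year_end + 1)
    for loc in hierarchy.location_ids:
        rng = substream(config.seed, "srvy", str(loc))
        n = min(config.n_surveys_per_country, len(candidates))
        ivs = np.sort(rng.choice(candidates, size=n, replace=False))
        for iy in ivs:
            surveys.append(simulate_survey(truth, loc, int(iy), config, rng))
    microdata = pd.concat(surveys, ignore_index=True)
    return SyntheticWorld(config, hierarchy, covariates, truth, envelope, microdata)


# ---------------------------------------------------------------------------
# fixtures on disk

_FILES = ("hierarchy", "births", "covariates", "envelope", "microdata", "truth")
_FLOAT_FMT = "%.17g"


def emit_fixtures(world: SyntheticWorld, directory) -> dict[str, str]:
    """Write the world as the CSV files the pipeline consumes.

    Covariates go out in long form (location_id, year, name, value). Fixed
    float formatting keeps the files byte-deterministic under a fixed seed;
    read-back reproduces the in-memory values.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {}
    cov_long = world.covariates.melt(
        id_vars=["location_id", "year"], var_name="name", value_name="value"
    ).sort_values(["location_id", "year", "name"], kind="stable")
    frames = {
        "hierarchy": world.hierarchy.locations,
        "births": world.hierarchy.births,
        "covariates": cov_long,
        "envelope": world.envelope,
        "microdata": world.microdata,
        "truth": world.truth,
    }
    for name, frame in frames.items():
        path = os.path.join(directory, f"{name}.csv")
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths[name] = path
    return paths


def read_fixtures(directory) -> SyntheticWorld:
    """Read back fixtures written by :func:`emit_fixtures`."""
    import os

    def rd(name):
        return pd.read_csv(os.path.join(directory, f"{name}.csv"))

    hierarchy = Hierarchy(rd("hierarchy"), rd("births"))
    cov = (
        rd("covariates")
        .pivot(index=["location_id", "year"], columns="name", values="value")
        .reset_index()
    )
    cov.columns.name = None
    return SyntheticWorld(
        SimulationConfig(),
        hierarchy,
        cov,
        rd("truth"),
        rd("envelope"),
        rd("microdata"),
    )
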