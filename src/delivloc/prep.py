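"""Turn categorised birth microdata into modellable location-year data.

Each survey contributes up to five birth-year cohorts (children up to age 5
at interview), and each (source, location, birth year) cell yields one
observed proportion per indicator. Six indicators are modelled, all as
shares of live births: the four level-by-sector combinations (public or
non-profit hospital, private hospital, public or non-profit lower-level,
private lower-level) and the two level-only totals (hospital, lower).

Facility births whose level or sector remains unknown after categorisation
are redistributed proportionally to the known categories within the cell
(level first, then sector within each level), conserving the total facility
mass exactly; cells with no known mass fall back to the country's
prior-survey shares.

Sampling uncertainty uses the Kish effective sample size and the binomial
variance p(1-p)/n_eff, with the proportion clamped away from 0 and 1 so the
variance is always positive. Modelling happens on the logit scale via the
same clamp; delta-method variance propagation is provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "INDICATORS",
    "SECTOR_INDICATORS",
    "LEVEL_INDICATORS",
    "PrepConfig",
    "effective_sample_size",
    "sampling_variance",
    "to_model_space",
    "from_model_space",
    "model_space_variance",
    "redistribute_unknowns",
    "tabulate_proportions",
]

SECTOR_INDICATORS = ("pub_hosp", "priv_hosp", "pub_low", "priv_low")
LEVEL_INDICATORS = ("hosp", "low")
INDICATORS = SECTOR_INDICATORS + LEVEL_INDICATORS

_LEVELS = ("hospital", "lower")
_SECTORS = ("public_nfp", "private_fp")
_CELL_TO_INDICATOR = {
    ("hospital", "public_nfp"): "pub_hosp",
    ("hospital", "private_fp"): "priv_hosp",
    ("lower", "public_nfp"): "pub_low",
    ("lower", "private_fp"): "priv_low",
}


@dataclass(frozen=True)
class PrepConfig:
    """Tabulation settings.

    clamp: offset keeping proportions inside [clamp, 1-clamp] before the
        logit transform and the variance formula. The default 0.001 keeps
        the smallest shares the method must report (well below 0.5% for
        private lower-level facilities in many countries) representable
        while still bounding the logit.
    variance_inflation: multiplicative design-effect factor on the sampling
        variance (1.0 = pure Kish).
    tau_level_sector / tau_level: inclusion thresholds on the share of
        facility births with known level+sector / known level.
    """

    clamp: float = 0.001
    variance_inflation: float = 1.0
    tau_level_sector: float = 0.85
    tau_level: float = 0.95


def effective_sample_size(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weights")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(w.sum() ** 2 / (w**2).sum())


def _clamp(p, c: float):
    return np.clip(p, c, 1.0 - c)


def sampling_variance(p, n_eff, clamp: float = 0.001):
    """Binomial sampling variance p(1-p)/n_eff with the proportion clamped.

    Clamping keeps the variance strictly positive at observed 0s and 1s.
    """
    pc = _clamp(np.asarray(p, dtype=float), clamp)
    return pc * (1.0 - pc) / np.asarray(n_eff, dtype=float)


def to_model_space(p, clamp: float = 0.001):
    """Clamped logit transform used for modelling."""
    return logit(_clamp(np.asarray(p, dtype=float), clamp))


def from_model_space(y):
    """Inverse of :func:`to_model_space` (plain inverse-logit)."""
    return expit(np.asarray(y, dtype=float))


def model_space_variance(p, var_p, clamp: float = 0.001):
    """Delta-method variance of the clamped logit: var_p / (p(1-p))^2."""
    pc = _clamp(np.asarray(p, dtype=float), clamp)
    return np.asarray(var_p, dtype=float) / (pc * (1.0 - pc)) ** 2


def redistribute_unknowns(
    masses: dict[tuple[str, str], float],
    prior_level_shares: dict[str, float] | None = None,
    prior_sector_shares: dict[str, dict[str, float]] | None = None,
) -> tuple[dict[tuple[str, str], float], list[str]]:
    """Allocate unknown-level/sector facility mass to the known categories.

    ``masses`` maps (level, sector) to weighted facility-birth mass, where
    level is hospital/lower/unknown_level and sector is
    public_nfp/private_fp/unknown_sector. Unknown-level mass is split across
    hospital/lower in proportion to the cell's known-level mass (carrying
    its sector label along); then, within each level, unknown-sector mass is
    split across the two sectors in proportion to that level's known-sector
    mass. Total facility mass is conserved exactly.

    When a redistribution group has zero known mass, the country's
    prior-survey shares are used; with no prior either, the mass stays
    unknown and the caller drops it from sector-specific tabulation (a
    warning string is returned).

    Returns the resolved (level, sector) masses — possibly retaining
    residual unknown cells — and a list of warnings.
    """
    m = {
        (lv, sc): float(masses.get((lv, sc), 0.0))
        for lv in ("hospital", "lower", "unknown_level")
        for sc in ("public_nfp", "private_fp", "unknown_sector")
    }
    if any(v < 0 for v in m.values()):
        raise ValueError("negative facility mass")
    warnings: list[str] = []
    total_before = sum(m.values())

    # --- level: split unknown_level mass across hospital/lower -------------
    known_level = {lv: sum(m[(lv, sc)] for sc in m_keys_sc()) for lv in _LEVELS}
    level_total = sum(known_level.values())
    unknown_level_total = sum(m[("unknown_level", sc)] for sc in m_keys_sc())
    if unknown_level_total > 0:
        if level_total > 0:
            shares = {lv: known_level[lv] / level_total for lv in _LEVELS}
        elif prior_level_shares:
            shares = dict(prior_level_shares)
        else:
            shares = None
            warnings.append("unknown-level mass with no known or prior level split")
        if shares is not None:
            for sc in m_keys_sc():
                mass = m.pop(("unknown_level", sc))
                m[("unknown_level", sc)] = 0.0
                for lv in _LEVELS:
                    m[(lv, sc)] += mass * shares[lv]

    # --- sector: within each level, split unknown_sector mass --------------
    for lv in _LEVELS:
        unknown = m[(lv, "unknown_sector")]
        if unknown <= 0:
            continue
        known = {sc: m[(lv, sc)] for sc in _SECTORS}
        known_total = sum(known.values())
        if known_total > 0:
            shares = {sc: known[sc] / known_total for sc in _SECTORS}
        elif prior_sector_shares and lv in prior_sector_shares:
            shares = dict(prior_sector_shares[lv])
        else:
            warnings.append(f"unknown-sector mass in {lv} with no known or prior split")
            continue
        m[(lv, "unknown_sector")] = 0.0
        for sc in _SECTORS:
            m[(lv, sc)] += unknown * shares[sc]

    total_after = sum(m.values())
    if abs(total_after - total_before) > 1e-9 * max(1.0, total_before):
        raise AssertionError("facility mass not conserved")
    return m, warnings


def m_keys_sc():
    return ("public_nfp", "private_fp", "unknown_sector")


def tabulate_proportions(
    microdata: pd.DataFrame, config: PrepConfig = PrepConfig()
) -> pd.DataFrame:
    """Tabulate the six indicators per (location, source, birth year).

    ``microdata`` has one row per birth with columns location_id, source_id,
    interview_year, birth_year, facility_status, level, sector_m, weight
    (csec is ignored here). Births with unknown facility status are dropped
    from the denominator. Unknown level/sector mass is redistributed per
    :func:`redistribute_unknowns`, with the country's earlier-survey shares
    as fallback (sources processed in interview-year order).

    Returns one row per (location_id, year, source_id, indicator) with p,
    n_eff, var_sampling and the two inclusion flags.
    """
    if microdata.empty:
        raise ValueError("empty microdata")
    required = {
        "location_id", "source_id", "interview_year", "birth_year",
        "facility_status", "level", "sector_m", "weight",
    }
    missing = required - set(microdata.columns)
    if missing:
        raise ValueError(f"microdata missing columns: {sorted(missing)}")

    rows: list[dict] = []
    prior_level: dict[str, dict[str, float]] = {}
    prior_sector: dict[str, dict[str, dict[str, float]]] = {}

    md = microdata.sort_values(["location_id", "interview_year", "source_id"])
    for (loc, _iy, src), sub in md.groupby(
        ["location_id", "interview_year", "source_id"], sort=True
    ):
        for year, cell in sub.groupby("birth_year", sort=True):
            known = cell[cell["facility_status"] != "unknown"]
            w_total = known["weight"].sum()
            if w_total <= 0:
                logger.warning(
                    "skipping %s/%s year %s: zero known-status weight", loc, src, year
                )
                continue
            fac = known[known["facility_status"] == "facility"]
            fac_mass = fac["weight"].sum()

            masses: dict[tuple[str, str], float] = {}
            for (lv, sc), g in fac.groupby(["level", "sector_m"]):
                masses[(lv, sc)] = masses.get((lv, sc), 0.0) + g["weight"].sum()

            if fac_mass > 0:
                lvl_mass = sum(
                    v for (lv, _), v in masses.items() if lv != "unknown_level"
                )
                both_mass = sum(
                    v
                    for (lv, sc), v in masses.items()
                    if lv != "unknown_level" and sc != "unknown_sector"
                )
                f_level = lvl_mass / fac_mass
                f_both = both_mass / fac_mass
            else:
                # all births non-facility: vacuously complete information
                f_level = f_both = 1.0

            resolved, warns = redistribute_unknowns(
                masses, prior_level.get(loc), prior_sector.get(loc)
            )
            for w in warns:
                logger.warning("%s/%s year %s: %s", loc, src, year, w)

            hosp_mass = sum(resolved[("hospital", sc)] for sc in m_keys_sc())
            low_mass = sum(resolved[("lower", sc)] for sc in m_keys_sc())
            residual_unknown = (
                sum(resolved[("unknown_level", sc)] for sc in m_keys_sc())
                + resolved[("hospital", "unknown_sector")]
                + resolved[("lower", "unknown_sector")]
            )

            n_eff = effective_sample_size(known["weight"].to_numpy())
            in_ls, in_l = f_both >= config.tau_level_sector, f_level >= config.tau_level

            values = {
                "hosp": hosp_mass / w_total,
                "low": low_mass / w_total,
            }
            for (lv, sc), ind in _CELL_TO_INDICATOR.items():
                values[ind] = resolved[(lv, sc)] / w_total

            for ind in INDICATORS:
                p = values[ind]
                rows.append(
                    {
                        "location_id": loc,
                        "year": int(year),
                        "indicator": ind,
                        "p": p,
                        "n_eff": n_eff,
                        "var_sampling": float(
                            sampling_variance(p, n_eff, config.clamp)
                            * config.variance_inflation
                        ),
                        "source_id": src,
                        "in_level_sector_models": bool(in_ls),
                        "in_level_models": bool(in_l),
                    }
                )

            # remember resolved shares as priors for later surveys
            if hosp_mass + low_mass > 0 and residual_unknown <= 1e-12:
                t = hosp_mass + low_mass
                prior_level[loc] = {"hospital": hosp_mass / t, "lower": low_mass / t}
                ps: dict[str, dict[str, float]] = {}
                for lv, lv_mass in (("hospital", hosp_mass), ("lower", low_mass)):
                    if lv_mass > 0:
                        ps[lv] = {
                            sc: resolved[(lv, sc)] / lv_mass for sc in _SECTORS
                        }
                if ps:
                    prior_sector[loc] = ps

    if not rows:
        raise ValueError("no tabulatable location-years")
    return pd.DataFrame(rows)
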