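"""Envelope raking, composition building, aggregation and change analysis.

The six modelled indicators are internally consistent only approximately;
this module enforces exact coherence by two-tier multiplicative raking, per
draw, in proportion space:

1. the hospital and lower-level totals are scaled to sum to the externally
   supplied in-facility envelope, defining hospital and lower envelopes;
2. the sector-specific pairs are scaled to sum to those level envelopes.

The non-facility share is one minus the facility envelope, so the five
final categories sum to one exactly for every draw. All scaling and
aggregation is performed on draws; summaries (mean and the 2.5th/97.5th
percentile uncertainty interval) are taken last. Regional and global
estimates are live-birth-weighted averages of country draws. The 1995-2023
change decomposition attributes the facility-share increase to the four
facility categories per draw.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "rake_to_envelope",
    "build_composition",
    "aggregate_regions",
    "summarize",
    "decompose_change",
]

CATEGORIES = ("pub_hosp", "priv_hosp", "pub_low", "priv_low", "non_facility")
FACILITY_CATEGORIES = CATEGORIES[:4]


def rake_to_envelope(components, envelope):
    """Multiplicatively scale components to sum to the envelope, per draw.

    ``components``: sequence of arrays, all broadcast-compatible with
    ``envelope``. Each component is multiplied by envelope / sum so the
    scaled components sum to the envelope exactly. Cells where the
    components sum to zero but the envelope is positive get an equal split
    (logged); a zero envelope zeroes all components.
    """
    comps = np.stack([np.asarray(c, dtype=float) for c in components])
    env = np.asarray(envelope, dtype=float)
    if (comps < 0).any() or (env < 0).any():
        raise ValueError("components and envelope must be non-negative")
    total = comps.sum(axis=0)
    factor = np.divide(env, total, out=np.zeros_like(env, dtype=float), where=total > 0)
    scaled = comps * factor
    degenerate = (total <= 0) & (env > 0)
    if degenerate.any():
        logger.warning(
            "raking: %d cells with zero components and positive envelope; "
            "splitting the envelope equally",
            int(degenerate.sum()),
        )
        equal = env / len(comps)
        for k in range(len(comps)):
            scaled[k] = np.where(degenerate, equal, scaled[k])
    return [scaled[k] for k in range(len(comps))]


def build_composition(level_draws, sector_level_draws, envelope):
    """Two-tier raking into the five-category composition.

    ``level_draws``: (hosp, low) draw arrays; ``sector_level_draws``:
    (pub_hosp, priv_hosp, pub_low, priv_low); ``envelope``: in-facility
    share draws, all aligned. Returns a dict over the five categories plus
    the derived ``hosp_envelope``/``low_envelope``.
    """
    hosp, low = level_draws
    pub_hosp, priv_hosp, pub_low, priv_low = sector_level_draws
    env = np.asarray(envelope, dtype=float)
    if (env < 0).any() or (env > 1).any():
        raise ValueError("envelope must lie in [0, 1]")

    e_hosp, e_low = rake_to_envelope([hosp, low], env)
    r_pub_hosp, r_priv_hosp = rake_to_envelope([pub_hosp, priv_hosp], e_hosp)
    r_pub_low, r_priv_low = rake_to_envelope([pub_low, priv_low], e_low)
    return {
        "pub_hosp": r_pub_hosp,
        "priv_hosp": r_priv_hosp,
        "pub_low": r_pub_low,
        "priv_low": r_priv_low,
        "non_facility": 1.0 - env,
        "hosp_envelope": e_hosp,
        "low_envelope": e_low,
    }


def aggregate_regions(composition: dict, members: dict, births: dict):
    """Births-weighted aggregation of country draws to higher levels.

    ``composition``: category -> {location_id -> (n_years, n_draws)} draws.
    ``members``: aggregate_id -> list of member location_ids.
    ``births``: location_id -> (n_years,) live births.

    Returns category -> {aggregate_id -> (n_years, n_draws)}. Aggregation is
    on draws (never on summaries) so it commutes with summing categories.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for agg_id, locs in members.items():
        missing = [l for l in locs if l not in births]
        if missing:
            raise KeyError(f"births missing for locations {missing} in {agg_id}")
        w = np.stack([np.asarray(births[l], dtype=float) for l in locs])  # (L, Y)
        denom = w.sum(axis=0)
        if (denom <= 0).any():
            raise ValueError(f"zero total births in aggregate {agg_id}")
        for cat in composition:
            if len(locs) == 1:  # exact identity for single-member aggregates
                out.setdefault(cat, {})[agg_id] = composition[cat][locs[0]].copy()
                continue
            arrs = np.stack([composition[cat][l] for l in locs])  # (L, Y, D)
            agg = (w[:, :, None] * arrs).sum(axis=0) / denom[:, None]
            out.setdefault(cat, {})[agg_id] = agg
    return out


def summarize(draws, axis: int = -1):
    """Mean and 2.5th/97.5th percentiles (linear interpolation) over draws."""
    d = np.asarray(draws, dtype=float)
    if d.shape[axis] < 2:
        raise ValueError("need at least two draws to summarise")
    mean = d.mean(axis=axis)
    lower = np.percentile(d, 2.5, axis=axis)
    upper = np.percentile(d, 97.5, axis=axis)
    return mean, lower, upper


def decompose_change(comp_y0: dict, comp_y1: dict, eps: float = 1e-6):
    """Per-category change between two years and share of facility increase.

    ``comp_y0``/``comp_y1``: category -> (n_draws,) share draws for the
    start and end year. Per draw, the change in each facility category and
    the total facility change are computed; the share of the increase is the
    ratio, defined only for draws where |facility change| > eps (the count
    of excluded draws is logged and returned).

    Returns a dict with per-category ``pp_change`` draws (percentage
    points), ``share_of_increase`` draws (masked array), and
    ``n_undefined``.
    """
    delta = {
        cat: (np.asarray(comp_y1[cat], dtype=float) - np.asarray(comp_y0[cat], dtype=float))
        for cat in FACILITY_CATEGORIES
    }
    delta_fac = sum(delta.values())
    defined = np.abs(delta_fac) > eps
    n_undefined = int((~defined).sum())
    if n_undefined:
        logger.warning(
            "change decomposition: %d draws with |facility change| <= %g excluded",
            n_undefined, eps,
        )
    share = {}
    for cat in FACILITY_CATEGORIES:
        s = np.full_like(delta_fac, np.nan)
        np.divide(delta[cat], delta_fac, out=s, where=defined)
        share[cat] = np.ma.masked_invalid(s)
    return {
        "pp_change": {cat: 100.0 * delta[cat] for cat in FACILITY_CATEGORIES},
        "pp_change_facility": 100.0 * delta_fac,
        "share_of_increase": share,
        "defined": defined,
        "n_undefined": n_undefined,
    }
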