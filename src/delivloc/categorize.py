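"""Standardise heterogeneous delivery-location survey responses.

Survey instruments record the place of delivery with free-text or
questionnaire-specific response options ("government hospital", "CSPS",
"private clinic", "home", ...). Downstream modelling needs each option
mapped onto a common frame:

* facility status — ``facility`` / ``non_facility`` / ``unknown``;
* level — ``hospital`` (CEmONC-capable: caesarean section and blood
  transfusion) vs ``lower`` (any other delivery facility), or
  ``unknown_level``;
* sector — ``public`` / ``private_for_profit`` / ``private_non_profit``
  ownership, or ``unknown_sector``.

Mapping is rule based: an ordered, case-insensitive keyword rulebook shipped
as package data, with per-country overrides taking precedence, plus a
caesarean-rate sorting step for options whose level the name does not
resolve (hospitals have much higher caesarean rates than lower-level
facilities). Because the private non-profit sector is small everywhere and
behaves like the public sector in cost and quality, the two are merged into
a single ``public_nfp`` sector for modelling.

Location-years only enter a model if enough of their facility births carry
the information that model needs: at least 85% with both level and sector
for the level-and-sector indicators, at least 95% with level for the
level-only indicators.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FACILITY_STATUSES",
    "LEVELS",
    "SECTORS",
    "MODELLING_SECTORS",
    "PROVENANCES",
    "ResponseOption",
    "CategoryAssignment",
    "Rule",
    "Rulebook",
    "InclusionThresholds",
    "load_default_rulebook",
    "classify_by_name",
    "classify_by_csection",
    "merge_nonprofit",
    "known_information_fractions",
    "inclusion_flags",
    "categorize_catalogue",
    "apply_csection_sorting",
]

FACILITY_STATUSES = ("facility", "non_facility", "unknown")
LEVELS = ("hospital", "lower", "unknown_level", "not_applicable")
SECTORS = (
    "public",
    "private_for_profit",
    "private_non_profit",
    "unknown_sector",
    "not_applicable",
)
MODELLING_SECTORS = ("public_nfp", "private_fp", "unknown_sector", "not_applicable")
PROVENANCES = (
    "name_rule",
    "country_literature",
    "csec_sort",
    "cross_survey_harmonised",
)

_WS = re.compile(r"\s+")


def _fold(label: str) -> str:
    """Case- and whitespace-fold a response label (no other normalisation)."""
    return _WS.sub(" ", str(label).strip().lower())


@dataclass(frozen=True)
class ResponseOption:
    """One delivery-location response option observed in one source."""

    label: str
    source_id: str
    location_id: str
    weighted_count: float
    csec_count: float = 0.0

    def __post_init__(self) -> None:
        if self.weighted_count < 0 or self.csec_count < 0:
            raise ValueError("counts must be non-negative")
        if self.csec_count > self.weighted_count + 1e-9:
            raise ValueError("csec_count cannot exceed weighted_count")


@dataclass(frozen=True)
class CategoryAssignment:
    """A (facility status, level, sector) triple attached to one option.

    Level and sector are ``not_applicable`` exactly when the option is not a
    health facility; each axis takes exactly one value.
    """

    facility_status: str
    level: str
    sector: str
    provenance: str = "name_rule"

    def __post_init__(self) -> None:
        if self.facility_status not in FACILITY_STATUSES:
            raise ValueError(f"bad facility_status {self.facility_status!r}")
        if self.level not in LEVELS:
            raise ValueError(f"bad level {self.level!r}")
        if self.sector not in SECTORS:
            raise ValueError(f"bad sector {self.sector!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"bad provenance {self.provenance!r}")
        is_fac = self.facility_status == "facility"
        if is_fac and ("not_applicable" in (self.level, self.sector)):
            raise ValueError("facility options need a level and sector category")
        if not is_fac and (self.level, self.sector) != ("not_applicable", "not_applicable"):
            raise ValueError("non-facility options must be not_applicable on both axes")


@dataclass(frozen=True)
class Rule:
    """One ordered rulebook entry: keyword pattern -> assignment."""

    pattern: str
    assignment: CategoryAssignment

    def matches(self, folded_label: str) -> bool:
        if self.pattern == "":
            return True
        pat = re.escape(_fold(self.pattern))
        return re.search(rf"(?<!\w){pat}(?!\w)", folded_label) is not None


_FALLBACK = CategoryAssignment("unknown", "not_applicable", "not_applicable")


@dataclass
class Rulebook:
    """Ordered keyword rules plus a (location, label) override table.

    The first matching rule wins; a country override beats every generic
    rule; a terminal empty-pattern rule guarantees every label resolves
    (to ``unknown`` in the shipped default).
    """

    rules: list[Rule]
    overrides: dict[tuple[str, str], CategoryAssignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rules or self.rules[-1].pattern != "":
            raise ValueError("rulebook must end with a catch-all (empty pattern) rule")

    @classmethod
    def from_dict(cls, obj: dict) -> "Rulebook":
        rules = [
            Rule(
                r["pattern"],
                CategoryAssignment(
                    r["facility_status"], r["level"], r["sector"], "name_rule"
                ),
            )
            for r in obj["rules"]
        ]
        overrides = {
            (str(o["location_id"]), _fold(o["label"])): CategoryAssignment(
                o["facility_status"],
                o["level"],
                o["sector"],
                o.get("provenance", "cross_survey_harmonised"),
            )
            for o in obj.get("overrides", [])
        }
        return cls(rules, overrides)

    @classmethod
    def from_json(cls, path) -> "Rulebook":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def load_default_rulebook() -> Rulebook:
    """Load the default rulebook shipped with the package."""
    text = resources.files("delivloc").joinpath("data/default_rulebook.json").read_text(
        encoding="utf-8"
    )
    return Rulebook.from_dict(json.loads(text))


def classify_by_name(label: str, location_id: str, rulebook: Rulebook) -> CategoryAssignment:
    """Classify one response label by keyword rules.

    Country overrides are checked first; otherwise the first matching rule
    in the ordered rulebook wins. The terminal catch-all guarantees a
    result, so this never raises for a valid rulebook.
    """
    folded = _fold(label)
    override = rulebook.overrides.get((str(location_id), folded))
    if override is not None:
        return override
    for rule in rulebook.rules:
        if rule.matches(folded):
            return rule.assignment
    return _FALLBACK  # unreachable with a valid rulebook


def classify_by_csection(
    option: ResponseOption,
    comparator_hospital_rate: float,
    comparator_lower_rate: float,
    min_weighted_count: float = 25.0,
) -> str:
    """Sort a level-ambiguous option into hospital/lower by caesarean rate.

    The option's caesarean rate is compared with the rates observed among
    options already known to be hospitals and lower-level facilities in the
    same source-location; the strictly nearer comparator wins. Ties, or an
    option with fewer than ``min_weighted_count`` weighted births, stay
    ``unknown_level``.
    """
    for r in (comparator_hospital_rate, comparator_lower_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("comparator rates must lie in [0, 1]")
    if option.weighted_count == 0:
        raise ValueError("cannot compute a caesarean rate for a zero-count option")
    if option.weighted_count < min_weighted_count:
        return "unknown_level"
    rate = option.csec_count / option.weighted_count
    d_hosp = abs(rate - comparator_hospital_rate)
    d_low = abs(rate - comparator_lower_rate)
    if abs(d_hosp - d_low) <= 1e-12:  # equidistant: stay unknown
        return "unknown_level"
    return "hospital" if d_hosp < d_low else "lower"


_MERGE = {
    "public": "public_nfp",
    "private_non_profit": "public_nfp",
    "private_for_profit": "private_fp",
    "unknown_sector": "unknown_sector",
    "not_applicable": "not_applicable",
    # already-merged values pass through, making the map idempotent
    "public_nfp": "public_nfp",
    "private_fp": "private_fp",
}


def merge_nonprofit(sector: str | CategoryAssignment) -> str:
    """Collapse ownership sectors to the two modelled ones.

    Private non-profit facilities are pooled with public ones
    (``public_nfp``); for-profit stays separate (``private_fp``). Unknown
    and not-applicable pass through. Idempotent.
    """
    if isinstance(sector, CategoryAssignment):
        sector = sector.sector
    try:
        return _MERGE[sector]
    except KeyError:
        raise ValueError(f"unknown sector {sector!r}") from None


def known_information_fractions(
    options: Iterable[tuple[ResponseOption, CategoryAssignment]],
) -> tuple[float, float]:
    """Weighted shares of facility births with known level/sector.

    Returns ``(f_both, f_level)``: the share of facility births whose
    assignment resolves both level and sector, and at least level,
    respectively. Computed over facility births only.
    """
    fac = both = lvl = 0.0
    for opt, asg in options:
        if asg.facility_status != "facility":
            continue
        fac += opt.weighted_count
        if asg.level != "unknown_level":
            lvl += opt.weighted_count
            if asg.sector != "unknown_sector":
                both += opt.weighted_count
    if fac <= 0:
        raise ValueError("no facility births to assess")
    return both / fac, lvl / fac


@dataclass(frozen=True)
class InclusionThresholds:
    """Minimum known-information shares for model inclusion (inclusive)."""

    tau_level_sector: float = 0.85
    tau_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.tau_level_sector <= self.tau_level <= 1:
            raise ValueError("need 0 < tau_level_sector <= tau_level <= 1")


def inclusion_flags(
    f_both: float,
    f_level: float,
    thresholds: InclusionThresholds = InclusionThresholds(),
) -> tuple[bool, bool]:
    """Model-inclusion flags from known-information fractions.

    ``in_level_sector_models`` requires at least 85% of facility births with
    both level and sector; ``in_level_models`` at least 95% with level.
    Comparisons are inclusive ("at least").
    """
    for f in (f_both, f_level):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    return f_both >= thresholds.tau_level_sector, f_level >= thresholds.tau_level


# ---------------------------------------------------------------------------
# table-level helpers used by the pipeline


def categorize_catalogue(catalogue: pd.DataFrame, rulebook: Rulebook) -> pd.DataFrame:
    """Attach assignments to a response-option catalogue.

    ``catalogue`` has one row per (source_id, location_id, label) with
    weighted_count and csec_count columns. Returns a copy with
    facility_status / level / sector / sector_m (merged) / provenance.
    """
    out = catalogue.copy()
    cols = {"facility_status": [], "level": [], "sector": [], "provenance": []}
    for loc, label in zip(out["location_id"], out["label"]):
        asg = classify_by_name(label, loc, rulebook)
        cols["facility_status"].append(asg.facility_status)
        cols["level"].append(asg.level)
        cols["sector"].append(asg.sector)
        cols["provenance"].append(asg.provenance)
    for k, v in cols.items():
        out[k] = v
    out["sector_m"] = [merge_nonprofit(s) for s in out["sector"]]
    return out


def apply_csection_sorting(
    catalogue: pd.DataFrame, min_weighted_count: float = 25.0
) -> pd.DataFrame:
    """Resolve unknown-level facility options by caesarean-rate sorting.

    Within each (source_id, location_id), comparator caesarean rates are the
    pooled rates of the options already classified hospital and lower; an
    unknown-level option is reassigned to the strictly nearer level. Skipped
    when either comparator is unavailable.
    """
    out = catalogue.copy()
    for (_, _), idx in out.groupby(["source_id", "location_id"]).groups.items():
        sub = out.loc[idx]
        known = sub[sub["facility_status"] == "facility"]
        hosp = known[known["level"] == "hospital"]
        low = known[known["level"] == "lower"]
        if hosp["weighted_count"].sum() <= 0 or low["weighted_count"].sum() <= 0:
            continue
        rate_h = hosp["csec_count"].sum() / hosp["weighted_count"].sum()
        rate_l = low["csec_count"].sum() / low["weighted_count"].sum()
        for i in sub.index[(sub["facility_status"] == "facility") & (sub["level"] == "unknown_level")]:
            row = out.loc[i]
            if row["weighted_count"] <= 0:
                continue
            opt = ResponseOption(
                row["label"], row["source_id"], row["location_id"],
                float(row["weighted_count"]), float(row["csec_count"]),
            )
            new = classify_by_csection(opt, rate_h, rate_l, min_weighted_count)
            if new != "unknown_level":
                out.loc[i, "level"] = new
                out.loc[i, "provenance"] = "csec_sort"
    return out
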