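"""End-to-end orchestration: simulate/load -> categorise -> prep -> six
ST-GPR fits -> envelope raking -> aggregation -> summaries -> change
decomposition, behind a single config with one root seed.

Every stage's randomness is a named substream of the root seed, so a rerun
with the same config reproduces byte-identical outputs. A manifest records
the config hash, row counts per stage and every warning emitted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import categorize as cz
from . import prep as pp
from . import rake_aggregate as ra
from . import stgpr as sg
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "make_table", "load_inputs"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Single configuration for a full pipeline run."""

    seed: int = 0
    n_draws: int = 1000
    simulate: bool = True
    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    inputs: dict = field(default_factory=dict)  # paths when simulate is False
    output_dir: str = "output"
    rulebook_path: str | None = None
    min_weighted_count: float = 25.0
    prep: pp.PrepConfig = field(default_factory=pp.PrepConfig)
    stgpr: sg.STGPRConfig = field(default_factory=sg.STGPRConfig)
    table_year: int | None = None
    write_draws: bool = True
    save_inputs: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        obj = dict(obj)
        if "simulation" in obj and isinstance(obj["simulation"], dict):
            obj["simulation"] = sd.SimulationConfig(**obj["simulation"])
        if "prep" in obj and isinstance(obj["prep"], dict):
            obj["prep"] = pp.PrepConfig(**obj["prep"])
        if "stgpr" in obj and isinstance(obj["stgpr"], dict):
            obj["stgpr"] = sg.STGPRConfig(**obj["stgpr"])
        unknown = set(obj) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        msg = record.getMessage()
        if msg not in self.messages:
            self.messages.append(msg)


def load_inputs(paths: dict) -> sd.SyntheticWorld:
    """Load pipeline inputs from CSV files (schema of emit_fixtures)."""
    for key in ("hierarchy", "births", "covariates", "envelope", "microdata"):
        if key not in paths:
            raise ValueError(f"config missing input path: {key!r}")
        if not os.path.exists(paths[key]):
            raise FileNotFoundError(paths[key])
    hierarchy = sg.Hierarchy(pd.read_csv(paths["hierarchy"]), pd.read_csv(paths["births"]))
    cov = (
        pd.read_csv(paths["covariates"])
        .pivot(index=["location_id", "year"], columns="name", values="value")
        .reset_index()
    )
    cov.columns.name = None
    truth = pd.read_csv(paths["truth"]) if "truth" in paths and os.path.exists(
        paths.get("truth", "")
    ) else None
    return sd.SyntheticWorld(
        sd.SimulationConfig(),
        hierarchy,
        cov,
        truth,
        pd.read_csv(paths["envelope"]),
        pd.read_csv(paths["microdata"]),
    )


def _categorize_microdata(
    microdata: pd.DataFrame, rulebook: cz.Rulebook, min_weighted_count: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label -> category assignment for every microdata row.

    Builds the response-option catalogue, applies name rules, caesarean
    sorting and the non-profit merge, and joins the result back to rows.
    """
    md = microdata.copy()
    md["_wcsec"] = md["weight"] * md["csec"]
    catalogue = (
        md.groupby(["source_id", "location_id", "response_label"], as_index=False)
        .agg(weighted_count=("weight", "sum"), csec_count=("_wcsec", "sum"))
        .rename(columns={"response_label": "label"})
    )
    catalogue = cz.categorize_catalogue(catalogue, rulebook)
    catalogue = cz.apply_csection_sorting(catalogue, min_weighted_count)
    merged = md.merge(
        catalogue[
            ["source_id", "location_id", "label",
             "facility_status", "level", "sector", "sector_m", "provenance"]
        ],
        left_on=["source_id", "location_id", "response_label"],
        right_on=["source_id", "location_id", "label"],
        how="left",
    ).drop(columns=["label", "_wcsec"])
    return merged, catalogue


def _envelope_draws(envelope: pd.DataFrame, n_draws: int) -> dict[str, np.ndarray]:
    """Per-location (n_years, n_draws) envelope arrays from the wide frame."""
    draw_cols = [c for c in envelope.columns if c.startswith("draw_")]
    if not draw_cols:
        raise ValueError("envelope file has no draw_ columns")
    out = {}
    for loc, sub in envelope.groupby("location_id", sort=True):
        arr = sub.sort_values("year")[draw_cols].to_numpy(dtype=float)
        if arr.shape[1] == 1 and n_draws > 1:
            logger.warning("envelope for %s supplied as mean only; replicating", loc)
            arr = np.repeat(arr, n_draws, axis=1)
        elif arr.shape[1] < n_draws:
            raise ValueError(
                f"envelope has {arr.shape[1]} draws < requested {n_draws}"
            )
        out[str(loc)] = arr[:, :n_draws]
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest."""
    collector = _WarningCollector()
    logging.getLogger("delivloc").addHandler(collector)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    try:
        os.makedirs(config.output_dir, exist_ok=True)

        # ------------------------------------------------------ inputs
        if config.simulate:
            sim = replace(config.simulation, seed=config.seed)
            world = sd.simulate_world(sim, n_envelope_draws=config.n_draws)
            if config.save_inputs:
                sd.emit_fixtures(world, os.path.join(config.output_dir, "inputs"))
        else:
            world = load_inputs(config.inputs)
        hierarchy = world.hierarchy
        years = np.sort(world.covariates["year"].unique())
        manifest["stages"]["inputs"] = {
            "locations": len(hierarchy.locations),
            "years": int(len(years)),
            "microdata_rows": len(world.microdata),
        }

        # -------------------------------------------------- categorize
        rulebook = (
            cz.Rulebook.from_json(config.rulebook_path)
            if config.rulebook_path
            else cz.load_default_rulebook()
        )
        microdata, catalogue = _categorize_microdata(
            world.microdata, rulebook, config.min_weighted_count
        )
        catalogue.sort_values(["source_id", "location_id", "label"]).to_csv(
            os.path.join(config.output_dir, "assignments.csv"),
            index=False, float_format=_FLOAT_FMT,
        )
        manifest["stages"]["categorize"] = {
            "options": len(catalogue),
            "csec_sorted": int((catalogue["provenance"] == "csec_sort").sum()),
        }

        # --------------------------------------------------------- prep
        data = pp.tabulate_proportions(microdata, config.prep)
        data.sort_values(["location_id", "year", "indicator", "source_id"]).to_csv(
            os.path.join(config.output_dir, "data.csv"),
            index=False, float_format=_FLOAT_FMT,
        )
        manifest["stages"]["prep"] = {
            "data_rows": len(data),
            "location_years": int(
                data.groupby(["location_id", "year"]).ngroups
            ),
        }

        # -------------------------------------------------------- stgpr
        stgpr_cfg = replace(config.stgpr, seed=config.seed, n_draws=config.n_draws)
        results: dict[str, sg.STGPRResult] = {}
        for ind in pp.INDICATORS:
            flag = (
                "in_level_models" if ind in pp.LEVEL_INDICATORS
                else "in_level_sector_models"
            )
            sub = data[(data["indicator"] == ind) & data[flag]].copy()
            sub["y"] = pp.to_model_space(sub["p"], config.prep.clamp)
            sub["var_y"] = pp.model_space_variance(
                sub["p"], sub["var_sampling"], config.prep.clamp
            )
            results[ind] = sg.run_stgpr(
                ind, sub[["location_id", "year", "y", "var_y", "source_id"]],
                world.covariates, hierarchy, stgpr_cfg, years,
            )
            if config.write_draws:
                _write_draws(
                    results[ind], years,
                    os.path.join(config.output_dir, f"draws_{ind}.csv"),
                )
        manifest["stages"]["stgpr"] = {
            ind: {"data_rows": int((data["indicator"] == ind).sum())}
            for ind in pp.INDICATORS
        }

        # --------------------------------------------------------- rake
        env = _envelope_draws(world.envelope, config.n_draws)
        composition: dict[str, dict[str, np.ndarray]] = {c: {} for c in ra.CATEGORIES}
        for loc in map(str, hierarchy.location_ids):
            built = ra.build_composition(
                (results["hosp"].draws[loc], results["low"].draws[loc]),
                (
                    results["pub_hosp"].draws[loc],
                    results["priv_hosp"].draws[loc],
                    results["pub_low"].draws[loc],
                    results["priv_low"].draws[loc],
                ),
                env[loc],
            )
            for cat in ra.CATEGORIES:
                composition[cat][loc] = built[cat]

        # ---------------------------------------------------- aggregate
        members: dict[str, list[str]] = {"global": list(map(str, hierarchy.location_ids))}
        for rid, g in hierarchy.locations.groupby("region_id"):
            members[str(rid)] = list(map(str, g["location_id"]))
        for sid, g in hierarchy.locations.groupby("super_region_id"):
            members[str(sid)] = list(map(str, g["location_id"]))
        births_by_loc = {
            str(loc): g.sort_values("year")["births"].to_numpy(dtype=float)
            for loc, g in hierarchy.births.groupby("location_id")
        }
        aggregates = ra.aggregate_regions(composition, members, births_by_loc)

        # ---------------------------------------------------- summarise
        level_of = dict.fromkeys(map(str, hierarchy.location_ids), "country")
        level_of.update(
            dict.fromkeys(map(str, hierarchy.locations["region_id"].unique()), "region")
        )
        level_of.update(
            dict.fromkeys(
                map(str, hierarchy.locations["super_region_id"].unique()),
                "super_region",
            )
        )
        level_of["global"] = "global"

        rows = []
        everything = {
            cat: {**composition[cat], **aggregates[cat]} for cat in ra.CATEGORIES
        }
        for cat in ra.CATEGORIES:
            for loc in sorted(everything[cat]):
                mean, lower, upper = ra.summarize(everything[cat][loc], axis=-1)
                for j, year in enumerate(years):
                    rows.append(
                        {
                            "level": level_of[loc],
                            "location_id": loc,
                            "year": int(year),
                            "category": cat,
                            "mean": mean[j],
                            "lower": lower[j],
                            "upper": upper[j],
                        }
                    )
        summary = pd.DataFrame(rows).sort_values(
            ["level", "location_id", "category", "year"], kind="stable"
        )
        summary.to_csv(
            os.path.join(config.output_dir, "summary.csv"),
            index=False, float_format=_FLOAT_FMT,
        )
        manifest["stages"]["summarize"] = {"rows": len(summary)}

        # -------------------------------------------------------- table
        table_year = int(config.table_year or years.max())
        table = make_table(summary, table_year)
        table.to_csv(os.path.join(config.output_dir, f"table_{table_year}.csv"), index=False)

        # --------------------------------------------- change decomposition
        y0, y1 = int(years.min()), int(years.max())
        i0, i1 = int(np.where(years == y0)[0][0]), int(np.where(years == y1)[0][0])
        dec_rows = []
        for loc in sorted(k for k in everything["pub_hosp"] if level_of[k] != "country"):
            comp0 = {c: everything[c][loc][i0] for c in ra.CATEGORIES}
            comp1 = {c: everything[c][loc][i1] for c in ra.CATEGORIES}
            dec = ra.decompose_change(comp0, comp1)
            fac_m, fac_l, fac_u = ra.summarize(dec["pp_change_facility"])
            for cat in ra.FACILITY_CATEGORIES:
                m, l, u = ra.summarize(dec["pp_change"][cat])
                share = dec["share_of_increase"][cat]
                sdef = np.asarray(share[dec["defined"]])
                if sdef.size >= 2:
                    sm, sl, su = ra.summarize(sdef)
                else:
                    sm = sl = su = np.nan
                dec_rows.append(
                    {
                        "location_id": loc,
                        "category": cat,
                        "year0": y0,
                        "year1": y1,
                        "pp_change_mean": m,
                        "pp_change_lower": l,
                        "pp_change_upper": u,
                        "facility_pp_change_mean": fac_m,
                        "facility_pp_change_lower": fac_l,
                        "facility_pp_change_upper": fac_u,
                        "share_of_increase_mean": sm,
                        "share_of_increase_lower": sl,
                        "share_of_increase_upper": su,
                        "n_undefined_draws": dec["n_undefined"],
                    }
                )
        pd.DataFrame(dec_rows).sort_values(["location_id", "category"]).to_csv(
            os.path.join(config.output_dir, "change_decomposition.csv"),
            index=False, float_format=_FLOAT_FMT,
        )

        manifest["warnings"] = list(collector.messages)
        manifest["status"] = "complete"
    except Exception as exc:  # fail fast, but say where
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        manifest["warnings"] = list(collector.messages)
        _write_manifest(manifest, config.output_dir)
        raise
    finally:
        logging.getLogger("delivloc").removeHandler(collector)

    _write_manifest(manifest, config.output_dir)
    return manifest


def _write_manifest(manifest: dict, output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    with open(os.path.join(output_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _write_draws(result: sg.STGPRResult, years, path: str) -> None:
    records = []
    for loc in sorted(result.draws):
        arr = result.draws[loc]
        for j, year in enumerate(years):
            records.append(
                {"location_id": loc, "year": int(year),
                 **{f"draw_{d + 1}": arr[j, d] for d in range(arr.shape[1])}}
            )
    pd.DataFrame(records).to_csv(path, index=False, float_format=_FLOAT_FMT)


def make_table(summary: pd.DataFrame, year: int) -> pd.DataFrame:
    """Report table for one year: one row per location, five category
    columns formatted "mean (lower-upper)" in percent with one decimal.

    Includes countries, regions and the global row (super-regions stay in
    the raw summary).
    """
    sub = summary[
        (summary["year"] == year) & summary["level"].isin(["country", "region", "global"])
    ]
    if sub.empty:
        raise ValueError(f"no summary rows for year {year}")

    def fmt(r):
        return (
            f"{100 * r['mean']:.1f} ({100 * r['lower']:.1f}–{100 * r['upper']:.1f})"
        )

    rows = []
    order = {"global": 0, "region": 1, "country": 2}
    for (lvl, loc), g in sub.groupby(["level", "location_id"]):
        row = {"level": lvl, "location_id": loc, "year": year}
        for cat in ra.CATEGORIES:
            r = g[g["category"] == cat].iloc[0]
            row[cat] = fmt(r)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["_o"] = out["level"].map(order)
    out = out.sort_values(["_o", "location_id"]).drop(columns="_o").reset_index(drop=True)
    return out
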