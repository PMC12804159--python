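"""The synthetic world: valid compositions, dialect/rulebook consistency,
reproducibility, covariate signal, and fixture round-trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import delivloc as dl
from delivloc.synthetic_data import (
    DIALECT_CATALOGUE,
    TRUTH_CATEGORIES,
    SimulationConfig,
    emit_fixtures,
    read_fixtures,
    simulate_covariates,
    simulate_survey,
    simulate_truth,
    simulate_world,
)


def test_truth_compositions_valid(tiny_world):
    truth = tiny_world.truth
    total = sum(truth[c] for c in TRUTH_CATEGORIES)
    assert np.max(np.abs(total - 1.0)) < 1e-12
    for c in TRUTH_CATEGORIES:
        assert truth[c].between(0, 1).all()
    assert np.allclose(truth["envelope"], 1.0 - truth["non_facility"])
    assert np.allclose(truth["hosp"], truth["pub_hosp"] + truth["priv_hosp"])


def test_truth_smooth_in_time(tiny_world):
    truth = tiny_world.truth.sort_values(["location_id", "year"])
    for c in TRUTH_CATEGORIES:
        steps = truth.groupby("location_id")[c].diff().dropna().abs()
        assert steps.max() < 0.05  # under 5 pp per year by construction


def test_truth_reproducible(tiny_config):
    t1 = simulate_truth(tiny_config)
    t2 = simulate_truth(tiny_config)
    pd.testing.assert_frame_equal(t1, t2)


def test_config_rejects_inverted_csec_rates():
    with pytest.raises(ValueError, match="caesarean"):
        SimulationConfig(csec_rate_hospital=0.02, csec_rate_lower=0.10)


def test_covariates_track_facility_latent(tiny_config):
    truth = simulate_truth(tiny_config)
    quiet = dataclasses.replace(tiny_config, covariate_noise=1e-9)
    cov = simulate_covariates(truth, quiet)
    rho = np.corrcoef(cov["dev_index"], truth["envelope"])[0, 1]
    assert rho > 0.99
    noisy = dataclasses.replace(tiny_config, covariate_noise=1e6)
    cov_n = simulate_covariates(truth, noisy)
    rho_n = np.corrcoef(cov_n["dev_index"], truth["envelope"])[0, 1]
    assert abs(rho_n) < 0.1


def test_dialect_catalogue_consistent_with_rulebook(rulebook):
    """Every generated label must resolve to its intended class."""
    expectations = {
        "pub_hosp": ("facility", "hospital", "public"),
        "nonprofit_hosp": ("facility", "hospital", "private_non_profit"),
        "priv_hosp": ("facility", "hospital", "private_for_profit"),
        "pub_low": ("facility", "lower", "public"),
        "nonprofit_low": ("facility", "lower", "private_non_profit"),
        "priv_low": ("facility", "lower", "private_for_profit"),
        "hosp_sector_unknown": ("facility", "hospital", "unknown_sector"),
        "low_sector_unknown": ("facility", "lower", "unknown_sector"),
        "level_unknown": ("facility", "unknown_level", "unknown_sector"),
        "csec_resolvable_hosp": ("facility", "unknown_level", "unknown_sector"),
        "csec_resolvable_low": ("facility", "unknown_level", "unknown_sector"),
        "non_facility": ("non_facility", "not_applicable", "not_applicable"),
        "unknown": ("unknown", "not_applicable", "not_applicable"),
    }
    for cls, labels in DIALECT_CATALOGUE.items():
        for label in labels:
            a = dl.classify_by_name(label, "anywhere", rulebook)
            assert (a.facility_status, a.level, a.sector) == expectations[cls], label


def test_survey_no_unknowns_gives_full_information(tiny_config, rulebook):
    from delivloc.stgpr import substream

    cfg = dataclasses.replace(
        tiny_config, unknown_level_rate=0.0, unknown_sector_rate=0.0,
        missing_rate=0.0,
    )
    truth = simulate_truth(cfg)
    md = simulate_survey(truth, "C000", 2010, cfg, substream(0, "t"))
    from delivloc.pipeline import _categorize_microdata

    rows, _ = _categorize_microdata(md, rulebook, 25.0)
    fac = rows[rows["facility_status"] == "facility"]
    assert (fac["level"] != "unknown_level").all()
    assert (fac["sector"] != "unknown_sector").all()


def test_survey_proportions_converge_to_truth(tiny_config):
    from delivloc.stgpr import substream

    cfg = dataclasses.replace(tiny_config, births_per_survey=200_000)
    truth = simulate_truth(cfg)
    md = simulate_survey(truth, "C000", 2010, cfg, substream(1, "t"))
    t = truth[truth["location_id"] == "C000"].set_index("year")
    for year, sub in md.groupby("birth_year"):
        non_fac_labels = set(DIALECT_CATALOGUE["non_facility"])
        share = (
            sub["response_label"].isin(non_fac_labels).astype(float)
            * sub["weight"]
        ).sum() / sub["weight"].sum()
        expected = t.loc[year, "non_facility"] * (1 - cfg.missing_rate)
        assert share == pytest.approx(expected, abs=0.005)


def test_survey_csec_rates_ordered(tiny_config):
    from delivloc.stgpr import substream

    cfg = dataclasses.replace(tiny_config, births_per_survey=20_000)
    truth = simulate_truth(cfg)
    md = simulate_survey(truth, "C000", 2010, cfg, substream(2, "t"))
    hosp_labels = set(
        DIALECT_CATALOGUE["pub_hosp"] + DIALECT_CATALOGUE["priv_hosp"]
        + DIALECT_CATALOGUE["nonprofit_hosp"] + DIALECT_CATALOGUE["hosp_sector_unknown"]
    )
    low_labels = set(
        DIALECT_CATALOGUE["pub_low"] + DIALECT_CATALOGUE["priv_low"]
        + DIALECT_CATALOGUE["nonprofit_low"] + DIALECT_CATALOGUE["low_sector_unknown"]
    )
    hosp = md[md["response_label"].isin(hosp_labels)]
    low = md[md["response_label"].isin(low_labels)]
    assert hosp["csec"].mean() > low["csec"].mean()
    assert hosp["csec"].mean() == pytest.approx(cfg.csec_rate_hospital, abs=0.02)


def test_survey_recall_window_and_precondition(tiny_config):
    from delivloc.stgpr import substream

    truth = simulate_truth(tiny_config)
    md = simulate_survey(truth, "C000", 2008, tiny_config, substream(3, "t"))
    assert set(md["birth_year"]) == set(range(2004, 2009))
    with pytest.raises(ValueError):
        simulate_survey(truth, "C000", tiny_config.year_start + 4,
                        tiny_config, substream(3, "t"))


def test_world_reproducible_bit_for_bit(tiny_config):
    w1 = simulate_world(tiny_config, n_envelope_draws=10)
    w2 = simulate_world(tiny_config, n_envelope_draws=10)
    pd.testing.assert_frame_equal(w1.microdata, w2.microdata)
    pd.testing.assert_frame_equal(w1.envelope, w2.envelope)
    pd.testing.assert_frame_equal(w1.covariates, w2.covariates)


def test_emit_fixtures_round_trip_and_determinism(tiny_world, tmp_path):
    d1 = tmp_path / "a"
    paths = emit_fixtures(tiny_world, d1)
    assert set(paths) == {"hierarchy", "births", "covariates", "envelope",
                          "microdata", "truth"}
    back = read_fixtures(d1)
    pd.testing.assert_frame_equal(
        back.hierarchy.locations, tiny_world.hierarchy.locations
    )
    pd.testing.assert_frame_equal(back.microdata, tiny_world.microdata)
    got = back.covariates.sort_values(["location_id", "year"]).reset_index(drop=True)
    want = tiny_world.covariates[got.columns].sort_values(
        ["location_id", "year"]
    ).reset_index(drop=True)
    pd.testing.assert_frame_equal(got, want)

    # expected row counts from the config
    cfg = tiny_world.config
    n_loc_years = cfg.n_countries * len(cfg.years)
    assert len(tiny_world.truth) == n_loc_years
    assert len(tiny_world.envelope) == n_loc_years
    assert len(tiny_world.hierarchy.births) == n_loc_years

    # byte determinism
    d2 = tmp_path / "b"
    emit_fixtures(tiny_world, d2)
    for name in paths:
        assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()
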