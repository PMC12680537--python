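"""Two-step human travel-demand estimation: harmonize, impute, combine."""

import numpy as np
import pandas as pd
import pytest

from biomove import mobility as mob
from biomove.errors import InvalidArgumentError, UndefinedValueError
from biomove.synthetic import CountryTableConfig, ModeDemandParams, gen_country_table


def tiny_countries():
    return pd.DataFrame({
        "country_id": ["A", "B", "C", "D"],
        "income_group": ["high", "high", "low", "low"],
        "population": [1e7, 2e7, 5e7, 1e8],
        "gdp_per_capita": [50000.0, 40000.0, 800.0, 600.0],
    })


class TestHarmonize:
    def test_unit_conversions(self):
        raw = pd.DataFrame([
            {"country_id": "A", "mode": "road", "quantity": 1000.0,
             "unit": "km_per_capita_yr"},
            {"country_id": "B", "mode": "road", "quantity": 2e10,
             "unit": "pkm_total_yr"},
            {"country_id": "C", "mode": "walk_cycle", "quantity": 2.0,
             "unit": "km_per_capita_day"},
        ])
        out = mob.harmonize(raw, tiny_countries()).set_index("country_id")
        assert out.loc["A", "per_capita_km_yr"] == 1000.0
        assert out.loc["B", "per_capita_km_yr"] == pytest.approx(1000.0)  # 2e10 / 2e7
        assert out.loc["C", "per_capita_km_yr"] == pytest.approx(730.0)
        assert (out["status"] == "reported").all()

    def test_unknown_unit_rejected_with_log(self, caplog):
        raw = pd.DataFrame([
            {"country_id": "A", "mode": "road", "quantity": 1.0, "unit": "furlongs"},
            {"country_id": "B", "mode": "road", "quantity": 10.0,
             "unit": "km_per_capita_yr"},
        ])
        with caplog.at_level("WARNING"):
            out = mob.harmonize(raw, tiny_countries())
        assert len(out) == 1
        assert "unknown unit" in caplog.text

    def test_duplicates_averaged(self):
        raw = pd.DataFrame([
            {"country_id": "A", "mode": "road", "quantity": 100.0,
             "unit": "km_per_capita_yr"},
            {"country_id": "A", "mode": "road", "quantity": 300.0,
             "unit": "km_per_capita_yr"},
        ])
        out = mob.harmonize(raw, tiny_countries())
        assert len(out) == 1
        assert out["per_capita_km_yr"].iloc[0] == 200.0

    def test_synthetic_truth_recovered(self):
        cb = gen_country_table(3)
        rep = mob.harmonize(cb.data["raw_demand"], cb.data["countries"])
        truth = cb.truth["full_demand"]
        merged = rep.merge(truth[~truth["masked"]], on=["country_id", "mode"],
                           suffixes=("", "_truth"))
        assert len(merged) == len(rep)
        assert np.allclose(merged["per_capita_km_yr"],
                           merged["per_capita_km_yr_truth"], rtol=1e-9)


class TestGroupMeanImputation:
    def test_no_gaps_is_identity(self):
        demand = pd.DataFrame({
            "country_id": ["A", "B", "C", "D"] * 4,
            "mode": np.repeat(list(mob.MODES), 4),
            "per_capita_km_yr": np.arange(16, dtype=float),
            "status": "reported",
        })
        out = mob.impute_group_mean(demand, tiny_countries())
        merged = out.merge(demand, on=["country_id", "mode"], suffixes=("", "_in"))
        assert (merged["per_capita_km_yr"] == merged["per_capita_km_yr_in"]).all()
        assert (out["status"] == "reported").all()

    def test_single_gap_gets_group_value(self):
        demand = pd.DataFrame({
            "country_id": ["A", "C", "D"],
            "mode": "road",
            "per_capita_km_yr": [1000.0, 50.0, 50.0],
            "status": "reported",
        })
        countries = tiny_countries()
        out = mob.impute_group_mean(demand[demand["mode"] == "road"], countries)
        row = out[(out["country_id"] == "B") & (out["mode"] == "road")]
        # B is high income; its only reported peer A has 1000
        assert row["per_capita_km_yr"].iloc[0] == 1000.0
        assert row["status"].iloc[0] == "imputed_group_mean"

    def test_population_weighted_mean(self):
        demand = pd.DataFrame({
            "country_id": ["C", "D"],
            "mode": "rail",
            "per_capita_km_yr": [300.0, 600.0],
            "status": "reported",
        })
        countries = tiny_countries().iloc[2:]  # low-income pair only
        countries = pd.concat([countries, pd.DataFrame([{
            "country_id": "E", "income_group": "low", "population": 1e6,
            "gdp_per_capita": 500.0}])], ignore_index=True)
        out = mob.impute_group_mean(demand, countries)
        row = out[out["country_id"] == "E"]
        expected = (300.0 * 5e7 + 600.0 * 1e8) / 1.5e8
        assert row[row["mode"] == "rail"]["per_capita_km_yr"].iloc[0] == pytest.approx(expected)

    def test_empty_group_errors_with_name(self):
        demand = pd.DataFrame({
            "country_id": ["A"], "mode": ["road"],
            "per_capita_km_yr": [100.0], "status": ["reported"],
        })
        with pytest.raises(UndefinedValueError, match="low.*road"):
            mob.impute_group_mean(demand, tiny_countries())


class TestGdpModel:
    def test_noiseless_elasticity_exact(self):
        countries = tiny_countries()
        demand = pd.DataFrame({
            "country_id": countries["country_id"],
            "mode": "road",
            "per_capita_km_yr": 0.5 * countries["gdp_per_capita"] ** 1.0,
            "status": "reported",
        })
        m = mob.fit_gdp_model(demand, countries, "road")
        assert m.elasticity == pytest.approx(1.0, abs=1e-9)
        assert np.exp(m.intercept) == pytest.approx(0.5, rel=1e-9)

    def test_prediction_monotone_in_gdp(self):
        countries = tiny_countries()
        demand = pd.DataFrame({
            "country_id": countries["country_id"],
            "mode": "air",
            "per_capita_km_yr": 0.01 * countries["gdp_per_capita"] ** 1.2,
            "status": "reported",
        })
        m = mob.fit_gdp_model(demand, countries, "air")
        g = np.array([500.0, 5e3, 5e4])
        pred = m.predict(g)
        assert np.all(np.diff(pred) > 0)

    def test_degenerate_design_rejected(self):
        countries = tiny_countries()
        countries["gdp_per_capita"] = 1000.0
        demand = pd.DataFrame({
            "country_id": countries["country_id"], "mode": "road",
            "per_capita_km_yr": [1.0, 2.0, 3.0, 4.0], "status": "reported",
        })
        with pytest.raises(InvalidArgumentError, match="degenerate"):
            mob.fit_gdp_model(demand, countries, "road")

    def test_too_few_countries_rejected(self):
        countries = tiny_countries()
        demand = pd.DataFrame({
            "country_id": ["A", "B"], "mode": "road",
            "per_capita_km_yr": [1.0, 2.0], "status": "reported",
        })
        with pytest.raises(InvalidArgumentError, match=">= 3"):
            mob.fit_gdp_model(demand, countries, "road")


class TestCombine:
    def _reported(self):
        return pd.DataFrame({
            "country_id": ["A", "B"], "mode": "road",
            "per_capita_km_yr": [100.0, 200.0], "status": "reported",
        })

    def test_no_gaps_total_is_reported_total(self):
        rep = self._reported()
        out = mob.combine(rep, rep, rep)
        assert out["per_capita_km_yr"].sum() == 300.0

    def test_agreeing_models_pass_through(self):
        rep = self._reported()
        fill = pd.DataFrame({
            "country_id": ["C"], "mode": "road",
            "per_capita_km_yr": [40.0], "status": "imputed_group_mean",
        })
        fill2 = fill.assign(status="imputed_regression")
        out = mob.combine(rep, pd.concat([rep, fill]), pd.concat([rep, fill2]))
        c = out[out["country_id"] == "C"]
        assert c["per_capita_km_yr"].iloc[0] == 40.0
        assert c["status"].iloc[0] == "combined"

    def test_models_averaged_on_gaps(self):
        rep = self._reported()
        f1 = pd.DataFrame({"country_id": ["C"], "mode": "road",
                           "per_capita_km_yr": [40.0], "status": "imputed_group_mean"})
        f2 = pd.DataFrame({"country_id": ["C"], "mode": "road",
                           "per_capita_km_yr": [60.0], "status": "imputed_regression"})
        out = mob.combine(rep, pd.concat([rep, f1]), pd.concat([rep, f2]))
        assert out[out["country_id"] == "C"]["per_capita_km_yr"].iloc[0] == 50.0

    def test_coverage_mismatch_names_offenders(self):
        rep = self._reported()
        f1 = pd.DataFrame({"country_id": ["C"], "mode": "road",
                           "per_capita_km_yr": [40.0], "status": "imputed_group_mean"})
        with pytest.raises(InvalidArgumentError, match="mismatch"):
            mob.combine(rep, pd.concat([rep, f1]), rep)

    def test_reported_values_bit_identical_end_to_end(self):
        cb = gen_country_table(5)
        rep = mob.harmonize(cb.data["raw_demand"], cb.data["countries"])
        est = mob.two_step_estimate(rep, cb.data["countries"])
        merged = est.demand[est.demand["status"] == "reported"].merge(
            rep, on=["country_id", "mode"], suffixes=("", "_orig"))
        assert len(merged) == len(rep)
        assert (merged["per_capita_km_yr"] == merged["per_capita_km_yr_orig"]).all()

    def test_combined_total_at_least_reported(self):
        cb = gen_country_table(6)
        rep = mob.harmonize(cb.data["raw_demand"], cb.data["countries"])
        est = mob.two_step_estimate(rep, cb.data["countries"])
        reported_only = mob.to_biomass_movement(rep, cb.data["countries"])
        assert est.total_gt_km_yr.mean >= reported_only


class TestBiomassConversion:
    def test_linear_in_body_mass(self):
        countries = tiny_countries()
        demand = pd.DataFrame({
            "country_id": ["A"], "mode": ["road"],
            "per_capita_km_yr": [1000.0], "status": ["reported"],
        })
        base = mob.to_biomass_movement(demand, countries)
        heavy = countries.assign(avg_body_mass_kg=108.0)
        assert mob.to_biomass_movement(demand, heavy) == pytest.approx(2 * base)

    def test_global_scale(self):
        # 8e9 people x 13,700 km/yr x 54 kg -> ~5,900 Gt km/yr
        countries = pd.DataFrame({
            "country_id": ["W"], "income_group": ["high"],
            "population": [8e9], "gdp_per_capita": [12000.0],
        })
        demand = pd.DataFrame({"country_id": ["W"], "mode": ["road"],
                               "per_capita_km_yr": [13700.0], "status": ["reported"]})
        gt = mob.to_biomass_movement(demand, countries)
        assert gt == pytest.approx(5918.4, rel=1e-6)

    def test_zero_demand(self):
        countries = tiny_countries()
        demand = pd.DataFrame({"country_id": ["A"], "mode": ["road"],
                               "per_capita_km_yr": [0.0], "status": ["reported"]})
        assert mob.to_biomass_movement(demand, countries) == 0.0


class TestSummaries:
    def test_single_mode_world(self):
        countries = tiny_countries()
        demand = pd.DataFrame({
            "country_id": countries["country_id"], "mode": "road",
            "per_capita_km_yr": 1000.0, "status": "reported",
        })
        est = mob.estimate(demand, countries)
        s = mob.summaries(est, countries)
        assert s.mode_shares_pct == {"road": 100.0}

    def test_shares_sum_to_100(self):
        cb = gen_country_table(4)
        rep = mob.harmonize(cb.data["raw_demand"], cb.data["countries"])
        est = mob.two_step_estimate(rep, cb.data["countries"])
        s = mob.summaries(est, cb.data["countries"])
        assert sum(s.mode_shares_pct.values()) == pytest.approx(100.0)
        assert sum(s.income_shares_pct.values()) == pytest.approx(100.0)
        assert sum(s.population_shares_pct.values()) == pytest.approx(100.0)

    def test_variants_ordered(self):
        cb = gen_country_table(2)
        rep = mob.harmonize(cb.data["raw_demand"], cb.data["countries"])
        est = mob.two_step_estimate(rep, cb.data["countries"])
        uv = est.total_gt_km_yr
        assert uv.low <= uv.mean <= uv.high
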