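"""Human biomass movement from per-country travel-demand tables.

Two-step estimation: (1) harmonize heterogeneous reported passenger-km
data to per-capita km per year for each country and transport mode;
(2) fill the gaps with the average of two models — extrapolating the
population-weighted per-capita mean of each World Bank income group, and
a per-mode log-log regression of per-capita demand on GDP per capita —
then convert person-km to biomass movement with an average body mass
(54 kg globally by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidArgumentError, UndefinedValueError
from .uncertain import Basis, UncertainValue
from .units import UNITS, UnitConventions

logger = logging.getLogger(__name__)

INCOME_GROUPS = ("high", "upper_middle", "lower_middle", "low")
MODES = ("road", "rail", "air", "walk_cycle")
DEFAULT_BODY_MASS_KG = 54.0

#: Units accepted by :func:`harmonize` and their conversion to per-capita km/yr.
#: ``pkm_total_yr`` additionally divides by national population.
KNOWN_UNITS = ("km_per_capita_yr", "km_per_capita_day", "pkm_total_yr")

#: Default low/high multipliers per entry status for scenario variants.
DEFAULT_SCENARIOS: Mapping[str, Tuple[float, float]] = {
    "reported": (0.9, 1.15),
    "combined": (0.5, 1.6),
}


def validate_countries(countries: pd.DataFrame) -> pd.DataFrame:
    req = {"country_id", "income_group", "population", "gdp_per_capita"}
    missing = req - set(countries.columns)
    if missing:
        raise InvalidArgumentError(f"countries table missing columns: {sorted(missing)}")
    bad = countries[~countries["income_group"].isin(INCOME_GROUPS)]
    if len(bad):
        raise InvalidArgumentError(f"unknown income groups: {bad['income_group'].unique()}")
    if (countries["population"] <= 0).any() or (countries["gdp_per_capita"] <= 0).any():
        raise InvalidArgumentError("population and gdp_per_capita must be > 0")
    out = countries.copy()
    if "avg_body_mass_kg" not in out.columns:
        out["avg_body_mass_kg"] = DEFAULT_BODY_MASS_KG
    out["avg_body_mass_kg"] = out["avg_body_mass_kg"].fillna(DEFAULT_BODY_MASS_KG)
    return out


def harmonize(
    raw: pd.DataFrame,
    countries: pd.DataFrame,
    duplicate_policy: str = "mean",
    units: UnitConventions = UNITS,
) -> pd.DataFrame:
    """Express raw demand rows as per-capita km/yr; reject unknown units.

    Returns a frame with columns country_id, mode, per_capita_km_yr,
    status='reported'. Unresolvable rows are dropped with a logged reason,
    duplicates resolved per ``duplicate_policy`` ('mean'|'first'|'error').
    """
    countries = validate_countries(countries)
    pop = countries.set_index("country_id")["population"]
    rows = []
    for _, r in raw.iterrows():
        unit = r["unit"]
        q = float(r["quantity"])
        if unit not in KNOWN_UNITS:
            logger.warning("row %s/%s rejected: unknown unit %r", r["country_id"], r["mode"], unit)
            continue
        if r["mode"] not in MODES:
            logger.warning("row %s rejected: unknown mode %r", r["country_id"], r["mode"])
            continue
        if q < 0 or not math.isfinite(q):
            logger.warning("row %s/%s rejected: bad quantity %r", r["country_id"], r["mode"], q)
            continue
        if unit == "km_per_capita_yr":
            pc = q
        elif unit == "km_per_capita_day":
            pc = q * units.days_per_year
        else:  # pkm_total_yr
            if r["country_id"] not in pop.index:
                logger.warning("row %s rejected: unknown country", r["country_id"])
                continue
            pc = q / float(pop[r["country_id"]])
        rows.append({"country_id": r["country_id"], "mode": r["mode"], "per_capita_km_yr": pc})
    df = pd.DataFrame(rows, columns=["country_id", "mode", "per_capita_km_yr"])
    if len(df):
        dup = df.duplicated(["country_id", "mode"], keep=False)
        if dup.any():
            if duplicate_policy == "error":
                raise InvalidArgumentError("duplicate country-mode rows present")
            if duplicate_policy == "first":
                df = df.drop_duplicates(["country_id", "mode"], keep="first")
            else:
                logger.info("averaging %d duplicate country-mode rows", int(dup.sum()))
                df = df.groupby(["country_id", "mode"], as_index=False)["per_capita_km_yr"].mean()
    df["status"] = "reported"
    return df.reset_index(drop=True)


def demand_grid(countries: pd.DataFrame, modes: Sequence[str] = MODES) -> pd.DataFrame:
    """The full country x mode grid every estimate must cover."""
    return pd.MultiIndex.from_product(
        [countries["country_id"], list(modes)], names=["country_id", "mode"]
    ).to_frame(index=False)


def impute_group_mean(demand: pd.DataFrame, countries: pd.DataFrame) -> pd.DataFrame:
    """Model 1: fill gaps with the income group's population-weighted mean.

    Reported values pass through bit-identical; only missing country-mode
    pairs receive values (status 'imputed_group_mean').
    """
    countries = validate_countries(countries)
    modes = list(dict.fromkeys(demand["mode"]))
    merged = demand_grid(countries, modes).merge(demand, on=["country_id", "mode"], how="left")
    merged = merged.merge(
        countries[["country_id", "income_group", "population"]], on="country_id"
    )
    out = []
    for (group, mode), sub in merged.groupby(["income_group", "mode"], sort=False):
        rep = sub[sub["per_capita_km_yr"].notna()]
        gaps = sub[sub["per_capita_km_yr"].isna()]
        if len(gaps) and not len(rep):
            raise UndefinedValueError(
                f"income group {group!r} has no reported country for mode {mode!r}"
            )
        if len(rep):
            w = rep["population"].to_numpy(float)
            gmean = float(np.average(rep["per_capita_km_yr"].to_numpy(float), weights=w))
        out.append(rep)
        if len(gaps):
            filled = gaps.copy()
            filled["per_capita_km_yr"] = gmean
            filled["status"] = "imputed_group_mean"
            out.append(filled)
    res = pd.concat(out, ignore_index=True)
    return res[["country_id", "mode", "per_capita_km_yr", "status"]]


@dataclass
class GdpDemandModel:
    """Log-log OLS of per-capita demand on GDP per capita for one mode."""

    mode: str
    intercept: float
    elasticity: float
    elasticity_se: float
    elasticity_ci95: Tuple[float, float]
    sigma_resid: float
    nobs: int
    rsquared: float

    def predict(self, gdp_per_capita) -> np.ndarray:
        g = np.asarray(gdp_per_capita, dtype=float)
        if np.any(g <= 0):
            raise InvalidArgumentError("gdp_per_capita must be > 0")
        return np.exp(self.intercept + self.elasticity * np.log(g))


def fit_gdp_model(demand: pd.DataFrame, countries: pd.DataFrame, mode: str) -> GdpDemandModel:
    """Model 2: fit log(per-capita km) ~ log(GDP per capita) on reported countries."""
    countries = validate_countries(countries)
    sub = demand[(demand["mode"] == mode) & (demand["per_capita_km_yr"] > 0)]
    sub = sub.merge(countries[["country_id", "gdp_per_capita"]], on="country_id")
    if len(sub) < 3:
        raise InvalidArgumentError(f"mode {mode!r}: need >= 3 reported countries, have {len(sub)}")
    x = np.log(sub["gdp_per_capita"].to_numpy(float))
    if np.ptp(x) == 0:
        raise InvalidArgumentError(f"mode {mode!r}: degenerate design (all GDP equal)")
    y = np.log(sub["per_capita_km_yr"].to_numpy(float))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return GdpDemandModel(
        mode=mode,
        intercept=float(res.params[0]),
        elasticity=float(res.params[1]),
        elasticity_se=float(res.bse[1]),
        elasticity_ci95=(float(ci[1][0]), float(ci[1][1])),
        sigma_resid=float(np.sqrt(res.scale)),
        nobs=int(res.nobs),
        rsquared=float(res.rsquared),
    )


def impute_regression(demand: pd.DataFrame, countries: pd.DataFrame) -> pd.DataFrame:
    """Fill gaps per mode from the fitted GDP model (status 'imputed_regression')."""
    countries = validate_countries(countries)
    modes = list(dict.fromkeys(demand["mode"]))
    merged = demand_grid(countries, modes).merge(demand, on=["country_id", "mode"], how="left")
    merged = merged.merge(countries[["country_id", "gdp_per_capita"]], on="country_id")
    out = []
    for mode, sub in merged.groupby("mode", sort=False):
        rep = sub[sub["per_capita_km_yr"].notna()]
        gaps = sub[sub["per_capita_km_yr"].isna()]
        out.append(rep)
        if len(gaps):
            model = fit_gdp_model(demand, countries, mode)
            filled = gaps.copy()
            filled["per_capita_km_yr"] = model.predict(filled["gdp_per_capita"].to_numpy())
            filled["status"] = "imputed_regression"
            out.append(filled)
    res = pd.concat(out, ignore_index=True)
    return res[["country_id", "mode", "per_capita_km_yr", "status"]]


def combine(
    reported: pd.DataFrame, model1: pd.DataFrame, model2: pd.DataFrame
) -> pd.DataFrame:
    """Reported values plus the average of the two gap-filling models.

    The two model outputs must fill the identical set of gaps (the
    country-mode pairs absent from ``reported``); any mismatch is an error
    naming the offending pairs.
    """
    key = ["country_id", "mode"]
    rep_keys = set(map(tuple, reported[key].to_numpy()))
    g1 = model1[model1["status"] != "reported"]
    g2 = model2[model2["status"] != "reported"]
    k1 = set(map(tuple, g1[key].to_numpy()))
    k2 = set(map(tuple, g2[key].to_numpy()))
    if k1 != k2:
        raise InvalidArgumentError(f"gap coverage mismatch: {sorted(k1 ^ k2)[:10]}")
    if k1 & rep_keys:
        raise InvalidArgumentError(f"models fill reported pairs: {sorted(k1 & rep_keys)[:10]}")
    merged = g1.merge(g2, on=key, suffixes=("_m1", "_m2"))
    merged["per_capita_km_yr"] = (
        merged["per_capita_km_yr_m1"] + merged["per_capita_km_yr_m2"]
    ) / 2.0
    merged["status"] = "combined"
    filled = merged[key + ["per_capita_km_yr", "status"]]
    return pd.concat([reported, filled], ignore_index=True)


@dataclass
class MobilityEstimate:
    """Totals by mode and income group, with low/mean/high scenario variants."""

    demand: pd.DataFrame  # country_id, mode, per_capita_km_yr, status
    total_gt_km_yr: UncertainValue
    total_person_km_yr: float
    by_mode_gt: Dict[str, float] = field(default_factory=dict)
    by_income_gt: Dict[str, float] = field(default_factory=dict)
    per_capita_by_income_km_yr: Dict[str, float] = field(default_factory=dict)


def to_biomass_movement(
    demand: pd.DataFrame,
    countries: pd.DataFrame,
    units: UnitConventions = UNITS,
) -> float:
    """Convert per-capita demand to biomass movement in Gt km yr^-1.

    person-km x average body mass [kg] gives kg km; 1 Gt km = 1e12 kg km.
    """
    countries = validate_countries(countries)
    m = demand.merge(
        countries[["country_id", "population", "avg_body_mass_kg"]], on="country_id"
    )
    kg_km = (m["per_capita_km_yr"] * m["population"] * m["avg_body_mass_kg"]).sum()
    return float(kg_km) / (units.kg_per_tonne * units.tonnes_per_gt)


def estimate(
    demand: pd.DataFrame,
    countries: pd.DataFrame,
    scenarios: Mapping[str, Tuple[float, float]] = DEFAULT_SCENARIOS,
    units: UnitConventions = UNITS,
) -> MobilityEstimate:
    """Assemble totals and scenario variants from a gap-filled demand table.

    Upper/mean/lower variants scale each entry by per-status multipliers
    (reported data are trusted more than gap-filled entries).
    """
    countries = validate_countries(countries)
    m = demand.merge(
        countries[["country_id", "income_group", "population", "avg_body_mass_kg"]],
        on="country_id",
    )
    m["person_km"] = m["per_capita_km_yr"] * m["population"]
    m["kg_km"] = m["person_km"] * m["avg_body_mass_kg"]
    to_gt = 1.0 / (units.kg_per_tonne * units.tonnes_per_gt)
    mean_gt = float(m["kg_km"].sum()) * to_gt

    low_gt = high_gt = 0.0
    for status, sub in m.groupby("status"):
        lo_mult, hi_mult = scenarios.get(status, scenarios.get("combined", (0.5, 1.6)))
        s = float(sub["kg_km"].sum()) * to_gt
        low_gt += s * lo_mult
        high_gt += s * hi_mult
    total = UncertainValue(mean_gt, min(low_gt, mean_gt), max(high_gt, mean_gt),
                           basis=Basis.CI95)

    by_mode = {
        mode: float(sub["kg_km"].sum()) * to_gt for mode, sub in m.groupby("mode")
    }
    by_income = {
        g: float(sub["kg_km"].sum()) * to_gt for g, sub in m.groupby("income_group")
    }
    pop_by_income = countries.groupby("income_group")["population"].sum()
    per_capita = {
        g: float(sub["person_km"].sum()) / float(pop_by_income[g])
        for g, sub in m.groupby("income_group")
    }
    return MobilityEstimate(
        demand=demand,
        total_gt_km_yr=total,
        total_person_km_yr=float(m["person_km"].sum()),
        by_mode_gt=by_mode,
        by_income_gt=by_income,
        per_capita_by_income_km_yr=per_capita,
    )


@dataclass
class MobilitySummary:
    mode_shares_pct: Dict[str, float]
    income_shares_pct: Dict[str, float]
    population_shares_pct: Dict[str, float]
    per_capita_by_income_km_yr: Dict[str, float]


def summaries(est: MobilityEstimate, countries: pd.DataFrame) -> MobilitySummary:
    """Mode shares, income-group shares and per-capita demand by group."""
    countries = validate_countries(countries)
    total = sum(est.by_mode_gt.values())
    if total <= 0:
        raise UndefinedValueError("summaries undefined for zero total movement")
    pop = countries.groupby("income_group")["population"].sum()
    pop_total = float(pop.sum())
    return MobilitySummary(
        mode_shares_pct={k: 100.0 * v / total for k, v in est.by_mode_gt.items()},
        income_shares_pct={k: 100.0 * v / total for k, v in est.by_income_gt.items()},
        population_shares_pct={g: 100.0 * float(p) / pop_total for g, p in pop.items()},
        per_capita_by_income_km_yr=dict(est.per_capita_by_income_km_yr),
    )


def two_step_estimate(
    reported: pd.DataFrame,
    countries: pd.DataFrame,
    scenarios: Mapping[str, Tuple[float, float]] = DEFAULT_SCENARIOS,
    walk_cycle_floor_km_d: float = 1.0,
    units: UnitConventions = UNITS,
) -> MobilityEstimate:
    """The full pipeline: group-mean + regression gap-fills, averaged, totaled.

    Walking/cycling data are globally scarce, so gap-filled walk_cycle
    entries are floored at ``walk_cycle_floor_km_d`` per capita (an
    explicit assumption, configurable; set 0 to disable).
    """
    m1 = impute_group_mean(reported, countries)
    m2 = impute_regression(reported, countries)
    full = combine(reported, m1, m2)
    if walk_cycle_floor_km_d > 0:
        floor = walk_cycle_floor_km_d * units.days_per_year
        mask = (full["mode"] == "walk_cycle") & (full["status"] == "combined")
        full.loc[mask, "per_capita_km_yr"] = full.loc[mask, "per_capita_km_yr"].clip(lower=floor)
    return estimate(full, countries, scenarios=scenarios, units=units)
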