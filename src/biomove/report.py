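"""Headline report assembly: every number recomputed from fixture inputs.

The report reproduces the study-style summary tables — the land-group
table with ranges and bounds, the locomotion-energy table, the
historical-change summary and the case-study comparison — by pushing the
fixture inputs through the accounting and energetics operations. Each
section builder declares the fixture entries it needs; deleting an input
removes exactly the outputs that depend on it (recorded under
``missing``), so nothing is ever echoed instead of computed.
"""

from __future__ import annotations

from typing import Dict, List, Optional

from . import accounting as acc
from . import energetics as en
from .errors import FixtureError
from .fixtures import FixtureSet
from .uncertain import propagate_uncertainty
from .units import UNITS, UnitConventions

TABLE1_ROWS = (
    ("Wild land mammals", "table1_wild_land_mammals"),
    ("Wild birds", "table1_wild_birds"),
    ("Marine mammals", "table1_marine_mammals"),
    ("Fish", "table1_fish"),
    ("Humans walking", "table1_humans_walking"),
    ("Humans, all transport modes", "table1_humans_all_modes"),
)


def _build(section: Dict, missing: List, key: str, needs: List[str],
           fixtures: FixtureSet, fn) -> None:
    absent = [n for n in needs if n not in fixtures]
    if absent:
        missing.append({"output": key, "missing_inputs": absent})
        return
    section[key] = fn()


def run_report(fixtures: FixtureSet, units: UnitConventions = UNITS,
               sigfigs: int = 1, power_mode: str = "raw") -> Dict:
    """Assemble the full report document as a nested dict.

    An empty fixture set yields an empty (but valid) report.
    """
    report: Dict = {"sections": {}, "missing": []}
    missing = report["missing"]

    # ---- land-group table with ranges and bounds -----------------------
    land: Dict = {}
    groups = {
        "wild_land_mammals": "land_mammals_wild_movement",
        "wild_birds": "land_birds_movement",
        "land_arthropods": "land_arthropods_movement",
    }
    for label, name in groups.items():
        _build(land, missing, label, [name], fixtures,
               lambda name=name: _uv_dict(fixtures.uncertain(name)))
    if len(land) == len(groups):
        uvs = [fixtures.uncertain(n) for n in groups.values()]
        total = propagate_uncertainty(uvs)
        land["terrestrial_wildlife_total"] = _uv_dict(total)
    _build(land, missing, "humans", ["humans_total_movement"], fixtures,
           lambda: _uv_dict(fixtures.uncertain("humans_total_movement")))
    _build(land, missing, "livestock", ["livestock_movement"], fixtures,
           lambda: _uv_dict(fixtures.uncertain("livestock_movement")))

    def mammal_distance():
        est = acc.MovementEstimate(
            movement_t_km_yr=fixtures.uncertain("land_mammals_wild_movement").scaled(
                units.tonnes_per_gt),
            biomass_t=fixtures.uncertain("land_mammals_wild_biomass"),
        )
        d = acc.weighted_mean_daily_distance(est, units)
        return {"km_per_day": d, "display": acc.round_sigfig(d, sigfigs)}

    _build(land, missing, "wild_mammal_weighted_daily_distance",
           ["land_mammals_wild_movement", "land_mammals_wild_biomass"], fixtures,
           mammal_distance)
    if land:
        report["sections"]["land_groups"] = land

    # ---- ratios and shares --------------------------------------------
    ratios: Dict = {}
    _build(ratios, missing, "human_biomass_gt",
           ["human_population", "human_body_mass_kg"], fixtures,
           lambda: fixtures.value("human_population")
           * fixtures.value("human_body_mass_kg")
           / units.kg_per_tonne / units.tonnes_per_gt)
    _build(ratios, missing, "human_to_terrestrial_wildlife",
           ["humans_total_movement", "land_animals_total_movement"], fixtures,
           lambda: acc.fold_change(fixtures.value("humans_total_movement"),
                                   fixtures.value("land_animals_total_movement")))
    _build(ratios, missing, "walking_share_percent",
           ["humans_walking_movement", "humans_total_movement"], fixtures,
           lambda: 100.0 * acc.relative_share(fixtures.value("humans_walking_movement"),
                                              fixtures.value("humans_total_movement")))
    _build(ratios, missing, "income_group_per_capita_ratio",
           ["high_income_population_share", "high_income_movement_share"], fixtures,
           lambda: _income_ratio(fixtures))
    _build(ratios, missing, "food_transport_per_capita_kg_km_d",
           ["food_miles_movement", "human_population"], fixtures,
           lambda: fixtures.value("food_miles_movement") * units.tonnes_per_gt
           * units.kg_per_tonne / fixtures.value("human_population") / units.days_per_year)
    if ratios:
        report["sections"]["ratios"] = ratios

    # ---- energy table --------------------------------------------------
    rows = [(label, name) for label, name in TABLE1_ROWS if name in fixtures]
    if rows:
        table = en.build_energy_table(
            [(label, fixtures.value(name), fixtures.get(name).cot,
              fixtures.get(name).analogue) for label, name in rows],
            sigfigs=sigfigs, power_mode=power_mode, units=units,
        )
        report["sections"]["energy_table"] = [r.__dict__ for r in table]
        for label, name in TABLE1_ROWS:
            if name not in fixtures:
                missing.append({"output": f"energy_table:{label}", "missing_inputs": [name]})
    cot_conv: Dict = {}
    _build(cot_conv, missing, "walking_cot_kcal_per_kg_km", ["cot_walking_j_kg_m"], fixtures,
           lambda: en.cot_to_kcal_per_kg_km(fixtures.value("cot_walking_j_kg_m"), units))
    if cot_conv:
        report["sections"].setdefault("energy_table_notes", {}).update(cot_conv)

    # ---- historical change ---------------------------------------------
    change: Dict = {}
    _build(change, missing, "marine_decline_percent",
           ["marine_movement_1850", "marine_movement_present"], fixtures,
           lambda: acc.decline_percent(fixtures.value("marine_movement_1850"),
                                       fixtures.value("marine_movement_present")))
    _build(change, missing, "human_fold_change",
           ["humans_total_movement", "human_movement_1850"], fixtures,
           lambda: acc.fold_change(fixtures.value("humans_total_movement"),
                                   fixtures.value("human_movement_1850")))
    marine_parts = ["marine_pelagic_fish_present", "marine_mesopelagic_fish_present",
                    "marine_zooplankton_present", "marine_mammals_present"]
    _build(change, missing, "marine_composition_percent", marine_parts, fixtures,
           lambda: dict(zip(
               [p.replace("marine_", "").replace("_present", "") for p in marine_parts],
               acc.composition_shares([fixtures.value(p) for p in marine_parts]))))
    human_parts = ["human_mode_road", "human_mode_walk_cycle", "human_mode_air",
                   "human_mode_rail"]
    _build(change, missing, "human_mode_shares_percent", human_parts, fixtures,
           lambda: dict(zip(
               [p.replace("human_mode_", "") for p in human_parts],
               acc.composition_shares([fixtures.value(p) for p in human_parts]))))
    if change:
        report["sections"]["change"] = change

    # ---- case studies ---------------------------------------------------
    cases: Dict = {}
    _build(cases, missing, "arctic_terns",
           ["terns_population", "terns_body_mass_kg", "terns_annual_km"], fixtures,
           lambda: _case(fixtures, "terns_population", "terns_body_mass_kg",
                         "terns_annual_km", units))
    _build(cases, missing, "humpback_whales",
           ["humpback_population", "humpback_body_mass_t", "humpback_annual_km"], fixtures,
           lambda: _case(fixtures, "humpback_population", "humpback_body_mass_t",
                         "humpback_annual_km", units, mass_in_tonnes=True))
    _build(cases, missing, "germany_domestic_travel",
           ["germany_population", "human_body_mass_kg", "germany_annual_km"], fixtures,
           lambda: _case(fixtures, "germany_population", "human_body_mass_kg",
                         "germany_annual_km", units))
    _build(cases, missing, "bacteria_upper_bound_gt_km_yr",
           ["bacteria_biomass_gt", "bacteria_speed_um_s"], fixtures,
           lambda: acc.upper_bound_movement(
               fixtures.value("bacteria_biomass_gt") * units.tonnes_per_gt,
               24.0,
               fixtures.value("bacteria_speed_um_s") * 1e-6 * 3600.0 / 1e3,
               units) / units.tonnes_per_gt)
    for name in ("wolves_movement", "vehicles_mass_movement", "food_miles_movement",
                 "maritime_trade_movement", "dvm_movement"):
        _build(cases, missing, name, [name], fixtures,
               lambda name=name: fixtures.value(name))
    if cases:
        report["sections"]["case_studies"] = cases

    return report


def _uv_dict(uv) -> Dict:
    return {"mean": uv.mean, "low": uv.low, "high": uv.high,
            "upper_bound": uv.hard_upper_bound, "basis": uv.basis.value}


def _income_ratio(fixtures: FixtureSet) -> float:
    """High-income per-capita movement relative to the rest of the world."""
    pop = fixtures.value("high_income_population_share")
    mov = fixtures.value("high_income_movement_share")
    if not (0 < pop < 100 and 0 < mov < 100):
        raise FixtureError("income shares must be percentages in (0, 100)")
    return (mov / pop) / ((100.0 - mov) / (100.0 - pop))


def _case(fixtures: FixtureSet, pop_name: str, mass_name: str, dist_name: str,
          units: UnitConventions, mass_in_tonnes: bool = False) -> Dict:
    mass_kg = fixtures.value(mass_name) * (units.kg_per_tonne if mass_in_tonnes else 1.0)
    movement = acc.movement_from_population(
        fixtures.value(pop_name), mass_kg, fixtures.value(dist_name), units)
    return {
        "population": fixtures.value(pop_name),
        "body_mass_kg": mass_kg,
        "annual_distance_km": fixtures.value(dist_name),
        "movement_t_km_yr": movement,
        "movement_gt_km_yr": movement / units.tonnes_per_gt,
    }
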