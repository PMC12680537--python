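"""Synthetic inputs with exact ground truth for every pipeline stage.

Each generator emulates one class of real input — literature-style
species tables with allometric day ranges, migration + foraging GPS
tracks, GDP-linked national travel demand with structured missingness,
and historical decline/growth series — and records the generator's exact
totals in a ``truth`` dictionary so recovery can be tested without any
external download. Noise is part of the *data*; the truth bookkeeping is
always exactly consistent with the emitted table by construction.

Determinism: one ``numpy.random.SeedSequence`` per bundle, spawned into
per-component substreams (PCG64), so identical (seed, config) yields a
bit-identical bundle and adding a generator never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .accounting import GroupNode, SpeciesRecord
from .errors import InvalidArgumentError
from .trajectory import Track, haversine_km
from .uncertain import UncertainValue
from .units import UNITS, UnitConventions


@dataclass
class SyntheticBundle:
    """Generated data plus the generator's exact totals and parameters."""

    data: object
    truth: Dict
    seed: int
    config: Dict


def _rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# species tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesGroupConfig:
    """One taxonomic group: how many species, their masses and total biomass."""

    name: str  # slash path, e.g. "land/mammals/wild"
    n_species: int
    mass_logmu: float  # ln(kg)
    mass_logsigma: float
    total_biomass_t: float
    locomotion_mode: str = "walk_run"
    dayrange_c: Optional[float] = None  # km/d at 1 kg; overrides the table default


@dataclass(frozen=True)
class SpeciesTableConfig:
    """Log-normal body masses with an allometric day range d = c * m**e * noise.

    Defaults emulate the terrestrial accounting conditions: wild mammals
    (~20 Mt, heavy-tailed masses), wild birds (~3 Mt, small bodies, long
    flights) and land arthropods (~1 Gt of tiny, slow movers), giving
    group movements of order tens of Gt km/yr each.
    """

    groups: Tuple[SpeciesGroupConfig, ...] = (
        SpeciesGroupConfig("land/mammals/wild", 60, math.log(5.0), 2.0, 2.0e7,
                           "walk_run", dayrange_c=1.5),
        SpeciesGroupConfig("land/birds/wild", 80, math.log(0.1), 1.2, 3.0e6,
                           "fly", dayrange_c=64.0),
        SpeciesGroupConfig("land/arthropods", 100, math.log(1e-4), 1.5, 1.0e9,
                           "crawl", dayrange_c=1.0),
    )
    dayrange_c: float = 1.0  # km/d at 1 kg
    dayrange_e: float = 0.25
    dayrange_sigma: float = 0.4

    def validate(self) -> None:
        for g in self.groups:
            if g.n_species < 1 or g.mass_logsigma < 0 or g.total_biomass_t <= 0:
                raise InvalidArgumentError(f"invalid group config: {g}")
        if self.dayrange_sigma < 0 or self.dayrange_c <= 0:
            raise InvalidArgumentError("invalid day-range parameters")


def gen_species_table(seed: int, config: SpeciesTableConfig = SpeciesTableConfig()
                      ) -> SyntheticBundle:
    """Generate a species table (as a GroupNode tree + DataFrame) with truth.

    Truth holds each group's exact biomass, movement and biomass-weighted
    daily distance, computed directly from the emitted records.
    """
    config.validate()
    rngs = _rngs(seed, len(config.groups))
    root = GroupNode(name="total")
    index: Dict[Tuple[str, ...], GroupNode] = {(): root}
    rows = []
    truth_groups: Dict[str, Dict[str, float]] = {}
    for g, rng in zip(config.groups, rngs):
        path = tuple(g.name.strip("/").split("/"))
        for i in range(1, len(path) + 1):
            if path[:i] not in index:
                node = GroupNode(name=path[i - 1])
                index[path[: i - 1]].children.append(node)
                index[path[:i]] = node
        masses = np.exp(rng.normal(g.mass_logmu, g.mass_logsigma, g.n_species))
        shares = np.exp(rng.normal(0.0, 1.0, g.n_species))
        biomass = g.total_biomass_t * shares / shares.sum()
        c = g.dayrange_c if g.dayrange_c is not None else config.dayrange_c
        noise = np.exp(rng.normal(0.0, config.dayrange_sigma, g.n_species))
        daily = c * masses ** config.dayrange_e * noise
        movement = biomass * daily * UNITS.days_per_year
        for i in range(g.n_species):
            rec = SpeciesRecord(
                id=f"{'_'.join(path)}_{i:03d}",
                group_path=path,
                locomotion_mode=g.locomotion_mode,
                biomass_t=UncertainValue.exact(float(biomass[i])),
                population=float(biomass[i] * UNITS.kg_per_tonne / masses[i]),
                body_mass_kg=float(masses[i]),
                daily_distance_km=UncertainValue.exact(float(daily[i])),
            )
            index[path].children.append(rec)
            rows.append(
                {
                    "id": rec.id,
                    "group_path": "/".join(path),
                    "locomotion_mode": g.locomotion_mode,
                    "population": rec.population,
                    "body_mass_kg": rec.body_mass_kg,
                    "biomass_t_mean": float(biomass[i]),
                    "biomass_t_low": float(biomass[i]),
                    "biomass_t_high": float(biomass[i]),
                    "biomass_t_basis": "extrema",
                    "daily_distance_km_mean": float(daily[i]),
                    "daily_distance_km_low": float(daily[i]),
                    "daily_distance_km_high": float(daily[i]),
                    "daily_distance_km_basis": "extrema",
                }
            )
        truth_groups[g.name] = {
            "biomass_t": float(math.fsum(biomass)),
            "movement_t_km_yr": float(math.fsum(movement)),
            "weighted_daily_km": float(math.fsum(movement))
            / float(math.fsum(biomass))
            / UNITS.days_per_year,
        }
    total_movement = math.fsum(v["movement_t_km_yr"] for v in truth_groups.values())
    truth = {
        "groups": truth_groups,
        "total_movement_t_km_yr": total_movement,
        "total_biomass_t": math.fsum(v["biomass_t"] for v in truth_groups.values()),
    }
    return SyntheticBundle(
        data={"tree": root, "table": pd.DataFrame(rows)},
        truth=truth,
        seed=seed,
        config=asdict(config),
    )


# ---------------------------------------------------------------------------
# GPS tracks
# ---------------------------------------------------------------------------

def _to_unit_vec(lat_deg: float, lon_deg: float) -> np.ndarray:
    la, lo = math.radians(lat_deg), math.radians(lon_deg)
    return np.array([math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)])


def _to_latlon(v: np.ndarray) -> Tuple[float, float]:
    v = v / np.linalg.norm(v)
    return math.degrees(math.asin(np.clip(v[2], -1, 1))), math.degrees(math.atan2(v[1], v[0]))


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    omega = math.acos(np.clip(float(np.dot(a, b)), -1.0, 1.0))
    if omega < 1e-12:
        return a
    return (math.sin((1 - f) * omega) * a + math.sin(f * omega) * b) / math.sin(omega)


def _destination(lat: float, lon: float, bearing_deg: float, dist_km: float,
                 radius_km: float = UNITS.earth_radius_km) -> Tuple[float, float]:
    """Spherical destination point along an initial bearing."""
    d = dist_km / radius_km
    th = math.radians(bearing_deg)
    p1, l1 = math.radians(lat), math.radians(lon)
    p2 = math.asin(math.sin(p1) * math.cos(d) + math.cos(p1) * math.sin(d) * math.cos(th))
    l2 = l1 + math.atan2(
        math.sin(th) * math.sin(d) * math.cos(p1),
        math.cos(d) - math.sin(p1) * math.sin(p2),
    )
    return math.degrees(p2), ((math.degrees(l2) + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class TrackSimConfig:
    """Migration along great-circle legs plus optional foraging random walk.

    Each individual flies the waypoint route (with per-individual waypoint
    jitter) at ``speed_km_h``, then forages as a correlated random walk.
    The exact integrated path length of every individual is recorded as
    truth; fixes are sampled every ``fix_interval_s`` with random dropout.
    """

    n_individuals: int = 25
    waypoints: Tuple[Tuple[float, float], ...] = (
        (65.0, 20.0), (48.0, 8.0), (20.0, 0.0), (-5.0, -10.0),
    )
    waypoint_jitter_deg: float = 1.0
    speed_km_h: float = 45.0
    fix_interval_s: float = 3600.0
    dropout: float = 0.05
    foraging_days: float = 60.0
    foraging_step_km: float = 2.0
    foraging_steps_per_day: int = 12
    turning_kappa: float = 2.0  # von Mises concentration of heading changes

    def validate(self) -> None:
        if not (0 <= self.dropout < 1):
            raise InvalidArgumentError("dropout must be in [0, 1)")
        if self.speed_km_h <= 0 or self.fix_interval_s <= 0:
            raise InvalidArgumentError("speed and fix interval must be > 0")
        if len(self.waypoints) < 2:
            raise InvalidArgumentError("need at least two waypoints")


def gen_tracks(seed: int, config: TrackSimConfig = TrackSimConfig()) -> SyntheticBundle:
    """Simulate individual tracks with exactly-known integrated path length."""
    config.validate()
    rngs = _rngs(seed, config.n_individuals)
    tracks: List[Track] = []
    per_ind: Dict[str, Dict[str, float]] = {}
    for k, rng in enumerate(rngs):
        wps = [
            (la + rng.normal(0, config.waypoint_jitter_deg),
             lo + rng.normal(0, config.waypoint_jitter_deg))
            for la, lo in config.waypoints
        ]
        # dense anchor path: great-circle legs sampled so that consecutive
        # anchors are much closer than one fix interval of travel
        anchor_km = config.speed_km_h * config.fix_interval_s / 3600.0 / 4.0
        lats: List[float] = []
        lons: List[float] = []
        mig_km = 0.0
        for (la1, lo1), (la2, lo2) in zip(wps[:-1], wps[1:]):
            a, b = _to_unit_vec(la1, lo1), _to_unit_vec(la2, lo2)
            leg = haversine_km(la1, lo1, la2, lo2)
            mig_km += leg
            n = max(2, int(math.ceil(leg / max(anchor_km, 1e-6))))
            for f in np.linspace(0.0, 1.0, n, endpoint=False):
                la, lo = _to_latlon(_slerp(a, b, float(f)))
                lats.append(la)
                lons.append(lo)
        lats.append(wps[-1][0])
        lons.append(wps[-1][1])
        # cumulative along-path distance -> time at cruise speed
        seg = haversine_km(np.array(lats[:-1]), np.array(lons[:-1]),
                           np.array(lats[1:]), np.array(lons[1:]))
        cum_km = np.concatenate(([0.0], np.cumsum(seg)))
        path_km = float(cum_km[-1])
        times = cum_km / config.speed_km_h * 3600.0

        # foraging: correlated random walk appended after arrival
        forage_km = 0.0
        if config.foraging_days > 0:
            n_steps = int(round(config.foraging_days * config.foraging_steps_per_day))
            step_dt = 86400.0 / config.foraging_steps_per_day
            heading = float(rng.uniform(0, 360))
            la, lo = lats[-1], lons[-1]
            t = times[-1]
            f_lats, f_lons, f_times = [], [], []
            for _ in range(n_steps):
                heading = (heading + math.degrees(rng.vonmises(0.0, config.turning_kappa))) % 360
                la, lo = _destination(la, lo, heading, config.foraging_step_km)
                t += step_dt
                forage_km += config.foraging_step_km
                f_lats.append(la)
                f_lons.append(lo)
                f_times.append(t)
            lats += f_lats
            lons += f_lons
            times = np.concatenate((times, np.array(f_times)))
        total_km = path_km + forage_km
        duration_days = float(times[-1] - times[0]) / 86400.0

        # sample fixes on the regular grid (nearest anchor at or before grid time)
        grid = np.arange(times[0], times[-1] + 1e-9, config.fix_interval_s)
        idx = np.searchsorted(times, grid, side="right") - 1
        idx = np.unique(np.clip(idx, 0, len(times) - 1))
        if idx[-1] != len(times) - 1:
            idx = np.append(idx, len(times) - 1)
        keep = np.ones(len(idx), dtype=bool)
        if config.dropout > 0 and len(idx) > 2:
            drop = rng.random(len(idx) - 2) < config.dropout
            keep[1:-1] = ~drop
        idx = idx[keep]
        t_fix = np.asarray(times)[idx]
        t_fix, uq = np.unique(t_fix, return_index=True)
        idx = idx[uq]
        ind_id = f"bird_{k:04d}"
        tracks.append(
            Track(
                individual_id=ind_id,
                times_s=t_fix,
                lats=np.asarray(lats)[idx],
                lons=np.asarray(lons)[idx],
                species="synthetic_migrant",
            )
        )
        per_ind[ind_id] = {
            "integrated_km": total_km,
            "migration_km": path_km,
            "migration_gc_km": mig_km,
            "foraging_km": forage_km,
            "duration_days": duration_days,
            "annual_km": total_km * UNITS.days_per_year / duration_days,
        }
    truth = {
        "per_individual": per_ind,
        "mean_integrated_km": float(np.mean([v["integrated_km"] for v in per_ind.values()])),
        "mean_annual_km": float(np.mean([v["annual_km"] for v in per_ind.values()])),
    }
    return SyntheticBundle(data=tracks, truth=truth, seed=seed, config=asdict(config))


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Movebank-export-style table (the same format read_tracks_csv parses)."""
    rows = []
    for t in tracks:
        stamps = pd.to_datetime(t.times_s, unit="s", utc=True)
        for ts, la, lo in zip(stamps, t.lats, t.lons):
            rows.append(
                {
                    "individual-local-identifier": t.individual_id,
                    "timestamp": ts.strftime("%Y-%m-%d %H:%M:%S.%f")[:-3],
                    "location-lat": la,
                    "location-long": lo,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# country travel-demand tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeDemandParams:
    """Per-capita demand model for one mode: alpha * gdp**beta * lognormal noise."""

    alpha: float
    beta: float
    sigma: float


@dataclass(frozen=True)
class CountryTableConfig:
    """GDP-linked travel demand with missingness concentrated at low GDP.

    Demand parameters are calibrated so a high-income country travels
    ~10,000 km/yr by road, ~3,000 by air, ~800 by rail and ~1,100 on foot
    or bicycle, broadly matching the reported global mobility profile.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"high": 30, "upper_middle": 30, "lower_middle": 30, "low": 25}
    )
    gdp_logmu: Mapping[str, float] = field(
        default_factory=lambda: {
            "high": math.log(45000.0),
            "upper_middle": math.log(10000.0),
            "lower_middle": math.log(2500.0),
            "low": math.log(700.0),
        }
    )
    gdp_logsigma: float = 0.35
    pop_logmu: float = math.log(2.0e7)
    pop_logsigma: float = 1.3
    modes: Mapping[str, ModeDemandParams] = field(
        default_factory=lambda: {
            "road": ModeDemandParams(1.9, 0.8, 0.3),
            "air": ModeDemandParams(0.0078, 1.2, 0.4),
            "rail": ModeDemandParams(1.3, 0.6, 0.4),
            "walk_cycle": ModeDemandParams(3200.0, -0.1, 0.25),
        }
    )
    missing_fraction: float = 0.3
    missing_gdp_ref: float = 5000.0  # masking odds scale with gdp_ref/gdp
    body_mass_kg: float = 54.0
    unit_mix: Tuple[str, ...] = ("km_per_capita_yr", "pkm_total_yr", "km_per_capita_day")

    def validate(self) -> None:
        if not (0 <= self.missing_fraction < 1):
            raise InvalidArgumentError("missing_fraction must be in [0, 1)")
        for m, p in self.modes.items():
            if p.alpha <= 0 or p.sigma < 0:
                raise InvalidArgumentError(f"invalid mode params for {m}")


def gen_country_table(seed: int, config: CountryTableConfig = CountryTableConfig()
                      ) -> SyntheticBundle:
    """Generate countries + raw demand rows; truth holds the unmasked table.

    The raw rows exercise the harmonization path (a mix of per-capita,
    total-pkm and per-day units); masked entries are drawn without
    replacement with odds proportional to 1/GDP, emulating the decline of
    data availability toward low-income countries.
    """
    config.validate()
    rng_c, rng_d, rng_m, rng_u = _rngs(seed, 4)
    rows = []
    for group in INCOME_GROUP_ORDER:
        n = int(config.n_per_group.get(group, 0))
        gdp = np.exp(rng_c.normal(config.gdp_logmu[group], config.gdp_logsigma, n))
        pop = np.exp(rng_c.normal(config.pop_logmu, config.pop_logsigma, n))
        for i in range(n):
            rows.append(
                {
                    "country_id": f"{_GROUP_PREFIX[group]}{i:03d}",
                    "income_group": group,
                    "population": float(pop[i]),
                    "gdp_per_capita": float(gdp[i]),
                    "avg_body_mass_kg": config.body_mass_kg,
                }
            )
    countries = pd.DataFrame(rows)

    demand_rows = []
    for mode, p in config.modes.items():
        noise = np.exp(rng_d.normal(0.0, p.sigma, len(countries)))
        pc = p.alpha * countries["gdp_per_capita"].to_numpy() ** p.beta * noise
        for cid, v in zip(countries["country_id"], pc):
            demand_rows.append({"country_id": cid, "mode": mode, "per_capita_km_yr": float(v)})
    full = pd.DataFrame(demand_rows)

    # masking: exact fraction, odds proportional to gdp_ref / gdp
    gdp_map = countries.set_index("country_id")["gdp_per_capita"]
    w = (config.missing_gdp_ref / full["country_id"].map(gdp_map).to_numpy()).astype(float)
    n_mask = int(round(config.missing_fraction * len(full)))
    masked_idx = rng_m.choice(len(full), size=n_mask, replace=False, p=w / w.sum())
    is_masked = np.zeros(len(full), dtype=bool)
    is_masked[masked_idx] = True

    raw_rows = []
    pop_map = countries.set_index("country_id")["population"]
    for i, r in full.iterrows():
        if is_masked[i]:
            continue
        unit = config.unit_mix[int(rng_u.integers(0, len(config.unit_mix)))]
        pc = r["per_capita_km_yr"]
        if unit == "km_per_capita_yr":
            q = pc
        elif unit == "km_per_capita_day":
            q = pc / UNITS.days_per_year
        else:
            q = pc * float(pop_map[r["country_id"]])
        raw_rows.append(
            {"country_id": r["country_id"], "mode": r["mode"], "quantity": q, "unit": unit}
        )
    raw = pd.DataFrame(raw_rows)

    mass = config.body_mass_kg
    merged = full.merge(countries[["country_id", "population"]], on="country_id")
    person_km = float((merged["per_capita_km_yr"] * merged["population"]).sum())
    truth = {
        "full_demand": full.assign(masked=is_masked),
        "total_person_km_yr": person_km,
        "total_gt_km_yr": person_km * mass / 1e12,
        "masked_fraction": n_mask / len(full),
        "mode_params": {m: asdict(p) for m, p in config.modes.items()},
    }
    return SyntheticBundle(
        data={"countries": countries, "raw_demand": raw},
        truth=truth,
        seed=seed,
        config={**asdict(config), "modes": {m: asdict(p) for m, p in config.modes.items()}},
    )


INCOME_GROUP_ORDER = ("high", "upper_middle", "lower_middle", "low")
_GROUP_PREFIX = {"high": "HI", "upper_middle": "UM", "lower_middle": "LM", "low": "LW"}


# ---------------------------------------------------------------------------
# historical series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistoricalSeriesConfig:
    """Exponentially declining marine components and logistically growing
    human modes, calibrated to exact start/end totals.

    Defaults reproduce the reported envelope: marine movement falling from
    80,000 to 30,000 Gt km/yr between 1850 and the present (a 62.5%
    decline) while human movement grows 40-fold from 100 to 4,000.
    """

    start_year: int = 1850
    end_year: int = 2020
    step: int = 10
    marine_start: Mapping[str, float] = field(
        default_factory=lambda: {
            "pelagic_fish": 56000.0, "mesopelagic_fish": 12000.0,
            "zooplankton": 8000.0, "marine_mammals": 4000.0,
        }
    )
    marine_end: Mapping[str, float] = field(
        default_factory=lambda: {
            "pelagic_fish": 21000.0, "mesopelagic_fish": 4500.0,
            "zooplankton": 3000.0, "marine_mammals": 1500.0,
        }
    )
    human_start: Mapping[str, float] = field(
        default_factory=lambda: {
            "walk_cycle": 97.0, "road": 2.0, "rail": 0.9, "air": 0.1,
        }
    )
    human_end: Mapping[str, float] = field(
        default_factory=lambda: {
            "walk_cycle": 800.0, "road": 2600.0, "rail": 200.0, "air": 400.0,
        }
    )
    logistic_rate: float = 0.05  # yr^-1
    logistic_midyear: float = 1970.0

    def validate(self) -> None:
        if self.end_year <= self.start_year or self.step <= 0:
            raise InvalidArgumentError("invalid year range")
        if set(self.marine_start) != set(self.marine_end):
            raise InvalidArgumentError("marine component names must match")
        if set(self.human_start) != set(self.human_end):
            raise InvalidArgumentError("human mode names must match")


def gen_historical_series(seed: int, config: HistoricalSeriesConfig = HistoricalSeriesConfig()
                          ) -> SyntheticBundle:
    """Year-by-component movement series with exact decline/fold truth.

    Deterministic given the config (seed kept for interface uniformity).
    """
    config.validate()
    years = np.arange(config.start_year, config.end_year + 1, config.step)
    if years[-1] != config.end_year:
        years = np.append(years, config.end_year)
    rows = []
    for name in config.marine_start:
        v0, v1 = config.marine_start[name], config.marine_end[name]
        rate = math.log(v1 / v0) / (config.end_year - config.start_year)
        for y in years:
            rows.append({"year": int(y), "component": name, "domain": "marine",
                         "movement_gt_km_yr": v0 * math.exp(rate * (y - config.start_year))})

    def logistic(y: float) -> float:
        return 1.0 / (1.0 + math.exp(-config.logistic_rate * (y - config.logistic_midyear)))

    s0, s1 = logistic(config.start_year), logistic(config.end_year)
    for name in config.human_start:
        v0, v1 = config.human_start[name], config.human_end[name]
        for y in years:
            f = (logistic(float(y)) - s0) / (s1 - s0)
            rows.append({"year": int(y), "component": name, "domain": "human",
                         "movement_gt_km_yr": v0 + (v1 - v0) * f})
    df = pd.DataFrame(rows)
    marine0 = math.fsum(config.marine_start.values())
    marine1 = math.fsum(config.marine_end.values())
    human0 = math.fsum(config.human_start.values())
    human1 = math.fsum(config.human_end.values())
    truth = {
        "marine_start_total": marine0,
        "marine_end_total": marine1,
        "marine_decline_percent": (1.0 - marine1 / marine0) * 100.0,
        "human_start_total": human0,
        "human_end_total": human1,
        "human_fold_change": human1 / human0,
    }
    return SyntheticBundle(data=df, truth=truth, seed=seed, config=asdict(config))
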