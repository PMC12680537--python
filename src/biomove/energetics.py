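"""Locomotion energetics via allometric cost of transport.

The cost of transport (COT) is the energy required to move one unit of
body mass one unit of distance (J kg^-1 m^-1). It follows allometric
scaling COT(m) = a * m**b per locomotion mode, with b <= 0: bigger
animals move each kilogram more cheaply. Multiplying a group's biomass
movement by its (movement-weighted) average COT gives the energy spent
on locomotion per year, and hence mean power.

The shipped mode constants are generic literature-style defaults
calibrated so a 70-kg walker costs ~3 J kg^-1 m^-1; group-average COTs
used for headline energy tables come from configuration, not from these
defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .accounting import round_sigfig
from .errors import InvalidArgumentError, UndefinedValueError
from .units import UNITS, UnitConventions


@dataclass(frozen=True)
class CotParams:
    """Allometric COT parameters for one locomotion mode: COT(m) = a * m**b."""

    mode: str
    coefficient_a: float  # J kg^-1 m^-1 at 1 kg body mass
    exponent_b: float  # dimensionless, <= 0

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0:
            raise InvalidArgumentError("coefficient_a must be > 0")
        if self.exponent_b > 0:
            raise InvalidArgumentError("exponent_b must be <= 0")


#: Default allometric registry; every entry is overridable via configuration.
DEFAULT_COT_REGISTRY: Dict[str, CotParams] = {
    "walk_run": CotParams("walk_run", 11.5, -0.316),  # 70 kg -> ~3.0 J/kg/m
    "fly": CotParams("fly", 4.6, -0.30),              # 100 g bird -> ~9 J/kg/m
    "swim": CotParams("swim", 0.7, -0.38),            # 10 g fish -> ~4 J/kg/m
    "crawl": CotParams("crawl", 20.0, -0.30),
    "vertical_migration": CotParams("vertical_migration", 0.7, -0.38),
    "vehicle_road": CotParams("vehicle_road", 30.0, 0.0),   # per passenger kg
    "vehicle_rail": CotParams("vehicle_rail", 5.0, 0.0),
    "vehicle_air": CotParams("vehicle_air", 20.0, 0.0),
    "vehicle_ship": CotParams("vehicle_ship", 0.5, 0.0),
}


def cot(body_mass_kg: float, params: CotParams) -> float:
    """Allometric cost of transport a * m**b in J kg^-1 m^-1."""
    if not (body_mass_kg > 0) or not math.isfinite(body_mass_kg):
        raise InvalidArgumentError(f"body mass must be > 0, got {body_mass_kg!r}")
    return params.coefficient_a * body_mass_kg ** params.exponent_b


def cot_to_kcal_per_kg_km(cot_j_kg_m: float, units: UnitConventions = UNITS) -> float:
    """Convert J kg^-1 m^-1 to dietary kcal kg^-1 km^-1 (x1000 / 4184)."""
    if cot_j_kg_m < 0:
        raise InvalidArgumentError("cot must be >= 0")
    return cot_j_kg_m * 1000.0 / units.joules_per_kcal


def kcal_per_kg_km_to_cot(kcal: float, units: UnitConventions = UNITS) -> float:
    return kcal * units.joules_per_kcal / 1000.0


def biomass_weighted_cot(entries: Sequence[Tuple[float, float]]) -> float:
    """Movement-weighted mean COT over (movement, cot) pairs.

    Efficient large animals dominate mammalian biomass movement, which is
    why a group average can sit near the large-body end of the COT range.
    """
    total = math.fsum(w for w, _ in entries)
    if total <= 0:
        raise UndefinedValueError("biomass_weighted_cot undefined for zero total movement")
    return math.fsum(w * c for w, c in entries) / total


def energy_twh(movement_gt_km_yr: float, cot_j_kg_m: float) -> float:
    """Locomotion energy in TWh yr^-1.

    1 Gt km = 1e15 kg m and 1 TWh = 3.6e15 J, so energy = movement * COT / 3.6.
    """
    if movement_gt_km_yr < 0 or cot_j_kg_m < 0:
        raise InvalidArgumentError("inputs must be >= 0")
    return movement_gt_km_yr * cot_j_kg_m / 3.6


def mean_power_gw(energy_twh_yr: float, units: UnitConventions = UNITS) -> float:
    """Mean power in GW sustained over the year by an annual energy use."""
    if energy_twh_yr < 0:
        raise InvalidArgumentError("energy must be >= 0")
    return energy_twh_yr * units.joules_per_twh / units.seconds_per_year / 1e9


@dataclass
class EnergyRecord:
    """One row of the locomotion-energy table (raw and 1-sig-fig values)."""

    group: str
    movement_gt_km_yr: float
    cot_avg: float
    energy_twh_yr: float
    power_gw: float
    energy_twh_yr_rounded: float
    power_gw_rounded: float
    analogue_label: str = ""


def build_energy_table(
    groups: Sequence[Tuple[str, float, float, str]],
    sigfigs: int = 1,
    power_mode: str = "raw",
    units: UnitConventions = UNITS,
) -> List[EnergyRecord]:
    """Energy and power per (group, movement, cot, analogue) row.

    ``power_mode='raw'`` (default) derives power from the unrounded energy
    and rounds afterwards; ``'round_then_derive'`` derives it from the
    already-rounded energy, a compatibility mode for tables whose printed
    power cells were computed from rounded energies.
    """
    if power_mode not in ("raw", "round_then_derive"):
        raise InvalidArgumentError(f"unknown power_mode {power_mode!r}")
    out: List[EnergyRecord] = []
    for group, movement, cot_avg, analogue in groups:
        e = energy_twh(movement, cot_avg)
        e_rounded = round_sigfig(e, sigfigs)
        p = mean_power_gw(e, units)
        if power_mode == "round_then_derive":
            p_rounded = round_sigfig(mean_power_gw(e_rounded, units), sigfigs)
        else:
            p_rounded = round_sigfig(p, sigfigs)
        out.append(
            EnergyRecord(
                group=group,
                movement_gt_km_yr=movement,
                cot_avg=cot_avg,
                energy_twh_yr=e,
                power_gw=p,
                energy_twh_yr_rounded=e_rounded,
                power_gw_rounded=p_rounded,
                analogue_label=analogue,
            )
        )
    return out
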