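"""Biomass-movement accounting.

The central metric is *biomass movement*: the total biomass of a group
multiplied by the average distance its individuals actively travel per
year, with units of mass x distance / time (Gt km yr^-1 for headline
values). Group estimates are the sum over constituent species or
subgroups; distances of aggregates are biomass-weighted averages; and
groups with insufficient movement data contribute only activity-time x
speed upper bounds, never to the mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import InvalidArgumentError, UndefinedValueError
from .uncertain import Basis, UncertainValue, propagate_uncertainty, sum_bounds
from .units import UNITS, UnitConventions

logger = logging.getLogger(__name__)

LOCOMOTION_MODES = (
    "walk_run",
    "fly",
    "swim",
    "crawl",
    "vertical_migration",
    "vehicle_road",
    "vehicle_rail",
    "vehicle_air",
    "vehicle_ship",
)


def _check_nonneg(x: float, name: str) -> None:
    if not math.isfinite(x) or x < 0:
        raise InvalidArgumentError(f"{name} must be finite and >= 0, got {x!r}")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def biomass_movement(biomass_t: float, annual_distance_km: float) -> float:
    """Biomass movement of one group: biomass [t] x annual distance [km yr^-1].

    Returns t km yr^-1; exact arithmetic, no rounding.
    """
    _check_nonneg(biomass_t, "biomass_t")
    _check_nonneg(annual_distance_km, "annual_distance_km")
    return biomass_t * annual_distance_km


def movement_from_population(
    population: float,
    body_mass_kg: float,
    annual_distance_km: float,
    units: UnitConventions = UNITS,
) -> float:
    """Biomass movement from a head count: N x m / 1000 x d  [t km yr^-1]."""
    _check_nonneg(population, "population")
    _check_nonneg(body_mass_kg, "body_mass_kg")
    _check_nonneg(annual_distance_km, "annual_distance_km")
    return population * body_mass_kg / units.kg_per_tonne * annual_distance_km


def upper_bound_movement(
    biomass_t: float,
    activity_hours_per_day: float,
    speed_km_h: float,
    units: UnitConventions = UNITS,
) -> float:
    """Upper-bound movement from activity time and characteristic speed.

    biomass x activity x speed x days_per_year; robust to under-sampled
    travel distances, hence used for data-poor groups.
    """
    _check_nonneg(biomass_t, "biomass_t")
    _check_nonneg(speed_km_h, "speed_km_h")
    if not (0 <= activity_hours_per_day <= 24):
        raise InvalidArgumentError(
            f"activity_hours_per_day must lie in [0, 24], got {activity_hours_per_day!r}"
        )
    return biomass_t * activity_hours_per_day * speed_km_h * units.days_per_year


def relative_share(part: float, whole: float) -> float:
    """Fraction of `whole` contributed by `part`."""
    _check_nonneg(part, "part")
    if whole <= 0:
        raise UndefinedValueError("relative_share undefined for whole <= 0")
    return part / whole


def composition_shares(parts: Sequence[float]) -> List[float]:
    """Percentages of a composition; sums to exactly 100 before display rounding."""
    total = math.fsum(parts)
    if total <= 0:
        raise UndefinedValueError("composition_shares undefined for zero total")
    return [100.0 * p / total for p in parts]


def decline_percent(initial: float, final: float) -> float:
    """Percent decline from `initial` to `final` (negative = growth)."""
    if initial <= 0:
        raise UndefinedValueError("decline_percent undefined for initial <= 0")
    return (1.0 - final / initial) * 100.0


def fold_change(final: float, initial: float) -> float:
    """Ratio final / initial."""
    if initial <= 0:
        raise UndefinedValueError("fold_change undefined for initial <= 0")
    return final / initial


def round_sigfig(x: float, n: int) -> float:
    """Round to `n` significant figures, ties away from zero.

    Headline values in reports are displayed at 1 significant figure; raw
    values are always retained alongside.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    shift = n - 1 - d.adjusted()
    q = d.scaleb(shift).quantize(Decimal(1), rounding=ROUND_HALF_UP).scaleb(-shift)
    return float(q)


# ---------------------------------------------------------------------------
# species records and group trees
# ---------------------------------------------------------------------------

@dataclass
class SpeciesRecord:
    """One taxon or subgroup row of the accounting table.

    Carries biomass with uncertainty and at least one way to obtain a
    travel distance: an annual distance, a daily distance, or an activity
    time + characteristic speed pair (which yields only an upper bound).
    """

    id: str
    group_path: Tuple[str, ...]
    locomotion_mode: str
    biomass_t: UncertainValue
    population: Optional[float] = None
    body_mass_kg: Optional[float] = None
    daily_distance_km: Optional[UncertainValue] = None
    annual_distance_km: Optional[UncertainValue] = None
    activity_hours_per_day: Optional[float] = None
    characteristic_speed_km_h: Optional[float] = None
    consistency_rel_tol: float = 0.25

    def __post_init__(self) -> None:
        if self.locomotion_mode not in LOCOMOTION_MODES:
            raise InvalidArgumentError(f"unknown locomotion_mode {self.locomotion_mode!r}")
        self.group_path = tuple(self.group_path)
        has_activity = (
            self.activity_hours_per_day is not None
            and self.characteristic_speed_km_h is not None
        )
        if self.daily_distance_km is None and self.annual_distance_km is None and not has_activity:
            raise InvalidArgumentError(
                f"record {self.id!r}: needs daily or annual distance, or activity+speed"
            )
        if self.activity_hours_per_day is not None and not (
            0 <= self.activity_hours_per_day <= 24
        ):
            raise InvalidArgumentError(f"record {self.id!r}: activity hours outside [0, 24]")
        if self.population is not None and self.body_mass_kg is not None:
            implied = self.population * self.body_mass_kg / UNITS.kg_per_tonne
            ref = self.biomass_t.mean
            if ref and abs(implied - ref) / ref > self.consistency_rel_tol:
                raise InvalidArgumentError(
                    f"record {self.id!r}: population x body mass = {implied:.4g} t "
                    f"disagrees with biomass {ref:.4g} t beyond "
                    f"{self.consistency_rel_tol:.0%} relative tolerance"
                )

    def resolve_annual_distance(self, units: UnitConventions = UNITS) -> Optional[UncertainValue]:
        """Annual distance in km yr^-1, converting daily x days_per_year if needed.

        Returns None for activity+speed-only records (bound-only leaves).
        """
        if self.annual_distance_km is not None and not self.annual_distance_km.is_bound_only:
            return self.annual_distance_km
        if self.daily_distance_km is not None and not self.daily_distance_km.is_bound_only:
            return self.daily_distance_km.scaled(units.days_per_year)
        return None


@dataclass
class MovementEstimate:
    """Aggregated movement for one node of the group tree.

    ``movement_t_km_yr`` is None only for bound-only nodes (no usable
    central distance anywhere below).
    """

    movement_t_km_yr: Optional[UncertainValue]
    biomass_t: UncertainValue
    weighted_daily_distance_km: Optional[float] = None
    upper_bound_t_km_yr: Optional[float] = None


@dataclass
class GroupNode:
    """A node of the taxonomic / locomotion grouping tree; leaves are species."""

    name: str
    children: List[Union["GroupNode", SpeciesRecord]] = field(default_factory=list)
    estimate: Optional[MovementEstimate] = None

    def leaves(self) -> List[SpeciesRecord]:
        out: List[SpeciesRecord] = []
        for c in self.children:
            if isinstance(c, SpeciesRecord):
                out.append(c)
            else:
                out.extend(c.leaves())
        return out


@dataclass
class CoverageReport:
    """What the aggregation actually used: nothing is ever silently dropped."""

    n_leaves: int = 0
    n_estimated: int = 0
    n_bound_only: int = 0
    skipped: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


@dataclass
class AggregationResult:
    root: GroupNode
    coverage: CoverageReport


def _leaf_estimate(
    rec: SpeciesRecord, report: CoverageReport, units: UnitConventions
) -> Optional[MovementEstimate]:
    report.n_leaves += 1
    ub = None
    if rec.activity_hours_per_day is not None and rec.characteristic_speed_km_h is not None:
        ub = upper_bound_movement(
            rec.biomass_t.upper,
            rec.activity_hours_per_day,
            rec.characteristic_speed_km_h,
            units,
        )
    distance = rec.resolve_annual_distance(units)
    if distance is None:
        if ub is None:
            report.skipped.append((rec.id, "no usable distance and no activity/speed bound"))
            logger.warning("leaf %s skipped: no usable distance information", rec.id)
            return None
        # data-poor group: only the upper bound is evaluated
        report.n_bound_only += 1
        return MovementEstimate(
            movement_t_km_yr=None, biomass_t=rec.biomass_t, upper_bound_t_km_yr=ub
        )
    movement = rec.biomass_t.times(distance)
    report.n_estimated += 1
    wdd = None
    if rec.biomass_t.mean:
        wdd = movement.mean / rec.biomass_t.mean / units.days_per_year
    return MovementEstimate(
        movement_t_km_yr=movement,
        biomass_t=rec.biomass_t,
        weighted_daily_distance_km=wdd,
        upper_bound_t_km_yr=ub,
    )


def aggregate(node: GroupNode, units: UnitConventions = UNITS) -> AggregationResult:
    """Fill every node of the tree with a MovementEstimate, bottom-up.

    Node movement = sum of child movements (arithmetic-sum uncertainty);
    biomass likewise; upper bounds add children's bounds, falling back to
    their interval highs. Unusable leaves are skipped with a warning and
    counted in the coverage report.
    """
    report = CoverageReport()
    _aggregate_into(node, report, units)
    return AggregationResult(root=node, coverage=report)


def _aggregate_into(
    node: GroupNode, report: CoverageReport, units: UnitConventions
) -> Optional[MovementEstimate]:
    child_estimates: List[MovementEstimate] = []
    for child in node.children:
        if isinstance(child, SpeciesRecord):
            est = _leaf_estimate(child, report, units)
        else:
            est = _aggregate_into(child, report, units)
        if est is not None:
            child_estimates.append(est)
    if not child_estimates:
        node.estimate = None
        return None

    movements = [e.movement_t_km_yr for e in child_estimates if e.movement_t_km_yr is not None]
    biomasses = [e.biomass_t for e in child_estimates]
    biomass = propagate_uncertainty(biomasses) if len(biomasses) > 1 else biomasses[0]
    movement = None
    if movements:
        movement = propagate_uncertainty(movements) if len(movements) > 1 else movements[0]

    bounds: List[float] = []
    bound_ok = True
    for e in child_estimates:
        if e.upper_bound_t_km_yr is not None:
            bounds.append(e.upper_bound_t_km_yr)
        elif e.movement_t_km_yr is not None:
            bounds.append(e.movement_t_km_yr.upper)
        else:
            bound_ok = False
    has_own_bound = any(e.upper_bound_t_km_yr is not None for e in child_estimates)
    ub = math.fsum(bounds) if (bound_ok and has_own_bound) else None

    wdd = None
    if movement is not None and biomass.mean:
        wdd = movement.mean / biomass.mean / units.days_per_year
    node.estimate = MovementEstimate(
        movement_t_km_yr=movement,
        biomass_t=biomass,
        weighted_daily_distance_km=wdd,
        upper_bound_t_km_yr=ub,
    )
    return node.estimate


def weighted_mean_daily_distance(
    estimate: MovementEstimate, units: UnitConventions = UNITS
) -> float:
    """Biomass-weighted average daily distance: movement / biomass / days_per_year."""
    if estimate.biomass_t.mean is None or estimate.biomass_t.mean <= 0:
        raise UndefinedValueError("weighted daily distance undefined for zero biomass")
    if estimate.movement_t_km_yr is None:
        raise UndefinedValueError("node has no central movement estimate")
    return estimate.movement_t_km_yr.mean / estimate.biomass_t.mean / units.days_per_year


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_UV_FIELDS = ("mean", "low", "high")


def _uv_from_row(row: pd.Series, prefix: str) -> Optional[UncertainValue]:
    mean = row.get(f"{prefix}_mean")
    if mean is None or (isinstance(mean, float) and math.isnan(mean)):
        return None
    low = row.get(f"{prefix}_low")
    high = row.get(f"{prefix}_high")
    low = None if low is None or (isinstance(low, float) and math.isnan(low)) else float(low)
    high = None if high is None or (isinstance(high, float) and math.isnan(high)) else float(high)
    basis = row.get(f"{prefix}_basis")
    basis = Basis(basis) if isinstance(basis, str) and basis else Basis.CI95
    return UncertainValue(float(mean), low, high, basis)


def _opt(row: pd.Series, col: str) -> Optional[float]:
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_species_csv(path) -> GroupNode:
    """Read a species table (one row per SpeciesRecord) into a group tree.

    ``group_path`` is a slash-separated string, e.g. ``land/mammals/wild``;
    uncertain columns follow the ``<name>_mean/_low/_high[/_basis]`` pattern.
    """
    df = pd.read_csv(path)
    root = GroupNode(name="total")
    index: dict = {(): root}
    for _, row in df.iterrows():
        path_parts = tuple(str(row["group_path"]).strip("/").split("/"))
        for i in range(1, len(path_parts) + 1):
            key = path_parts[:i]
            if key not in index:
                node = GroupNode(name=key[-1])
                index[key[:-1]].children.append(node)
                index[key] = node
        rec = SpeciesRecord(
            id=str(row["id"]),
            group_path=path_parts,
            locomotion_mode=str(row["locomotion_mode"]),
            biomass_t=_uv_from_row(row, "biomass_t"),
            population=_opt(row, "population"),
            body_mass_kg=_opt(row, "body_mass_kg"),
            daily_distance_km=_uv_from_row(row, "daily_distance_km"),
            annual_distance_km=_uv_from_row(row, "annual_distance_km"),
            activity_hours_per_day=_opt(row, "activity_hours_per_day"),
            characteristic_speed_km_h=_opt(row, "characteristic_speed_km_h"),
        )
        index[path_parts].children.append(rec)
    return root


def estimates_to_frame(root: GroupNode, units: UnitConventions = UNITS) -> pd.DataFrame:
    """Flatten an aggregated tree into a tidy per-node table (Gt km yr^-1)."""
    rows = []

    def visit(node: GroupNode, path: Tuple[str, ...]) -> None:
        est = node.estimate
        if est is not None:
            mv = est.movement_t_km_yr
            rows.append(
                {
                    "node": "/".join(path) or node.name,
                    "movement_gt_km_yr": None if mv is None else mv.mean / units.tonnes_per_gt,
                    "movement_low_gt": None if mv is None else mv.low / units.tonnes_per_gt,
                    "movement_high_gt": None if mv is None else mv.high / units.tonnes_per_gt,
                    "biomass_mt": est.biomass_t.mean / 1e6
                    if est.biomass_t.mean is not None
                    else None,
                    "weighted_daily_km": est.weighted_daily_distance_km,
                    "upper_bound_gt": None
                    if est.upper_bound_t_km_yr is None
                    else est.upper_bound_t_km_yr / units.tonnes_per_gt,
                }
            )
        for c in node.children:
            if isinstance(c, GroupNode):
                visit(c, path + (c.name,))

    visit(root, (root.name,))
    return pd.DataFrame(rows)
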