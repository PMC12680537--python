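"""Bundled fixture values: the reported headline numbers the report recomputes from.

The fixture file stores *inputs* (biomasses, distances, populations,
per-mode components, COT averages) with units and provenance; every
derived number in a report is recomputed from these through the
accounting and energetics operations, never copied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional

import yaml

from .errors import FixtureError
from .uncertain import Basis, UncertainValue

_DEFAULT_RESOURCE = "headline_values.yaml"


@dataclass(frozen=True)
class FixtureEntry:
    """One named scalar with units, optional range/bound and provenance."""

    name: str
    value: Optional[float]
    units: str
    provenance: str
    low: Optional[float] = None
    high: Optional[float] = None
    upper_bound: Optional[float] = None
    basis: Basis = Basis.CI95
    cot: Optional[float] = None
    analogue: str = ""

    def uncertain(self) -> UncertainValue:
        if self.basis is Basis.BOUND_ONLY:
            return UncertainValue.bound(self.upper_bound if self.upper_bound is not None
                                        else self.value)
        return UncertainValue(self.value, self.low, self.high, self.basis, self.upper_bound)


@dataclass
class FixtureSet:
    """Validated mapping of fixture names to entries."""

    entries: Dict[str, FixtureEntry] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def get(self, name: str) -> FixtureEntry:
        if name not in self.entries:
            raise FixtureError(f"fixture entry {name!r} not found")
        return self.entries[name]

    def value(self, name: str) -> float:
        v = self.get(name).value
        if v is None:
            raise FixtureError(f"fixture entry {name!r} has no central value")
        return v

    def uncertain(self, name: str) -> UncertainValue:
        return self.get(name).uncertain()

    def without(self, *names: str) -> "FixtureSet":
        """A copy with the named entries removed (for sensitivity checks)."""
        return FixtureSet({k: v for k, v in self.entries.items() if k not in names})


def _parse_entry(name: str, raw: dict) -> FixtureEntry:
    if not isinstance(raw, dict):
        raise FixtureError(f"entry {name!r}: expected a mapping, got {type(raw).__name__}")
    problems = []
    if "units" not in raw:
        problems.append("units")
    if "provenance" not in raw:
        problems.append("provenance")
    basis = Basis(raw.get("basis", "ci95"))
    value = raw.get("value")
    if value is None and basis is not Basis.BOUND_ONLY:
        problems.append("value")
    if problems:
        raise FixtureError(f"entry {name!r}: missing fields {problems}")
    for fname in ("value", "low", "high", "upper_bound", "cot"):
        v = raw.get(fname)
        if v is not None and (not isinstance(v, (int, float)) or not math.isfinite(v) or v < 0):
            raise FixtureError(f"entry {name!r}: field {fname} must be a nonnegative number")
    entry = FixtureEntry(
        name=name,
        value=None if value is None else float(value),
        units=str(raw["units"]),
        provenance=str(raw["provenance"]),
        low=None if raw.get("low") is None else float(raw["low"]),
        high=None if raw.get("high") is None else float(raw["high"]),
        upper_bound=None if raw.get("upper_bound") is None else float(raw["upper_bound"]),
        basis=basis,
        cot=None if raw.get("cot") is None else float(raw["cot"]),
        analogue=str(raw.get("analogue", "")),
    )
    entry.uncertain()  # validates interval ordering
    return entry


def load_fixtures(path=None) -> FixtureSet:
    """Load a fixture YAML file; defaults to the bundled headline values."""
    if path is None:
        text = resources.files("biomove.data").joinpath(_DEFAULT_RESOURCE).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise FixtureError("fixture file must contain a top-level 'entries' mapping")
    entries = {name: _parse_entry(name, raw) for name, raw in doc["entries"].items()}
    return FixtureSet(entries)
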