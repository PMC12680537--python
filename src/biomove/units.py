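"""Shared unit conventions.

Internal canonical units are tonnes, kilometres and years; headline
quantities are displayed in Gt km yr^-1. Every module reads its conversion
constants from one shared :data:`UNITS` instance so the whole pipeline
agrees on, e.g., the length of a year.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class UnitConventions:
    """Conversion constants used throughout the package.

    All constants are strictly positive and fixed at construction.
    """

    days_per_year: float = 365.0
    seconds_per_year: float = 3.1536e7
    joules_per_twh: float = 3.6e15
    joules_per_kcal: float = 4184.0
    tonnes_per_gt: float = 1e9
    kg_per_tonne: float = 1e3
    earth_radius_km: float = 6371.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValueError(f"unit constant {f.name} must be strictly positive, got {v!r}")


#: The shared instance read by every operation in the package.
UNITS = UnitConventions()
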