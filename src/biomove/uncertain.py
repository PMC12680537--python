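"""Interval-style uncertain values and conservative propagation.

A group estimate carries a central value together with a lower/upper
uncertainty range (from 95% CIs or extrema, depending on data quality) and
optionally a hard upper bound that is robust to systematic under-sampling.
Ranges of aggregated groups are combined by the arithmetic sum of the
sub-group uncertainties — deliberately conservative compared with
quadrature, which is offered as an off-by-default alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import InvalidArgumentError


class Basis(str, Enum):
    """Provenance of an uncertainty range."""

    CI95 = "ci95"
    EXTREMA = "extrema"
    BOUND_ONLY = "bound_only"


def _finite_nonneg(x: float, name: str) -> None:
    if not math.isfinite(x) or x < 0:
        raise InvalidArgumentError(f"{name} must be finite and >= 0, got {x!r}")


@dataclass(frozen=True)
class UncertainValue:
    """A nonnegative quantity with an uncertainty range.

    ``low <= mean <= high``; if a ``hard_upper_bound`` is present it
    dominates ``high``. A ``bound_only`` value has no central estimate at
    all — only the bound — and is used for groups with insufficient
    movement data.
    """

    mean: Optional[float]
    low: Optional[float] = None
    high: Optional[float] = None
    basis: Basis = Basis.CI95
    hard_upper_bound: Optional[float] = None

    def __post_init__(self) -> None:
        if self.basis is Basis.BOUND_ONLY:
            if self.hard_upper_bound is None:
                raise InvalidArgumentError("bound_only value requires hard_upper_bound")
            _finite_nonneg(self.hard_upper_bound, "hard_upper_bound")
            return
        if self.mean is None:
            raise InvalidArgumentError("non-bound value requires a mean")
        low = self.mean if self.low is None else self.low
        high = self.mean if self.high is None else self.high
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)
        for name in ("mean", "low", "high"):
            _finite_nonneg(getattr(self, name), name)
        if not (self.low <= self.mean <= self.high):
            raise InvalidArgumentError(
                f"interval ordering violated: low={self.low} mean={self.mean} high={self.high}"
            )
        if self.hard_upper_bound is not None:
            _finite_nonneg(self.hard_upper_bound, "hard_upper_bound")
            if self.hard_upper_bound < self.high:
                raise InvalidArgumentError(
                    f"hard_upper_bound {self.hard_upper_bound} < high {self.high}"
                )

    # -- constructors -------------------------------------------------
    @classmethod
    def exact(cls, x: float) -> "UncertainValue":
        """A value with zero-width uncertainty."""
        return cls(mean=x, low=x, high=x, basis=Basis.EXTREMA)

    @classmethod
    def bound(cls, upper: float) -> "UncertainValue":
        return cls(mean=None, basis=Basis.BOUND_ONLY, hard_upper_bound=upper)

    # -- helpers ------------------------------------------------------
    @property
    def is_bound_only(self) -> bool:
        return self.basis is Basis.BOUND_ONLY

    @property
    def upper(self) -> float:
        """The most defensible upper limit: the hard bound if present, else ``high``."""
        if self.hard_upper_bound is not None:
            return self.hard_upper_bound
        if self.high is None:
            raise InvalidArgumentError("value has neither high nor hard_upper_bound")
        return self.high

    def scaled(self, k: float) -> "UncertainValue":
        """Multiply by a nonnegative constant (unit conversion, annualization)."""
        _finite_nonneg(k, "scale factor")
        if self.is_bound_only:
            return UncertainValue.bound(self.hard_upper_bound * k)
        hub = None if self.hard_upper_bound is None else self.hard_upper_bound * k
        return UncertainValue(self.mean * k, self.low * k, self.high * k, self.basis, hub)

    def times(self, other: "UncertainValue") -> "UncertainValue":
        """Endpoint product (low*low, mean*mean, high*high).

        Conservative for the product of two positively-correlated or
        independent nonnegative ranges; used for biomass x distance.
        """
        if self.is_bound_only or other.is_bound_only:
            return UncertainValue.bound(self.upper * other.upper)
        basis = self.basis if self.basis == other.basis else Basis.EXTREMA
        hub = None
        if self.hard_upper_bound is not None or other.hard_upper_bound is not None:
            hub = self.upper * other.upper
        return UncertainValue(
            self.mean * other.mean, self.low * other.low, self.high * other.high, basis, hub
        )

    def with_basis(self, basis: Basis) -> "UncertainValue":
        return replace(self, basis=basis)


def propagate_uncertainty(
    children: Sequence[UncertainValue], method: str = "arithmetic_sum"
) -> UncertainValue:
    """Sum child estimates, combining their uncertainty ranges.

    ``arithmetic_sum`` (the default) adds the lower and upper offsets of the
    children — the conservative convention used for every aggregate in this
    package. ``quadrature`` root-sum-squares the offsets instead and is
    strictly narrower whenever more than one child has nonzero width.
    """
    children = [c for c in children]
    if not children:
        raise InvalidArgumentError("propagate_uncertainty requires a nonempty list")
    if any(c.is_bound_only for c in children):
        raise InvalidArgumentError("bound_only children cannot enter a mean aggregate")
    if method not in ("arithmetic_sum", "quadrature"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    mean = math.fsum(c.mean for c in children)
    lo_off = [c.mean - c.low for c in children]
    hi_off = [c.high - c.mean for c in children]
    if method == "arithmetic_sum":
        low = mean - math.fsum(lo_off)
        high = mean + math.fsum(hi_off)
    else:
        low = mean - math.sqrt(math.fsum(o * o for o in lo_off))
        high = mean + math.sqrt(math.fsum(o * o for o in hi_off))
    bases = {c.basis for c in children}
    basis = bases.pop() if len(bases) == 1 else Basis.EXTREMA
    hubs = [c.hard_upper_bound for c in children]
    hub = None
    if any(h is not None for h in hubs):
        hub = math.fsum(c.upper for c in children)
        hub = max(hub, high)
    return UncertainValue(mean, max(low, 0.0), high, basis, hub)


def sum_bounds(children: Iterable[UncertainValue]) -> Optional[float]:
    """Upper bound of a sum: add each child's hard bound, falling back to its high."""
    total = 0.0
    saw_bound = False
    for c in children:
        if c.hard_upper_bound is not None:
            saw_bound = True
            total += c.hard_upper_bound
        elif c.high is not None:
            total += c.high
        else:
            return None
    return total if saw_bound else None
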