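"""Exact dual-isotope bookkeeping for iron.

Every Fe reservoir in the model is carried as a pair of amounts
(``fe56``, ``fe54``) rather than as (total, delta), so that conservation of
each isotope is exact to machine precision.  Delta notation is defined
relative to the IRMM-014 reference material,

    delta56Fe [permil] = ((fe56/fe54) / R_std - 1) * 1000,

with R_std = (56Fe/54Fe)_IRMM-014 ~ 15.67.  The much smaller 57Fe and 58Fe
abundances are neglected throughout, so the "light" isotope 54Fe stands for
everything that is not 56Fe.

Two flux-splitting rules convert a bulk Fe flux into its isotope pair:

* at an external source the flux carries a prescribed endmember delta
  (:func:`split_source_flux`);
* during an internal transformation the flux samples the donor pool's
  instantaneous ratio, optionally biased by a fractionation factor alpha
  (:func:`split_process_flux`); alpha < 1 favours light Fe, alpha > 1
  heavy Fe.

Both rules preserve the bulk flux exactly: ``j56 + j54 == j`` by
construction (the second component is computed as a difference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "IRMM014_RATIO",
    "DEFAULT_STANDARD",
    "ReferenceStandard",
    "IsotopePool",
    "IsotopeFluxPair",
    "FractionationFactor",
    "UndefinedRatioError",
    "InvalidDeltaError",
    "ratio_from_delta",
    "delta_from_ratio",
    "delta_of",
    "pool_from_total_delta",
    "split_source_flux",
    "split_process_flux",
]

#: 56Fe/54Fe of the IRMM-014 iron isotope reference material.
IRMM014_RATIO = 15.67

ArrayLike = Union[float, np.ndarray]


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a delta is requested for a pool with no 54Fe."""


class InvalidDeltaError(ValueError):
    """Raised for a delta value at or below -1000 permil (ratio <= 0)."""


@dataclass(frozen=True)
class ReferenceStandard:
    """Isotope reference material defined by its 56Fe/54Fe ratio."""

    r56_54: float = IRMM014_RATIO

    def __post_init__(self) -> None:
        if not self.r56_54 > 0:
            raise ValueError(f"reference ratio must be positive, got {self.r56_54}")


DEFAULT_STANDARD = ReferenceStandard()


@dataclass(frozen=True)
class FractionationFactor:
    """Dimensionless isotope fractionation factor alpha.

    Values outside (0.9, 1.1) are almost certainly input mistakes for iron
    (natural mass-dependent effects are a few permil at most); the sanity
    bound can be lifted with ``strict=False`` for deliberately extreme
    sensitivity runs.
    """

    alpha: float
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.strict and not (0.9 < self.alpha < 1.1):
            raise ValueError(
                f"alpha={self.alpha} outside sanity bounds (0.9, 1.1); "
                "pass strict=False to override"
            )

    @property
    def epsilon(self) -> float:
        """First-order enrichment (alpha - 1) * 1000, in permil."""
        return (self.alpha - 1.0) * 1000.0

    @property
    def inverse(self) -> "FractionationFactor":
        return FractionationFactor(1.0 / self.alpha, strict=self.strict)


def _alpha_value(alpha: Union[float, FractionationFactor]) -> float:
    return alpha.alpha if isinstance(alpha, FractionationFactor) else float(alpha)


@dataclass
class IsotopePool:
    """Paired (56Fe, 54Fe) amounts of any Fe tracer.

    Amounts are concentrations (mol m-3) or inventories (mol); both
    components share the units, and the bulk amount is their sum.
    Components may be scalars or numpy arrays of matching shape.
    """

    fe56: ArrayLike
    fe54: ArrayLike

    @property
    def total(self) -> ArrayLike:
        return self.fe56 + self.fe54

    def delta(self, std: ReferenceStandard = DEFAULT_STANDARD, name: str = "pool") -> ArrayLike:
        return delta_of(self, std, name=name)

    def __add__(self, other: "IsotopePool") -> "IsotopePool":
        return IsotopePool(self.fe56 + other.fe56, self.fe54 + other.fe54)


@dataclass
class IsotopeFluxPair:
    """A bulk flux split into its 56Fe and 54Fe components (same units)."""

    j56: ArrayLike
    j54: ArrayLike

    @property
    def total(self) -> ArrayLike:
        return self.j56 + self.j54

    def delta(self, std: ReferenceStandard = DEFAULT_STANDARD, name: str = "flux") -> ArrayLike:
        return delta_of(IsotopePool(self.j56, self.j54), std, name=name)

    def scaled(self, factor: ArrayLike) -> "IsotopeFluxPair":
        return IsotopeFluxPair(self.j56 * factor, self.j54 * factor)

    def __add__(self, other: "IsotopeFluxPair") -> "IsotopeFluxPair":
        return IsotopeFluxPair(self.j56 + other.j56, self.j54 + other.j54)


def ratio_from_delta(delta: ArrayLike, std: ReferenceStandard = DEFAULT_STANDARD) -> ArrayLike:
    """56Fe/54Fe ratio corresponding to a delta value (permil)."""
    delta = np.asarray(delta, dtype=float) if np.ndim(delta) else float(delta)
    if np.any(np.asarray(delta) <= -1000.0):
        raise InvalidDeltaError(f"delta={delta} permil implies a non-positive isotope ratio")
    return std.r56_54 * (delta / 1000.0 + 1.0)


def delta_from_ratio(ratio: ArrayLike, std: ReferenceStandard = DEFAULT_STANDARD) -> ArrayLike:
    """Delta (permil) corresponding to a 56Fe/54Fe ratio."""
    return (np.asarray(ratio, dtype=float) / std.r56_54 - 1.0) * 1000.0 if np.ndim(ratio) else (
        float(ratio) / std.r56_54 - 1.0
    ) * 1000.0


def delta_of(
    pool: IsotopePool,
    std: ReferenceStandard = DEFAULT_STANDARD,
    name: str = "pool",
) -> ArrayLike:
    """Delta (permil) of an isotope pool relative to the standard.

    Raises :class:`UndefinedRatioError` if the pool holds no 54Fe anywhere.
    """
    fe54 = np.asarray(pool.fe54, dtype=float)
    if np.any(fe54 <= 0.0):
        raise UndefinedRatioError(
            f"delta of '{name}' undefined: 54Fe amount is zero (or negative)"
        )
    ratio = np.asarray(pool.fe56, dtype=float) / fe54
    out = (ratio / std.r56_54 - 1.0) * 1000.0
    return out if np.ndim(pool.fe56) or np.ndim(pool.fe54) else float(out)


def pool_from_total_delta(
    total: ArrayLike,
    delta: ArrayLike,
    std: ReferenceStandard = DEFAULT_STANDARD,
) -> IsotopePool:
    """Construct a pool from a bulk amount and its delta.

    The heavy fraction is r/(1+r) with r the sample ratio implied by the
    delta; for delta = 0 this is the natural 56Fe abundance implied by the
    reference ratio (15.67/16.67 ~ 0.940, the "ca. 94%" of natural iron).
    ``fe56 + fe54 == total`` exactly (fe54 is computed by difference).
    """
    scalar = not (np.ndim(total) or np.ndim(delta))
    total_a = np.asarray(total, dtype=float)
    if np.any(total_a < 0.0):
        raise ValueError("total Fe amount must be non-negative")
    r = ratio_from_delta(delta, std)
    fe56 = total_a * (np.asarray(r) / (np.asarray(r) + 1.0))
    fe54 = total_a - fe56
    if scalar:
        return IsotopePool(float(fe56), float(fe54))
    return IsotopePool(fe56, fe54)


def split_source_flux(
    j: ArrayLike,
    endmember: ArrayLike,
    std: ReferenceStandard = DEFAULT_STANDARD,
) -> IsotopeFluxPair:
    """Split a bulk source flux using a prescribed endmember delta.

    j56 = j * R/(R+1), j54 = j - j56 with R the endmember's sample ratio, so
    the bulk input strength is unchanged and the recombined delta equals the
    endmember exactly.
    """
    scalar = not (np.ndim(j) or np.ndim(endmember))
    j_a = np.asarray(j, dtype=float)
    if np.any(j_a < 0.0):
        raise ValueError("source flux must be non-negative")
    r = np.asarray(ratio_from_delta(endmember, std))
    j56 = j_a * (r / (r + 1.0))
    j54 = j_a - j56
    if scalar:
        return IsotopeFluxPair(float(j56), float(j54))
    return IsotopeFluxPair(j56, j54)


def split_process_flux(
    j_proc: ArrayLike,
    donor: IsotopePool,
    alpha: Union[float, FractionationFactor] = 1.0,
) -> IsotopeFluxPair:
    """Split a bulk process flux against the donor pool's instantaneous ratio.

    j56 = j * R a / (R a + 1) with R = donor.fe56/donor.fe54 and a the
    fractionation factor; j54 is the remainder.  To first order the
    transferred delta differs from the donor's by (a - 1) * 1000 permil.
    Cells where the donor is empty (fe54 = 0) must carry zero flux.
    """
    a = _alpha_value(alpha)
    scalar = not (
        np.ndim(j_proc) or np.ndim(donor.fe56) or np.ndim(donor.fe54)
    )
    j_a = np.asarray(j_proc, dtype=float)
    if np.any(j_a < 0.0):
        raise ValueError("process flux must be non-negative")
    fe54 = np.asarray(donor.fe54, dtype=float)
    fe56 = np.asarray(donor.fe56, dtype=float)
    empty = fe54 <= 0.0
    if np.any(empty & (j_a > 0.0)):
        raise UndefinedRatioError("process flux drawn from a donor pool with no 54Fe")
    ratio = np.where(empty, 1.0, fe56 / np.where(empty, 1.0, fe54))
    w = ratio * a
    j56 = np.where(empty, 0.0, j_a * (w / (w + 1.0)))
    j54 = j_a - j56
    if scalar:
        return IsotopeFluxPair(float(j56), float(j54))
    return IsotopeFluxPair(j56, j54)
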