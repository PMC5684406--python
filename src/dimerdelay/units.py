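"""Conversion between spectroscopic wavenumbers (cm⁻¹) and angular rates (fs⁻¹).

Vibrational-bath coupling strengths in the light-harvesting literature are
quoted in wavenumbers, while the equations of motion propagate amplitudes
with rates in inverse femtoseconds.  A wavenumber ``x`` cm⁻¹ corresponds to
the angular frequency ``2π·c·x`` with the speed of light ``c`` expressed in
cm/fs; the plain (non-angular) convention ``c·x`` is also selectable, since
figure captions alone cannot disambiguate which one a given dataset used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_CM_PER_FS",
    "ANGULAR_FACTOR",
    "PLAIN_FACTOR",
    "Quantity",
    "wavenumber_to_rate",
    "rate_to_wavenumber",
]

#: Speed of light in cm per femtosecond (exact, CODATA definition of c).
SPEED_OF_LIGHT_CM_PER_FS = 2.99792458e-5

#: cm⁻¹ → fs⁻¹ factor under the angular-frequency convention (default).
ANGULAR_FACTOR = 2.0 * np.pi * SPEED_OF_LIGHT_CM_PER_FS

#: cm⁻¹ → fs⁻¹ factor under the plain-frequency convention.
PLAIN_FACTOR = SPEED_OF_LIGHT_CM_PER_FS

_FACTORS = {"angular": ANGULAR_FACTOR, "plain": PLAIN_FACTOR}

_UNITS = ("cm-1", "fs-1", "fs", "rad")


def _factor(convention: str) -> float:
    try:
        return _FACTORS[convention]
    except KeyError:
        raise ValueError(
            f"unknown convention {convention!r}; use 'angular' or 'plain'"
        ) from None


def _check_nonnegative(x, what: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} must be finite and non-negative, got {x!r}")
    return arr if arr.ndim else float(arr)


def wavenumber_to_rate(x, convention: str = "angular"):
    """Convert a wavenumber in cm⁻¹ to an angular rate in fs⁻¹.

    Parameters
    ----------
    x : float or array_like
        Wavenumber(s) in cm⁻¹; must be non-negative (rates and delays in
        this model are magnitudes).
    convention : {"angular", "plain"}
        ``"angular"`` multiplies by 2πc (default, appropriate when the rate
        multiplies amplitudes directly in the equation of motion);
        ``"plain"`` multiplies by c.
    """
    return _check_nonnegative(x, "wavenumber") * _factor(convention)


def rate_to_wavenumber(x, convention: str = "angular"):
    """Convert an angular rate in fs⁻¹ to a wavenumber in cm⁻¹ (exact inverse
    of :func:`wavenumber_to_rate` under the same convention)."""
    return _check_nonnegative(x, "rate") / _factor(convention)


@dataclass(frozen=True)
class Quantity:
    """A number tagged with one of the units used by this package.

    Only the conversions the model needs are supported: ``cm-1`` ↔ ``fs-1``.
    Times (``fs``) and phases (``rad``) carry no conversions.
    """

    value: float
    unit: str

    def __post_init__(self):
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; one of {_UNITS}")
        if self.unit in ("cm-1", "fs-1", "fs") and self.value < 0:
            raise ValueError(f"{self.unit} quantities must be non-negative")

    def to(self, unit: str, convention: str = "angular") -> "Quantity":
        if unit == self.unit:
            return self
        if (self.unit, unit) == ("cm-1", "fs-1"):
            return Quantity(wavenumber_to_rate(self.value, convention), unit)
        if (self.unit, unit) == ("fs-1", "cm-1"):
            return Quantity(rate_to_wavenumber(self.value, convention), unit)
        raise ValueError(f"no conversion from {self.unit!r} to {unit!r}")
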