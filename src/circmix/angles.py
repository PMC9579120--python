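"""Circular (angular) primitives shared by every other module.

All public functions work in radians on the canonical interval (-pi, pi].
Unit conversion from the three supported input conventions — ``degrees``
(1-360), ``degrees_180`` (1-180, for axial stimuli such as bar
orientations), and ``radians`` — happens once at ingestion; everything
downstream assumes canonical radians.

Axial (``degrees_180``) data are doubled onto the full circle before any
computation, the standard treatment of orientation data.  Concentration
estimates therefore live in the doubled space; linear summaries of error
(mean absolute error, bias) are halved back to the native scale by the
summary-statistics layer.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

__all__ = [
    "UNITS",
    "wrap_angle",
    "convert_to_radians",
    "convert_from_radians",
    "vm_pdf",
    "vm_logpdf",
    "vm_sample",
    "CircularMoments",
    "circular_moments",
    "kappa_to_R",
    "kappa_to_sd",
    "sd_to_kappa",
]

#: Supported angular unit tags for input data.
UNITS = ("degrees", "degrees_180", "radians")

_TWO_PI = 2.0 * np.pi


def _check_unit(unit: str) -> None:
    if unit not in UNITS:
        raise ValueError(
            f"unknown angular unit {unit!r}; expected one of {UNITS}"
        )


def wrap_angle(x):
    """Wrap angles (radians) onto the canonical interval (-pi, pi].

    Idempotent and 2*pi-periodic.  Accepts scalars or arrays; NaN is
    propagated (missing non-targets) but +/-inf raises.
    """
    x = np.asarray(x, dtype=float)
    if np.isinf(x).any():
        raise ValueError("angles must be finite (or NaN for missing values)")
    wrapped = np.mod(x, _TWO_PI)
    # mod maps onto [0, 2pi); fold the open upper half-circle down
    wrapped = np.where(wrapped > np.pi, wrapped - _TWO_PI, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def convert_to_radians(values, unit: str = "degrees"):
    """Convert angles in the declared unit to canonical radians.

    degrees (1-360) are mapped by pi/180 then wrapped; degrees_180 data
    are doubled onto the full circle first; radians are wrapped as-is.
    Values outside the declared unit's nominal range are wrapped with a
    warning rather than rejected.
    """
    _check_unit(unit)
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        if unit == "degrees":
            out_of_range = (values < -360) | (values > 360)
            radians = np.deg2rad(values)
        elif unit == "degrees_180":
            out_of_range = (values < -180) | (values > 180)
            radians = np.deg2rad(2.0 * values)
        else:
            out_of_range = (values < -_TWO_PI) | (values > _TWO_PI)
            radians = values
    if bool(np.nansum(out_of_range)):
        warnings.warn(
            f"{int(np.nansum(out_of_range))} value(s) outside the nominal "
            f"range of unit {unit!r}; wrapping onto the circle",
            stacklevel=2,
        )
    return wrap_angle(radians)


def convert_from_radians(values, unit: str = "radians"):
    """Inverse of :func:`convert_to_radians` (used when writing tables)."""
    _check_unit(unit)
    values = np.asarray(wrap_angle(values), dtype=float)
    if unit == "degrees":
        return np.mod(np.rad2deg(values), 360.0)
    if unit == "degrees_180":
        return np.mod(np.rad2deg(values) / 2.0, 180.0)
    return values


def vm_pdf(x, mu=0.0, kappa: float = 1.0):
    """von Mises probability density at ``x`` (radians).

    Evaluated in exponentially scaled form,
    exp(kappa*(cos(x - mu) - 1)) / (2*pi*i0e(kappa)), which is stable for
    concentrations up to the thousands.
    """
    if kappa < 0 or not np.isfinite(kappa):
        raise ValueError(f"kappa must be finite and >= 0, got {kappa}")
    x = np.asarray(x, dtype=float)
    out = np.exp(kappa * (np.cos(x - mu) - 1.0)) / (_TWO_PI * i0e(kappa))
    return out if out.ndim else float(out)


def vm_logpdf(x, mu=0.0, kappa: float = 1.0):
    """Log of :func:`vm_pdf`, computed directly in log space."""
    if kappa < 0 or not np.isfinite(kappa):
        raise ValueError(f"kappa must be finite and >= 0, got {kappa}")
    x = np.asarray(x, dtype=float)
    out = kappa * (np.cos(x - mu) - 1.0) - np.log(_TWO_PI * i0e(kappa))
    return out if out.ndim else float(out)


def vm_sample(n: int, mu: float = 0.0, kappa: float = 0.0, rng=None):
    """Draw ``n`` i.i.d. von Mises angles, wrapped to (-pi, pi]."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    rng = np.random.default_rng(rng)
    return wrap_angle(rng.vonmises(mu, kappa, size=int(n)))


class CircularMoments(NamedTuple):
    mean: float  #: circular mean direction, radians in (-pi, pi]
    R: float  #: mean resultant vector length in [0, 1]
    sd: float  #: circular standard deviation sqrt(-2 ln R); inf at R == 0


def circular_moments(angles) -> CircularMoments:
    """First circular moment of a sample: mean direction, R, circular SD.

    R = 1 means every angle coincides; R = 0 means full dispersion, for
    which the circular SD is reported as +inf (a legitimate outcome for
    uniform data, not an error).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular_moments requires at least one angle")
    z = np.exp(1j * angles).mean()
    R = min(float(np.abs(z)), 1.0)
    if R < 1e-12:  # fully dispersed up to float round-off
        R = 0.0
    mean = wrap_angle(float(np.angle(z)))
    sd = np.sqrt(-2.0 * np.log(R)) if R > 0 else np.inf
    return CircularMoments(mean=mean, R=R, sd=float(sd))


def kappa_to_R(kappa: float) -> float:
    """Mean resultant length A(kappa) = I1(kappa)/I0(kappa) of a von Mises law."""
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    # scaled Bessel ratio: the exp(kappa) factors cancel, stable at large kappa
    return float(i1e(kappa) / i0e(kappa))


def kappa_to_sd(kappa: float) -> float:
    """Circular SD sqrt(-2 ln A(kappa)) implied by concentration ``kappa``."""
    R = kappa_to_R(kappa)
    return float(np.sqrt(-2.0 * np.log(R))) if R > 0 else np.inf


def sd_to_kappa(sd: float, tol: float = 1e-10) -> float:
    """Invert :func:`kappa_to_sd` by monotone bracketing of A(kappa).

    A(kappa) is strictly increasing on [0, inf), so the root is unique.
    """
    if not sd > 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    target_R = float(np.exp(-(sd**2) / 2.0))
    if target_R <= 0.0:
        return 0.0
    lo, hi = 1e-12, 2.0
    while kappa_to_R(hi) < target_R:
        hi *= 4.0
        if hi > 1e12:  # pragma: no cover - unreachable for representable sd
            raise RuntimeError("failed to bracket kappa inversion")
    return float(brentq(lambda k: kappa_to_R(k) - target_R, lo, hi, xtol=tol))
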