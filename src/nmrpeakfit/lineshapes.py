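"""One- and two-dimensional NMR line-shape models.

Four 1D profiles are supported, all normalized to unit height at the
center so that the fitted amplitude of a peak *is* its apex intensity:

* ``gaussian``   — ``exp(-4 ln2 (x-c)^2 / fwhm^2)``
* ``lorentzian`` — ``1 / (1 + 4 (x-c)^2 / fwhm^2)``
* ``galore``     — pseudo-Voigt: ``a*gaussian + (1-a)*lorentzian`` with a
  single shared FWHM and mixing fraction ``a`` in [0, 1]
* ``voigt``      — true convolution of a Gaussian (standard deviation
  ``sigma``) and a Lorentzian (half-width at half-maximum ``gamma``),
  evaluated through the Faddeeva function ``w(z)``

2D peaks are separable products ``amplitude * f1(x1) * f2(x2)``, the
standard model for absorption-mode cross peaks.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import wofz

if TYPE_CHECKING:  # pragma: no cover
    from .spectrum_io import AxisCalibration

__all__ = [
    "ShapeKind",
    "ShapeParams1D",
    "ShapeParams2D",
    "eval_shape_1d",
    "shape_volume_1d",
    "eval_shape_2d",
    "shape_volume_2d",
    "gaussian_fwhm_from_sigma",
    "sigma_from_gaussian_fwhm",
]

_4LN2 = 4.0 * math.log(2.0)
#: FWHM of a unit-σ Gaussian, 2 sqrt(2 ln 2)
_GAUSS_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class ShapeKind(str, enum.Enum):
    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"
    GALORE = "galore"
    VOIGT = "voigt"


def gaussian_fwhm_from_sigma(sigma: float) -> float:
    """FWHM of a Gaussian with standard deviation ``sigma``."""
    return _GAUSS_FWHM_PER_SIGMA * sigma


def sigma_from_gaussian_fwhm(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given FWHM."""
    return fwhm / _GAUSS_FWHM_PER_SIGMA


@dataclass
class ShapeParams1D:
    """Parameters of one 1D line shape.

    ``fwhm`` applies to gaussian/lorentzian/galore; ``mixing_a`` to galore
    only; voigt uses ``sigma`` (Gaussian SD) and ``gamma`` (Lorentzian HWHM)
    instead of a single width.  All widths are in ppm.
    """

    kind: ShapeKind
    center: float
    fwhm: float | None = None
    mixing_a: float | None = None
    sigma: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        self.kind = ShapeKind(self.kind)
        if self.kind is ShapeKind.VOIGT:
            if self.sigma is None or self.gamma is None:
                raise ValueError("voigt requires sigma and gamma")
            if self.sigma <= 0:
                raise ValueError(f"voigt sigma must be > 0, got {self.sigma}")
            if self.gamma < 0:
                raise ValueError(f"voigt gamma must be >= 0, got {self.gamma}")
        else:
            if self.fwhm is None or self.fwhm <= 0:
                raise ValueError(f"{self.kind.value} requires fwhm > 0, got {self.fwhm}")
            if self.kind is ShapeKind.GALORE:
                if self.mixing_a is None or not (0.0 <= self.mixing_a <= 1.0):
                    raise ValueError(
                        f"galore mixing fraction must be in [0, 1], got {self.mixing_a}"
                    )


@dataclass
class ShapeParams2D:
    """Separable 2D peak: ``amplitude * f1(x1) * f2(x2)``.

    ``f1`` is the indirect dimension, ``f2`` the direct (acquisition)
    dimension; ``amplitude`` is the apex height and may be negative
    (e.g. folded peaks or inversion-recovery planes).
    """

    f1: ShapeParams1D
    f2: ShapeParams1D
    amplitude: float = 1.0


def _voigt_norm(sigma: float, gamma: float) -> float:
    """Re[w(i gamma / (sigma sqrt2))] — the apex value of the raw Faddeeva form."""
    z0 = 1j * gamma / (sigma * math.sqrt(2.0))
    return float(wofz(z0).real)


def eval_shape_1d(p: ShapeParams1D, x) -> np.ndarray | float:
    """Evaluate the unit-height line shape at ppm position(s) ``x``."""
    x = np.asarray(x, dtype=float)
    d = x - p.center
    if p.kind is ShapeKind.GAUSSIAN:
        out = np.exp(-_4LN2 * d * d / (p.fwhm * p.fwhm))
    elif p.kind is ShapeKind.LORENTZIAN:
        out = 1.0 / (1.0 + 4.0 * d * d / (p.fwhm * p.fwhm))
    elif p.kind is ShapeKind.GALORE:
        a = p.mixing_a
        g = np.exp(-_4LN2 * d * d / (p.fwhm * p.fwhm))
        l = 1.0 / (1.0 + 4.0 * d * d / (p.fwhm * p.fwhm))
        out = a * g + (1.0 - a) * l
    elif p.kind is ShapeKind.VOIGT:
        if p.gamma == 0.0:
            # Faddeeva form degenerates to a pure Gaussian; evaluate directly
            out = np.exp(-d * d / (2.0 * p.sigma * p.sigma))
        else:
            z = (d + 1j * p.gamma) / (p.sigma * math.sqrt(2.0))
            out = wofz(z).real / _voigt_norm(p.sigma, p.gamma)
    else:  # pragma: no cover
        raise ValueError(f"unknown shape kind {p.kind}")
    return out if out.ndim else float(out)


def shape_volume_1d(p: ShapeParams1D) -> float:
    """Analytic integral of the unit-height shape over the whole line (ppm units)."""
    if p.kind is ShapeKind.GAUSSIAN:
        return p.fwhm * math.sqrt(math.pi / _4LN2)
    if p.kind is ShapeKind.LORENTZIAN:
        return math.pi * p.fwhm / 2.0
    if p.kind is ShapeKind.GALORE:
        a = p.mixing_a
        return a * p.fwhm * math.sqrt(math.pi / _4LN2) + (1.0 - a) * math.pi * p.fwhm / 2.0
    if p.kind is ShapeKind.VOIGT:
        if p.gamma == 0.0:
            return p.sigma * math.sqrt(2.0 * math.pi)
        # raw Faddeeva profile has unit area scaled by 1/(sigma sqrt(2 pi));
        # dividing by the apex value Re[w(z0)] gives the unit-height area
        return math.sqrt(2.0 * math.pi) * p.sigma / _voigt_norm(p.sigma, p.gamma)
    raise ValueError(f"unknown shape kind {p.kind}")  # pragma: no cover


def eval_shape_2d(
    p: ShapeParams2D,
    box: tuple[tuple[int, int], tuple[int, int]],
    axes: tuple["AxisCalibration", "AxisCalibration"],
) -> np.ndarray:
    """Evaluate the separable 2D peak over a half-open grid box.

    ``box`` is ``((i1_lo, i1_hi), (i2_lo, i2_hi))`` in 0-based point
    indices; ``axes`` the (F1, F2) calibrations mapping points to ppm.
    Returns an array of shape ``(i1_hi - i1_lo, i2_hi - i2_lo)``.
    """
    (i1_lo, i1_hi), (i2_lo, i2_hi) = box
    if i1_hi <= i1_lo or i2_hi <= i2_lo:
        raise ValueError(f"empty evaluation box {box}")
    ax1, ax2 = axes
    x1 = ax1.point_to_ppm(np.arange(i1_lo, i1_hi, dtype=float))
    x2 = ax2.point_to_ppm(np.arange(i2_lo, i2_hi, dtype=float))
    f1 = eval_shape_1d(p.f1, x1)
    f2 = eval_shape_1d(p.f2, x2)
    return p.amplitude * np.outer(f1, f2)


def shape_volume_2d(p: ShapeParams2D) -> float:
    """Analytic 2D peak volume: amplitude times both 1D areas (ppm^2 * height)."""
    return p.amplitude * shape_volume_1d(p.f1) * shape_volume_1d(p.f2)
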