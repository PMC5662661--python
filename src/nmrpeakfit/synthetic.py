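"""Synthetic pseudo-3D spectra with known ground truth.

Every generated cube is a sum of separable 2D peaks whose per-plane
amplitudes follow a chosen intensity model (constant, exponential decay,
saturation recovery, or CPMG dispersion through the constant-time
intensity transform), plus seeded white Gaussian noise.  The generator
also emits the matching Sparky-style peak list, plane table, plain-matrix
planes and calibration sidecar, so the full pipeline can run on files it
has never seen.

Default study conditions mirror a small-protein 15N-1H correlation map:
a 15N indirect axis of ~22 ppm at 60.8 MHz and a 1H direct axis of
~3.3 ppm at 600 MHz, amide-like line widths, and overlap scenarios from
well-separated singletons up to an 11-peak cluster (the worst case seen
in crowded spectra).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intensity_models import DispersionParams, carver_richards_r2eff
from .lineshapes import ShapeKind, ShapeParams1D, ShapeParams2D, eval_shape_1d
from .spectrum_io import (
    AxisCalibration,
    Peak,
    PlaneKind,
    SpectrumCube,
    write_peak_list,
    write_plain_matrix,
    write_plane_table,
)

__all__ = [
    "PlaneModel",
    "TruthSpec",
    "TruthPeak",
    "default_axes",
    "make_cube",
    "make_overlap_scenario",
    "write_fixture_project",
]


class PlaneModel(str, enum.Enum):
    CONSTANT = "constant"
    EXPONENTIAL_DECAY = "exponential_decay"
    CPMG_DISPERSION = "cpmg_dispersion"
    RECOVERY = "recovery"


@dataclass
class TruthPeak:
    """One ground-truth peak: shape plus its intensity-model parameters."""

    assignment: str
    shape: ShapeParams2D
    rate: float = 0.0                       # R (s^-1) for decay / R1 for recovery
    dispersion: DispersionParams | None = None

    @property
    def position(self) -> tuple[float, float]:
        return (self.shape.f1.center, self.shape.f2.center)


@dataclass
class TruthSpec:
    """Full recipe for a synthetic cube; same spec -> identical cube."""

    peaks: list[TruthPeak]
    plane_model: PlaneModel = PlaneModel.CONSTANT
    noise_sigma: float = 0.0
    seed: int = 0
    T_relax: float = 0.04   # s, constant-time CPMG relaxation period


def default_axes(n1: int = 128, n2: int = 256) -> tuple[AxisCalibration, AxisCalibration]:
    """A 15N-1H amide-region axis pair at a 600 MHz spectrometer."""
    f1 = AxisCalibration(n_points=n1, spectral_width=1350.0, observe_freq=60.8,
                         carrier_ppm=118.0, label="15N")
    f2 = AxisCalibration(n_points=n2, spectral_width=2000.0, observe_freq=600.0,
                         carrier_ppm=8.3, label="1H")
    return f1, f2


def _plane_factor(tp: TruthPeak, model: PlaneModel, value: float, T_relax: float) -> float:
    if model is PlaneModel.CONSTANT:
        return 1.0
    if model is PlaneModel.EXPONENTIAL_DECAY:
        return math.exp(-tp.rate * value)
    if model is PlaneModel.RECOVERY:
        return 1.0 - math.exp(-tp.rate * value)
    if model is PlaneModel.CPMG_DISPERSION:
        if value == 0.0:
            return 1.0  # reference plane without the CPMG element
        if tp.dispersion is None:
            raise ValueError(f"peak {tp.assignment}: dispersion model without parameters")
        r2 = carver_richards_r2eff(tp.dispersion, value)
        return math.exp(-T_relax * r2)
    raise ValueError(f"unknown plane model {model}")  # pragma: no cover


def make_cube(
    spec: TruthSpec,
    axes: tuple[AxisCalibration, AxisCalibration] | None = None,
    plane_values: list[float] | None = None,
    plane_kind: PlaneKind | None = None,
) -> SpectrumCube:
    """Render a TruthSpec onto a grid and add seeded Gaussian noise."""
    axes = axes or default_axes()
    if plane_values is None:
        plane_values = [0.0]
    if plane_kind is None:
        plane_kind = {
            PlaneModel.CONSTANT: PlaneKind.GENERIC,
            PlaneModel.EXPONENTIAL_DECAY: PlaneKind.DELAY,
            PlaneModel.RECOVERY: PlaneKind.DELAY,
            PlaneModel.CPMG_DISPERSION: PlaneKind.CPMG_FIELD,
        }[spec.plane_model]
    x1 = np.asarray(axes[0].point_to_ppm(np.arange(axes[0].n_points, dtype=float)))
    x2 = np.asarray(axes[1].point_to_ppm(np.arange(axes[1].n_points, dtype=float)))
    n_planes = len(plane_values)
    data = np.zeros((n_planes, axes[0].n_points, axes[1].n_points))
    for tp in spec.peaks:
        prof = np.outer(eval_shape_1d(tp.shape.f1, x1), eval_shape_1d(tp.shape.f2, x2))
        for pl, v in enumerate(plane_values):
            amp = tp.shape.amplitude * _plane_factor(tp, spec.plane_model, v, spec.T_relax)
            data[pl] += amp * prof
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)
    cube = SpectrumCube(data=data, axes=axes)
    if plane_kind is not PlaneKind.GENERIC:
        cube.attach_plane_table(plane_values, plane_kind)
    return cube


def truth_peak_list(spec: TruthSpec, radii: tuple[float, float] = (0.45, 0.06)) -> list[Peak]:
    """Peaks at the exact ground-truth positions (for fitting the fixture)."""
    return [Peak(tp.assignment, tp.position, radii=radii) for tp in spec.peaks]


# ---------------------------------------------------------------------------
# canonical overlap scenarios

def _gauss2d(assign: str, c1: float, c2: float, amp: float,
             fwhm: tuple[float, float] = (0.35, 0.035),
             kind: ShapeKind = ShapeKind.GAUSSIAN) -> TruthPeak:
    if kind is ShapeKind.VOIGT:
        s = fwhm[0] / (2 * math.sqrt(2 * math.log(2)))
        f1 = ShapeParams1D(kind, c1, sigma=s, gamma=0.25 * fwhm[0])
        s2 = fwhm[1] / (2 * math.sqrt(2 * math.log(2)))
        f2 = ShapeParams1D(kind, c2, sigma=s2, gamma=0.25 * fwhm[1])
    elif kind is ShapeKind.GALORE:
        f1 = ShapeParams1D(kind, c1, fwhm=fwhm[0], mixing_a=0.6)
        f2 = ShapeParams1D(kind, c2, fwhm=fwhm[1], mixing_a=0.6)
    else:
        f1 = ShapeParams1D(kind, c1, fwhm=fwhm[0])
        f2 = ShapeParams1D(kind, c2, fwhm=fwhm[1])
    return TruthPeak(assign, ShapeParams2D(f1=f1, f2=f2, amplitude=amp))


def make_overlap_scenario(kind: str, shape_kind: ShapeKind = ShapeKind.GAUSSIAN,
                          noise_sigma: float = 0.0, seed: int = 0) -> TruthSpec:
    """Canonical peak configurations for grouping and co-fitting tests.

    * ``isolated`` — three well-separated peaks (all singleton groups);
    * ``chain3``   — three peaks in a chain at 1.2-1.4x FWHM spacing, the
      classic partially-overlapped trio that must be co-fitted;
    * ``clique11`` — an 11-peak cluster emulating the worst overlap in a
      crowded spectrum.
    """
    fwhm = (0.35, 0.035)
    if kind == "isolated":
        peaks = [
            _gauss2d("A10N-H", 112.0, 7.4, 100.0, fwhm, shape_kind),
            _gauss2d("G33N-H", 118.5, 8.3, 80.0, fwhm, shape_kind),
            _gauss2d("K94N-H", 124.0, 9.1, 120.0, fwhm, shape_kind),
        ]
    elif kind == "chain3":
        # spacing ~1.3 FWHM along F1, ~1.2 FWHM along F2: A-B and B-C
        # overlap at the default radii but A-C do not
        peaks = [
            _gauss2d("L20N-H", 117.40, 8.10, 100.0, fwhm, shape_kind),
            _gauss2d("S21N-H", 117.86, 8.14, 70.0, fwhm, shape_kind),
            _gauss2d("D22N-H", 118.32, 8.18, 110.0, fwhm, shape_kind),
        ]
    elif kind == "clique11":
        rng = np.random.default_rng(seed + 7)
        peaks = []
        for k in range(11):
            ang = 2 * math.pi * k / 11
            r = 0.55 if k % 2 else 0.30
            c1 = 118.0 + r * math.cos(ang)
            c2 = 8.30 + 0.055 * r * math.sin(ang) / 0.55
            amp = float(rng.uniform(50.0, 150.0))
            peaks.append(_gauss2d(f"X{40 + k}N-H", c1, c2, amp, fwhm, shape_kind))
    else:
        raise ValueError(f"unknown scenario {kind!r}")
    return TruthSpec(peaks=peaks, noise_sigma=noise_sigma, seed=seed)


def write_fixture_project(
    out_dir,
    spec: TruthSpec,
    axes: tuple[AxisCalibration, AxisCalibration] | None = None,
    plane_values: list[float] | None = None,
    radii: tuple[float, float] = (0.45, 0.06),
) -> dict:
    """Write a complete fixture project (planes, sidecar, list, plane table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    axes = axes or default_axes()
    cube = make_cube(spec, axes, plane_values)
    paths = write_plain_matrix(out, cube, stem="plane")
    peaks = truth_peak_list(spec, radii)
    list_path = out / "peaks.list"
    write_peak_list(list_path, peaks)
    table_path = None
    if cube.plane_kind is not PlaneKind.GENERIC:
        table_path = out / "planes.tab"
        write_plane_table(table_path, cube.plane_values)
    return {
        "cube": cube,
        "peaks": peaks,
        "planes": paths["planes"],
        "sidecar": paths["sidecar"],
        "peak_list": list_path,
        "plane_table": table_path,
    }
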