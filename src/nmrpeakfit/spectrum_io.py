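"""Spectrum, peak-list and plane-table I/O.

Coordinate conventions
----------------------
Internally everything is 0-based fractional point indices; every
user-facing file speaks ppm.  Point 0 sits at the high-ppm edge of the
window (standard NMR display convention: ppm decreases left to right),

    ppm(i)   = ppm_max - i * sw / (obs * n)
    ppm_max  = carrier_ppm + (sw / 2) / obs

Intervals in points are half-open ``[lo, hi)``.

Supported formats
-----------------
* NMRPipe binary 2D planes and pseudo-3D streams (see :mod:`._nmrpipe`);
* a plain-text matrix dialect (one whitespace-delimited matrix per plane
  plus a ``key: value`` calibration sidecar) used as the normative
  round-trip format;
* Sparky-style peak lists: ``assignment  w1_ppm  w2_ppm``;
* two-column plane-parameter tables: ``plane_index  value``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AxisCalibration",
    "SpectrumCube",
    "Peak",
    "PlaneKind",
    "FormatError",
    "read_nmrpipe",
    "write_nmrpipe",
    "read_plain_matrix",
    "write_plain_matrix",
    "read_peak_list",
    "write_peak_list",
    "read_plane_table",
    "write_plane_table",
    "ppm_to_point",
    "point_to_ppm",
    "fold_position",
]

#: default integration half-widths (ppm): 0.6 indirect, 0.08 direct
DEFAULT_RADII = (0.6, 0.08)


class FormatError(ValueError):
    """A file did not match its declared format."""


class PlaneKind(str, enum.Enum):
    DELAY = "delay"          # relaxation delay, s
    CPMG_FIELD = "cpmg_field"  # nu_CPMG, Hz
    OFFSET = "offset"        # saturation offset, Hz or ppm
    GENERIC = "generic"


@dataclass(frozen=True)
class AxisCalibration:
    """Frequency-axis calibration of one spectral dimension."""

    n_points: int
    spectral_width: float   # Hz
    observe_freq: float     # MHz
    carrier_ppm: float      # ppm at the window center
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.spectral_width <= 0:
            raise ValueError(f"spectral_width must be > 0, got {self.spectral_width}")
        if self.observe_freq <= 0:
            raise ValueError(f"observe_freq must be > 0, got {self.observe_freq}")

    @property
    def sw_ppm(self) -> float:
        """Spectral width in ppm."""
        return self.spectral_width / self.observe_freq

    @property
    def ppm_per_point(self) -> float:
        return self.spectral_width / (self.observe_freq * self.n_points)

    @property
    def ppm_max(self) -> float:
        """ppm of point 0 (high-field edge of the window)."""
        return self.carrier_ppm + 0.5 * self.sw_ppm

    @property
    def ppm_min(self) -> float:
        """ppm of (virtual) point n_points — the exclusive low edge."""
        return self.carrier_ppm - 0.5 * self.sw_ppm

    def ppm_to_point(self, x) -> np.ndarray | float:
        """Fractional point index of ppm position(s); may fall outside [0, n)."""
        x = np.asarray(x, dtype=float)
        out = (self.ppm_max - x) / self.ppm_per_point
        return out if out.ndim else float(out)

    def point_to_ppm(self, i) -> np.ndarray | float:
        i = np.asarray(i, dtype=float)
        out = self.ppm_max - i * self.ppm_per_point
        return out if out.ndim else float(out)

    def contains_ppm(self, x: float) -> bool:
        return self.ppm_min < x <= self.ppm_max


def ppm_to_point(axis: AxisCalibration, x):
    """Module-level alias of :meth:`AxisCalibration.ppm_to_point`."""
    return axis.ppm_to_point(x)


def point_to_ppm(axis: AxisCalibration, i):
    return axis.point_to_ppm(i)


@dataclass
class SpectrumCube:
    """A pseudo-3D stack of 2D planes sharing one pair of axis calibrations.

    ``plane_values`` carries the experimental parameter of each plane
    (relaxation delay in s, nu_CPMG in Hz, or saturation offset) once a
    plane table is attached; ``plane_kind`` stays ``generic`` until then.
    """

    data: np.ndarray  # (n_planes, n1, n2)
    axes: tuple[AxisCalibration, AxisCalibration]
    plane_values: list[float] = field(default_factory=list)
    plane_kind: PlaneKind = PlaneKind.GENERIC
    noise_rms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3D (planes, F1, F2), got {self.data.ndim}D")
        self.plane_kind = PlaneKind(self.plane_kind)
        if self.plane_kind is not PlaneKind.GENERIC and len(self.plane_values) != self.n_planes:
            raise ValueError(
                f"{len(self.plane_values)} plane values for {self.n_planes} planes"
            )

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def attach_plane_table(self, values: Sequence[float], kind: PlaneKind) -> None:
        """Attach experimental plane parameters; never reorders the data."""
        kind = PlaneKind(kind)
        if kind is not PlaneKind.GENERIC and len(values) != self.n_planes:
            raise ValueError(
                f"plane table has {len(values)} entries for {self.n_planes} planes"
            )
        self.plane_values = [float(v) for v in values]
        self.plane_kind = kind


@dataclass
class Peak:
    """One cross peak: assignment, (F1, F2) position in ppm and fit flags."""

    assignment: str
    position: tuple[float, float]
    radii: tuple[float, float] = DEFAULT_RADII
    fixed_position: tuple[bool, bool] = (False, False)
    fixed_width: tuple[bool, bool] = (False, False)
    group_id: int | None = None
    folded: tuple[bool, bool] = (False, False)

    def __post_init__(self) -> None:
        self.position = (float(self.position[0]), float(self.position[1]))
        self.radii = (float(self.radii[0]), float(self.radii[1]))
        if self.radii[0] <= 0 or self.radii[1] <= 0:
            raise ValueError(f"peak {self.assignment}: radii must be > 0, got {self.radii}")


def fold_position(x: float, axis: AxisCalibration) -> float:
    """Shift ``x`` by multiples of the spectral width (ppm) into the window.

    The number of width shifts is chosen to minimize the displacement,
    matching how peaks alias in an undersampled dimension.
    """
    sw = axis.sw_ppm
    n = round((axis.carrier_ppm - x) / sw)
    return x + n * sw


# ---------------------------------------------------------------------------
# peak lists

def read_peak_list(path) -> list[Peak]:
    """Parse a Sparky-style peak list: ``assignment w1_ppm w2_ppm`` per line.

    Lines starting with ``#`` and blank lines are skipped; an optional
    header line beginning with ``Assignment`` is tolerated.  Duplicate
    assignments are rejected.
    """
    peaks: list[Peak] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if lineno == 1 and parts[0].lower() == "assignment":
            continue
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 'assignment w1 w2', got {line!r}")
        name = parts[0]
        try:
            w1, w2 = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric position in {line!r}") from exc
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate assignment {name!r}")
        seen.add(name)
        peaks.append(Peak(assignment=name, position=(w1, w2)))
    return peaks


def write_peak_list(path, peaks: Iterable[Peak]) -> None:
    lines = ["# Assignment  w1_ppm  w2_ppm"]
    for p in peaks:
        lines.append(f"{p.assignment}  {p.position[0]:.5f}  {p.position[1]:.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# plane tables

def read_plane_table(path) -> list[float]:
    """Read a two-column ``index value`` table; returns values sorted by index."""
    rows: list[tuple[int, float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'index value', got {line!r}")
        try:
            rows.append((int(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric entry in {line!r}") from exc
    idx = [i for i, _ in rows]
    if sorted(idx) != list(range(len(rows))):
        raise FormatError(f"{path}: plane indices must be a permutation of 0..{len(rows)-1}")
    return [v for _, v in sorted(rows)]


def write_plane_table(path, values: Sequence[float]) -> None:
    Path(path).write_text(
        "".join(f"{i}  {v:.6g}\n" for i, v in enumerate(values))
    )


# ---------------------------------------------------------------------------
# plain-matrix dialect

_SIDECAR_FIELDS = ("label", "n_points", "spectral_width", "observe_freq", "carrier_ppm")


def _parse_sidecar(path) -> tuple[AxisCalibration, AxisCalibration]:
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, val = line.split(":", 1)
        kv[key.strip()] = val.strip()
    axes = []
    for dim in ("f1", "f2"):
        vals = {}
        for f in _SIDECAR_FIELDS:
            key = f"{dim}.{f}"
            if key not in kv:
                raise FormatError(f"{path}: missing calibration key {key!r}")
            vals[f] = kv[key]
        try:
            axes.append(
                AxisCalibration(
                    n_points=int(vals["n_points"]),
                    spectral_width=float(vals["spectral_width"]),
                    observe_freq=float(vals["observe_freq"]),
                    carrier_ppm=float(vals["carrier_ppm"]),
                    label=vals["label"],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: bad calibration for {dim}: {exc}") from exc
    return axes[0], axes[1]


def _read_matrix(path) -> np.ndarray:
    rows: list[list[float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rows.append([float(t) for t in line.split()])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric matrix entry") from exc
        if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
            raise FormatError(
                f"{path}: ragged matrix at row {len(rows) - 1} "
                f"({len(rows[-1])} columns, expected {len(rows[0])})"
            )
    if not rows:
        raise FormatError(f"{path}: empty matrix")
    return np.asarray(rows, dtype=float)


def read_plain_matrix(paths, calibration_sidecar) -> SpectrumCube:
    """Read one or more plain-text matrix planes plus a calibration sidecar.

    Each plane file is one whitespace-delimited ``n1 x n2`` matrix (rows =
    F1, columns = F2).  Plane order follows the order of ``paths``.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    axes = _parse_sidecar(calibration_sidecar)
    planes = [_read_matrix(p) for p in paths]
    shape = planes[0].shape
    for p, arr in zip(paths, planes):
        if arr.shape != shape:
            raise FormatError(f"{p}: plane shape {arr.shape} != first plane {shape}")
    expected = (axes[0].n_points, axes[1].n_points)
    if shape != expected:
        raise FormatError(
            f"matrix shape {shape} does not match sidecar calibration {expected}"
        )
    return SpectrumCube(data=np.stack(planes), axes=axes)


def write_plain_matrix(dir_path, cube: SpectrumCube, stem: str = "plane") -> dict[str, list]:
    """Write a cube as plain-matrix planes + sidecar; returns written paths."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    plane_paths = []
    for k in range(cube.n_planes):
        p = d / f"{stem}{k:03d}.txt"
        np.savetxt(p, cube.data[k], fmt="%.17g")
        plane_paths.append(p)
    sidecar = d / f"{stem}.axes"
    lines = []
    for dim, ax in zip(("f1", "f2"), cube.axes):
        lines += [
            f"{dim}.label: {ax.label}",
            f"{dim}.n_points: {ax.n_points}",
            f"{dim}.spectral_width: {ax.spectral_width!r}",
            f"{dim}.observe_freq: {ax.observe_freq!r}",
            f"{dim}.carrier_ppm: {ax.carrier_ppm!r}",
        ]
    sidecar.write_text("\n".join(lines) + "\n")
    return {"planes": plane_paths, "sidecar": sidecar}


# ---------------------------------------------------------------------------
# NMRPipe binary (implemented in _nmrpipe to keep header plumbing separate)

def read_nmrpipe(path) -> SpectrumCube:
    """Read an NMRPipe 2D plane or pseudo-3D stream into a SpectrumCube."""
    from ._nmrpipe import read_nmrpipe as _read

    return _read(path)


def write_nmrpipe(path, cube: SpectrumCube) -> None:
    from ._nmrpipe import write_nmrpipe as _write

    _write(path, cube)


def parse_residue_number(assignment: str) -> int | None:
    """Extract the residue number from a protein-style assignment.

    ``K94N-H`` -> 94, ``G33N-H`` -> 33; returns None when no leading
    letter+integer pattern is present.
    """
    m = re.match(r"^[A-Za-z]+(\d+)", assignment)
    return int(m.group(1)) if m else None
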