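"""Minimal NMRPipe binary codec for processed 2D planes and pseudo-3D streams.

Only the subset of the 512-float32 FDATA header needed to reconstruct a
:class:`~nmrpeakfit.spectrum_io.SpectrumCube` is interpreted: dimension
count, matrix sizes, and per-axis spectral width / observe frequency /
carrier.  Real (absorption-mode) data only.  Byte order is auto-detected
from the FDFLTORDER sentinel (2.345).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .spectrum_io import AxisCalibration, FormatError, SpectrumCube

HEADER_WORDS = 512

# FDATA word offsets (fdatap.h names)
FDMAGIC = 0
FDFLTFORMAT = 1
FDFLTORDER = 2
FDDIMCOUNT = 9
FDF3SIZE = 15
FDF2LABEL = 16   # words 16-17, 8 ASCII chars
FDF1LABEL = 18   # words 18-19
FDDIMORDER = 24  # words 24-27
FDPIPEFLAG = 57
FDF2CAR = 66
FDF1CAR = 67
FDREALSIZE = 97
FDSIZE = 99      # points in the direct (F2) dimension
FDF2SW = 100
FDF2ORIG = 101
FDQUADFLAG = 106
FDF2OBS = 119
FDF1OBS = 218
FDSPECNUM = 219  # points in the indirect (F1) dimension
FDF2FTFLAG = 220
FDTRANSPOSED = 221
FDF1FTFLAG = 222
FDF1SW = 229
FDF1ORIG = 249

_ORDER_SENTINEL = 2.345
_FLTFORMAT = np.array([0xEEEEEEEE], dtype=np.uint32).view(np.float32)[0]


def _pack_label(text: str) -> np.ndarray:
    raw = text.encode("ascii", errors="replace")[:8].ljust(8, b"\x00")
    return np.frombuffer(raw, dtype=np.float32).copy()


def _unpack_label(words: np.ndarray) -> str:
    return words.astype(np.float32).tobytes().split(b"\x00", 1)[0].decode(
        "ascii", errors="replace"
    )


def _orig_hz(ax: AxisCalibration) -> float:
    # NMRPipe ORIG: absolute frequency (Hz) of the last point of the axis
    last_ppm = ax.ppm_max - (ax.n_points - 1) * ax.ppm_per_point
    return last_ppm * ax.observe_freq


def write_nmrpipe(path, cube: SpectrumCube) -> None:
    """Write a cube as one NMRPipe file (2D plane or pseudo-3D stream)."""
    n_planes, n1, n2 = cube.shape
    h = np.zeros(HEADER_WORDS, dtype=np.float32)
    h[FDMAGIC] = 0.0
    h[FDFLTFORMAT] = _FLTFORMAT
    h[FDFLTORDER] = _ORDER_SENTINEL
    h[FDDIMCOUNT] = 2.0 if n_planes == 1 else 3.0
    h[FDPIPEFLAG] = 0.0 if n_planes == 1 else 1.0
    h[FDF3SIZE] = float(n_planes)
    h[FDDIMORDER : FDDIMORDER + 4] = (2.0, 1.0, 3.0, 4.0)
    h[FDSIZE] = float(n2)
    h[FDSPECNUM] = float(n1)
    h[FDREALSIZE] = float(n2)
    h[FDQUADFLAG] = 1.0  # real data
    h[FDF2FTFLAG] = 1.0
    h[FDF1FTFLAG] = 1.0
    ax1, ax2 = cube.axes
    h[FDF2LABEL : FDF2LABEL + 2] = _pack_label(ax2.label)
    h[FDF1LABEL : FDF1LABEL + 2] = _pack_label(ax1.label)
    h[FDF2SW], h[FDF2OBS], h[FDF2CAR] = ax2.spectral_width, ax2.observe_freq, ax2.carrier_ppm
    h[FDF1SW], h[FDF1OBS], h[FDF1CAR] = ax1.spectral_width, ax1.observe_freq, ax1.carrier_ppm
    h[FDF2ORIG] = _orig_hz(ax2)
    h[FDF1ORIG] = _orig_hz(ax1)
    with open(path, "wb") as fh:
        fh.write(h.tobytes())
        fh.write(np.ascontiguousarray(cube.data, dtype=np.float32).tobytes())


def _axis_from_header(h: np.ndarray, n: int, sw_w: int, obs_w: int, car_w: int,
                      orig_w: int, label: str, path) -> AxisCalibration:
    sw, obs, car = float(h[sw_w]), float(h[obs_w]), float(h[car_w])
    if sw <= 0 or obs <= 0:
        raise FormatError(
            f"{path}: invalid axis calibration (sw={sw}, obs={obs}) in header"
        )
    if car == 0.0 and h[orig_w] != 0.0:
        # derive carrier from ORIG when CAR is absent
        orig = float(h[orig_w])
        car = (orig + sw / 2.0 - sw / n) / obs
    return AxisCalibration(
        n_points=n, spectral_width=sw, observe_freq=obs, carrier_ppm=car, label=label
    )


def read_nmrpipe(path) -> SpectrumCube:
    """Read an NMRPipe 2D plane or pseudo-3D stream."""
    raw = Path(path).read_bytes()
    if len(raw) < HEADER_WORDS * 4:
        raise FormatError(f"{path}: truncated NMRPipe header ({len(raw)} bytes)")
    h = np.frombuffer(raw[: HEADER_WORDS * 4], dtype=np.float32)
    swap = False
    if abs(float(h[FDFLTORDER]) - _ORDER_SENTINEL) > 1e-4:
        h_sw = h.byteswap()
        if abs(float(h_sw[FDFLTORDER]) - _ORDER_SENTINEL) > 1e-4:
            raise FormatError(
                f"{path}: bad FDFLTORDER sentinel {float(h[FDFLTORDER])!r}; "
                "not an NMRPipe file"
            )
        h, swap = h_sw, True
    if float(h[FDMAGIC]) != 0.0:
        raise FormatError(f"{path}: nonzero FDMAGIC word; not an NMRPipe file")
    dim = int(round(float(h[FDDIMCOUNT])))
    if dim not in (2, 3):
        raise FormatError(
            f"{path}: FDDIMCOUNT={dim}; only 2D planes and pseudo-3D streams supported"
        )
    n2 = int(round(float(h[FDSIZE])))
    n1 = int(round(float(h[FDSPECNUM])))
    n_planes = int(round(float(h[FDF3SIZE]))) if dim == 3 else 1
    if n1 < 2 or n2 < 2 or n_planes < 1:
        raise FormatError(f"{path}: bad matrix sizes FDSIZE={n2} FDSPECNUM={n1}")
    npts = n_planes * n1 * n2
    payload = np.frombuffer(raw[HEADER_WORDS * 4 :], dtype=np.float32)
    if swap:
        payload = payload.byteswap()
    if payload.size < npts:
        raise FormatError(
            f"{path}: truncated data section ({payload.size} points, expected {npts})"
        )
    data = payload[:npts].astype(float).reshape(n_planes, n1, n2)
    ax2 = _axis_from_header(h, n2, FDF2SW, FDF2OBS, FDF2CAR, FDF2ORIG,
                            _unpack_label(h[FDF2LABEL : FDF2LABEL + 2]), path)
    ax1 = _axis_from_header(h, n1, FDF1SW, FDF1OBS, FDF1CAR, FDF1ORIG,
                            _unpack_label(h[FDF1LABEL : FDF1LABEL + 2]), path)
    return SpectrumCube(data=data, axes=(ax1, ax2))
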