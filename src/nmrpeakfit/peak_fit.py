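"""Peak detection, overlap grouping and joint line-shape fitting.

Peaks whose integration ellipses intersect (transitively) form an
overlap group and are co-fitted: one nonlinear least-squares problem per
group spanning every plane of the cube, with positions and widths shared
across planes and one amplitude per peak per plane.  The fit region is
the union of the axis-aligned boxes ``position +- radii`` of the member
peaks; the ellipse is used only to decide overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter
from scipy.optimize import least_squares, minimize_scalar

from .lineshapes import (
    ShapeKind,
    ShapeParams1D,
    ShapeParams2D,
    eval_shape_1d,
    shape_volume_1d,
)
from .spectrum_io import DEFAULT_RADII, AxisCalibration, Peak, SpectrumCube

__all__ = [
    "FitOptions",
    "OverlapGroup",
    "GroupFitResult",
    "GroupLineShapeModel",
    "estimate_noise",
    "ellipses_overlap",
    "detect_overlap_groups",
    "center_peak_isolated",
    "center_peaks_grouped",
    "pick_peaks",
    "fit_group",
]

#: default initial FWHM estimates (ppm): indirect, direct
DEFAULT_FWHM = (0.3, 0.03)
MAX_ITERATIONS = 1000


@dataclass
class FitOptions:
    """Options controlling one group fit."""

    shape: ShapeKind = ShapeKind.GAUSSIAN
    init_fwhm: tuple[float, float] = DEFAULT_FWHM
    init_mixing: float = 0.5
    share_across_planes: bool = True    # positions/widths common to all planes
    max_iterations: int = MAX_ITERATIONS
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self) -> None:
        self.shape = ShapeKind(self.shape)


@dataclass
class OverlapGroup:
    """Connected component of mutually overlapping peaks."""

    peaks: list[Peak]
    indices: list[int]              # positions in the source peak list
    group_id: int = 0

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class GroupFitResult:
    """Joint line-shape fit of one overlap group across all planes."""

    group: OverlapGroup
    shapes: list[ShapeParams2D]                   # per peak, amplitude of plane 0
    amplitudes: np.ndarray                        # (n_peaks, n_planes) heights
    volumes: np.ndarray                           # (n_peaks, n_planes)
    param_errors: list[dict[str, float]]          # per peak, shared-parameter SEs
    region_slices: tuple[slice, slice]            # bounding box in the full plane
    region_mask: np.ndarray                       # bool, shape of the bounding box
    residual_maps: np.ndarray                     # (n_planes, *bounding box)
    converged: bool
    n_iterations: int
    cost: float                                   # sum of squared residuals

    def summary(self) -> str:
        lines = [
            f"Group {self.group.group_id}: {len(self.group)} peak(s), "
            f"cost={self.cost:.6g}, iterations={self.n_iterations}, "
            f"converged={self.converged}",
            f"{'assignment':>14} {'F1 ppm':>9} {'F2 ppm':>9} "
            f"{'height(0)':>12} {'volume(0)':>12}",
        ]
        for k, (pk, sp) in enumerate(zip(self.group.peaks, self.shapes)):
            lines.append(
                f"{pk.assignment:>14} {sp.f1.center:>9.4f} {sp.f2.center:>9.4f} "
                f"{self.amplitudes[k, 0]:>12.5g} {self.volumes[k, 0]:>12.5g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# noise

def estimate_noise(cube: SpectrumCube) -> np.ndarray:
    """Robust per-plane noise RMS: 1.4826 x median absolute deviation.

    The MAD over all grid points is insensitive to the sparse strong
    peaks sitting on top of the noise floor.  The per-plane values are
    returned and their median is stored in ``cube.noise_rms``.
    """
    flat = cube.data.reshape(cube.n_planes, -1)
    med = np.median(flat, axis=1, keepdims=True)
    mad = np.median(np.abs(flat - med), axis=1)
    rms = 1.4826 * mad
    cube.noise_rms = float(np.median(rms))
    return rms


# ---------------------------------------------------------------------------
# overlap detection

def _circle_ellipse_gap(d: np.ndarray, a: float, b: float) -> float:
    """Min distance from the origin to the region of an axis-aligned ellipse.

    The ellipse has center ``d`` and semi-axes ``(a, b)``; returns 0 when
    the origin lies inside.
    """
    if (d[0] / a) ** 2 + (d[1] / b) ** 2 <= 1.0:
        return 0.0

    def dist2(t):
        return (d[0] + a * math.cos(t)) ** 2 + (d[1] + b * math.sin(t)) ** 2

    ts = np.linspace(0.0, 2.0 * math.pi, 91)
    vals = (d[0] + a * np.cos(ts)) ** 2 + (d[1] + b * np.sin(ts)) ** 2
    k = int(np.argmin(vals))
    lo, hi = ts[max(k - 1, 0)], ts[min(k + 1, ts.size - 1)]
    res = minimize_scalar(dist2, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return math.sqrt(min(float(res.fun), float(vals[k])))


def ellipses_overlap(c1: Sequence[float], r1: Sequence[float],
                     c2: Sequence[float], r2: Sequence[float]) -> bool:
    """Do two axis-aligned ellipses (centers ``c``, semi-axes ``r``) intersect?

    Cheap separating-box rejection and a Minkowski-sum inclusion
    acceptance handle almost every pair; borderline cases fall back to a
    1D minimization of the center distance over the scaled boundary.
    """
    dx = c2[0] - c1[0]
    dy = c2[1] - c1[1]
    ax, by = r1[0] + r2[0], r1[1] + r2[1]
    if abs(dx) > ax or abs(dy) > by:
        return False
    # E(a1+a2, b1+b2) is contained in the Minkowski sum of the two ellipses
    if (dx / ax) ** 2 + (dy / by) ** 2 <= 1.0:
        return True
    # exact test in coordinates where ellipse 1 is the unit circle
    d = np.array([dx / r1[0], dy / r1[1]])
    gap = _circle_ellipse_gap(d, r2[0] / r1[0], r2[1] / r1[1])
    return gap <= 1.0


def detect_overlap_groups(peaks: Sequence[Peak],
                          radii: tuple[float, float] | None = None) -> list[OverlapGroup]:
    """Partition peaks into connected components of the overlap relation.

    Two peaks overlap when their integration ellipses (semi-axes =
    radii, ppm) intersect; components are closed transitively.  Peaks
    carrying the same preassigned ``group_id`` are forced together.
    Groups are ordered by their first member's index in ``peaks`` and
    member order follows the input list.
    """
    n = len(peaks)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rad = [radii if radii is not None else p.radii for p in peaks]
    for i in range(n):
        for j in range(i + 1, n):
            if ellipses_overlap(peaks[i].position, rad[i], peaks[j].position, rad[j]):
                g.add_edge(i, j)
    manual: dict[int, int] = {}
    for i, p in enumerate(peaks):
        if p.group_id is not None:
            if p.group_id in manual:
                g.add_edge(manual[p.group_id], i)
            else:
                manual[p.group_id] = i
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    groups = []
    for gid, comp in enumerate(comps):
        grp = OverlapGroup(peaks=[peaks[i] for i in comp], indices=comp, group_id=gid)
        for p in grp.peaks:
            p.group_id = gid
        groups.append(grp)
    return groups


# ---------------------------------------------------------------------------
# peak centering and picking

def _search_box(axes: tuple[AxisCalibration, AxisCalibration],
                position: tuple[float, float],
                radius: tuple[float, float],
                shape: tuple[int, int]) -> tuple[slice, slice]:
    lo1 = axes[0].ppm_to_point(position[0] + radius[0])
    hi1 = axes[0].ppm_to_point(position[0] - radius[0])
    lo2 = axes[1].ppm_to_point(position[1] + radius[1])
    hi2 = axes[1].ppm_to_point(position[1] - radius[1])
    s1 = slice(max(int(math.floor(lo1)), 0), min(int(math.ceil(hi1)) + 1, shape[0]))
    s2 = slice(max(int(math.floor(lo2)), 0), min(int(math.ceil(hi2)) + 1, shape[1]))
    return s1, s2


def center_peak_isolated(cube: SpectrumCube, peak: Peak,
                         search_radius: tuple[float, float] | float = (0.5, 0.1),
                         ref_plane: int = 0) -> tuple[tuple[float, float], bool]:
    """Recenter an isolated peak on the intensity-weighted centroid.

    The strongest local extremum of the reference plane within
    ``search_radius`` of the listed position anchors the centroid, which
    is taken over the half-maximum footprint around it.  Fails (flag
    False, position unchanged) when nothing exceeds 3x the noise RMS.
    """
    if np.isscalar(search_radius):
        search_radius = (float(search_radius), float(search_radius))
    if cube.noise_rms is None:
        estimate_noise(cube)
    plane = cube.data[ref_plane]
    s1, s2 = _search_box(cube.axes, peak.position, search_radius, plane.shape)
    sub = np.abs(plane[s1, s2])
    if sub.size == 0 or sub.max() <= 3.0 * cube.noise_rms:
        return peak.position, False
    k1, k2 = np.unravel_index(int(np.argmax(sub)), sub.shape)
    apex = sub[k1, k2]
    half = sub >= 0.5 * apex
    # keep only the half-max points in the apex's own footprint: walk a
    # small window outward so a second peak inside the box is excluded
    w = 0
    while True:
        w += 1
        w1 = slice(max(k1 - w, 0), min(k1 + w + 1, sub.shape[0]))
        w2 = slice(max(k2 - w, 0), min(k2 + w + 1, sub.shape[1]))
        window = half[w1, w2]
        if not window.all() or (w1 == slice(0, sub.shape[0]) and w2 == slice(0, sub.shape[1])):
            break
    weights = np.where(half, sub, 0.0)[w1, w2]
    ii, jj = np.mgrid[w1, w2]
    tot = weights.sum()
    c1 = float((weights * ii).sum() / tot) + s1.start
    c2 = float((weights * jj).sum() / tot) + s2.start
    new = (float(cube.axes[0].point_to_ppm(c1)), float(cube.axes[1].point_to_ppm(c2)))
    shift = (new[0] - peak.position[0], new[1] - peak.position[1])
    clipped = (
        peak.position[0] + float(np.clip(shift[0], -search_radius[0], search_radius[0])),
        peak.position[1] + float(np.clip(shift[1], -search_radius[1], search_radius[1])),
    )
    return clipped, True


def center_peaks_grouped(cube: SpectrumCube, group: OverlapGroup,
                         options: FitOptions | None = None,
                         ref_plane: int = 0) -> tuple[list[tuple[float, float]], list[bool]]:
    """Refine positions of (possibly overlapped) peaks near their true spots.

    Two restricted group fits on the reference plane, widths held at
    their initial estimates throughout:

    1. amplitudes only, positions fixed at the listed values — a stable
       screen that assigns each peak the intensity its own footprint can
       claim; peaks whose amplitude stays below 3x the noise RMS are
       flagged unreliable and take no further part (a signal-free peak
       left in the joint fit would drift onto its neighbours' intensity);
    2. centers (bounded by each peak's radii) plus amplitudes for the
       remaining peaks.

    Returns the refined positions (input position wherever the flag is
    False) and the per-peak reliability flags.
    """
    options = options or FitOptions()
    if cube.noise_rms is None:
        estimate_noise(cube)
    floor = 3.0 * cube.noise_rms
    n = len(group.peaks)
    positions = [p.position for p in group.peaks]
    flags = [False] * n
    ref = SpectrumCube(data=cube.data[ref_plane : ref_plane + 1].copy(), axes=cube.axes)

    def _restricted_fit(indices, fix_pos):
        peaks = [
            Peak(group.peaks[k].assignment, group.peaks[k].position,
                 group.peaks[k].radii, (fix_pos, fix_pos), (True, True))
            for k in indices
        ]
        sub = OverlapGroup(peaks=peaks, indices=list(range(len(peaks))),
                           group_id=group.group_id)
        return GroupLineShapeModel(ref, sub, options).fit()

    try:
        screen = _restricted_fit(range(n), fix_pos=True)
    except (ValueError, RuntimeError):
        return positions, flags
    active = [k for k in range(n) if abs(screen.amplitudes[k, 0]) > floor]
    if not active:
        return positions, flags
    try:
        res = _restricted_fit(active, fix_pos=False)
    except (ValueError, RuntimeError):
        return positions, flags
    for j, k in enumerate(active):
        ok = bool(res.converged) and abs(res.amplitudes[j, 0]) > floor
        if ok:
            positions[k] = (res.shapes[j].f1.center, res.shapes[j].f2.center)
        flags[k] = ok
    return positions, flags


def pick_peaks(cube: SpectrumCube, threshold: float = 5.0,
               name_format: str = "P{i}", ref_plane: int = 0,
               radii: tuple[float, float] | None = None) -> list[Peak]:
    """Pick local extrema above ``threshold`` x noise RMS on the reference plane.

    A grid node is picked when it is an 8-neighborhood maximum of the
    positive signal or minimum of the negative signal and its magnitude
    exceeds the threshold.  Peaks are returned in descending magnitude
    (ties: F1 then F2 index) with dummy assignments from ``name_format``.
    """
    if cube.noise_rms is None:
        estimate_noise(cube)
    plane = cube.data[ref_plane]
    cutoff = threshold * cube.noise_rms
    is_max = (plane == maximum_filter(plane, size=3, mode="nearest")) & (plane > cutoff)
    is_min = (plane == minimum_filter(plane, size=3, mode="nearest")) & (plane < -cutoff)
    idx = np.argwhere(is_max | is_min)
    if idx.size == 0:
        return []
    heights = plane[idx[:, 0], idx[:, 1]]
    order = np.lexsort((idx[:, 1], idx[:, 0], -np.abs(heights)))
    peaks = []
    for rank, row in enumerate(order, start=1):
        i1, i2 = idx[row]
        pos = (float(cube.axes[0].point_to_ppm(float(i1))),
               float(cube.axes[1].point_to_ppm(float(i2))))
        peaks.append(
            Peak(assignment=name_format.format(i=rank), position=pos,
                 radii=radii if radii is not None else DEFAULT_RADII)
        )
    return peaks


# ---------------------------------------------------------------------------
# the group fitter

def _region_of(group: OverlapGroup, axes, shape) -> tuple[tuple[slice, slice], np.ndarray]:
    """Union of per-peak boxes as (bounding slices, boolean mask)."""
    boxes = []
    for p in group.peaks:
        s1, s2 = _search_box(axes, p.position, p.radii, shape)
        if s1.stop <= s1.start or s2.stop <= s2.start:
            raise ValueError(f"peak {p.assignment}: integration box falls outside the spectrum")
        boxes.append((s1, s2))
    lo1 = min(b[0].start for b in boxes)
    hi1 = max(b[0].stop for b in boxes)
    lo2 = min(b[1].start for b in boxes)
    hi2 = max(b[1].stop for b in boxes)
    mask = np.zeros((hi1 - lo1, hi2 - lo2), dtype=bool)
    for s1, s2 in boxes:
        mask[s1.start - lo1 : s1.stop - lo1, s2.start - lo2 : s2.stop - lo2] = True
    return (slice(lo1, hi1), slice(lo2, hi2)), mask


class _ParamLayout:
    """Maps the free-parameter vector of a group fit to per-peak shapes.

    Per peak and dimension: center (unless fixed_position), width(s)
    (unless fixed_width), galore mixing; then one amplitude per peak per
    plane.  Fixed entries keep their initial values.
    """

    def __init__(self, group: OverlapGroup, options: FitOptions, n_planes: int,
                 init_amp: np.ndarray):
        self.options = options
        self.n_peaks = len(group.peaks)
        self.n_planes = n_planes
        self.names: list[str] = []
        self.init: list[float] = []
        self.lower: list[float] = []
        self.upper: list[float] = []
        self.fixed: dict[str, float] = {}
        kind = options.shape
        for k, p in enumerate(group.peaks):
            for dim in (0, 1):
                name = f"p{k}_c{dim + 1}"
                val = p.position[dim]
                if p.fixed_position[dim]:
                    self.fixed[name] = val
                else:
                    self._free(name, val, val - p.radii[dim], val + p.radii[dim])
                if kind is ShapeKind.VOIGT:
                    f0 = options.init_fwhm[dim]
                    sg0 = f0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
                    for wn, wv in ((f"p{k}_sigma{dim + 1}", sg0), (f"p{k}_gamma{dim + 1}", 0.3 * f0)):
                        if p.fixed_width[dim]:
                            self.fixed[wn] = wv
                        else:
                            lo = 1e-6 if "sigma" in wn else 0.0
                            self._free(wn, wv, lo, np.inf)
                else:
                    wn = f"p{k}_fwhm{dim + 1}"
                    wv = options.init_fwhm[dim]
                    if p.fixed_width[dim]:
                        self.fixed[wn] = wv
                    else:
                        self._free(wn, wv, 1e-6, np.inf)
            if kind is ShapeKind.GALORE:
                self._free(f"p{k}_mix", options.init_mixing, 0.0, 1.0)
        for k in range(self.n_peaks):
            for pl in range(n_planes):
                self._free(f"p{k}_amp{pl}", float(init_amp[k, pl]), -np.inf, np.inf)
        self._index = {n: i for i, n in enumerate(self.names)}

    def _free(self, name, val, lo, hi):
        self.names.append(name)
        self.init.append(float(np.clip(val, lo, hi)))
        self.lower.append(lo)
        self.upper.append(hi)

    @property
    def n_free(self) -> int:
        return len(self.names)

    def value(self, vec: np.ndarray, name: str) -> float:
        if name in self.fixed:
            return self.fixed[name]
        return float(vec[self._index[name]])

    def shapes(self, vec: np.ndarray) -> tuple[list[ShapeParams2D], np.ndarray]:
        """Per-peak shapes (amplitude = plane 0) and the (peak, plane) amplitude matrix."""
        kind = self.options.shape
        get = lambda n: self.value(vec, n)
        out = []
        amps = np.empty((self.n_peaks, self.n_planes))
        for k in range(self.n_peaks):
            dims = []
            for dim in (1, 2):
                c = get(f"p{k}_c{dim}")
                if kind is ShapeKind.VOIGT:
                    dims.append(ShapeParams1D(kind, c, sigma=get(f"p{k}_sigma{dim}"),
                                              gamma=get(f"p{k}_gamma{dim}")))
                elif kind is ShapeKind.GALORE:
                    dims.append(ShapeParams1D(kind, c, fwhm=get(f"p{k}_fwhm{dim}"),
                                              mixing_a=get(f"p{k}_mix")))
                else:
                    dims.append(ShapeParams1D(kind, c, fwhm=get(f"p{k}_fwhm{dim}")))
            for pl in range(self.n_planes):
                amps[k, pl] = get(f"p{k}_amp{pl}")
            out.append(ShapeParams2D(f1=dims[0], f2=dims[1], amplitude=float(amps[k, 0])))
        return out, amps


class GroupLineShapeModel:
    """Joint separable-line-shape model of one overlap group.

    Built from a :class:`SpectrumCube` and an :class:`OverlapGroup`;
    ``fit()`` runs bounded trust-region least squares over every plane
    simultaneously and returns a :class:`GroupFitResult`.
    """

    def __init__(self, cube: SpectrumCube, group: OverlapGroup,
                 options: FitOptions | None = None):
        self.cube = cube
        self.group = group
        self.options = options or FitOptions()
        if not np.all(np.isfinite(cube.data)):
            raise ValueError("spectrum contains non-finite values")
        self.region, self.mask = _region_of(group, cube.axes, cube.data.shape[1:])
        s1, s2 = self.region
        self._i1 = np.arange(s1.start, s1.stop, dtype=float)
        self._i2 = np.arange(s2.start, s2.stop, dtype=float)
        self._x1 = np.asarray(cube.axes[0].point_to_ppm(self._i1), dtype=float)
        self._x2 = np.asarray(cube.axes[1].point_to_ppm(self._i2), dtype=float)
        self._data = cube.data[:, s1, s2]
        init_amp = np.empty((len(group.peaks), cube.n_planes))
        for k, p in enumerate(group.peaks):
            j1 = int(np.clip(round(cube.axes[0].ppm_to_point(p.position[0])), 0,
                             cube.data.shape[1] - 1))
            j2 = int(np.clip(round(cube.axes[1].ppm_to_point(p.position[1])), 0,
                             cube.data.shape[2] - 1))
            init_amp[k] = cube.data[:, j1, j2]
        self.layout = _ParamLayout(group, self.options, cube.n_planes, init_amp)
        n_data = int(self.mask.sum()) * cube.n_planes
        if n_data <= self.layout.n_free:
            raise ValueError(
                f"under-determined fit: {n_data} data points for "
                f"{self.layout.n_free} free parameters"
            )

    def _model_planes(self, vec: np.ndarray) -> np.ndarray:
        shapes, amps = self.layout.shapes(vec)
        out = np.zeros_like(self._data)
        for k, sp in enumerate(shapes):
            prof = np.outer(eval_shape_1d(sp.f1, self._x1), eval_shape_1d(sp.f2, self._x2))
            out += amps[k][:, None, None] * prof[None]
        return out

    def _residuals(self, vec: np.ndarray) -> np.ndarray:
        return (self._model_planes(vec) - self._data)[:, self.mask].ravel()

    def fit(self) -> GroupFitResult:
        lay = self.layout
        max_nfev = self.options.max_iterations * (lay.n_free + 1)
        res = least_squares(
            self._residuals,
            np.asarray(lay.init),
            bounds=(np.asarray(lay.lower), np.asarray(lay.upper)),
            method="trf",
            xtol=self.options.xtol,
            ftol=self.options.ftol,
            gtol=self.options.gtol,
            max_nfev=max_nfev,
        )
        n_iter = int(res.njev if res.njev is not None else res.nfev)
        converged = res.status > 0 and n_iter <= self.options.max_iterations
        shapes, amps = lay.shapes(res.x)
        volumes = np.empty_like(amps)
        for k, sp in enumerate(shapes):
            v1 = shape_volume_1d(sp.f1)
            v2 = shape_volume_1d(sp.f2)
            volumes[k] = amps[k] * v1 * v2
        n_region = int(self.mask.sum()) * self.cube.n_planes
        se_vec = _shared_param_errors(res, n_region)
        per_peak_errors: list[dict[str, float]] = []
        for k in range(lay.n_peaks):
            d = {}
            prefix = f"p{k}_"
            for name, se in zip(lay.names, se_vec):
                if name.startswith(prefix) and "amp" not in name:
                    d[name[len(prefix):]] = float(se)
            per_peak_errors.append(d)
        model = self._model_planes(res.x)
        residual = np.where(self.mask[None], self._data - model, 0.0)
        return GroupFitResult(
            group=self.group,
            shapes=shapes,
            amplitudes=amps,
            volumes=volumes,
            param_errors=per_peak_errors,
            region_slices=self.region,
            region_mask=self.mask,
            residual_maps=residual,
            converged=bool(converged),
            n_iterations=n_iter,
            cost=float(2.0 * res.cost),
        )


def _shared_param_errors(res, n_obs: int) -> np.ndarray:
    dof = max(n_obs - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    J = res.jac
    try:
        cov = np.linalg.pinv(J.T @ J) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(res.x.size, np.nan)


def fit_group(cube: SpectrumCube, group: OverlapGroup,
              options: FitOptions | None = None) -> GroupFitResult:
    """Co-fit all peaks of one overlap group across every plane of the cube."""
    return GroupLineShapeModel(cube, group, options).fit()
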