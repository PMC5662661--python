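"""Noise estimation, overlap grouping, centering, picking and group fits."""

import numpy as np
import pytest

from nmrpeakfit.lineshapes import ShapeKind, ShapeParams1D, ShapeParams2D
from nmrpeakfit.peak_fit import (
    FitOptions,
    OverlapGroup,
    center_peak_isolated,
    center_peaks_grouped,
    detect_overlap_groups,
    ellipses_overlap,
    estimate_noise,
    fit_group,
    pick_peaks,
)
from nmrpeakfit.spectrum_io import Peak, SpectrumCube
from nmrpeakfit.synthetic import (
    TruthPeak,
    TruthSpec,
    default_axes,
    make_cube,
    make_overlap_scenario,
    truth_peak_list,
)

from oracles import brute_force_groups, random_peak_config


# --- noise ------------------------------------------------------------

def test_noise_zero_plane(small_axes):
    cube = SpectrumCube(data=np.zeros((1, 64, 128)), axes=small_axes)
    assert estimate_noise(cube)[0] == 0.0


def test_noise_pure_gaussian():
    axes = default_axes(256, 256)
    rng = np.random.default_rng(0)
    cube = SpectrumCube(data=rng.normal(0, 1.0, (1, 256, 256)), axes=axes)
    assert estimate_noise(cube)[0] == pytest.approx(1.0, rel=0.05)


def test_noise_robust_to_tall_peaks():
    axes = default_axes(256, 256)
    rng = np.random.default_rng(1)
    data = rng.normal(0, 1.0, (1, 256, 256))
    for c1, c2 in [(50, 60), (128, 128), (200, 40)]:
        ii, jj = np.mgrid[-8:9, -8:9]
        data[0, c1 - 8 : c1 + 9, c2 - 8 : c2 + 9] += 500.0 * np.exp(
            -(ii**2 + jj**2) / 8.0
        )
    cube = SpectrumCube(data=data, axes=axes)
    assert estimate_noise(cube)[0] == pytest.approx(1.0, rel=0.05)


# --- grouping ---------------------------------------------------------

def test_two_distant_peaks_are_singletons():
    peaks = [Peak("A", (110.0, 7.0), radii=(0.4, 0.05)),
             Peak("B", (120.0, 9.0), radii=(0.4, 0.05))]
    groups = detect_overlap_groups(peaks)
    assert [len(g) for g in groups] == [1, 1]


def test_chain_overlap_is_transitive():
    """A-B and B-C overlap, A-C do not: one co-fitted group of three."""
    peaks = [Peak("A", (118.0, 8.2), radii=(0.3, 0.04)),
             Peak("B", (118.5, 8.2), radii=(0.3, 0.04)),
             Peak("C", (119.0, 8.2), radii=(0.3, 0.04))]
    assert ellipses_overlap(peaks[0].position, peaks[0].radii,
                            peaks[1].position, peaks[1].radii)
    assert not ellipses_overlap(peaks[0].position, peaks[0].radii,
                                peaks[2].position, peaks[2].radii)
    groups = detect_overlap_groups(peaks)
    assert len(groups) == 1 and len(groups[0]) == 3


def test_grouping_matches_union_find_oracle():
    rng = np.random.default_rng(123)
    for _ in range(10):
        pos, rad = random_peak_config(rng, 10)
        peaks = [Peak(f"P{i}", tuple(pos[i]), radii=tuple(rad[i])) for i in range(10)]
        groups = detect_overlap_groups(peaks)
        ours = sorted(sorted(g.indices) for g in groups)
        assert ours == brute_force_groups(pos, rad)


def test_manual_group_ids_merge():
    peaks = [Peak("A", (110.0, 7.0), radii=(0.3, 0.04), group_id=5),
             Peak("B", (120.0, 9.0), radii=(0.3, 0.04), group_id=5)]
    groups = detect_overlap_groups(peaks)
    assert len(groups) == 1


def test_ellipse_tangency_cases():
    # touching along one axis counts as intersecting
    assert ellipses_overlap((0.0, 0.0), (1.0, 0.5), (2.0, 0.0), (1.0, 0.5))
    assert not ellipses_overlap((0.0, 0.0), (1.0, 0.5), (2.001, 0.0), (1.0, 0.5))
    # diagonal near-miss that a bounding-box test would get wrong
    assert not ellipses_overlap((0.0, 0.0), (1.0, 0.1), (1.9, 0.19), (1.0, 0.1))


# --- centering --------------------------------------------------------

def _one_peak_cube(dc1=0.0, dc2=0.0, noise=0.0, seed=0, amp=100.0):
    axes = default_axes(64, 128)
    spec = TruthSpec(
        peaks=[TruthPeak("K94N-H", ShapeParams2D(
            f1=ShapeParams1D(ShapeKind.GAUSSIAN, 118.0 + dc1, fwhm=0.35),
            f2=ShapeParams1D(ShapeKind.GAUSSIAN, 8.3 + dc2, fwhm=0.035),
            amplitude=amp))],
        noise_sigma=noise, seed=seed)
    return make_cube(spec, axes), axes


def test_center_isolated_at_apex_stays_put():
    cube, axes = _one_peak_cube()
    peak = Peak("K94N-H", (118.0, 8.3))
    pos, ok = center_peak_isolated(cube, peak, search_radius=(0.5, 0.1))
    assert ok
    assert abs(axes[0].ppm_to_point(pos[0]) - axes[0].ppm_to_point(118.0)) < 1.0
    assert abs(axes[1].ppm_to_point(pos[1]) - axes[1].ppm_to_point(8.3)) < 1.0


def test_center_isolated_recovers_displaced_peak():
    """True apex 0.2 ppm (F1) off the listed position is found to <0.25 pt."""
    cube, axes = _one_peak_cube(dc1=0.2, dc2=0.0)
    peak = Peak("K94N-H", (118.0, 8.3))
    pos, ok = center_peak_isolated(cube, peak, search_radius=(0.5, 0.1))
    assert ok
    assert abs(axes[0].ppm_to_point(pos[0]) - axes[0].ppm_to_point(118.2)) < 0.25
    assert abs(axes[1].ppm_to_point(pos[1]) - axes[1].ppm_to_point(8.3)) < 0.25


def test_center_isolated_noise_only_fails():
    axes = default_axes(64, 128)
    rng = np.random.default_rng(2)
    cube = SpectrumCube(data=rng.normal(0, 1.0, (1, 64, 128)), axes=axes)
    peak = Peak("X1N-H", (118.0, 8.3))
    pos, ok = center_peak_isolated(cube, peak, search_radius=(0.3, 0.05))
    assert not ok
    assert pos == peak.position


def test_center_grouped_recovers_two_overlapped_peaks():
    """Two peaks at 1.2x FWHM spacing, each listed 0.3x FWHM off.

    Axes sampled at ~4-5 points per FWHM, the resolution regime the
    restricted (widths-held) refinement is designed for.
    """
    fwhm1 = 0.35
    axes = default_axes(256, 512)
    spec = TruthSpec(peaks=[
        TruthPeak("A", ShapeParams2D(
            f1=ShapeParams1D(ShapeKind.GAUSSIAN, 118.0, fwhm=fwhm1),
            f2=ShapeParams1D(ShapeKind.GAUSSIAN, 8.30, fwhm=0.035),
            amplitude=100.0)),
        TruthPeak("B", ShapeParams2D(
            f1=ShapeParams1D(ShapeKind.GAUSSIAN, 118.0 + 1.2 * fwhm1, fwhm=fwhm1),
            f2=ShapeParams1D(ShapeKind.GAUSSIAN, 8.30, fwhm=0.035),
            amplitude=80.0)),
    ])
    cube = make_cube(spec, axes)
    off = 0.3 * fwhm1
    peaks = [Peak("A", (118.0 + off, 8.30), radii=(0.45, 0.06)),
             Peak("B", (118.0 + 1.2 * fwhm1 - off, 8.30), radii=(0.45, 0.06))]
    group = detect_overlap_groups(peaks)[0]
    assert len(group) == 2
    positions, flags = center_peaks_grouped(cube, group)
    assert all(flags)
    assert abs(positions[0][0] - 118.0) < 0.1 * fwhm1
    assert abs(positions[1][0] - (118.0 + 1.2 * fwhm1)) < 0.1 * fwhm1


def test_center_grouped_fixed_point():
    axes = default_axes(256, 512)
    spec = TruthSpec(peaks=[TruthPeak("K94N-H", ShapeParams2D(
        f1=ShapeParams1D(ShapeKind.GAUSSIAN, 118.0, fwhm=0.35),
        f2=ShapeParams1D(ShapeKind.GAUSSIAN, 8.3, fwhm=0.035),
        amplitude=100.0))])
    cube = make_cube(spec, axes)
    peaks = [Peak("K94N-H", (118.0, 8.3), radii=(0.45, 0.06))]
    group = detect_overlap_groups(peaks)[0]
    positions, flags = center_peaks_grouped(cube, group)
    assert flags[0]
    assert abs(positions[0][0] - 118.0) < 0.02 * 0.35
    assert abs(positions[0][1] - 8.3) < 0.02 * 0.035


def test_center_grouped_zero_amplitude_flagged():
    axes = default_axes(256, 512)
    spec = TruthSpec(peaks=[
        TruthPeak("A", ShapeParams2D(
            f1=ShapeParams1D(ShapeKind.GAUSSIAN, 118.0, fwhm=0.35),
            f2=ShapeParams1D(ShapeKind.GAUSSIAN, 8.30, fwhm=0.035),
            amplitude=100.0)),
        TruthPeak("GHOST", ShapeParams2D(
            f1=ShapeParams1D(ShapeKind.GAUSSIAN, 118.4, fwhm=0.35),
            f2=ShapeParams1D(ShapeKind.GAUSSIAN, 8.33, fwhm=0.035),
            amplitude=0.0)),
    ], noise_sigma=1.0, seed=4)
    cube = make_cube(spec, axes)
    peaks = truth_peak_list(spec)
    group = detect_overlap_groups(peaks)[0]
    positions, flags = center_peaks_grouped(cube, group)
    assert flags[0]
    assert not flags[1]
    assert positions[1] == peaks[1].position


# --- picking ----------------------------------------------------------

def test_pick_three_separated_peaks():
    spec = make_overlap_scenario("isolated")
    cube = make_cube(spec, default_axes(64, 128))
    cube.noise_rms = 1.0  # noise-free plane: use an explicit floor
    picked = pick_peaks(cube, threshold=5.0, name_format="P{i}")
    assert len(picked) == 3
    assert [p.assignment for p in picked] == ["P1", "P2", "P3"]
    # descending magnitude: truth amplitudes 120, 100, 80
    truth_sorted = sorted(spec.peaks, key=lambda t: -t.shape.amplitude)
    for got, want in zip(picked, truth_sorted):
        assert got.position[0] == pytest.approx(want.shape.f1.center, abs=0.2)
        assert got.position[1] == pytest.approx(want.shape.f2.center, abs=0.02)


def test_pick_empty_plane(small_axes):
    cube = SpectrumCube(data=np.zeros((1, 64, 128)), axes=small_axes)
    cube.noise_rms = 1.0
    assert pick_peaks(cube, threshold=5.0) == []


def test_pick_negative_peaks_found():
    axes = default_axes(64, 128)
    spec = TruthSpec(peaks=[TruthPeak("NEG", ShapeParams2D(
        f1=ShapeParams1D(ShapeKind.GAUSSIAN, 118.0, fwhm=0.35),
        f2=ShapeParams1D(ShapeKind.GAUSSIAN, 8.3, fwhm=0.035),
        amplitude=-50.0))])
    cube = make_cube(spec, axes)
    cube.noise_rms = 1.0
    picked = pick_peaks(cube, threshold=5.0)
    assert len(picked) == 1


# --- group fitting ----------------------------------------------------

@pytest.mark.parametrize("shape", list(ShapeKind), ids=lambda s: s.value)
def test_noiseless_singleton_recovery(shape):
    spec = make_overlap_scenario("isolated", shape_kind=shape)
    spec.peaks = spec.peaks[:1]
    axes = default_axes(64, 128)
    cube = make_cube(spec, axes)
    peaks = truth_peak_list(spec)
    group = detect_overlap_groups(peaks)[0]
    res = fit_group(cube, group, FitOptions(shape=shape))
    assert res.converged
    tp = spec.peaks[0]
    assert res.amplitudes[0, 0] == pytest.approx(tp.shape.amplitude, rel=1e-6)
    assert res.shapes[0].f1.center == pytest.approx(tp.shape.f1.center, rel=1e-6)
    assert res.shapes[0].f2.center == pytest.approx(tp.shape.f2.center, rel=1e-6)
    if shape is ShapeKind.VOIGT:
        assert res.shapes[0].f1.sigma == pytest.approx(tp.shape.f1.sigma, rel=1e-5)
    else:
        assert res.shapes[0].f1.fwhm == pytest.approx(tp.shape.f1.fwhm, rel=1e-6)


def test_noiseless_chain3_recovery():
    spec = make_overlap_scenario("chain3")
    axes = default_axes(64, 128)
    cube = make_cube(spec, axes)
    peaks = truth_peak_list(spec)
    groups = detect_overlap_groups(peaks)
    assert len(groups) == 1 and len(groups[0]) == 3
    res = fit_group(cube, groups[0])
    assert res.converged
    for k, tp in enumerate(spec.peaks):
        assert res.amplitudes[k, 0] == pytest.approx(tp.shape.amplitude, rel=1e-6)
    total_power = float(np.sum(cube.data**2))
    assert res.cost < 1e-10 * total_power


def test_fixed_position_mask_honored():
    spec = make_overlap_scenario("isolated")
    spec.peaks = spec.peaks[:1]
    axes = default_axes(64, 128)
    cube = make_cube(spec, axes)
    wrong = (spec.peaks[0].shape.f1.center + 0.01, spec.peaks[0].shape.f2.center)
    peaks = [Peak("A10N-H", wrong, radii=(0.45, 0.06), fixed_position=(True, True))]
    group = detect_overlap_groups(peaks)[0]
    res = fit_group(cube, group)
    assert res.shapes[0].f1.center == wrong[0]
    assert res.shapes[0].f2.center == wrong[1]
    # amplitude compensates but the offset forces a nonzero residual
    assert res.cost > 0


def test_freeing_fixed_parameter_never_raises_cost():
    spec = make_overlap_scenario("isolated")
    spec.peaks = spec.peaks[:1]
    cube = make_cube(spec, default_axes(64, 128))
    wrong = (spec.peaks[0].shape.f1.center + 0.05, spec.peaks[0].shape.f2.center)
    fixed = [Peak("A", wrong, radii=(0.45, 0.06), fixed_position=(True, True))]
    free = [Peak("A", wrong, radii=(0.45, 0.06))]
    cost_fixed = fit_group(cube, detect_overlap_groups(fixed)[0]).cost
    cost_free = fit_group(cube, detect_overlap_groups(free)[0]).cost
    assert cost_free <= cost_fixed + 1e-12


def test_misfit_detectable_wrong_shape_model():
    """Lorentzian truth forced through a Gaussian model: residual floor."""
    spec = make_overlap_scenario("isolated", shape_kind=ShapeKind.LORENTZIAN)
    spec.peaks = spec.peaks[:1]
    cube = make_cube(spec, default_axes(64, 128))
    peaks = truth_peak_list(spec)
    res = fit_group(cube, detect_overlap_groups(peaks)[0],
                    FitOptions(shape=ShapeKind.GAUSSIAN))
    res_right = fit_group(cube, detect_overlap_groups(truth_peak_list(spec))[0],
                          FitOptions(shape=ShapeKind.LORENTZIAN))
    assert res.cost > 10.0 * max(res_right.cost, 1e-12)
    assert res.cost > 10.0  # absolute: far above any numerical noise floor


def test_residual_plus_model_equals_data():
    spec = make_overlap_scenario("chain3", noise_sigma=1.0, seed=9)
    cube = make_cube(spec, default_axes(64, 128))
    groups = detect_overlap_groups(truth_peak_list(spec))
    res = fit_group(cube, groups[0])
    s1, s2 = res.region_slices
    data = cube.data[:, s1, s2]
    from nmrpeakfit.peak_fit import GroupLineShapeModel

    # reconstruct the fitted surface from the returned shapes/amplitudes
    model = np.zeros_like(data)
    x1 = np.asarray(cube.axes[0].point_to_ppm(np.arange(s1.start, s1.stop, dtype=float)))
    x2 = np.asarray(cube.axes[1].point_to_ppm(np.arange(s2.start, s2.stop, dtype=float)))
    from nmrpeakfit.lineshapes import eval_shape_1d

    for k, sp in enumerate(res.shapes):
        prof = np.outer(eval_shape_1d(sp.f1, x1), eval_shape_1d(sp.f2, x2))
        model += res.amplitudes[k][:, None, None] * prof[None]
    np.testing.assert_allclose((model + res.residual_maps)[:, res.region_mask],
                               data[:, res.region_mask], rtol=0, atol=1e-9)


def test_fit_determinism():
    spec = make_overlap_scenario("chain3", noise_sigma=2.0, seed=21)
    cube = make_cube(spec, default_axes(64, 128))
    groups = detect_overlap_groups(truth_peak_list(spec))
    r1 = fit_group(cube, groups[0])
    r2 = fit_group(cube, groups[0])
    np.testing.assert_array_equal(r1.amplitudes, r2.amplitudes)
    assert r1.cost == r2.cost


def test_under_determined_region_rejected(small_axes):
    """Three coincident peaks over a ~3x3-point region: 15 free parameters
    cannot be constrained by 9 data points."""
    cube = SpectrumCube(data=np.zeros((1, 64, 128)), axes=small_axes)
    peaks = [Peak(f"A{i}", (118.0, 8.3), radii=(0.02, 0.002)) for i in range(3)]
    group = detect_overlap_groups(peaks)[0]
    with pytest.raises(ValueError, match="under-determined"):
        fit_group(cube, group)


def test_non_finite_data_rejected(small_axes):
    data = np.zeros((1, 64, 128))
    data[0, 10, 10] = np.nan
    cube = SpectrumCube(data=data, axes=small_axes)
    peaks = [Peak("A", (118.0, 8.3), radii=(0.45, 0.06))]
    with pytest.raises(ValueError, match="non-finite"):
        fit_group(cube, detect_overlap_groups(peaks)[0])


def test_pseudo3d_amplitudes_per_plane():
    """Shared positions/widths, one amplitude per plane, decay recovered."""
    spec = make_overlap_scenario("isolated")
    spec.peaks = spec.peaks[:1]
    from nmrpeakfit.synthetic import PlaneModel

    spec.plane_model = PlaneModel.EXPONENTIAL_DECAY
    spec.peaks[0].rate = 2.0
    delays = [0.0, 0.1, 0.25, 0.5]
    cube = make_cube(spec, default_axes(64, 128), plane_values=delays)
    res = fit_group(cube, detect_overlap_groups(truth_peak_list(spec))[0])
    amps = res.amplitudes[0]
    expected = spec.peaks[0].shape.amplitude * np.exp(-2.0 * np.asarray(delays))
    np.testing.assert_allclose(amps, expected, rtol=1e-6)
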