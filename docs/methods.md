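# Methods

This note records the models implemented in `nmrpeakfit`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Spectral model and coordinates

A processed 2D spectrum is a real-valued matrix with one calibration per
axis: point count n, spectral width sw (Hz), observe frequency obs (MHz) and
carrier position (ppm). Point 0 sits at the high-ppm edge,

    ppm(i) = carrier + (sw/2)/obs − i · sw/(obs · n),

and ppm decreases with index (standard display convention). All internal
coordinates are 0-based fractional points with half-open `[lo, hi)`
intervals; every file format speaks ppm. A pseudo-3D experiment is a stack
of such planes sharing both calibrations, tagged with one experimental value
per plane (delay in s, νCPMG in Hz, or saturation offset).

NMRPipe binary reading/writing interprets only the header words needed for
this model (sizes, sw/obs/car per axis, dimension count); byte order is
detected from the 2.345 float-order sentinel. The plain-text matrix dialect
(matrix per plane + `key: value` sidecar) is the normative round-trip format
and what all file-based tests use.

## Line shapes

All four 1D profiles are normalized to unit height at the center, so a
peak's fitted amplitude equals its apex intensity; "volume" is amplitude ×
the product of the closed-form 1D areas:

| shape | form | area (unit height) |
|---|---|---|
| Gaussian | exp(−4 ln2 d²/f²) | f·√(π/4 ln2) |
| Lorentzian | 1/(1+4d²/f²) | πf/2 |
| Galore | a·G + (1−a)·L, shared f | convex mix of the above |
| Voigt | Re w((d+iγ)/(σ√2)) / Re w(iγ/(σ√2)) | √(2π)·σ / Re w(iγ/(σ√2)) |

Unit-height (not unit-area) normalization was chosen because the downstream
relaxation fits consume peak heights. The Voigt is parameterized by the
Gaussian SD σ and Lorentzian HWHM γ directly — no approximate FWHM
inversion — with γ = 0 special-cased to the exact Gaussian. The Galore
mixing fraction is a bounded fit parameter in [0, 1], one per peak.

**Voigt limit behaviour.** As σ→0 the Voigt converges to the Lorentzian at
second order in σ/γ (measured 1.6e−8 relative at ratio 1e−4). As γ→0 the
unit-height Voigt converges to the Gaussian only at *first* order in γ/σ:
the apex-normalized first-order perturbation of Re w(z) does not vanish, and
the measured deviation is ≈3.6e−5 (unit-height scale) at γ/σ = 1e−4,
shrinking exactly 10× per decade. Tests assert this convergence law rather
than a tighter rate that no correct implementation could achieve.

## Overlap detection and group fitting

Two peaks overlap when their axis-aligned integration ellipses (semi-axes =
per-peak radii in ppm) intersect; overlap groups are the connected
components of this relation, so an A–B, B–C chain is one group even when A
and C are disjoint. The ellipse intersection test uses a cheap separating
box, a Minkowski-sum inclusion acceptance (E(a1+a2, b1+b2) is always inside
the Minkowski sum, by the triangle inequality on support functions), and a
bounded 1D minimization for the rare borderline pair. The test suite checks
grouping against an independent all-pairs + union-find oracle on random
crowded configurations.

Default integration radii are 0.6 ppm (indirect) × 0.08 ppm (direct); the
direct-dimension value is a typical amide ¹H footprint and both are
config-exposed. The *fit region* of a group is the union of the axis-aligned
boxes `position ± radii` (clipped to the spectrum); the ellipse is used only
for the overlap decision.

Each group is fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) over all planes jointly:

- positions and widths shared across planes; one amplitude per peak per
  plane (the sharing is what makes "intensity vs experimental parameter"
  well-posed for pseudo-3D data);
- bounds: centers within ±radii, widths > 0, Galore mixing in [0, 1];
  `fixed_position` / `fixed_width` masks remove parameters from the vector;
- initial estimates: listed positions, data value at the nearest grid node
  for amplitudes, FWHM 0.3/0.03 ppm (indirect/direct, configurable);
- uniform weights within a fit (noise is plane-stationary); the noise RMS is
  used for error propagation, not weighting;
- iteration cap 1000 (function-evaluation budget scaled by parameter count);
  the convergence flag reports whether the solver stopped on its own;
- no randomness anywhere in the fitter: identical inputs give identical
  outputs.

Residual maps (data − model over the fit region) are returned per plane and
written by the CLI, giving the numeric equivalent of a difference map for
fit diagnostics.

Noise is estimated per plane as 1.4826 × median absolute deviation of all
points — consistent for Gaussian noise and insensitive to the sparse strong
peaks sitting on the floor (tests: within 5% with three tall peaks added).

**Peak centering.** Two routines, matching their distinct use cases. For
isolated peaks far from their listed position: the strongest extremum within
a search box anchors an intensity-weighted centroid over its half-maximum
footprint. For overlapped peaks near their true positions: a restricted
group fit in two passes — amplitudes only at fixed positions first (a linear
screen that flags signal-free entries below 3× noise RMS and excludes them,
since a signal-free peak left free drifts onto its neighbours' intensity),
then bounded centers + amplitudes for the survivors.

**Peak picking** takes 8-neighborhood extrema above a threshold × noise RMS
(both signs), ordered by descending magnitude with (F1, F2) index
tie-breaks, and names them from a `P{i}`-style format string.

## Intensity models

Fitted per peak, in the Model → fit() → results idiom; closed-form starting
values (log-linear regression for exponentials), analytic Jacobians, and
asymptotic standard errors from (JᵀJ)⁻¹s². The set: linear (with a
through-origin variant), exponential decay (with an offset variant),
saturation recovery I∞(1−e^{−R1 t}), inversion recovery with a free I₀
(imperfect inversion), hetNOE ratio with first-order error propagation,
R1ρ→R2 via R2 = (R1ρ − R1 cos²θ)/sin²θ, and CPMG dispersion.

**CPMG dispersion.** Intensities convert to rates via
R2eff = −ln(I/I0)/T_relax (constant-time element; plane value 0 marks the
reference plane). The dispersion model is the Davis-corrected
Carver–Richards expression with equal intrinsic R2 in both states:

    τcp = 1/(2 νCPMG),  Ψ = k_ex² − Δω²,  ζ = −2 Δω k_ex (p_A − p_B)
    D± = ½[±1 + (Ψ + 2Δω²)/√(Ψ² + ζ²)]
    η± = (τcp/√2)·√(±Ψ + √(Ψ² + ζ²))
    R2eff = R2⁰ + ½[k_ex − (1/τcp)·arccosh(D₊ cosh η₊ − D₋ cos η₋)]

Numerical safety: √(Ψ²+ζ²) via `hypot`; the degenerate no-exchange limits
(Δω = 0 or p_A = 1) short-circuit to R2⁰; for η₊ > 30 the arccosh is
evaluated in log space (ln cosh η ≈ η − ln 2 + ln(1+e^{−2η})) so no overflow
occurs at slow fields. The implementation broadcasts over all parameters,
which the grid search exploits.

An independent route — propagation of the two-state Bloch–McConnell
transverse-magnetization equations with a complex 2×2 generator,
matrix-exponential free-precession segments and ideal 180° pulses
(conjugation), measuring the per-cycle decay from the magnetization ratio
between 2n and 4n echoes to strip the initial transient — reproduces the
closed form to ≤0.15% over the tested sweep (k_ex 100–5000 s⁻¹, p_A
0.85–0.99, Δω 300–4000 rad/s, ν 50–1000 Hz). In the fast-exchange regime
(k_ex/Δω ≥ 20) it also matches the Luz–Meiboom form to <1%.

A genuine property of the exact equal-R2 solution worth knowing: in slow
exchange (k_ex ≪ Δω) R2eff(ν) develops small low-field ripples and is not
strictly monotone; monotone decay holds in the intermediate/fast regime.

**Grid search.** Starting values come from an exhaustive grid — k_ex
log-spaced 10–10⁴ s⁻¹ (13), p_A 0.70–0.99 (8), Δω 100–6000 rad/s (12) — with
R2⁰ pinned to the minimum observed R2eff at every node and first-in-order
tie-breaking. The grid response is data-independent up to that additive
constant, so it is computed once and cached per (grid, field set). The
refit always also tries the exchange-free corner (Δω = 0, R2⁰ = mean) as a
second start, which guarantees the fitted RSS never exceeds the nested flat
model's — the invariant the F-test relies on.

**F-test.** F = ((RSS₁−RSS₂)/(df₁−df₂)) / (RSS₂/df₂) with the flat model
(1 parameter) against the dispersion model (4), p from the F(3, n−4) upper
tail, significance at α = 0.01 by default. For this *nonlinear* comparison
the classical reference distribution is conservative: under the flat null
the exchange parameters are unidentifiable and the bounded, monotone
dispersion family cannot absorb white noise, so the realized type-I rate at
α = 0.01 is ≈0.1–0.2% rather than 1% (measured by simulation in the test
suite; a multi-start refit does not change it, so it is not an optimizer
artifact). Practically: significance calls err on the side of fewer false
positives; p-values should be read as upper bounds.

## Uncertainties

Three genuinely different schemes over any fit function:

- **jackknife** — deterministic delete-1 refits,
  SE² = (n−1)/n · Σ(θ̂₍ᵢ₎ − θ̄)²; requires n ≥ p + 2;
- **bootstrap** — with-replacement resampling of (x, I) pairs, replicate SD
  and 2.5–97.5 percentile intervals; default 200 replicates, seed 0;
- **Monte Carlo** — parametric: seeded Gaussian noise of known σ (typically
  the spectral noise RMS) added to the *fitted* curve, then refit; distinct
  from the bootstrap by construction.

Data are canonically sorted by x before any resampling indices are drawn, so
results are invariant to input point order. Failed replicates are dropped
and counted; results with >10% failures are flagged unreliable. When every
replicate agrees bitwise the SD is reported as exactly 0 (the naive mean of
n identical floats rounds, leaving ~1e−16 artifacts).

## Synthetic data

The generator renders separable peaks on a 15N–¹H amide-region grid
(22.2 ppm at 60.8 MHz × 3.3 ppm at 600 MHz on a 600 MHz instrument),
modulates per-plane amplitudes by the chosen intensity model (constant,
exponential, saturation recovery, or CPMG via the constant-time transform),
and adds seeded white Gaussian noise per grid node. Canonical scenarios:
three well-separated singletons; a 3-peak chain at 1.2–1.4 × FWHM spacing
(the classic "must be co-fitted" trio); an 11-peak cluster emulating the
worst overlap in a crowded spectrum. Line widths default to 0.35/0.035 ppm.

What it deliberately does not emulate: correlated or ridge noise, baseline
distortions, phase-twist or apodization-dependent line shapes, solvent
artifacts, and TopSpin-format data. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to processing artifacts in real spectra.

**Problem sizes used in tests.** Recovery and centering tests run on grids
sampled at ~4–5 points per FWHM (256×512 over the amide region). This is a
property of the data, not of the fitter: at 1–2 points per FWHM, amplitude
and width are mutually degenerate under noise for any estimator, and the
tests document that regime choice. Simulation counts (100 noisy recovery
trials, 1000 F-test nulls, 500 bootstrap coverage runs with 200 replicates)
were chosen to keep sampling error well below the asserted tolerances.

## Degenerate inputs and tie-breaks

- Flat CPMG data: the fit is reported as-is (Δω·√(p_A p_B) → 0); parameters
  are never auto-zeroed — significance is the F-test's job.
- RSS₂ = 0 in the F-test: p = 0 with a degeneracy warning.
- Peak picking ties: stable sort by (−|height|, F1 index, F2 index).
- Grid-search ties: first node in iteration order (k_ex, then p_A, then Δω).
- Folded peaks: position shifted by the integer number of spectral widths
  that minimizes the displacement.
- Ratio I/I0 ≤ 0 cannot convert to R2eff and raises, as does an
  off-resonance R1ρ conversion without R1.

## Limitations

Single-field data only (no multi-field co-fitting), no global multi-residue
dispersion fits, no model-free analysis, no CEST model fitting (offset
profiles are integrated but not fitted), no Bloch–McConnell R1ρ fits, and no
spectral processing (the input must be a processed absorption-mode
spectrum). The F-test conservatism above means borderline exchange (p just
under α) is rarer than nominal theory suggests; users who need calibrated
error rates should calibrate the threshold by simulation for their design.
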