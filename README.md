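# nmrpeakfit

Line-shape fitting of two-dimensional and pseudo-3D NMR spectra, with
downstream fitting of peak intensities to relaxation and chemical-exchange
models.

Quantitative NMR studies of biomolecular dynamics — R1/R2 relaxation,
heteronuclear NOE, R1ρ, and CPMG relaxation dispersion — all start from the
same task: measuring peak intensities accurately in crowded 2D correlation
maps, plane by plane, as a function of an experimental parameter (relaxation
delay, refocusing field νCPMG, saturation offset). `nmrpeakfit` does that by
fitting analytical line shapes to the data rather than summing boxes of
points, which keeps overlapped peaks quantitative: peaks whose integration
regions intersect are detected automatically and co-fitted as a group, with
positions and line widths shared across all planes and one amplitude per peak
per plane.

## What it computes

**Line shapes.** Each cross peak is a separable product
`A · f1(ω1) · f2(ω2)` of unit-height 1D profiles, so the fitted amplitude is
the apex intensity. Four profiles are available per dimension:

- Gaussian `exp(−4 ln2 (x−c)²/FWHM²)`
- Lorentzian `1 / (1 + 4(x−c)²/FWHM²)`
- Galore (pseudo-Voigt): `a·G + (1−a)·L` with one shared FWHM, `a ∈ [0,1]`
- Voigt: Gaussian ⊗ Lorentzian with independent widths (σ, γ), evaluated
  through the Faddeeva function `w(z)`

Peak volumes come from the closed-form areas of these profiles.

**Intensity models.** Per-peak intensity series are fitted to linear,
exponential-decay, saturation/inversion-recovery, and CPMG dispersion models;
hetNOE ratios and R1ρ→R2 conversion (via the spin-lock tilt angle
θ = arctan(ω1/Ω)) are provided as closed forms. CPMG profiles are fitted in
R2eff space with the Davis-corrected Carver–Richards equation for two-state
exchange A ⇌ B (parameters: exchange-free rate R2⁰, exchange rate
k_ex = k_AB + k_BA, major population p_A, shift difference Δω), preceded by an
exhaustive grid search for starting values. A matrix-exponential propagation
of the two-state Bloch–McConnell equations through the ideal-pulse echo train
is included and cross-validates the closed form to ≪1%.

**Statistics.** Parameter uncertainties by delete-1 jackknife, seeded
nonparametric bootstrap (with percentile intervals), or parametric Monte
Carlo driven by the spectral noise RMS (estimated robustly as
1.4826 × MAD). Significance of exchange is decided by a partial F-test of the
dispersion model against a flat null (default α = 0.01); note the test is
conservative for this nonlinear comparison (see `docs/methods.md`).

## Worked example

Generate a synthetic three-peak overlapped fixture whose amplitudes decay
exponentially across five planes (true rates 1.0, 1.5, 2.0 s⁻¹), then run the
full pipeline:

```sh
nmrpeakfit make-fixtures --out demo --scenario chain3 \
    --plane-model exponential_decay --noise-sigma 0.5 --seed 3
nmrpeakfit integrate --config demo/project.cfg
nmrpeakfit fit --config demo/project.cfg
nmrpeakfit report --config demo/project.cfg --parameter R
```

`integrate` prints `integrated 3 peak(s) -> demo/results/peak_parameters.tsv`
and writes per-plane intensities; `fit` writes `model_fits.tsv` with the
fitted decay rates and bootstrap errors; `report` emits a per-residue series.
With the seed above, `demo/results/report_R.tsv` contains:

```
residue	assignment	value	error
22	D22N-H	1.99313863	0.0170235044
20	L20N-H	1.000487913	0.003161771637
21	S21N-H	1.503913559	0.01117419991
```

i.e. the three true rates recovered to well under 1% despite the peaks
overlapping at ~1.3 × FWHM spacing. The same `fit`/`report` steps applied to
a `--plane-model cpmg_dispersion` fixture produce k_ex, p_A, Δω, R2⁰ columns
plus F-test p-values and a significance flag per peak.

The library mirrors the CLI: `GroupLineShapeModel(cube, group).fit()` returns
a `GroupFitResult` (amplitudes, volumes, residual maps, `summary()`), and the
intensity models (`ExponentialModel`, `CpmgDispersionModel`, …) follow the
same Model → `fit()` → results-with-`summary()` pattern.

Spectra are read from NMRPipe binary planes/pseudo-3D streams or from a
plain-text matrix dialect (one whitespace-delimited matrix per plane plus a
`key: value` calibration sidecar); peak lists are Sparky-style
`assignment w1 w2` text files.

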