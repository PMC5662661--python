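"""Resampling- and simulation-based parameter uncertainties.

Three genuinely different schemes, all applicable to any intensity-model
fit function (a callable ``series -> ModelFit``):

* jackknife — deterministic delete-1 refits;
* bootstrap — seeded with-replacement resampling of (x, I) pairs, with
  percentile intervals as a byproduct;
* Monte Carlo — parametric: seeded Gaussian noise is added to the
  *fitted* model curve and the fit repeated, propagating a known
  spectral noise level into the parameters.

For reproducibility the data are canonically sorted by x before any
resampling indices are drawn, so the results do not depend on input
point order.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .intensity_models import IntensitySeries, ModelFit

__all__ = [
    "UncertaintyMethod",
    "UncertaintyConfig",
    "UncertaintyResult",
    "jackknife_errors",
    "bootstrap_errors",
    "monte_carlo_errors",
    "estimate_errors",
]

FitFn = Callable[[IntensitySeries], ModelFit]


class UncertaintyMethod(str, enum.Enum):
    JACKKNIFE = "jackknife"
    BOOTSTRAP = "bootstrap"
    MONTE_CARLO = "monte_carlo"


@dataclass
class UncertaintyConfig:
    method: UncertaintyMethod = UncertaintyMethod.BOOTSTRAP
    n_replicates: int = 200
    seed: int = 0
    noise_sigma: float | np.ndarray | None = None  # Monte Carlo only

    def __post_init__(self) -> None:
        self.method = UncertaintyMethod(self.method)
        if self.method is not UncertaintyMethod.JACKKNIFE and self.n_replicates < 50:
            raise ValueError(
                f"{self.method.value} needs >= 50 replicates, got {self.n_replicates}"
            )


@dataclass
class UncertaintyResult:
    method: UncertaintyMethod
    std_errors: dict[str, float]
    intervals: dict[str, tuple[float, float]] | None = None  # bootstrap percentiles
    n_replicates: int = 0
    n_failed: int = 0

    @property
    def unreliable(self) -> bool:
        """More than 10% of replicates failed to converge."""
        total = self.n_replicates + self.n_failed
        return total > 0 and self.n_failed > 0.1 * total


def _replicate_matrix(fits: list[dict[str, float]], names: list[str]) -> np.ndarray:
    return np.array([[f[n] for n in names] for f in fits], dtype=float)


def _replicate_sd(theta: np.ndarray) -> np.ndarray:
    """Replicate SD with exact zeros when every replicate agrees bitwise
    (the mean of n identical floats rounds, leaving ~1e-16 residuals)."""
    if theta.shape[0] < 2:
        return np.zeros(theta.shape[1])
    sd = theta.std(axis=0, ddof=1)
    return np.where(np.ptp(theta, axis=0) == 0.0, 0.0, sd)


def jackknife_errors(fit_fn: FitFn, series: IntensitySeries) -> UncertaintyResult:
    """Delete-1 jackknife standard errors.

    SE_j = sqrt( (n-1)/n * sum_i (theta_(i) - theta_bar)^2 ).
    Requires at least two more observations than model parameters so
    every leave-one-out fit is still overdetermined.
    """
    s = series.sorted_by_x()
    full = fit_fn(s)
    n = s.n
    if n < full.n_params + 2:
        raise ValueError(
            f"jackknife needs n_obs >= n_params + 2 ({full.n_params + 2}), got {n}"
        )
    names = list(full.params)
    reps = []
    for i in range(n):
        keep = np.arange(n) != i
        sub = IntensitySeries(s.x[keep], s.I[keep],
                              None if s.sigma_I is None else s.sigma_I[keep],
                              s.kind, s.assignment)
        reps.append(fit_fn(sub).params)
    theta = _replicate_matrix(reps, names)
    mean = theta.mean(axis=0)
    se = np.sqrt((n - 1) / n * np.sum((theta - mean) ** 2, axis=0))
    return UncertaintyResult(UncertaintyMethod.JACKKNIFE,
                             dict(zip(names, map(float, se))), n_replicates=n)


def bootstrap_errors(fit_fn: FitFn, series: IntensitySeries,
                     cfg: UncertaintyConfig | None = None) -> UncertaintyResult:
    """Nonparametric bootstrap: resample (x, I) pairs with replacement and refit.

    Returns the replicate standard deviation per parameter and the 2.5th
    to 97.5th percentile interval.  Replicates whose fit raises or fails
    to converge are dropped and counted.
    """
    cfg = cfg or UncertaintyConfig(method=UncertaintyMethod.BOOTSTRAP)
    s = series.sorted_by_x()
    full = fit_fn(s)
    names = list(full.params)
    rng = np.random.default_rng(cfg.seed)
    reps, failed = [], 0
    for _ in range(cfg.n_replicates):
        idx = rng.integers(0, s.n, size=s.n)
        sub = IntensitySeries(s.x[idx], s.I[idx],
                              None if s.sigma_I is None else s.sigma_I[idx],
                              s.kind, s.assignment)
        try:
            f = fit_fn(sub)
        except (ValueError, RuntimeError):
            failed += 1
            continue
        if not f.converged:
            failed += 1
            continue
        reps.append(f.params)
    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    theta = _replicate_matrix(reps, names)
    se = _replicate_sd(theta)
    lo = np.percentile(theta, 2.5, axis=0)
    hi = np.percentile(theta, 97.5, axis=0)
    result = UncertaintyResult(
        UncertaintyMethod.BOOTSTRAP,
        dict(zip(names, map(float, se))),
        intervals={n: (float(a), float(b)) for n, a, b in zip(names, lo, hi)},
        n_replicates=len(reps),
        n_failed=failed,
    )
    if result.unreliable:
        warnings.warn(
            f"bootstrap: {failed}/{cfg.n_replicates} replicates failed; "
            "errors flagged unreliable", stacklevel=2,
        )
    return result


def monte_carlo_errors(fit_fn: FitFn, series: IntensitySeries,
                       cfg: UncertaintyConfig) -> UncertaintyResult:
    """Parametric Monte Carlo: perturb the fitted curve with Gaussian noise.

    ``cfg.noise_sigma`` (scalar or per point) is the intensity noise —
    typically the spectral noise RMS propagated from the line-shape fit.
    """
    if cfg.noise_sigma is None:
        raise ValueError("Monte Carlo errors require noise_sigma")
    s = series.sorted_by_x()
    full = fit_fn(s)
    if full.predict is None:
        raise ValueError("fit function must return a ModelFit with a predict callable")
    names = list(full.params)
    base = np.asarray(full.predict(s.x), dtype=float)
    sigma = np.broadcast_to(np.asarray(cfg.noise_sigma, dtype=float), base.shape)
    rng = np.random.default_rng(cfg.seed)
    reps, failed = [], 0
    for _ in range(cfg.n_replicates):
        sub = IntensitySeries(s.x, base + rng.normal(0.0, 1.0, base.shape) * sigma,
                              s.sigma_I, s.kind, s.assignment)
        try:
            f = fit_fn(sub)
        except (ValueError, RuntimeError):
            failed += 1
            continue
        if not f.converged:
            failed += 1
            continue
        reps.append(f.params)
    if not reps:
        raise RuntimeError("all Monte Carlo replicates failed")
    theta = _replicate_matrix(reps, names)
    se = _replicate_sd(theta)
    result = UncertaintyResult(
        UncertaintyMethod.MONTE_CARLO,
        dict(zip(names, map(float, se))),
        n_replicates=len(reps), n_failed=failed,
    )
    if result.unreliable:
        warnings.warn(
            f"monte carlo: {failed}/{cfg.n_replicates} replicates failed; "
            "errors flagged unreliable", stacklevel=2,
        )
    return result


def estimate_errors(fit_fn: FitFn, series: IntensitySeries,
                    cfg: UncertaintyConfig) -> UncertaintyResult:
    """Dispatch to the configured uncertainty method."""
    if cfg.method is UncertaintyMethod.JACKKNIFE:
        return jackknife_errors(fit_fn, series)
    if cfg.method is UncertaintyMethod.BOOTSTRAP:
        return bootstrap_errors(fit_fn, series, cfg)
    return monte_carlo_errors(fit_fn, series, cfg)
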