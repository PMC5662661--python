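"""Models for peak-intensity series: relaxation decays, recovery curves,
CPMG relaxation dispersion, heteronuclear NOE and R1rho conversion.

The fitting surface follows the Model/Results idiom: each model class is
constructed from an :class:`IntensitySeries` and ``fit()`` returns a
:class:`ModelFit` carrying estimates, asymptotic standard errors, the
residual sum of squares and a ``summary()`` table.  Module-level
``fit_*`` functions are thin wrappers kept for pipeline use.

Chemical exchange model
-----------------------
Two-state exchange A <-> B with exchange rate ``k_ex = k_AB + k_BA``,
major-state population ``p_A`` and chemical-shift difference
``delta_omega`` (rad/s) modulates the effective transverse relaxation
rate measured in a CPMG experiment.  The closed form used is the
Carver-Richards expression with the Davis correction, assuming equal
intrinsic R2 for both states:

    tau_cp  = 1 / (2 nu_cpmg)            inter-pulse delay
    Psi     = k_ex^2 - dw^2
    zeta    = -2 dw k_ex (p_A - p_B)
    D_pm    = 1/2 [ +-1 + (Psi + 2 dw^2) / sqrt(Psi^2 + zeta^2) ]
    eta_pm  = (tau_cp / sqrt 2) sqrt( +-Psi + sqrt(Psi^2 + zeta^2) )
    R2eff   = r2_0 + 1/2 [ k_ex - (1/tau_cp) arccosh( D+ cosh eta+ - D- cos eta- ) ]

A matrix-exponential propagation of the two-state Bloch-McConnell
equations through an ideal-pulse CPMG echo train
(:func:`bloch_mcconnell_r2eff`) provides an independent numerical route
to the same quantity and is used to validate the closed form.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import expm
from scipy.optimize import least_squares

__all__ = [
    "SeriesKind",
    "IntensitySeries",
    "DispersionParams",
    "ModelFit",
    "LinearModel",
    "ExponentialModel",
    "RecoveryModel",
    "CpmgDispersionModel",
    "FlatModel",
    "fit_linear",
    "fit_exponential",
    "fit_recovery",
    "fit_flat",
    "fit_cpmg",
    "grid_search_cpmg",
    "carver_richards_r2eff",
    "luz_meiboom_r2eff",
    "bloch_mcconnell_r2eff",
    "intensities_to_r2eff",
    "hetnoe",
    "r1rho_to_r2",
    "f_test_exchange",
    "GridSpec",
]


class SeriesKind(str, enum.Enum):
    DELAY = "delay"
    CPMG_FIELD = "cpmg_field"
    RATIO_PAIR = "ratio_pair"
    R1RHO_INPUT = "r1rho_input"
    GENERIC = "generic"


@dataclass
class IntensitySeries:
    """Peak intensity (or R2eff) versus an experimental parameter."""

    x: np.ndarray
    I: np.ndarray
    sigma_I: np.ndarray | None = None
    kind: SeriesKind = SeriesKind.GENERIC
    assignment: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.kind = SeriesKind(self.kind)
        if self.x.shape != self.I.shape:
            raise ValueError(f"x and I lengths differ: {self.x.shape} vs {self.I.shape}")
        if self.sigma_I is not None:
            self.sigma_I = np.asarray(self.sigma_I, dtype=float)
            if self.sigma_I.shape != self.x.shape:
                raise ValueError("sigma_I length must match x")
            if np.any(self.sigma_I <= 0):
                raise ValueError("sigma_I must be strictly positive")

    @property
    def n(self) -> int:
        return self.x.size

    def sorted_by_x(self) -> "IntensitySeries":
        order = np.argsort(self.x, kind="stable")
        return IntensitySeries(
            self.x[order], self.I[order],
            None if self.sigma_I is None else self.sigma_I[order],
            self.kind, self.assignment,
        )


@dataclass
class DispersionParams:
    """Two-state exchange parameters for CPMG dispersion."""

    r2_0: float          # s^-1, exchange-free transverse rate
    k_ex: float          # s^-1, k_AB + k_BA
    p_A: float           # major-state population, [0.5, 1]
    delta_omega: float   # rad s^-1, |shift difference| (sign unidentifiable)

    def __post_init__(self) -> None:
        if self.r2_0 < 0:
            raise ValueError(f"r2_0 must be >= 0, got {self.r2_0}")
        if self.k_ex <= 0:
            raise ValueError(f"k_ex must be > 0, got {self.k_ex}")
        if not (0.5 <= self.p_A <= 1.0):
            raise ValueError(f"p_A must be in [0.5, 1], got {self.p_A}")
        if self.delta_omega < 0:
            raise ValueError(f"delta_omega must be >= 0, got {self.delta_omega}")


@dataclass
class ModelFit:
    """Result of one intensity-model fit."""

    model: str
    params: dict[str, float]
    param_errors: dict[str, float]
    rss: float
    n_obs: int
    n_params: int
    converged: bool = True
    predict: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.n_params

    def summary(self) -> str:
        lines = [
            f"Model: {self.model}",
            f"Observations: {self.n_obs}   Parameters: {self.n_params}   "
            f"RSS: {self.rss:.6g}   converged: {self.converged}",
            f"{'parameter':>12} {'estimate':>14} {'std err':>12}",
        ]
        for k, v in self.params.items():
            se = self.param_errors.get(k, float("nan"))
            lines.append(f"{k:>12} {v:>14.6g} {se:>12.4g}")
        return "\n".join(lines)


def _covariance_errors(res, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from a least_squares result (J^T J)^-1 s^2."""
    n_params = res.x.size
    dof = max(n_obs - n_params, 1)
    s2 = 2.0 * res.cost / dof
    J = res.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    return se


# ---------------------------------------------------------------------------
# simple models

class LinearModel:
    """I = a + b x, closed-form weighted least squares."""

    param_names = ("a", "b")

    def __init__(self, series: IntensitySeries, through_origin: bool = False):
        if series.n < (2 if through_origin else 3):
            raise ValueError("linear fit needs at least 3 points (2 through origin)")
        self.series = series
        self.through_origin = through_origin

    def fit(self) -> ModelFit:
        x, y = self.series.x, self.series.I
        n = x.size
        if self.through_origin:
            b = float(np.dot(x, y) / np.dot(x, x))
            resid = y - b * x
            rss = float(np.dot(resid, resid))
            s2 = rss / max(n - 1, 1)
            se_b = math.sqrt(s2 / float(np.dot(x, x)))
            return ModelFit(
                "linear_origin", {"b": b}, {"b": se_b}, rss, n, 1,
                predict=lambda xx, b=b: b * np.asarray(xx, dtype=float),
            )
        A = np.vstack([np.ones_like(x), x]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a, b = float(coef[0]), float(coef[1])
        resid = y - (a + b * x)
        rss = float(np.dot(resid, resid))
        s2 = rss / max(n - 2, 1)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se_b = math.sqrt(s2 / sxx) if sxx > 0 else float("inf")
        se_a = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)) if sxx > 0 else float("inf")
        return ModelFit(
            "linear", {"a": a, "b": b}, {"a": se_a, "b": se_b}, rss, n, 2,
            predict=lambda xx, a=a, b=b: a + b * np.asarray(xx, dtype=float),
        )


class ExponentialModel:
    """Exponential decay I(x) = I0 exp(-R x), optionally with a baseline offset.

    Initial estimates come from a log-linear regression on |I| (offset
    variant: on |I - min|); refinement is bounded trust-region least
    squares with an analytic Jacobian.
    """

    def __init__(self, series: IntensitySeries, offset: bool = False):
        min_pts = 4 if offset else 3
        if series.n < min_pts:
            raise ValueError(f"exponential fit needs at least {min_pts} points")
        self.series = series
        self.offset = offset

    def _start(self) -> np.ndarray:
        x, y = self.series.x, self.series.I
        c0 = float(y.min()) - 1e-3 * abs(float(y.min())) if self.offset else 0.0
        z = np.abs(y - c0)
        if np.all(z <= 0):
            raise ValueError("cannot initialize exponential fit: all intensities <= 0")
        pos = z > 0
        if pos.sum() < 2:
            raise ValueError("cannot initialize exponential fit: fewer than 2 usable points")
        coef = np.polyfit(x[pos], np.log(z[pos]), 1)
        R0 = max(-float(coef[0]), 0.0)
        I00 = float(np.exp(coef[1])) * math.copysign(1.0, float(y[np.argmin(x)]) - c0)
        start = [I00, R0]
        if self.offset:
            start.append(c0)
        return np.asarray(start, dtype=float)

    def fit(self, start: Sequence[float] | None = None) -> ModelFit:
        x, y = self.series.x, self.series.I
        p0 = np.asarray(start, dtype=float) if start is not None else self._start()

        if self.offset:
            def resid(p):
                return p[0] * np.exp(-p[1] * x) + p[2] - y

            def jac(p):
                e = np.exp(-p[1] * x)
                return np.stack([e, -p[0] * x * e, np.ones_like(x)], axis=1)

            names = ("I0", "R", "C")
        else:
            def resid(p):
                return p[0] * np.exp(-p[1] * x) - y

            def jac(p):
                e = np.exp(-p[1] * x)
                return np.stack([e, -p[0] * x * e], axis=1)

            names = ("I0", "R")

        res = least_squares(resid, p0, jac=jac, method="lm", xtol=1e-14, ftol=1e-14)
        se = _covariance_errors(res, x.size)
        params = dict(zip(names, (float(v) for v in res.x)))
        errors = dict(zip(names, (float(v) for v in se)))
        model_id = "exponential_offset" if self.offset else "exponential"
        p_fit = res.x.copy()

        if self.offset:
            pred = lambda xx: p_fit[0] * np.exp(-p_fit[1] * np.asarray(xx, float)) + p_fit[2]
        else:
            pred = lambda xx: p_fit[0] * np.exp(-p_fit[1] * np.asarray(xx, float))
        return ModelFit(
            model_id, params, errors, float(2.0 * res.cost), x.size, len(names),
            converged=res.status > 0, predict=pred,
        )


class RecoveryModel:
    """Longitudinal relaxation recovery.

    ``mode='saturation'``: I(t) = I_inf (1 - exp(-R1 t)) — magnetization
    grows from zero after saturation.
    ``mode='inversion'``: I(t) = I_inf - (I_inf - I_0) exp(-R1 t) with
    I_0 free, absorbing imperfect inversion.
    """

    def __init__(self, series: IntensitySeries, mode: str = "saturation"):
        if mode not in ("saturation", "inversion"):
            raise ValueError(f"unknown recovery mode {mode!r}")
        if series.n < 4:
            raise ValueError("recovery fit needs at least 4 points")
        self.series = series
        self.mode = mode

    def fit(self, start: Sequence[float] | None = None) -> ModelFit:
        x, y = self.series.x, self.series.I
        i_inf0 = float(y[np.argmax(x)])
        if i_inf0 == 0.0:
            i_inf0 = float(np.max(np.abs(y))) or 1.0
        span = max(float(x.max() - x.min()), 1e-12)
        r0 = 1.0 / span

        if self.mode == "saturation":
            names = ("I_inf", "R1")
            p0 = np.asarray(start if start is not None else [i_inf0, r0], float)

            def resid(p):
                return p[0] * (1.0 - np.exp(-p[1] * x)) - y

            def jac(p):
                e = np.exp(-p[1] * x)
                return np.stack([1.0 - e, p[0] * x * e], axis=1)
        else:
            names = ("I_inf", "I_0", "R1")
            i00 = float(y[np.argmin(x)])
            p0 = np.asarray(start if start is not None else [i_inf0, i00, r0], float)

            def resid(p):
                return p[0] - (p[0] - p[1]) * np.exp(-p[2] * x) - y

            def jac(p):
                e = np.exp(-p[2] * x)
                return np.stack([1.0 - e, e, (p[0] - p[1]) * x * e], axis=1)

        res = least_squares(resid, p0, jac=jac, method="lm", xtol=1e-14, ftol=1e-14)
        se = _covariance_errors(res, x.size)
        params = dict(zip(names, (float(v) for v in res.x)))
        errors = dict(zip(names, (float(v) for v in se)))
        p_fit = res.x.copy()
        if self.mode == "saturation":
            pred = lambda xx: p_fit[0] * (1.0 - np.exp(-p_fit[1] * np.asarray(xx, float)))
        else:
            pred = lambda xx: p_fit[0] - (p_fit[0] - p_fit[1]) * np.exp(
                -p_fit[2] * np.asarray(xx, float)
            )
        return ModelFit(
            f"recovery_{self.mode}", params, errors, float(2.0 * res.cost),
            x.size, len(names), converged=res.status > 0, predict=pred,
        )


class FlatModel:
    """Constant model I = c (the no-exchange null for dispersion data)."""

    def __init__(self, series: IntensitySeries):
        if series.n < 2:
            raise ValueError("flat fit needs at least 2 points")
        self.series = series

    def fit(self) -> ModelFit:
        y = self.series.I
        c = float(y.mean())
        rss = float(np.sum((y - c) ** 2))
        se = math.sqrt(rss / max(y.size - 1, 1) / y.size)
        return ModelFit(
            "flat", {"c": c}, {"c": se}, rss, y.size, 1,
            predict=lambda xx, c=c: np.full(np.asarray(xx, float).shape, c),
        )


# ---------------------------------------------------------------------------
# ratios and conversions

def hetnoe(I_sat: float, I_ref: float, sigma_sat: float = 0.0,
           sigma_ref: float = 0.0) -> tuple[float, float]:
    """Heteronuclear NOE = I_sat / I_ref with first-order error propagation."""
    if I_ref == 0:
        raise ValueError("reference intensity must be nonzero")
    noe = I_sat / I_ref
    if I_sat == 0:
        err = abs(sigma_sat / I_ref)
    else:
        err = abs(noe) * math.sqrt((sigma_sat / I_sat) ** 2 + (sigma_ref / I_ref) ** 2)
    return noe, err


def r1rho_to_r2(r1rho: float, r1: float | None, omega1: float, offset: float = 0.0) -> float:
    """Convert R1rho to R2 through the spin-lock tilt angle.

    theta = arctan(omega1 / Omega); on resonance (Omega = 0) theta = pi/2
    and R2 = R1rho.  Off resonance R1 is required:
    R2 = (R1rho - R1 cos^2 theta) / sin^2 theta.
    """
    if omega1 <= 0:
        raise ValueError(f"spin-lock field omega1 must be > 0, got {omega1}")
    if offset == 0.0:
        return r1rho
    if r1 is None:
        raise ValueError("off-resonance R1rho -> R2 conversion requires R1")
    theta = math.atan2(omega1, offset)
    s2 = math.sin(theta) ** 2
    c2 = math.cos(theta) ** 2
    return (r1rho - r1 * c2) / s2


def intensities_to_r2eff(I, I0: float, T_relax: float):
    """R2eff = -(1/T) ln(I / I0) for a constant-time CPMG element."""
    if T_relax <= 0:
        raise ValueError(f"T_relax must be > 0, got {T_relax}")
    ratio = np.asarray(I, dtype=float) / I0
    if np.any(ratio <= 0):
        raise ValueError("intensity ratio I/I0 must be > 0 to convert to R2eff")
    out = -np.log(ratio) / T_relax
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Carver-Richards closed form (+ limits, + Bloch-McConnell oracle route)

def carver_richards_r2eff(p: DispersionParams, nu_cpmg):
    """Effective R2 under two-state exchange at CPMG field(s) ``nu_cpmg`` (Hz).

    Davis-corrected Carver-Richards with equal intrinsic R2 for both
    states.  Safe for large eta+ (log-scaled cosh) and for the
    degenerate no-dispersion limits (dw = 0 or p_A = 1).
    """
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be > 0")
    out = _cr_r2eff(p.r2_0, p.k_ex, p.p_A, p.delta_omega, nu)
    return out if out.ndim else float(out)


def _cr_r2eff(r2_0, k_ex, p_A, dw, nu):
    """Broadcasting core of the Carver-Richards expression."""
    r2_0 = np.asarray(r2_0, float)
    k_ex = np.asarray(k_ex, float)
    p_A = np.asarray(p_A, float)
    dw = np.asarray(dw, float)
    nu = np.asarray(nu, float)

    p_B = 1.0 - p_A
    tau = 1.0 / (2.0 * nu)
    psi = k_ex**2 - dw**2
    zeta = -2.0 * dw * k_ex * (p_A - p_B)
    s = np.hypot(psi, zeta)
    # no minor state or no shift difference: exchange contribution vanishes
    degenerate = (dw * np.sqrt(np.clip(p_A * p_B, 0.0, None))) == 0.0
    s_safe = np.where(s > 0.0, s, 1.0)
    dpl = 0.5 * (1.0 + (psi + 2.0 * dw**2) / s_safe)
    dmi = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / s_safe)
    eta_pl = (tau / math.sqrt(2.0)) * np.sqrt(np.clip(s + psi, 0.0, None))
    eta_mi = (tau / math.sqrt(2.0)) * np.sqrt(np.clip(s - psi, 0.0, None))

    # arccosh(D+ cosh eta+ - D- cos eta-), log-scaled when eta+ is large
    small = eta_pl < 30.0
    arg = dpl * np.cosh(np.where(small, eta_pl, 0.0)) - dmi * np.cos(eta_mi)
    acosh_small = np.arccosh(np.clip(arg, 1.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        # cosh(eta+) = e^eta+ (1 + e^-2eta+) / 2 for large eta+
        ln_x = eta_pl + np.log(
            np.clip(
                0.5 * dpl * (1.0 + np.exp(-2.0 * eta_pl))
                - dmi * np.cos(eta_mi) * np.exp(-eta_pl),
                1e-300,
                None,
            )
        )
        acosh_large = ln_x + np.log1p(np.sqrt(np.clip(1.0 - np.exp(-2.0 * ln_x), 0.0, 1.0)))
    acosh = np.where(small, acosh_small, acosh_large)
    rex = 0.5 * (k_ex - acosh / tau)
    return np.where(degenerate, r2_0 + np.zeros_like(rex), r2_0 + rex)


def luz_meiboom_r2eff(p: DispersionParams, nu_cpmg):
    """Fast-exchange (k_ex >> dw) closed form, for cross-validation only."""
    nu = np.asarray(nu_cpmg, dtype=float)
    p_B = 1.0 - p.p_A
    phi = p.p_A * p_B * p.delta_omega**2
    out = p.r2_0 + (phi / p.k_ex) * (
        1.0 - (4.0 * nu / p.k_ex) * np.tanh(p.k_ex / (4.0 * nu))
    )
    return out if out.ndim else float(out)


def bloch_mcconnell_r2eff(p: DispersionParams, nu_cpmg: float,
                          n_cycles: int = 16) -> float:
    """R2eff from numerical propagation of the two-state Bloch-McConnell
    equations through an ideal-pulse CPMG echo train.

    Transverse magnetization of the two sites evolves under free
    precession + exchange (complex 2x2 generator built from k_AB, k_BA,
    the shift difference and the shared intrinsic R2); each ideal
    180-degree pulse conjugates the magnetization.  One echo unit is
    ``tau/2 - pulse - tau/2`` with ``tau = 1/(2 nu_cpmg)``.  Starting
    from equilibrium ``(p_A, p_B)``, the train is propagated for
    ``2 n_cycles`` and ``4 n_cycles`` echoes and the effective rate is
    taken from the magnetization ratio between the two train lengths,
    which removes the initial transient:

        R2eff = -ln( |M(2 T_n)| / |M(T_n)| ) / T_n,   T_n = 2 n_cycles tau.
    """
    p_B = 1.0 - p.p_A
    if p.p_A >= 1.0:
        return p.r2_0
    k_AB = p.k_ex * p_B
    k_BA = p.k_ex * p.p_A
    tau = 1.0 / (2.0 * nu_cpmg)
    # site A on resonance, site B at +dw; equal R2 for both states
    L = np.array(
        [
            [-p.r2_0 - k_AB, k_BA],
            [k_AB, -p.r2_0 - k_BA + 1j * p.delta_omega],
        ],
        dtype=complex,
    )
    U = expm(L * (tau / 2.0))
    M = np.array([p.p_A, p_B], dtype=complex)
    m_half = None
    for cycle in range(2 * n_cycles):
        for _ in range(2):  # two echo units per cycle
            M = U @ M
            M = np.conj(M)  # ideal 180-degree pulse
            M = U @ M
        if cycle + 1 == n_cycles:
            m_half = abs(M.sum())
    T_n = n_cycles * 2.0 * tau
    ratio = abs(M.sum()) / max(m_half, 1e-300)
    return -math.log(max(ratio, 1e-300)) / T_n


# ---------------------------------------------------------------------------
# CPMG grid search + fit

@dataclass(frozen=True)
class GridSpec:
    """Search grid for CPMG dispersion starting values."""

    k_ex: tuple[float, float, int] = (10.0, 1.0e4, 13)     # log-spaced
    p_A: tuple[float, float, int] = (0.70, 0.99, 8)        # linear
    delta_omega: tuple[float, float, int] = (100.0, 6000.0, 12)  # linear, rad/s

    def nodes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        kex = np.logspace(math.log10(self.k_ex[0]), math.log10(self.k_ex[1]),
                          self.k_ex[2])
        pa = np.linspace(*self.p_A)
        dw = np.linspace(*self.delta_omega)
        return kex, pa, dw


_GRID_CACHE: dict = {}


def _grid_rex(grid: GridSpec, nu: np.ndarray) -> tuple[np.ndarray, ...]:
    """Exchange contribution (r2_0 = 0) on all grid nodes x fields, cached.

    The grid response is data independent — r2_0 only shifts it by a
    constant — so repeated searches over the same fields reuse it.
    """
    key = (grid, nu.tobytes())
    if key not in _GRID_CACHE:
        kex, pa, dw = grid.nodes()
        rex = _cr_r2eff(
            0.0,
            kex[:, None, None, None],
            pa[None, :, None, None],
            dw[None, None, :, None],
            nu[None, None, None, :],
        )
        if len(_GRID_CACHE) > 32:
            _GRID_CACHE.clear()
        _GRID_CACHE[key] = (kex, pa, dw, rex)
    return _GRID_CACHE[key]


def grid_search_cpmg(series: IntensitySeries, grid: GridSpec | None = None) -> DispersionParams:
    """Best Carver-Richards starting point over an exhaustive grid.

    ``series`` must already be in R2eff units.  At each (k_ex, p_A, dw)
    node ``r2_0`` is pinned to the minimum observed R2eff; ties break to
    the first node in iteration order (k_ex outer, then p_A, then dw).
    """
    if series.n < 5:
        raise ValueError("grid search needs at least 5 CPMG fields")
    grid = grid or GridSpec()
    nu = series.x
    r2_obs = series.I
    r2_min = float(r2_obs.min())
    kex, pa, dw, rex = _grid_rex(grid, nu)
    rss = np.sum((r2_min + rex - r2_obs) ** 2, axis=-1)
    i, j, k = np.unravel_index(int(np.argmin(rss)), rss.shape)
    return DispersionParams(r2_0=max(r2_min, 0.0), k_ex=float(kex[i]),
                            p_A=float(pa[j]), delta_omega=float(dw[k]))


class CpmgDispersionModel:
    """Carver-Richards fit of a CPMG dispersion profile.

    Accepts the series either in R2eff units directly, or as intensities
    plus ``T_relax`` and a reference intensity ``I0`` for the standard
    constant-time conversion.
    """

    param_names = ("r2_0", "k_ex", "p_A", "delta_omega")

    def __init__(self, series: IntensitySeries, T_relax: float | None = None,
                 I0: float | None = None, grid: GridSpec | None = None):
        if series.kind is not SeriesKind.CPMG_FIELD:
            raise ValueError("CPMG fit requires a cpmg_field series")
        if I0 is not None:
            if T_relax is None:
                raise ValueError("intensity-space CPMG input requires T_relax")
            r2 = intensities_to_r2eff(series.I, I0, T_relax)
            series = IntensitySeries(series.x, r2, None, SeriesKind.CPMG_FIELD,
                                     series.assignment)
        if np.unique(series.x).size < len(self.param_names) + 1:
            raise ValueError("CPMG fit needs at least 5 distinct fields")
        self.series = series
        self.grid = grid

    def fit(self, start: DispersionParams | None = None) -> ModelFit:
        s = self.series
        if start is None:
            start = grid_search_cpmg(s, self.grid)
        lo = np.array([0.0, 1e-3, 0.5, 0.0])
        hi = np.array([np.inf, 1e7, 1.0, np.inf])

        def resid(p):
            return _cr_r2eff(p[0], p[1], p[2], p[3], s.x) - s.I

        # two starts: the requested/grid point, and the exchange-free corner
        # (dw = 0, r2_0 = mean) whose residual equals the flat model's — the
        # refit can then never end above the nested flat solution
        starts = [
            np.clip([start.r2_0, start.k_ex, start.p_A, start.delta_omega],
                    lo, [1e6, 1e6, 1.0 - 1e-6, 1e6]),
            np.array([max(float(s.I.mean()), 0.0), 1000.0, 0.95, 0.0]),
        ]
        res = None
        for p0 in starts:
            cand = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if res is None or cand.cost < res.cost:
                res = cand
        se = _covariance_errors(res, s.n)
        params = dict(zip(self.param_names, (float(v) for v in res.x)))
        errors = dict(zip(self.param_names, (float(v) for v in se)))
        p_fit = res.x.copy()
        return ModelFit(
            "carver_richards", params, errors, float(2.0 * res.cost), s.n, 4,
            converged=res.status > 0,
            predict=lambda nu: _cr_r2eff(p_fit[0], p_fit[1], p_fit[2], p_fit[3],
                                         np.asarray(nu, float)),
        )


# ---------------------------------------------------------------------------
# model selection

def f_test_exchange(fit_flat: ModelFit, fit_exchange: ModelFit,
                    alpha: float = 0.01) -> tuple[float, float, bool]:
    """Partial F-test of the exchange model against the flat null.

    Returns ``(F, p, significant)``; models must be fitted to the same
    data and nested (flat 1 parameter inside the 4-parameter dispersion
    model — any nested pair with n_params strictly increasing is
    accepted).
    """
    if fit_flat.n_obs != fit_exchange.n_obs:
        raise ValueError("F-test requires fits to the same data")
    if fit_exchange.n_params <= fit_flat.n_params:
        raise ValueError("models are not nested (exchange must add parameters)")
    df1 = fit_flat.df_resid
    df2 = fit_exchange.df_resid
    if df2 <= 0:
        raise ValueError("exchange model leaves no residual degrees of freedom")
    if fit_exchange.rss <= 0.0:
        warnings.warn("degenerate fit: exchange model has zero residual", stacklevel=2)
        return float("inf"), 0.0, True
    F = ((fit_flat.rss - fit_exchange.rss) / (df1 - df2)) / (fit_exchange.rss / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1 - df2, df2))
    return float(F), p, p < alpha


# ---------------------------------------------------------------------------
# functional wrappers

def fit_linear(series: IntensitySeries, through_origin: bool = False) -> ModelFit:
    return LinearModel(series, through_origin=through_origin).fit()


def fit_exponential(series: IntensitySeries, offset: bool = False,
                    start=None) -> ModelFit:
    return ExponentialModel(series, offset=offset).fit(start=start)


def fit_recovery(series: IntensitySeries, mode: str = "saturation",
                 start=None) -> ModelFit:
    return RecoveryModel(series, mode=mode).fit(start=start)


def fit_flat(series: IntensitySeries) -> ModelFit:
    return FlatModel(series).fit()


def fit_cpmg(series: IntensitySeries, T_relax: float | None = None,
             I0: float | None = None, start: DispersionParams | None = None,
             grid: GridSpec | None = None) -> ModelFit:
    return CpmgDispersionModel(series, T_relax=T_relax, I0=I0, grid=grid).fit(start=start)
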