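"""Classical stress-relaxation models and their least-squares calibration.

Two constitutive laws are provided for the relaxation stress of a
near-incompressible spherical specimen held at constant strain ``eps0``:

* the triple-element (generalized) Maxwell model — two Maxwell elements in
  parallel with an equilibrium spring,

  ``sigma(t) = [E1*exp(-t/T1) + E2*exp(-t/T2) + E0] * eps0``

* the Caputo fractional-derivative model — a single power-law viscous
  element of fractional order ``alpha`` in (0, 1),

  ``sigma(t) = chi_alpha / Gamma(1 - alpha) * t**(-alpha) * eps0``

Both are linear in the initial strain and strictly decreasing in time for
positive parameters.  Calibration minimises the pooled sum of squared stress
residuals over one or more relaxation curves, each carrying its own initial
strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

__all__ = [
    "MaxwellParams",
    "CaputoParams",
    "FitDiagnostics",
    "FitError",
    "maxwell_stress",
    "caputo_stress",
    "fit_maxwell",
    "fit_caputo",
    "parameter_table",
]


class FitError(RuntimeError):
    """Raised when a calibration fails to converge; carries the best-so-far fit."""

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class MaxwellParams:
    """Triple-element Maxwell parameters.

    E0 is the equilibrium modulus (MPa), E1/E2 the decay elastic moduli
    (MPa) and T1/T2 the relaxation times (s).  The canonical labelling is
    T1 < T2 (fast element first); ``canonical()`` reorders if needed.
    """

    E0: float
    E1: float
    E2: float
    T1: float
    T2: float

    n_params = 5

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"Maxwell parameter {f.name} must be finite and > 0, got {v!r}")

    def canonical(self) -> "MaxwellParams":
        if self.T1 <= self.T2:
            return self
        return MaxwellParams(self.E0, self.E2, self.E1, self.T2, self.T1)

    def as_array(self) -> np.ndarray:
        return np.array([self.E0, self.E1, self.E2, self.T1, self.T2])

    def scale_moduli(self, factor: float) -> "MaxwellParams":
        """Return a copy with all elastic moduli multiplied by ``factor``."""
        return MaxwellParams(self.E0 * factor, self.E1 * factor, self.E2 * factor, self.T1, self.T2)


@dataclass(frozen=True)
class CaputoParams:
    """Caputo fractional-derivative parameters.

    chi_alpha is the relaxation modulus (MPa); alpha the fractional order,
    strictly inside (0, 1).
    """

    chi_alpha: float
    alpha: float

    n_params = 2

    def __post_init__(self):
        if not (np.isfinite(self.chi_alpha) and self.chi_alpha > 0):
            raise ValueError(f"chi_alpha must be finite and > 0, got {self.chi_alpha!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.chi_alpha, self.alpha])

    def scale_moduli(self, factor: float) -> "CaputoParams":
        return CaputoParams(self.chi_alpha * factor, self.alpha)


@dataclass
class FitDiagnostics:
    """Convergence record for a least-squares calibration."""

    cost: float
    rmse: float
    converged: bool
    n_points: int
    n_starts: int
    message: str = ""


def maxwell_stress(params: MaxwellParams, t, strain0: float):
    """Relaxation stress (MPa) of the triple-element Maxwell model at time t (s) >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("Maxwell model requires t >= 0")
    return (params.E1 * np.exp(-t / params.T1) + params.E2 * np.exp(-t / params.T2) + params.E0) * strain0


def caputo_stress(params: CaputoParams, t, strain0: float):
    """Relaxation stress (MPa) of the Caputo fractional model at time t (s) > 0.

    The power law t**(-alpha) is singular at t = 0, so strictly positive
    times are required.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("Caputo model requires t > 0 (power law is singular at 0)")
    return params.chi_alpha / gamma_fn(1.0 - params.alpha) * t ** (-params.alpha) * strain0


# --- calibration -----------------------------------------------------------

def _pool(curves) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate (t, sigma, eps0-per-point) over a sequence of relaxation curves."""
    ts, sigmas, eps = [], [], []
    for c in curves:
        t = np.asarray(c.times, dtype=float)
        s = np.asarray(c.stress, dtype=float)
        ts.append(t)
        sigmas.append(s)
        eps.append(np.full_like(t, float(c.strain0)))
    return np.concatenate(ts), np.concatenate(sigmas), np.concatenate(eps)


def _maxwell_init(t: np.ndarray, s_unit: np.ndarray) -> np.ndarray:
    """Heuristic start for the Maxwell fit from a pooled strain-normalized curve.

    E0 from the tail mean, then log-linear fits of the positive residual over
    a late window (slow element) and an early window (fast element).
    """
    tmax = float(t.max())
    tail = t >= 0.8 * tmax
    E0 = max(float(s_unit[tail].mean()), 1e-6)
    resid = np.clip(s_unit - E0, 1e-12, None)

    def loglin(mask, fallback_E, fallback_T):
        if mask.sum() < 3:
            return fallback_E, fallback_T
        A = np.vstack([np.ones(mask.sum()), t[mask]]).T
        coef, *_ = np.linalg.lstsq(A, np.log(resid[mask]), rcond=None)
        b, m = coef
        if m >= -1e-12:
            return fallback_E, fallback_T
        return max(math.exp(b), 1e-6), min(-1.0 / m, 10.0 * tmax)

    E2, T2 = loglin((t > 0.1 * tmax) & (t < 0.6 * tmax), 0.5 * E0, tmax / 6.0)
    resid2 = np.clip(resid - E2 * np.exp(-t / max(T2, 1e-6)), 1e-12, None)

    def loglin_fast(mask, fallback_E, fallback_T):
        if mask.sum() < 3:
            return fallback_E, fallback_T
        A = np.vstack([np.ones(mask.sum()), t[mask]]).T
        coef, *_ = np.linalg.lstsq(A, np.log(resid2[mask]), rcond=None)
        b, m = coef
        if m >= -1e-12:
            return fallback_E, fallback_T
        return max(math.exp(b), 1e-6), min(-1.0 / m, 10.0 * tmax)

    E1, T1 = loglin_fast(t < 0.05 * tmax, 0.3 * E0, 0.02 * tmax)
    return np.array([E0, E1, E2, T1, T2])


def fit_maxwell(curves: Iterable, n_starts: int = 5, seed: int = 0) -> tuple[MaxwellParams, FitDiagnostics]:
    """Calibrate the triple-element Maxwell model to pooled relaxation curves.

    Minimises sum over all supplied curves of (sigma_obs - sigma_model)^2,
    each curve entering with its own initial strain.  A data-driven start is
    refined by trust-region least squares; jittered restarts guard against
    poor local minima.  Returned parameters follow the canonical T1 < T2
    ordering.
    """
    curves = list(curves)
    t, sigma, eps = _pool(curves)
    if len(np.unique(t)) < 5:
        raise ValueError("fit_maxwell needs at least 5 distinct pooled time points")
    tmax = float(t.max())

    def residuals(x):
        E0, E1, E2, T1, T2 = x
        model = (E1 * np.exp(-t / T1) + E2 * np.exp(-t / T2) + E0) * eps
        return model - sigma

    lb = np.full(5, 1e-8)
    ub = np.array([np.inf, np.inf, np.inf, 10.0 * tmax, 10.0 * tmax])
    x0 = np.clip(_maxwell_init(t, sigma / eps), lb, ub)

    rng = np.random.default_rng(seed)
    best = None
    tried = 0
    for k in range(max(1, n_starts)):
        start = x0 if k == 0 else np.clip(x0 * rng.lognormal(0.0, 0.5, size=5), lb, ub)
        try:
            sol = least_squares(residuals, start, bounds=(lb, ub), method="trf", x_scale="jac")
        except Exception:  # pragma: no cover - defensive
            continue
        tried += 1
        if best is None or sol.cost < best.cost:
            best = sol
        if best.success and best.cost < 1e-18:
            break
    if best is None:
        raise FitError("Maxwell calibration failed on every start")

    params = MaxwellParams(*np.maximum(best.x, 1e-12)).canonical()
    diag = FitDiagnostics(
        cost=float(best.cost),
        rmse=float(np.sqrt(np.mean(best.fun**2))),
        converged=bool(best.success),
        n_points=t.size,
        n_starts=tried,
        message=best.message,
    )
    if not best.success:
        raise FitError("Maxwell calibration did not converge", params, diag)
    return params, diag


def fit_caputo(curves: Iterable, n_starts: int = 5, seed: int = 0) -> tuple[CaputoParams, FitDiagnostics]:
    """Calibrate the Caputo fractional model to pooled relaxation curves.

    Initialised from the log–log regression of strain-normalized stress on
    time (the power-law slope is -alpha); alpha is constrained to (0, 1).
    """
    curves = list(curves)
    t, sigma, eps = _pool(curves)
    if len(np.unique(t)) < 5:
        raise ValueError("fit_caputo needs at least 5 distinct pooled time points")

    s_unit = sigma / eps
    A = np.vstack([np.ones_like(t), np.log(t)]).T
    coef, *_ = np.linalg.lstsq(A, np.log(np.clip(s_unit, 1e-300, None)), rcond=None)
    alpha0 = float(np.clip(-coef[1], 1e-4, 1.0 - 1e-4))
    chi0 = max(float(np.exp(coef[0])) * gamma_fn(1.0 - alpha0), 1e-8)

    def residuals(x):
        chi, alpha = x
        model = chi / gamma_fn(1.0 - alpha) * t ** (-alpha) * eps
        return model - sigma

    lb = np.array([1e-8, 1e-4])
    ub = np.array([np.inf, 1.0 - 1e-4])
    x0 = np.clip([chi0, alpha0], lb, ub)

    rng = np.random.default_rng(seed)
    best = None
    tried = 0
    for k in range(max(1, n_starts)):
        start = x0 if k == 0 else np.clip([chi0 * rng.lognormal(0, 0.5), rng.uniform(0.02, 0.9)], lb, ub)
        sol = least_squares(residuals, start, bounds=(lb, ub), method="trf", x_scale="jac")
        tried += 1
        if best is None or sol.cost < best.cost:
            best = sol
        if best.success and best.cost < 1e-18:
            break

    params = CaputoParams(float(max(best.x[0], 1e-12)), float(np.clip(best.x[1], 1e-6, 1 - 1e-6)))
    diag = FitDiagnostics(
        cost=float(best.cost),
        rmse=float(np.sqrt(np.mean(best.fun**2))),
        converged=bool(best.success),
        n_points=t.size,
        n_starts=tried,
        message=best.message,
    )
    if not best.success:
        raise FitError("Caputo calibration did not converge", params, diag)
    return params, diag


def parameter_table(fits: Sequence) -> pd.DataFrame:
    """Mean ± sample-SD summary of per-fruit parameter fits.

    Accepts a sequence (length >= 2) of MaxwellParams or CaputoParams and
    returns a DataFrame with one row per parameter and columns
    ``mean``/``sd``, mirroring the usual reporting layout for relaxation
    constants.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("parameter_table needs at least 2 fits to form a standard deviation")
    kinds = {type(f) for f in fits}
    if len(kinds) != 1:
        raise ValueError("parameter_table requires fits of a single model family")
    names = [f.name for f in fields(fits[0])]
    arr = np.array([[getattr(f, n) for n in names] for f in fits], dtype=float)
    return pd.DataFrame({"mean": arr.mean(axis=0), "sd": arr.std(axis=0, ddof=1)}, index=names)
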