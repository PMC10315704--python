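"""Perfusion-weighted MRI parameters.

Two acquisitions feed three lesion parameters:

* DSC (dynamic susceptibility contrast): the first-pass gadolinium bolus
  darkens T2*-weighted images; ``dsc_delta_r2star`` converts the signal
  drop to a transverse relaxation-rate change and ``rcbv_ratio`` forms
  the relative cerebral blood volume as the lesion-to-reference ratio of
  trapezoid-integrated bolus areas.
* DCE (dynamic contrast-enhanced): tissue gadolinium concentration is
  modeled with the standard two-parameter Tofts compartment model,

      dCt/dt = Ktrans * Cp(t) - (Ktrans / ve) * Ct(t),

  whose solution is the convolution
  ``Ct(t) = Ktrans * int_0^t Cp(u) exp(-(Ktrans/ve)(t-u)) du``.
  ``ToftsModel`` / ``tofts_fit`` estimate ``Ktrans`` (1/min) and the
  extravascular extracellular volume fraction ``ve`` by bounded
  nonlinear least squares with a fixed multi-start grid.

No plasma-volume term and no DSC leakage correction are applied (known
limitation of the simple models used here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "AifModel",
    "BiexponentialAif",
    "PerfusionMetrics",
    "dsc_delta_r2star",
    "rcbv_ratio",
    "tofts_forward",
    "tofts_fit",
    "ToftsModel",
]

# Bounds and multi-start grid for the Tofts fit, fixed for reproducibility.
KTRANS_BOUNDS = (0.0, 5.0)  # 1/min
VE_BOUNDS = (1e-6, 1.0)
TOFTS_STARTS = ((0.1, 0.2), (0.5, 0.5), (1.0, 0.3), (0.05, 0.8))
TOFTS_TOL = 1e-8


@dataclass
class PerfusionMetrics:
    """The three perfusion parameters for one lesion."""

    rcbv: float  # dimensionless lesion/reference blood-volume ratio
    ktrans: float  # 1/min
    ve: float  # fraction in (0, 1]

    def to_dict(self) -> dict[str, float]:
        return {"rcbv": self.rcbv, "ktrans": self.ktrans, "ve": self.ve}


class AifModel:
    """Arterial input function: plasma contrast concentration over time.

    Subclasses implement :meth:`plasma_concentration`; those with an
    analytic exponential convolution (needed by the Tofts solution) may
    override :meth:`exp_convolution`, otherwise a fine-grid exponential
    integrator is used.
    """

    arrival_s: float = 0.0

    def plasma_concentration(self, times_min: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def exp_convolution(self, kep_per_min: float, times_min: np.ndarray) -> np.ndarray:
        """``int_0^t Cp(u) exp(-kep (t - u)) du`` evaluated at ``times_min``."""
        return _numeric_exp_convolution(
            self.plasma_concentration, kep_per_min, np.asarray(times_min, dtype=float)
        )


@dataclass
class BiexponentialAif(AifModel):
    """Population biexponential AIF, ``Cp(t) = D (a1 e^{-m1 t} + a2 e^{-m2 t})``
    for ``t`` past bolus arrival (classic two-compartment plasma clearance).

    Defaults are the standard population values for a 0.1 mmol/kg bolus:
    amplitudes in kg/L so that ``Cp`` is in mmol/L, rates in 1/min.
    """

    dose_mmol_kg: float = 0.1
    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    arrival_s: float = 0.0

    def plasma_concentration(self, times_min: np.ndarray) -> np.ndarray:
        t = np.asarray(times_min, dtype=float) - self.arrival_s / 60.0
        cp = self.dose_mmol_kg * (
            self.a1 * np.exp(-self.m1 * np.maximum(t, 0.0))
            + self.a2 * np.exp(-self.m2 * np.maximum(t, 0.0))
        )
        return np.where(t < 0, 0.0, cp)

    def exp_convolution(self, kep_per_min: float, times_min: np.ndarray) -> np.ndarray:
        t = np.asarray(times_min, dtype=float) - self.arrival_s / 60.0
        tau = np.maximum(t, 0.0)
        out = np.zeros_like(tau)
        for a, m in ((self.a1, self.m1), (self.a2, self.m2)):
            if np.isclose(kep_per_min, m, rtol=1e-10, atol=1e-12):
                out += a * tau * np.exp(-m * tau)
            else:
                out += (
                    a
                    * (np.exp(-m * tau) - np.exp(-kep_per_min * tau))
                    / (kep_per_min - m)
                )
        return np.where(t < 0, 0.0, self.dose_mmol_kg * out)


def _numeric_exp_convolution(
    cp: Callable[[np.ndarray], np.ndarray],
    kep: float,
    times_min: np.ndarray,
    dt_min: float = 0.002,
) -> np.ndarray:
    """Exponential-kernel convolution on a fine internal grid.

    Uses the exact decay factor per step with trapezoidal quadrature of the
    source term, so stiffness from large ``kep`` does not degrade accuracy.
    """
    t_max = float(np.max(times_min)) if times_min.size else 0.0
    if t_max <= 0:
        return np.zeros_like(times_min)
    n = int(np.ceil(t_max / dt_min)) + 1
    grid = np.linspace(0.0, t_max, n)
    dt = grid[1] - grid[0]
    cp_vals = np.asarray(cp(grid), dtype=float)
    decay = np.exp(-kep * dt)
    y = np.zeros(n)
    for i in range(1, n):
        y[i] = y[i - 1] * decay + dt * 0.5 * (cp_vals[i - 1] * decay + cp_vals[i])
    return np.interp(times_min, grid, y)


def dsc_delta_r2star(
    signal: np.ndarray,
    baseline_frames: int,
    echo_time_s: float,
) -> np.ndarray:
    """Transverse relaxation-rate change from a DSC signal curve.

    ``dR2*(t) = -ln(S(t)/S0) / TE`` with the baseline ``S0`` taken as the
    mean of the first ``baseline_frames`` pre-bolus samples.
    """
    signal = np.asarray(signal, dtype=float)
    if echo_time_s <= 0:
        raise ValueError("echo time must be positive")
    if baseline_frames < 1 or baseline_frames > signal.size:
        raise ValueError("baseline window must cover >= 1 sample within the curve")
    if np.any(signal <= 0):
        raise ValueError("signal must be strictly positive")
    s0 = signal[:baseline_frames].mean()
    return -np.log(signal / s0) / echo_time_s


def rcbv_ratio(
    lesion_dr2: np.ndarray,
    reference_dr2: np.ndarray,
    times_s: np.ndarray,
    window: tuple[float, float] | None = None,
) -> float:
    """Relative cerebral blood volume: ratio of trapezoid-integrated bolus
    areas, lesion over contralateral reference, on a common time base."""
    lesion_dr2 = np.asarray(lesion_dr2, dtype=float)
    reference_dr2 = np.asarray(reference_dr2, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if not (lesion_dr2.shape == reference_dr2.shape == times_s.shape):
        raise ValueError("lesion, reference and time arrays must share one shape")
    if window is not None:
        mask = (times_s >= window[0]) & (times_s <= window[1])
        lesion_dr2, reference_dr2, times_s = (
            lesion_dr2[mask],
            reference_dr2[mask],
            times_s[mask],
        )
    ref_area = np.trapezoid(reference_dr2, times_s)
    if ref_area <= 0:
        raise ValueError("reference bolus area must be positive")
    return float(np.trapezoid(lesion_dr2, times_s) / ref_area)


def tofts_forward(
    ktrans_per_min: float,
    ve: float,
    aif: AifModel,
    times_s: np.ndarray,
) -> np.ndarray:
    """Tissue concentration predicted by the two-parameter Tofts model.

    ``Ct(t) = Ktrans * int_0^t Cp(u) exp(-(Ktrans/ve)(t-u)) du``; limits:
    zero everywhere for ``Ktrans = 0`` and ``Ct -> ve * c`` for a constant
    plasma level ``c``.
    """
    if ktrans_per_min < 0:
        raise ValueError("ktrans must be non-negative")
    if not (0 < ve <= 1):
        raise ValueError("ve must lie in (0, 1]")
    times_min = np.asarray(times_s, dtype=float) / 60.0
    if ktrans_per_min == 0:
        return np.zeros_like(times_min)
    kep = ktrans_per_min / ve
    return ktrans_per_min * aif.exp_convolution(kep, times_min)


class ToftsModel(BaseEstimator, RegressorMixin):
    """Two-parameter Tofts estimator for DCE concentration curves.

    Fits ``Ktrans`` and ``ve`` by bounded nonlinear least squares against
    :func:`tofts_forward`, restarting from a fixed grid of initial values
    and keeping the lowest-residual solution.

    Parameters
    ----------
    aif:
        Arterial input function; defaults to the population biexponential.

    Attributes
    ----------
    ktrans_ : float
        Volume transfer constant, 1/min.
    ve_ : float
        Extravascular extracellular volume fraction.
    residual_norm_ : float
        2-norm of the residual at the solution.
    converged_ : bool
        False when no restart converged (best candidate still returned).
    """

    def __init__(self, aif: AifModel | None = None):
        self.aif = aif

    def fit(self, X, y=None):
        """Fit to a sampled concentration curve.

        ``X`` is the sample-time vector in seconds (1-D or column), ``y``
        the measured tissue concentration at those times.
        """
        times_s = np.asarray(X, dtype=float).reshape(-1)
        ct = np.asarray(y, dtype=float).reshape(-1)
        if times_s.size != ct.size:
            raise ValueError("times and concentrations must have equal length")
        if times_s.size < 10:
            raise ValueError("need at least 10 samples for a stable Tofts fit")
        aif = self.aif if self.aif is not None else BiexponentialAif()

        if np.allclose(ct, 0.0):
            # No enhancement: transfer constant is zero, ve unidentifiable.
            self.ktrans_, self.ve_ = 0.0, float("nan")
            self.residual_norm_ = 0.0
            self.converged_ = True
            self.n_starts_used_ = 0
            return self

        def residual(theta):
            return tofts_forward(theta[0], theta[1], aif, times_s) - ct

        lb = np.array([KTRANS_BOUNDS[0], VE_BOUNDS[0]])
        ub = np.array([KTRANS_BOUNDS[1], VE_BOUNDS[1]])
        best = None
        any_converged = False
        for start in TOFTS_STARTS:
            sol = least_squares(
                residual,
                np.asarray(start, dtype=float),
                bounds=(lb, ub),
                xtol=TOFTS_TOL,
                ftol=TOFTS_TOL,
                gtol=TOFTS_TOL,
            )
            any_converged = any_converged or sol.success
            if best is None or sol.cost < best.cost:
                best = sol
        self.ktrans_ = float(best.x[0])
        self.ve_ = float(best.x[1])
        self.residual_norm_ = float(np.sqrt(2.0 * best.cost))
        self.converged_ = bool(any_converged)
        self.n_starts_used_ = len(TOFTS_STARTS)
        return self

    def predict(self, X):
        """Model concentration at sample times ``X`` (seconds)."""
        times_s = np.asarray(X, dtype=float).reshape(-1)
        aif = self.aif if self.aif is not None else BiexponentialAif()
        if np.isnan(self.ve_):
            return np.zeros_like(times_s)
        return tofts_forward(self.ktrans_, self.ve_, aif, times_s)


def tofts_fit(
    ct: np.ndarray,
    aif: AifModel,
    times_s: np.ndarray,
) -> tuple[float, float, dict]:
    """Functional wrapper over :class:`ToftsModel`.

    Returns ``(ktrans, ve, diagnostics)`` with the residual norm and
    convergence flag in ``diagnostics``.
    """
    model = ToftsModel(aif=aif).fit(times_s, ct)
    diagnostics = {
        "residual_norm": model.residual_norm_,
        "converged": model.converged_,
        "n_starts": model.n_starts_used_,
    }
    return model.ktrans_, model.ve_, diagnostics
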