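"""Time-continuous data and uncertainty representations.

The variational objective replaces the discrete measurements of each
component by a differentiable data prior S(t) — here a cubic smoothing
spline — together with a variance course Sσ²(t), equivalently a weight
w(t) = 1/Sσ²(t).  Two uncertainty modes are provided:

* interpolated σ course from the reported per-point uncertainties
  (appropriate for dense sampling), and
* a sum-of-Gaussians weight concentrated around the measurement times with
  correlation length τ, which lets the prior lose confidence between sparse
  measurement points:

      w_τ(t) = Σ_i (2πτ²)^{-1/2} exp(-(t-t_i)²/(2τ²)) / σ_i².

Small τ permits interstitial variability (good for input reconstruction);
larger τ propagates the measured uncertainty more broadly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

__all__ = [
    "ContinuousRepresentation",
    "WeightFunction",
    "fit_spline_prior",
    "gaussian_sum_weight",
    "constant_prior",
]


@dataclass
class ContinuousRepresentation:
    """A differentiable data prior S(t) with variance course Sσ²(t) on [0,T]."""

    S: Callable[[np.ndarray], np.ndarray]
    dS: Callable[[np.ndarray], np.ndarray]
    sigma2: Callable[[np.ndarray], np.ndarray]
    domain: tuple

    def weight(self, t):
        return 1.0 / self.sigma2(t)


@dataclass
class WeightFunction:
    """Sum-of-Gaussians weight w(t) with correlation length tau (time units).

    ``anchors`` are the measurement times with their uncertainties; w decays
    to zero away from all anchors, so the implied variance 1/w grows without
    bound there (capped when converted to a variance course).
    """

    w: Callable[[np.ndarray], np.ndarray]
    tau: float
    anchors: tuple  # (times, sigmas)

    def __call__(self, t):
        return self.w(t)


def _clamped(fn, lo, hi):
    def wrapped(t):
        return fn(np.clip(np.asarray(t, dtype=float), lo, hi))
    return wrapped


def _clamped_deriv(fn_d, lo, hi):
    # derivative of a constant-extrapolated function: 0 outside [lo, hi]
    def wrapped(t):
        t = np.asarray(t, dtype=float)
        inside = (t >= lo) & (t <= hi)
        out = np.where(inside, fn_d(np.clip(t, lo, hi)), 0.0)
        return out
    return wrapped


def fit_spline_prior(times, values, smoothing: Optional[float] = None,
                     sigmas=None, domain: Optional[tuple] = None,
                     weight: Optional[WeightFunction] = None,
                     var_cap: float = 1e6) -> ContinuousRepresentation:
    """Cubic smoothing-spline data prior through (times, values).

    ``smoothing`` is the spline penalty: ``None`` selects it by generalized
    cross-validation, ``0`` gives the interpolating limit.  Outside the data
    range the prior continues constantly at the boundary values.

    The variance course comes from ``weight`` (sum-of-Gaussians mode,
    Sσ² = min(1/w, var_cap)) when given, otherwise from linear interpolation
    of the per-point ``sigmas`` (squared); if neither is supplied the
    variance course is unit.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times)
    times, values = times[order], values[order]
    if sigmas is not None:
        sigmas = np.asarray(sigmas, dtype=float)[order]
    if len(np.unique(times)) < 2:
        raise ValueError(
            "need at least 2 distinct time points for a spline prior; "
            "use constant_prior for a single value")

    npts = len(times)
    if smoothing == 0 or npts < 5:
        # interpolating spline (GCV needs >= 5 points)
        k = min(3, npts - 1)
        spl = make_interp_spline(times, values, k=k)
    else:
        spl = make_smoothing_spline(times, values, lam=smoothing)
    dspl = spl.derivative()

    lo, hi = float(times[0]), float(times[-1])
    S = _clamped(spl, lo, hi)
    dS = _clamped_deriv(dspl, lo, hi)

    if weight is not None:
        def sigma2(t):
            return np.minimum(1.0 / weight.w(t), var_cap)
    elif sigmas is not None:
        def sigma2(t, _t=times, _s2=sigmas ** 2):
            return np.interp(np.asarray(t, dtype=float), _t, _s2)
    else:
        def sigma2(t):
            return np.ones_like(np.asarray(t, dtype=float))

    dom = domain if domain is not None else (min(lo, 0.0), hi)
    return ContinuousRepresentation(S=S, dS=dS, sigma2=sigma2, domain=dom)


def gaussian_sum_weight(times, sigmas, tau: float) -> WeightFunction:
    """Weight course from Gaussian kernels at the measurement points.

    w(t) = Σ_i (2πτ²)^{-1/2} exp(-(t-t_i)²/(2τ²)) / σ_i²; the implied
    variance course is Sσ²(t) = 1/w(t).  For a single anchor the integral of
    w over the real line equals 1/σ².
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    times = np.asarray(times, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if times.shape != sigmas.shape:
        raise ValueError("times and sigmas must have equal length")
    if np.any(sigmas <= 0):
        raise ValueError("all sigmas must be positive")

    norm = 1.0 / np.sqrt(2.0 * np.pi * tau ** 2)
    inv_s2 = 1.0 / sigmas ** 2

    def w(t):
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - times) / tau
        return norm * np.sum(np.exp(-0.5 * z ** 2) * inv_s2, axis=-1)

    return WeightFunction(w=w, tau=float(tau), anchors=(times, sigmas))


def constant_prior(value: float, sigma: float, T: float) -> ContinuousRepresentation:
    """Constant data prior S ≡ value with constant variance sigma² on [0, T].

    With value 0 this is the flat prior used for the relaxation-rate inputs
    of the positivity extension: it penalizes the first derivative of the
    promoted input without pulling it toward any particular course.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    v, s2 = float(value), float(sigma) ** 2

    def S(t):
        return np.full_like(np.asarray(t, dtype=float), v)

    def dS(t):
        return np.zeros_like(np.asarray(t, dtype=float))

    def sigma2(t):
        return np.full_like(np.asarray(t, dtype=float), s2)

    return ContinuousRepresentation(S=S, dS=dS, sigma2=sigma2, domain=(0.0, T))
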