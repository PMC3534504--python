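"""Parameter estimation and profile-likelihood confidence intervals.

Two estimators share the same outer optimiser and differ in how model
predictions are produced:

* **variational** — at each iterate (p, y0) the augmented boundary-value
  problem is solved, so the predicted species courses are already optimal
  with respect to the unknown input; the discrete χ² includes both species
  residuals and residuals of the reconstructed input at the input
  measurement times.
* **fixed input** — the input course is frozen (typically at the spline
  prior through the input data) and predictions come from a plain forward
  solve; only species residuals enter the χ², since the input is not a
  model output.  This is the conventional baseline that ignores input
  uncertainty.

The outer optimiser is Gauss-Newton with Levenberg damping on
θ = (log p, y0): rates are positive and are estimated on log scale, initial
values on natural scale.  Profile-likelihood confidence intervals scan one
θ component while re-optimising the rest and threshold the χ² increase at
the 1-dof χ² quantile of the nominal level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .model_core import ODEModel
from .priors import ContinuousRepresentation
from .variational_bvp import (AugmentedSystem, AugmentedTrajectory,
                              BVPSolveError, forward_solve,
                              solve_augmented_bvp)

__all__ = [
    "Measurements",
    "FitResult",
    "ProfileCI",
    "discrete_chi2",
    "fit_variational",
    "fit_fixed_input",
    "profile_likelihood_ci",
]

LM_DEFAULTS = {
    "max_iter": 50,
    "lam0": 1e-3,
    "fd_step": 1e-6,
    "tol_chi2": 1e-8,
    "tol_step": 1e-8,
    "max_rejects": 15,
    "bvp_tol": 1e-5,
    "ivp_rtol": 1e-8,
    "ivp_atol": 1e-10,
}


class Measurements:
    """Tabular time-stamped measurements: component, time, value, sigma."""

    COLUMNS = ("component", "time", "value", "sigma")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"measurement table lacks columns {sorted(missing)}")
        tab = table.loc[:, list(self.COLUMNS)].copy()
        tab["time"] = tab["time"].astype(float)
        tab["value"] = tab["value"].astype(float)
        tab["sigma"] = tab["sigma"].astype(float)
        if (tab["sigma"] <= 0).any():
            raise ValueError("all measurement sigmas must be positive")
        self.table = tab.sort_values(["component", "time"],
                                     kind="stable").reset_index(drop=True)

    @classmethod
    def from_arrays(cls, component, times, values, sigmas):
        return cls(pd.DataFrame({
            "component": component, "time": times,
            "value": values, "sigma": sigmas}))

    @classmethod
    def concat(cls, parts):
        return cls(pd.concat([p.table for p in parts], ignore_index=True))

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @property
    def components(self):
        return tuple(dict.fromkeys(self.table["component"]))

    def for_component(self, name):
        sub = self.table[self.table["component"] == name]
        return (sub["time"].to_numpy(), sub["value"].to_numpy(),
                sub["sigma"].to_numpy())

    def __len__(self):
        return len(self.table)


def discrete_chi2(predictions: Dict[str, Callable], data: Measurements) -> float:
    """Σ ((value - prediction(t)) / σ)² over the components present in
    ``predictions``; components of ``data`` without a prediction (e.g. input
    measurements under the fixed-input method) do not contribute."""
    total = 0.0
    for comp, pred in predictions.items():
        t, v, s = data.for_component(comp)
        if t.size == 0:
            continue
        yhat = np.asarray(pred(t), dtype=float).reshape(t.shape)
        total += float(np.sum(((v - yhat) / s) ** 2))
    return total


@dataclass
class FitResult:
    """Outcome of a Gauss-Newton fit of (p, y0)."""

    p_hat: np.ndarray
    y0_hat: np.ndarray
    chi2: float
    n_iter: int
    converged: bool
    method: str
    parameter_names: tuple = ()
    species_names: tuple = ()
    theta: np.ndarray = field(repr=False, default=None)
    jacobian: np.ndarray = field(repr=False, default=None)
    objective: object = field(repr=False, default=None)

    @property
    def theta_names(self):
        return tuple(f"log_{nm}" for nm in self.parameter_names) + \
            tuple(f"{nm}0" for nm in self.species_names)

    def covariance(self):
        """Gauss-Newton covariance estimate on θ scale: (JᵀJ)⁻¹ for the
        χ² = Σ r² parametrization (Δχ² = δᵀ JᵀJ δ)."""
        JtJ = self.jacobian.T @ self.jacobian
        return np.linalg.pinv(JtJ)

    def to_dict(self):
        return {
            "method": self.method,
            "p_hat": {nm: float(v) for nm, v in
                      zip(self.parameter_names, self.p_hat)},
            "y0_hat": {nm: float(v) for nm, v in
                       zip(self.species_names, self.y0_hat)},
            "chi2": float(self.chi2),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }

    def to_json(self, path=None, **kw):
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


@dataclass
class ProfileCI:
    """Profile-likelihood confidence intervals per parameter and level.

    ``intervals[param][level] = (lo, hi)`` on the natural parameter scale
    (NaN marks a side where the profile never crossed the threshold within
    the scan bounds — an open interval).  ``curves[param]`` holds the scanned
    (value, profile χ²) pairs.
    """

    intervals: dict
    curves: dict
    chi2_min: float
    levels: tuple

    def contains(self, param, level, value):
        lo, hi = self.intervals[param][level]
        lo = -np.inf if np.isnan(lo) else lo
        hi = np.inf if np.isnan(hi) else hi
        return lo <= value <= hi

    def to_dict(self):
        return {
            "chi2_min": float(self.chi2_min),
            "intervals": {
                param: {f"{lvl:g}": [float(lo), float(hi)]
                        for lvl, (lo, hi) in by_level.items()}
                for param, by_level in self.intervals.items()},
        }


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

class _ObjectiveBase:
    """Maps θ = (log p, y0) to the residual vector of the discrete χ²."""

    def __init__(self, model: ODEModel, data: Measurements, options=None):
        self.model = model
        self.data = data
        self.options = dict(LM_DEFAULTS)
        if options:
            self.options.update(options)
        self.n_theta = model.r + model.n

    def split(self, theta):
        p = np.exp(theta[:self.model.r])
        y0 = theta[self.model.r:]
        return p, y0

    def pack(self, p, y0):
        return np.concatenate([np.log(np.asarray(p, dtype=float)),
                               np.asarray(y0, dtype=float)])

    def residuals(self, theta):  # pragma: no cover - interface
        raise NotImplementedError


class VariationalObjective(_ObjectiveBase):
    """Residuals from the augmented BVP: species at their measurement times
    plus the reconstructed input at the input measurement times.

    Successive solves are warm-started from the last converged mesh, which
    keeps the finite-difference Jacobian evaluations cheap and smooth.
    """

    method = "variational"

    def __init__(self, model, priors: Dict[str, ContinuousRepresentation],
                 data, options=None):
        super().__init__(model, data, options)
        self.system = AugmentedSystem(
            model,
            [priors[nm] for nm in model.species_names],
            [priors[nm] for nm in model.input_names])
        self._warm = None

    def _solve(self, p, y0) -> AugmentedTrajectory:
        opts = {"bvp_tol": self.options["bvp_tol"]}
        if self._warm is not None:
            opts["initial_guess"] = self._warm
        try:
            traj = solve_augmented_bvp(self.system, p, y0, opts)
        except BVPSolveError:
            if self._warm is None:
                raise
            traj = solve_augmented_bvp(self.system, p, y0,
                                       {"bvp_tol": self.options["bvp_tol"]})
        mesh = traj.grid
        if mesh.size > 400:  # keep warm starts lean
            idx = np.linspace(0, mesh.size - 1, 400).round().astype(int)
            self._warm = (mesh[idx], np.vstack([traj.y, traj.u])[:, idx])
        else:
            self._warm = (mesh, np.vstack([traj.y, traj.u]))
        return traj

    def predict(self, theta) -> AugmentedTrajectory:
        p, y0 = self.split(theta)
        return self._solve(p, y0)

    def residuals(self, theta):
        traj = self.predict(theta)
        model = self.model
        res = []
        for i, nm in enumerate(model.species_names):
            t, v, s = self.data.for_component(nm)
            if t.size:
                res.append((traj.y_at(t)[i] - v) / s)
        for j, nm in enumerate(model.input_names):
            t, v, s = self.data.for_component(nm)
            if t.size:
                res.append((traj.x_at(t)[j] - v) / s)
        return np.concatenate(res)


class FixedInputObjective(_ObjectiveBase):
    """Residuals from a forward solve under a frozen input course; only
    species measurements contribute."""

    method = "fixed_input"

    def __init__(self, model, input_course: Callable, data, options=None,
                 t_span=None):
        super().__init__(model, data, options)
        self.input_course = input_course
        if t_span is None:
            tmax = float(data.table["time"].max())
            t_span = (0.0, tmax)
        self.t_span = t_span
        # cache the measurement layout so residuals need a single IVP solve
        self._meas = []
        t_all = []
        for i, nm in enumerate(model.species_names):
            t, v, s = data.for_component(nm)
            if t.size:
                self._meas.append((i, t, v, s))
                t_all.append(t)
        self._t_eval = np.unique(np.concatenate(t_all)) if t_all else None

    def predict(self, theta):
        p, y0 = self.split(theta)
        return forward_solve(
            self.model, p, y0, self.input_course, self.t_span,
            rtol=self.options["ivp_rtol"], atol=self.options["ivp_atol"])

    def residuals(self, theta):
        from scipy.integrate import odeint

        p, y0 = self.split(theta)
        model, course = self.model, self.input_course

        def rhs(y, t):
            x = np.atleast_1d(np.asarray(course(t), dtype=float))
            return model.f(y, x.ravel()[:model.m], p)

        t_eval = self._t_eval
        prepend = t_eval[0] > self.t_span[0]
        ts = np.concatenate([[self.t_span[0]], t_eval]) if prepend else t_eval
        Y = odeint(rhs, np.asarray(y0, dtype=float), ts,
                   rtol=self.options["ivp_rtol"],
                   atol=self.options["ivp_atol"])
        if not np.all(np.isfinite(Y)):
            raise RuntimeError("forward solve produced non-finite states")
        Y = Y[1:] if prepend else Y
        lookup = {t: k for k, t in enumerate(t_eval)}
        res = []
        for i, t, v, s in self._meas:
            idx = np.array([lookup[tv] for tv in t])
            res.append((Y[idx, i] - v) / s)
        return np.concatenate(res)


# ---------------------------------------------------------------------------
# Gauss-Newton with Levenberg damping
# ---------------------------------------------------------------------------

def _safe_residuals(objective, theta):
    try:
        r = objective.residuals(theta)
    except (BVPSolveError, RuntimeError, FloatingPointError):
        return None
    if not np.all(np.isfinite(r)):
        return None
    return r


def minimize_chi2(objective, theta0, free=None, options=None):
    """Levenberg-damped Gauss-Newton on the residual vector.

    ``free`` is a boolean mask over θ; fixed components are held at their
    ``theta0`` values (used by the profile-likelihood scan).  Deterministic:
    no internal randomness.  Returns a dict with θ̂, χ², the final Jacobian
    over the free components, iteration count and convergence flag.
    """
    opts = dict(LM_DEFAULTS)
    opts.update(objective.options)
    if options:
        opts.update(options)
    theta = np.asarray(theta0, dtype=float).copy()
    free = np.ones(theta.size, dtype=bool) if free is None else np.asarray(free)
    idx = np.where(free)[0]

    r = _safe_residuals(objective, theta)
    if r is None:
        raise RuntimeError("objective failed at the initial point")
    chi2 = float(r @ r)
    lam = opts["lam0"]
    h = opts["fd_step"]
    converged = False
    J = None
    n_iter = 0

    for n_iter in range(1, opts["max_iter"] + 1):
        # forward-difference Jacobian over free components
        J = np.empty((r.size, idx.size))
        for col, j in enumerate(idx):
            th = theta.copy()
            th[j] += h
            rj = _safe_residuals(objective, th)
            if rj is None:
                th[j] -= 2 * h
                rj = _safe_residuals(objective, th)
                if rj is None:
                    raise RuntimeError(
                        f"objective failed during Jacobian at component {j}")
                J[:, col] = (r - rj) / h
            else:
                J[:, col] = (rj - r) / h

        g = J.T @ r
        JtJ = J.T @ J
        diag = np.maximum(np.diag(JtJ), 1e-12)
        accepted = False
        for _ in range(opts["max_rejects"]):
            try:
                step = np.linalg.solve(JtJ + lam * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            th_new = theta.copy()
            th_new[idx] += step
            r_new = _safe_residuals(objective, th_new)
            if r_new is not None and float(r_new @ r_new) < chi2:
                chi2_new = float(r_new @ r_new)
                accepted = True
                lam = max(lam / 10, 1e-12)
                break
            lam *= 10
        if not accepted:
            converged = True  # no downhill step exists at this damping range
            break
        rel_drop = (chi2 - chi2_new) / max(chi2, 1e-300)
        step_norm = float(np.linalg.norm(step))
        theta, r, chi2 = th_new, r_new, chi2_new
        if rel_drop < opts["tol_chi2"] or step_norm < opts["tol_step"]:
            converged = True
            break

    return {"theta": theta, "chi2": chi2, "n_iter": n_iter,
            "converged": converged, "jacobian": J, "free": free}


def _package_fit(objective, res) -> FitResult:
    p, y0 = objective.split(res["theta"])
    return FitResult(
        p_hat=p, y0_hat=y0, chi2=res["chi2"], n_iter=res["n_iter"],
        converged=res["converged"], method=objective.method,
        parameter_names=objective.model.parameter_names,
        species_names=objective.model.species_names,
        theta=res["theta"], jacobian=res["jacobian"], objective=objective)


def fit_variational(model: ODEModel, priors: Dict[str, ContinuousRepresentation],
                    data: Measurements, p_init, y0_init,
                    options: Optional[dict] = None) -> FitResult:
    """Gauss-Newton estimation of (p, y0) with BVP-based predictions."""
    obj = VariationalObjective(model, priors, data, options)
    theta0 = obj.pack(p_init, y0_init)
    return _package_fit(obj, minimize_chi2(obj, theta0))


def fit_fixed_input(model: ODEModel, input_course: Callable,
                    data: Measurements, p_init, y0_init,
                    options: Optional[dict] = None,
                    t_span=None) -> FitResult:
    """Gauss-Newton estimation of (p, y0) with the input frozen."""
    obj = FixedInputObjective(model, input_course, data, options, t_span)
    theta0 = obj.pack(p_init, y0_init)
    return _package_fit(obj, minimize_chi2(obj, theta0))


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

def _theta_to_natural(name_idx, model, value):
    """Map a θ component back to the natural parameter scale."""
    return float(np.exp(value)) if name_idx < model.r else float(value)


def profile_likelihood_ci(fit: FitResult, levels=(0.68, 0.90),
                          params: Optional[Sequence[str]] = None,
                          max_steps: int = 40, n_bisect: int = 2,
                          objective=None) -> ProfileCI:
    """Profile-likelihood confidence intervals.

    For each requested parameter the corresponding θ component is scanned
    away from the optimum with all other components re-optimised; the CI at
    level ℓ is {θ_j : χ²_profile(θ_j) - χ²_min ≤ q_ℓ} with q_ℓ the 1-dof χ²
    quantile.  Crossings are bracketed on the scan grid, tightened by a few
    bisection refits, and located by linear interpolation of the signed root
    of Δχ² inside the final bracket.  Rate parameters are profiled on log
    scale and the bounds mapped back to the natural scale.
    """
    obj = objective if objective is not None else fit.objective
    if obj is None:
        raise ValueError("fit carries no objective; pass objective=")
    if not fit.converged:
        raise ValueError("profile requires a converged fit")
    model = obj.model
    names = list(fit.theta_names)
    natural_names = list(model.parameter_names) + \
        [f"{nm}0" for nm in model.species_names]
    if params is None:
        params = natural_names
    levels = tuple(sorted(levels))
    quants = {lvl: float(chi2_dist.ppf(lvl, 1)) for lvl in levels}
    q_max = max(quants.values())

    chi2_min = fit.chi2
    theta_hat = fit.theta
    cov = fit.covariance()

    intervals = {pn: {} for pn in params}
    curves = {}

    for pn in params:
        j = natural_names.index(pn)
        se = float(np.sqrt(max(cov[j, j], 1e-12)))
        free = np.ones(theta_hat.size, dtype=bool)
        free[j] = False

        # refits need Δχ² only to ~1e-2 accuracy; stop earlier than the
        # main fit does
        refit_opts = {"tol_chi2": 1e-5, "tol_step": 1e-5}

        def refit(value, theta_start):
            th = theta_start.copy()
            th[j] = value
            res = minimize_chi2(obj, th, free=free, options=refit_opts)
            return res["chi2"], res["theta"]

        curve = [(theta_hat[j], chi2_min)]
        bounds = {lvl: [np.nan, np.nan] for lvl in levels}
        for direction in (-1, +1):
            step = se * np.sqrt(q_max) / 2
            th_start = theta_hat.copy()
            prev_val, prev_chi2 = theta_hat[j], chi2_min
            found_max = False
            for _ in range(max_steps):
                val = prev_val + direction * step
                c, th_start = refit(val, th_start)
                curve.append((val, c))
                # bracket each level crossing as it is passed
                for lvl in levels:
                    q = quants[lvl]
                    done = not np.isnan(bounds[lvl][0 if direction < 0 else 1])
                    if done:
                        continue
                    if c - chi2_min >= q:
                        lo_v, lo_c = prev_val, prev_chi2
                        hi_v, hi_c = val, c
                        qr = np.sqrt(q)

                        def _interp(av, ac, bv, bc):
                            # the signed root of Δχ² is near-linear in θ
                            ra = np.sqrt(max(ac - chi2_min, 0.0))
                            rb = np.sqrt(max(bc - chi2_min, 0.0))
                            frac = (qr - ra) / (rb - ra) if rb > ra else 0.5
                            return av + np.clip(frac, 0.05, 0.95) * (bv - av)

                        th_b = th_start.copy()
                        for _ in range(n_bisect):
                            mid = _interp(lo_v, lo_c, hi_v, hi_c)
                            cm, th_b = refit(mid, th_b)
                            curve.append((mid, cm))
                            if cm - chi2_min >= q:
                                hi_v, hi_c = mid, cm
                            else:
                                lo_v, lo_c = mid, cm
                        cross = _interp(lo_v, lo_c, hi_v, hi_c)
                        bounds[lvl][0 if direction < 0 else 1] = cross
                if all(not np.isnan(bounds[lvl][0 if direction < 0 else 1])
                       for lvl in levels):
                    found_max = True
                    break
                if (c - chi2_min) < 0.05 * q_max:
                    step *= 2  # profile nearly flat: stride out faster
                prev_val, prev_chi2 = val, c
            # an unfound bound stays NaN: open interval flagged to the caller
            del found_max

        by_level = {}
        for lvl in levels:
            lo, hi = bounds[lvl]
            lo_n = _theta_to_natural(j, model, lo) if not np.isnan(lo) else np.nan
            hi_n = _theta_to_natural(j, model, hi) if not np.isnan(hi) else np.nan
            by_level[lvl] = (lo_n, hi_n)
        intervals[pn] = by_level
        curve = sorted(curve)
        curves[pn] = [(
            _theta_to_natural(j, model, v), c) for v, c in curve]

    return ProfileCI(intervals=intervals, curves=curves,
                     chi2_min=chi2_min, levels=levels)
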