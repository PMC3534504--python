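"""ODE reaction-network models with time-varying inputs.

A model is the triple of dimensions ``(n, m, r)`` — species, inputs, rate
parameters — together with the right-hand side ``f(y, x, p)`` and its analytic
Jacobians with respect to the species (``jac_y``) and the inputs (``jac_x``).
The adjoint machinery in :mod:`varode.variational_bvp` consumes both Jacobians
at every node of the boundary-value mesh, so they are required analytically;
a finite-difference self-check runs at registration time.

Models are autonomous in ``y`` and ``x``: explicit time dependence enters only
through reconstructed or prescribed input courses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ODEModel",
    "InputTransform",
    "eval_model",
    "make_toy_model",
    "extend_positive_input",
    "apply_input_transform",
    "register_model",
    "get_model",
    "check_jacobians",
]


@dataclass(frozen=True)
class ODEModel:
    """An ODE model ``dy/dt = f(y, x, p)`` with m time-dependent inputs.

    Parameters
    ----------
    n, m, r
        Number of species, inputs and rate parameters.
    f
        Right-hand side ``(y, x, p) -> R^n`` (rates per time unit).
    jac_y, jac_x
        Analytic Jacobians ``∂f/∂y`` (n×n) and ``∂f/∂x`` (n×m).
    species_names, input_names, parameter_names
        Component identifiers, used in measurement tables and results.
    f_vec, jac_y_vec, jac_x_vec
        Optional vectorized variants operating on stacked states with a
        trailing node axis: ``y (n,k), x (m,k) -> (n,k) / (n,n,k) / (n,m,k)``.
        They let the BVP collocation evaluate whole meshes in single numpy
        calls; when absent, a python loop fallback is used.
    linear_input
        Declares that ``f`` is linear in ``x`` (``jac_x`` independent of x),
        the condition under which the input can be eliminated in closed form.
    """

    n: int
    m: int
    r: int
    f: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    jac_y: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    jac_x: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    species_names: tuple = ()
    input_names: tuple = ()
    parameter_names: tuple = ()
    f_vec: Optional[Callable] = None
    jac_y_vec: Optional[Callable] = None
    jac_x_vec: Optional[Callable] = None
    linear_input: bool = True
    name: str = ""

    def __post_init__(self):
        if not self.species_names:
            object.__setattr__(self, "species_names",
                               tuple(f"y{i}" for i in range(self.n)))
        if not self.input_names:
            object.__setattr__(self, "input_names",
                               tuple(f"x{i}" for i in range(self.m)))
        if not self.parameter_names:
            object.__setattr__(self, "parameter_names",
                               tuple(f"p{i}" for i in range(self.r)))


@dataclass(frozen=True)
class InputTransform:
    """A monotone change of input variables ``x̃ = φ(x, p)``.

    Used when the right-hand side factorizes as
    ``f_μ = Σ_ν g_{μν}(y,p)·φ_ν(x,p) + g_{μ0}(y,p)``: re-expressing the model
    in x̃ makes the input entry linear so that the closed-form elimination
    applies.  ``phi`` must be monotone on the declared domain so that the
    original input can be reported back; supply ``phi_inv`` to enable that.
    """

    phi: Callable[[np.ndarray, np.ndarray], np.ndarray]
    description: str = ""
    phi_inv: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None


_MODEL_REGISTRY: dict = {}


def register_model(name: str, model: ODEModel, check: bool = True) -> ODEModel:
    """Register a model by name, running the finite-difference Jacobian
    self-check unless ``check=False``."""
    if check:
        check_jacobians(model)
    model = replace(model, name=name)
    _MODEL_REGISTRY[name] = model
    return model


def get_model(name: str) -> ODEModel:
    try:
        return _MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(_MODEL_REGISTRY)}"
        ) from None


def _as_vec(v, length, label):
    a = np.atleast_1d(np.asarray(v, dtype=float))
    if a.shape != (length,):
        raise ValueError(
            f"argument {label!r} has shape {a.shape}, expected ({length},)"
        )
    return a


def eval_model(model: ODEModel, y, x, p):
    """Evaluate ``(f, ∂f/∂y, ∂f/∂x)`` at one state, with dimension checks."""
    y = _as_vec(y, model.n, "y")
    x = _as_vec(x, model.m, "x")
    p = _as_vec(p, model.r, "p")
    f = np.asarray(model.f(y, x, p), dtype=float).reshape(model.n)
    jy = np.asarray(model.jac_y(y, x, p), dtype=float).reshape(model.n, model.n)
    jx = np.asarray(model.jac_x(y, x, p), dtype=float).reshape(model.n, model.m)
    return f, jy, jx


def check_jacobians(model: ODEModel, n_states: int = 100, rtol: float = 1e-5,
                    rng=None) -> None:
    """Verify analytic Jacobians against central finite differences of ``f``
    at randomly sampled states.  Raises ``AssertionError`` on disagreement."""
    rng = np.random.default_rng(0) if rng is None else rng
    for _ in range(n_states):
        y = rng.uniform(0.1, 2.0, model.n)
        x = rng.uniform(0.1, 2.0, model.m)
        p = rng.uniform(0.1, 2.0, model.r)
        f0, jy, jx = eval_model(model, y, x, p)
        h = 1e-6
        for i in range(model.n):
            dy = np.zeros(model.n); dy[i] = h
            fd = (np.asarray(model.f(y + dy, x, p)) -
                  np.asarray(model.f(y - dy, x, p))) / (2 * h)
            np.testing.assert_allclose(jy[:, i], fd, rtol=rtol, atol=1e-7)
        for i in range(model.m):
            dx = np.zeros(model.m); dx[i] = h
            fd = (np.asarray(model.f(y, x + dx, p)) -
                  np.asarray(model.f(y, x - dx, p))) / (2 * h)
            np.testing.assert_allclose(jx[:, i], fd, rtol=rtol, atol=1e-7)


# ---------------------------------------------------------------------------
# built-in toy model: x-driven reversible conversion A <=> B
# ---------------------------------------------------------------------------

def make_toy_model() -> ODEModel:
    """The reversible two-species model ``A ⇌ B`` whose forward reaction is
    mediated by a time-dependent input x:

        dA/dt = -k1·A·x + k2·B
        dB/dt = +k1·A·x - k2·B

    Two species, one input, two rate parameters; the input enters linearly so
    the closed-form input elimination applies.  Total mass A+B is conserved.
    """

    def f(y, x, p):
        A, B = y
        fwd = p[0] * A * x[0]
        back = p[1] * B
        return np.array([-fwd + back, fwd - back])

    def jac_y(y, x, p):
        k1x = p[0] * x[0]
        return np.array([[-k1x, p[1]], [k1x, -p[1]]])

    def jac_x(y, x, p):
        k1A = p[0] * y[0]
        return np.array([[-k1A], [k1A]])

    # vectorized variants over a trailing node axis
    def f_vec(y, x, p):
        fwd = p[0] * y[0] * x[0]
        back = p[1] * y[1]
        return np.stack([-fwd + back, fwd - back])

    def jac_y_vec(y, x, p):
        k = y.shape[1]
        out = np.empty((2, 2, k))
        out[0, 0] = -p[0] * x[0]
        out[0, 1] = p[1]
        out[1, 0] = p[0] * x[0]
        out[1, 1] = -p[1]
        return out

    def jac_x_vec(y, x, p):
        k = y.shape[1]
        out = np.empty((2, 1, k))
        out[0, 0] = -p[0] * y[0]
        out[1, 0] = p[0] * y[0]
        return out

    return ODEModel(
        n=2, m=1, r=2,
        f=f, jac_y=jac_y, jac_x=jac_x,
        species_names=("A", "B"), input_names=("x",),
        parameter_names=("k1", "k2"),
        f_vec=f_vec, jac_y_vec=jac_y_vec, jac_x_vec=jac_x_vec,
        linear_input=True,
    )


register_model("reversible_toy", make_toy_model())


# ---------------------------------------------------------------------------
# structural transformations
# ---------------------------------------------------------------------------

def extend_positive_input(model: ODEModel) -> ODEModel:
    """Promote the inputs to state variables with relaxation dynamics
    ``dx/dt = -D(t)·x``, ``D = diag(d_1..d_m)``, driven by new inputs d.

    The sign of each x component is frozen at its initial value (solutions of
    a scalar linear ODE cannot cross zero), which enforces positivity of
    concentration-like inputs by construction.  The new inputs d enter the
    extended right-hand side linearly even if the original x did not, so the
    closed-form elimination applies to the extended model.
    """
    if model.m < 1:
        raise ValueError("model has no inputs to extend")
    n, m = model.n, model.m

    def f_ext(z, d, p):
        y, x = z[:n], z[n:]
        return np.concatenate([np.asarray(model.f(y, x, p)), -d * x])

    def jac_y_ext(z, d, p):
        y, x = z[:n], z[n:]
        J = np.zeros((n + m, n + m))
        J[:n, :n] = model.jac_y(y, x, p)
        J[:n, n:] = model.jac_x(y, x, p)
        J[n:, n:] = -np.diag(d)
        return J

    def jac_x_ext(z, d, p):
        x = z[n:]
        J = np.zeros((n + m, m))
        J[n:, :] = -np.diag(x)
        return J

    return ODEModel(
        n=n + m, m=m, r=model.r,
        f=f_ext, jac_y=jac_y_ext, jac_x=jac_x_ext,
        species_names=model.species_names + model.input_names,
        input_names=tuple(f"d_{nm}" for nm in model.input_names),
        parameter_names=model.parameter_names,
        linear_input=True,
        name=(model.name + "+positive_input") if model.name else "",
    )


class NonlinearInputError(ValueError):
    """The right-hand side is not linear in the (transformed) inputs."""


def _factor_coefficients(model, transform, y, p, x_refs, phis):
    """Solve for G (n×m) and g0 (n) from m+1 reference input points, using
    f(y,x,p) = G·φ(x,p) + g0."""
    m = model.m
    A = np.column_stack([phis, np.ones(m + 1)])         # (m+1, m+1) rows (φ,1)
    F = np.stack([np.asarray(model.f(y, xr, p), dtype=float)
                  for xr in x_refs])                     # (m+1, n)
    coef = np.linalg.solve(A, F)                         # (m+1, n)
    G = coef[:m].T                                       # (n, m)
    g0 = coef[m]
    return G, g0


def apply_input_transform(model: ODEModel, transform: InputTransform,
                          x_domain: tuple = (0.25, 1.75),
                          rtol: float = 1e-6) -> ODEModel:
    """Re-express the model in transformed inputs ``x̃ = φ(x, p)``.

    Requires the factorization ``f_μ = Σ_ν g_{μν}(y,p)·x̃_ν + g_{μ0}(y,p)``,
    which is verified numerically: the affine reconstruction from m+1
    reference input points must reproduce ``f`` at an independent point.  On
    failure a :class:`NonlinearInputError` is raised suggesting
    :func:`extend_positive_input` as the general-purpose alternative.

    The returned model takes x̃ as its input; ``∂f/∂x̃`` is the coefficient
    matrix ``g_{μν}(y,p)``, independent of x̃ (linear input entry).
    """
    m = model.m
    lo, hi = x_domain
    # m+1 affinely independent reference points in input space
    x_refs = [np.full(m, lo)]
    for j in range(m):
        xr = np.full(m, lo)
        xr[j] = hi
        x_refs.append(xr)
    x_check = np.full(m, 0.5 * (lo + hi))

    def _phis(p):
        return np.stack([np.atleast_1d(np.asarray(
            transform.phi(xr, p), dtype=float)) for xr in x_refs])

    # linearity validation at a few random states
    rng = np.random.default_rng(12345)
    for _ in range(5):
        y = rng.uniform(0.2, 2.0, model.n)
        p = rng.uniform(0.2, 2.0, model.r)
        phis = _phis(p)
        try:
            G, g0 = _factor_coefficients(model, transform, y, p, x_refs, phis)
        except np.linalg.LinAlgError:
            raise NonlinearInputError(
                "transform produced degenerate reference points; "
                "use extend_positive_input instead") from None
        f_pred = G @ np.atleast_1d(transform.phi(x_check, p)) + g0
        f_true = np.asarray(model.f(y, x_check, p), dtype=float)
        scale = max(1.0, float(np.max(np.abs(f_true))))
        if np.max(np.abs(f_pred - f_true)) > rtol * scale:
            raise NonlinearInputError(
                "right-hand side does not factorize as G(y,p)·φ(x,p) + g0(y,p) "
                "under this transform; use extend_positive_input instead")

    def f_t(y, xt, p):
        phis = _phis(p)
        G, g0 = _factor_coefficients(model, transform, y, p, x_refs, phis)
        return G @ xt + g0

    def jac_x_t(y, xt, p):
        phis = _phis(p)
        G, _ = _factor_coefficients(model, transform, y, p, x_refs, phis)
        return G

    def jac_y_t(y, xt, p):
        # ∂f_t/∂y is the same affine combination of model.jac_y at the
        # reference points that reproduces (xt, 1) in (φ, 1)-coordinates
        phis = _phis(p)
        A = np.column_stack([phis, np.ones(m + 1)])   # (m+1, m+1): rows (φ,1)
        target = np.concatenate([np.atleast_1d(xt), [1.0]])
        w = np.linalg.solve(A.T, target)              # weights over refs
        Js = np.stack([np.asarray(model.jac_y(y, xr, p), dtype=float)
                       for xr in x_refs])
        return np.tensordot(w, Js, axes=(0, 0))

    return ODEModel(
        n=model.n, m=m, r=model.r,
        f=f_t, jac_y=jac_y_t, jac_x=jac_x_t,
        species_names=model.species_names,
        input_names=tuple(f"phi({nm})" for nm in model.input_names),
        parameter_names=model.parameter_names,
        linear_input=True,
        name=(model.name + "+transform") if model.name else "",
    )
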