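# varode

Joint estimation of **unknown time-course inputs** and **kinetic
parameters** in ODE reaction-network models, for systems biologists and
modellers whose networks are open: a drug stimulus drives a pathway, or a
module has been cut out of a larger network and its boundary nodes act as
unconstrained inputs.

## The problem and the method

A network with species `y`, rates `p` and inputs `x` follows
`dy/dt = f(y, x, p)`, `y(0) = y0`.  Noisy measurements exist for species
and (possibly very few) input time points.  The conventional approach
freezes `x(t)` at a smoothing spline through the input data and fits only
`(p, y0)` — ignoring the uncertainty in the input, which makes parameter
confidence intervals systematically too small.

`varode` instead treats the whole input course as unknown.  The χ²
objective is extended to a time-continuous functional

    J[x] = ∫ Σ_μ (y_μ(t;[x]) − S_yμ)²/Sσ²_yμ dt + ∫ Σ_ν (x_ν − S_xν)²/Sσ²_xν dt

with spline data priors `S(t)` and variance courses `Sσ²(t)`.  Vanishing
first variation yields an adjoint (costate) system — for linear input
entry the input is eliminated in closed form:

    du/dt = −(∂f/∂y)ᵀ u − (y − S_y)/Sσ²_y ,   u(T) = 0
    x     = S_x − Sσ²_x · (∂f/∂x)ᵀ u

so each evaluation of the model is a two-point boundary-value problem in
`(y, u)` with `y(0) = y0`, `u(T) = 0`, solved by collocation.  On top of
this, ordinary Gauss-Newton minimisation of the discrete χ² estimates
`(p, y0)`, and profile likelihood gives confidence intervals that now
carry the input uncertainty.

The built-in toy model is the reversible conversion `A ⇌ B` whose forward
rate `k1·A·x(t)` is driven by the input while the back reaction `k2·B` is
not.  Nonlinear input entry is handled by a positivity-preserving
extension (`dx/dt = −D(t)x` with new linear inputs) or a factorizing
change of variables `x̃ = φ(x)`.

## Worked example

```python
import numpy as np
from varode import (make_toy_model, ScenarioConfig, simulate_dataset,
                    build_priors, fit_variational, profile_likelihood_ci)

model = make_toy_model()                      # A <=> B, input-driven forward
scenario = ScenarioConfig(seed=3)             # Gaussian pulse, 20+20+20 pts
data = simulate_dataset(model, scenario)      # sigma = 0.1 Gaussian noise
priors = build_priors(model, data, scenario)  # splines + variance courses

fit = fit_variational(model, priors, data, p_init=[1, 1], y0_init=[1, 0.05])
print(fit.p_hat, fit.chi2, fit.converged)
ci = fit and profile_likelihood_ci(fit, levels=(0.68, 0.90), params=["k1", "k2"])
print(ci.intervals["k1"][0.9])
```

Output (truth k1 = 2, k2 = 0.5):

```
[2.48070979 0.61290411] 58.62666058727807 True
(1.826172908290347, 3.570671729956346)
```

The estimate `k̂1 = 2.48` sits about one standard error above the truth
for this noise realization; its 90% profile interval (1.83, 3.57)
comfortably contains 2.  Because the input course was estimated jointly,
the interval is wider — and honestly so — than the fixed-input baseline
produces on the same data ((1.97, 3.28)), which is exactly the coverage
defect the method repairs.

A command-line interface wraps the same operations:

```
varode simulate --config toy_dense.yaml --seed 1 --out data.csv
varode fit --data data.csv --config toy_dense.yaml --method variational --out fit.json
varode coverage --config toy_dense.yaml --n-reps 100 --seed 1 --out coverage.csv
```

Each run writes a JSON manifest (seed, config hash, version) next to its
output.

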