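import numpy as np
import pytest

from varode.model_core import make_toy_model
from varode.priors import ContinuousRepresentation
from varode.variational_bvp import AugmentedSystem, forward_solve
from varode.simulation_study import ScenarioConfig, make_input, simulate_dataset

TOY_P = np.array([2.0, 0.5])
TOY_Y0 = np.array([1.0, 0.0])
T_END = 5.0


@pytest.fixture(scope="session")
def toy():
    return make_toy_model()


@pytest.fixture(scope="session")
def dense_scenario():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def sparse_scenario():
    return ScenarioConfig(n_input_times=4)


@pytest.fixture(scope="session")
def dense_data(toy, dense_scenario):
    return simulate_dataset(toy, dense_scenario)


def const_sigma_rep(S, s2, T=T_END):
    """Continuous representation with a constant variance course."""
    return ContinuousRepresentation(
        S=S, dS=lambda t: np.zeros_like(np.asarray(t, dtype=float)),
        sigma2=lambda t: np.full_like(np.asarray(t, dtype=float), s2),
        domain=(0.0, T))


def zero_residual_system(toy, family="gaussian", s2=0.01):
    """Priors generated by a forward solve: the BVP solution must then be
    u ≡ 0, y ≡ S_y, x ≡ S_x exactly (the functional's global minimum 0)."""
    params = {"amplitude": 2.0, "t_dip": 2.0, "tau_in": 0.7,
              "alpha": 1.0, "beta": 0.2}
    course = make_input(family, params)
    sol = forward_solve(toy, TOY_P, TOY_Y0,
                        lambda t: np.atleast_1d(course(t)), (0.0, T_END))
    priors_y = [
        const_sigma_rep(lambda t, i=i: sol.sol(np.asarray(t, dtype=float))[i], s2)
        for i in range(2)]
    priors_x = [const_sigma_rep(lambda t: np.asarray(course(t), dtype=float), s2)]
    return AugmentedSystem(toy, priors_y, priors_x), course


@pytest.fixture(scope="session")
def gaussian_zero_residual(toy):
    return zero_residual_system(toy, "gaussian")
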