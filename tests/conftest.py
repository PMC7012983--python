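import numpy as np
import pytest

import structpop as sp


@pytest.fixture(scope="session")
def chemostat():
    """Surviving-regime chemostat: monod(S_ext) = 2/3 > D = 1/2."""
    return sp.ChemostatConfig(D=0.5, S_ext=2.0, gamma=1.0, a=1.0, b=1.0)


@pytest.fixture(scope="session")
def x_grid():
    return np.geomspace(0.1, 10.0, 200)


@pytest.fixture(scope="session")
def age_model():
    """Constant-rate age-structured model (g = 1, point birth at 0)."""
    beta, m = 1.0, 0.3
    space = sp.IStateSpace(0.0, 40.0, birth_state=0.0)
    rates = sp.RateSet(
        g=lambda x, E: np.ones_like(np.asarray(x, float)),
        mu=lambda x, E: m * np.ones_like(np.asarray(x, float)),
        beta=sp.PointBirthKernel(
            lambda x, E: beta * np.ones_like(np.asarray(x, float)), 0.0
        ),
    )
    model = sp.StructuredModel(space, rates, name="lotka")
    model.meta["beta"] = beta
    model.meta["mu"] = m
    return model


@pytest.fixture(scope="session")
def monod_coupled(chemostat):
    """One shared coupled Monod run (p = 1, constant fission rate) next to
    its reduced ODE solution."""
    model, reduced = sp.build_monod_fission(chemostat, beta0=0.5, span=32768)
    history = sp.BirthHistory.point_cohort(0.0, [1.0], [0.2])
    run = sp.simulate_coupled(model, chemostat, history, S0=1.0,
                              horizon=20.0, dt=0.005, outputs=[sp.w_x])
    Y = reduced.solve(run.t, [0.2, 1.0])
    return {"run": run, "ode": Y, "model": model, "reduced": reduced}
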