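"""Pre-built chemostat models and their reduced ODE systems.

Two size-structured cell-fission models are provided together with the
exact ODE systems they reduce to:

* the Monod model — fission into equal halves, growth proportional to
  size with Michaelis-Menten substrate dependence; the biomass
  ``X = int x m(dx)`` obeys the classical chemostat ODE pair,
* the volume/surface model — growth proportional to surface area
  (``x^(2/3)`` for ball-shaped organisms of volume ``x``), with a net
  fission kernel; the pair ``(N1, N2) = (volume, surface)`` closes into a
  linear two-by-two system driven by the substrate.

``simulate_coupled`` co-integrates a structured model with the substrate
feedback ODE by operator splitting (substrate frozen during each
population step, advanced with the trapezoid-averaged uptake).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    ConfigError,
    FissionKernel,
    FissionNetKernel,
    IStateSpace,
    ModelError,
    RateSet,
    StructuredModel,
)
from .renewal import BirthHistory, CohortEngine
from .weights import Weight, WeightFamily, w_x, w_x23

CBRT2 = 2.0 ** (1.0 / 3.0)


# --------------------------------------------------------------------------
# chemostat configuration and reduced systems
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemostatConfig:
    """Continuous-culture parameters.

    D: dilution rate (1/time); S_ext: reservoir substrate concentration;
    gamma: substrate consumed per unit biomass produced; a: maximal
    specific uptake/growth rate; b: half-saturation constant.
    """

    D: float
    S_ext: float
    gamma: float
    a: float
    b: float

    def __post_init__(self):
        if self.D < 0 or self.S_ext < 0:
            raise ConfigError("D and S_ext must be non-negative")
        if self.gamma <= 0 or self.a <= 0 or self.b <= 0:
            raise ConfigError("gamma, a and b must be positive")

    def monod(self, S):
        """Michaelis-Menten rate a S / (b + S)."""
        S = np.maximum(S, 0.0)
        return self.a * S / (self.b + S)


@dataclass
class ReducedODESystem:
    """A finite-dimensional reduction dN/dt = f(t, N)."""

    state_names: list
    rhs: Callable
    provenance: str = ""

    def solve(self, t_grid, y0, rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
        t_grid = np.asarray(t_grid, dtype=float)
        sol = solve_ivp(
            self.rhs, (t_grid[0], t_grid[-1]), np.asarray(y0, dtype=float),
            t_eval=t_grid, rtol=rtol, atol=atol, method="RK45", max_step=np.inf,
        )
        if not sol.success:
            raise ModelError(f"reduced ODE integration failed: {sol.message}")
        return sol.y.T


@dataclass
class ChemostatCoupling:
    """How a structured population consumes substrate:
    dS/dt = D (S_ext - S) - gamma * uptake_rate(S) * int uptake_weight dm."""

    uptake_weight: Weight
    uptake_rate: Callable


# --------------------------------------------------------------------------
# Monod fission model
# --------------------------------------------------------------------------

def _as_xs_callable(c):
    if callable(c):
        return c
    v = float(c)
    return lambda x, S: v * np.ones_like(np.asarray(x, dtype=float))


def build_monod_fission(
    chemostat: ChemostatConfig,
    p: Callable | float | None = None,
    beta0: Callable | float = 1.0,
    compensate: bool = True,
    x0: float = 1.0,
    span: float = 64.0,
) -> tuple[StructuredModel, ReducedODESystem]:
    """Size-structured fission model reducing to the Monod chemostat ODEs.

    Fission into equal halves at rate beta0(x, S), successful with
    probability p(x, S); an unsuccessful attempt removes the mother.  The
    death rate is the attempt rate plus washout, mu = beta0 + D.  With
    every division successful the growth rate is g = monod(S) x; with
    p < 1 the loss through failed divisions must be compensated in the
    individual growth rate, g = (monod(S) + (1 - p) beta0) x, for the
    biomass to keep obeying the Monod ODEs.  ``compensate=False`` builds
    the uncompensated variant (g = monod(S) x regardless of p), which is
    *not* equivalent to the reduced system — useful as a negative control.
    """
    ch = chemostat
    b0 = _as_xs_callable(beta0)
    pf = _as_xs_callable(p) if p is not None else (lambda x, S: np.ones_like(np.asarray(x, float)))
    # config check on a sample grid
    xs = np.geomspace(x0 / span, x0 * span, 33)
    pv = np.asarray(pf(xs, 1.0), dtype=float) * np.ones_like(xs)
    if np.any(pv < 0) or np.any(pv > 1 + 1e-12):
        raise ConfigError("success probability p must lie in [0, 1]")
    if np.any(np.asarray(b0(xs, 1.0), dtype=float) * np.ones_like(xs) < 0):
        raise ConfigError("fission rate beta0 must be non-negative")

    if compensate:
        def g(x, S):
            x = np.asarray(x, dtype=float)
            return (ch.monod(S) + (1.0 - pf(x, S)) * b0(x, S)) * x
    else:
        def g(x, S):
            x = np.asarray(x, dtype=float)
            return ch.monod(S) * x

    def mu(x, S):
        x = np.asarray(x, dtype=float)
        return np.asarray(b0(x, S), dtype=float) * np.ones_like(x) + ch.D

    space = IStateSpace(x_min=x0 / span, x_max=x0 * span, birth_state=None)
    model = StructuredModel(
        space=space,
        rates=RateSet(g=g, mu=mu, beta=FissionKernel(b0, pf)),
        name="monod_fission",
        meta={
            "coupling": ChemostatCoupling(uptake_weight=w_x, uptake_rate=ch.monod),
            "chemostat": ch,
            "compensate": compensate,
        },
    )

    def rhs(t, y):
        X, S = y
        m = ch.monod(S)
        return [m * X - ch.D * X, -ch.gamma * m * X + ch.D * (ch.S_ext - S)]

    reduced = ReducedODESystem(
        state_names=["X", "S"], rhs=rhs, provenance="Monod chemostat pair (biomass, substrate)"
    )
    return model, reduced


def monod_equilibrium(chemostat: ChemostatConfig) -> dict:
    """Equilibrium of the Monod pair: washout when monod(S_ext) < D,
    otherwise S* with monod(S*) = D and gamma X* = S_ext - S*."""
    ch = chemostat
    if ch.monod(ch.S_ext) <= ch.D:
        return {"regime": "washout", "X": 0.0, "S": ch.S_ext}
    S_star = ch.D * ch.b / (ch.a - ch.D)
    return {"regime": "survival", "X": (ch.S_ext - S_star) / ch.gamma, "S": S_star}


# --------------------------------------------------------------------------
# volume/surface model
# --------------------------------------------------------------------------

def build_surface_model(
    chemostat: ChemostatConfig,
    k21: float = 1.0,
    x0: float = 1.0,
    span: float = 64.0,
) -> tuple[StructuredModel, ReducedODESystem]:
    """Two-output model: volume w1 = x and surface area w2 = x^(2/3).

    Growth is proportional to surface area, g = 3 k12(S) x^(2/3) with the
    Michaelis-Menten uptake k12(S) = a S / (b + S); death is
    mu = D + 2 k12(S) x^(-1/3); reproduction is net fission
    beta0(x) (2 delta_{x/2} - delta_x) with beta0 = k21 x^(1/3) / (2^(1/3) - 1)
    (k21 constant: the substrate dependence of division is carried by the
    size-specific factor).  The outputs close into the linear system
    dN1/dt = -D N1 + k12(S) N2, dN2/dt = k21 N1 - D N2, with substrate
    feedback dS/dt = D (S_ext - S) - gamma k12(S) N2.
    """
    if k21 <= 0:
        raise ConfigError("k21 must be positive")
    ch = chemostat
    k12 = ch.monod
    c = k21 / (CBRT2 - 1.0)

    def beta0(x, S):
        x = np.asarray(x, dtype=float)
        return c * x ** (1.0 / 3.0)

    def g(x, S):
        x = np.asarray(x, dtype=float)
        return 3.0 * k12(S) * x ** (2.0 / 3.0)

    def mu(x, S):
        x = np.asarray(x, dtype=float)
        return ch.D + 2.0 * k12(S) * x ** (-1.0 / 3.0)

    space = IStateSpace(x_min=x0 / span, x_max=x0 * span, birth_state=None)
    model = StructuredModel(
        space=space,
        rates=RateSet(g=g, mu=mu, beta=FissionNetKernel(beta0)),
        name="surface_fission",
        meta={
            "coupling": ChemostatCoupling(uptake_weight=w_x23, uptake_rate=k12),
            "chemostat": ch,
            "k21": k21,
        },
    )

    def rhs(t, y):
        N1, N2, S = y
        return [
            -ch.D * N1 + k12(S) * N2,
            k21 * N1 - ch.D * N2,
            ch.D * (ch.S_ext - S) - ch.gamma * k12(S) * N2,
        ]

    reduced = ReducedODESystem(
        state_names=["N1", "N2", "S"],
        rhs=rhs,
        provenance="volume/surface pair with substrate feedback",
    )
    return model, reduced


def surface_reduced_prescribed(
    chemostat: ChemostatConfig, k21: float, S_of_t: Callable
) -> ReducedODESystem:
    """The (N1, N2) system of the volume/surface model under a prescribed
    substrate trajectory."""
    k12 = chemostat.monod
    D = chemostat.D

    def rhs(t, y):
        N1, N2 = y
        S = S_of_t(t)
        return [-D * N1 + k12(S) * N2, k21 * N1 - D * N2]

    return ReducedODESystem(state_names=["N1", "N2"], rhs=rhs,
                            provenance="volume/surface pair, prescribed substrate")


# --------------------------------------------------------------------------
# coupled simulation
# --------------------------------------------------------------------------

@dataclass
class CoupledResult:
    """Time series of a structured-plus-substrate coupled run."""

    t: np.ndarray
    S: np.ndarray
    N: np.ndarray
    output_names: list
    total_number: np.ndarray
    total_biomass: np.ndarray
    truncated_mass: np.ndarray
    final_state: object
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        data = {"t": self.t, "E": self.S}
        for i, name in enumerate(self.output_names):
            data[f"N_{i + 1}"] = self.N[:, i]
        data["total_number"] = self.total_number
        data["total_biomass"] = self.total_biomass
        data["truncated_mass"] = self.truncated_mass
        return pd.DataFrame(data)


def simulate_coupled(
    model: StructuredModel,
    chemostat: ChemostatConfig,
    history: BirthHistory,
    S0: float,
    horizon: float,
    dt: float,
    outputs: Sequence[Weight] | WeightFamily | None = None,
    merge_dx: float | None = 2e-3,
    max_halvings: int = 8,
) -> CoupledResult:
    """Co-integrate a structured model with the substrate feedback ODE.

    Operator splitting per step: the substrate is advanced half a step by
    its current rate, the population is stepped with the substrate frozen
    at that midpoint value, and the substrate completes the step using the
    trapezoid average of the uptake functional.  A step that would drive
    the substrate negative is retried with halved substeps (up to
    ``max_halvings``).
    """
    if S0 < 0:
        raise ConfigError("initial substrate must be non-negative")
    if dt <= 0:
        raise ConfigError("dt must be positive")
    coupling: ChemostatCoupling = model.meta.get("coupling")
    if coupling is None:
        raise ConfigError("model has no chemostat coupling metadata")
    ch = chemostat
    w_u = coupling.uptake_weight
    u = coupling.uptake_rate
    for a in history.atoms:
        if a.time < history.s - 1e-12:
            raise ConfigError("feedback runs require the initial population "
                              "as point cohorts at the start time")
    weights = (
        outputs if isinstance(outputs, WeightFamily)
        else WeightFamily(outputs) if outputs is not None else None
    )

    n = int(math.ceil(horizon / dt - 1e-9))
    t_grid = history.s + dt * np.arange(n + 1)
    eng = CohortEngine(model, merge_dx=merge_dx)
    hx = np.array([a.state for a in history.atoms], dtype=float)
    hm = np.array([a.mass for a in history.atoms], dtype=float)
    if hx.size:
        eng.add(hx, hm)

    k = len(weights) if weights is not None else 0
    N = np.zeros((n + 1, k))
    Sv = np.zeros(n + 1)
    number = np.zeros(n + 1)
    biomass = np.zeros(n + 1)
    trunc = np.zeros(n + 1)
    S = float(S0)

    def uptake_sum():
        return float(np.sum(w_u(eng.x) * eng.m)) if eng.x.size else 0.0

    def halved(t, h, S, depth):
        S1 = substep(t, 0.5 * h, S, depth + 1)
        return substep(t + 0.5 * h, 0.5 * h, S1, depth + 1)

    def substep(t, h, S, depth=0):
        """One splitting substep; returns the updated substrate."""
        W0 = uptake_sum()
        S_half = S + 0.5 * h * (ch.D * (ch.S_ext - S) - ch.gamma * u(S) * W0)
        if S_half < 0 and depth < max_halvings:
            return halved(t, h, S, depth)
        S_half = max(S_half, 0.0)
        saved = (eng.x.copy(), eng.m.copy(), eng.truncated_mass)
        eng.step(t, h, lambda _t, _S=S_half: _S, spawn=True)
        W1 = uptake_sum()
        S_new = S + h * (ch.D * (ch.S_ext - S_half) - ch.gamma * u(S_half) * 0.5 * (W0 + W1))
        if S_new < 0 and depth < max_halvings:
            # step rejection: restore the population and retry with halved dt
            eng.x, eng.m, eng.truncated_mass = saved
            return halved(t, h, S, depth)
        return max(S_new, 0.0)

    for j in range(n + 1):
        Sv[j] = S
        if weights is not None:
            N[j] = np.array([float(np.sum(wi(eng.x) * eng.m)) if eng.x.size else 0.0
                             for wi in weights])
        number[j] = eng.m.sum()
        biomass[j] = float(np.sum(eng.x * eng.m)) if eng.x.size else 0.0
        trunc[j] = eng.truncated_mass
        if j < n:
            S = substep(t_grid[j], dt, S)

    return CoupledResult(
        t=t_grid, S=Sv, N=N,
        output_names=weights.names if weights is not None else [],
        total_number=number, total_biomass=biomass, truncated_mass=trunc,
        final_state=eng.measure(t_grid[-1]),
        meta={"dt": dt, "merge_dx": merge_dx, "S0": S0},
    )


# --------------------------------------------------------------------------
# trajectory comparison
# --------------------------------------------------------------------------

def compare_trajectories(series: dict, reference: dict, names: Sequence[str]) -> dict:
    """Per-component sup-norm relative error max_t |a - ref| / max_t |ref|.

    Both inputs are mappings name -> array on a common time grid."""
    report = {}
    for name in names:
        a = np.asarray(series[name], dtype=float)
        r = np.asarray(reference[name], dtype=float)
        if a.shape != r.shape:
            raise ConfigError(f"series {name!r} not on a common grid")
        denom = float(np.abs(r).max())
        report[name] = float(np.abs(a - r).max()) / max(denom, 1e-300)
    report["max"] = max(report.values()) if names else 0.0
    return report


def mass_balance_deviation(gamma: float, X: np.ndarray, S: np.ndarray, S_ext: float) -> np.ndarray:
    """The conserved chemostat combination gamma X + S - S_ext, which
    decays at exactly rate D in the reduced system."""
    return gamma * np.asarray(X, dtype=float) + np.asarray(S, dtype=float) - S_ext
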