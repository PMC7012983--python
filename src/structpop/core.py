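"""Model ingredients for physiologically structured populations.

A structured population model is specified at the individual level: an
i-state space (here one-dimensional, e.g. cell size or volume), a growth
rate ``g(x, E)``, a death rate ``mu(x, E)`` and a birth kernel
``beta(x, E, .)`` giving the rate at which an individual in state ``x``
produces offspring with given states-at-birth, all modulated by a scalar
environmental condition ``E`` (for the chemostat models: the substrate
concentration ``S``).

From these ingredients this module builds the three primitives that the
renewal-equation formulation needs:

* the i-state flow ``X_E(t, s, xi)`` (deterministic development),
* the survival probability ``F_E(t, s, xi)``,
* the generation kernel ``lambda_E(t, s)(xi, .)`` — the rate at which an
  individual that had state ``xi`` at time ``s`` produces offspring at
  time ``t``, as a list of atoms on the set of birth states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp


class ModelError(ValueError):
    """A model ingredient is invalid or produced a non-finite value."""


class ConfigError(ValueError):
    """A configuration value is malformed or inconsistent."""


# --------------------------------------------------------------------------
# i-state space and environment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IStateSpace:
    """Interval of admissible individual states.

    ``birth_state`` is the fixed state-at-birth ``x_b`` for point-birth
    kernels, or ``None`` when the birth state is derived from the mother
    (fission: offspring at ``x/2``).  For fission models ``x_min`` must be
    positive so that halving stays representable; offspring that would fall
    below ``x_min`` are deposited at ``x_min`` and the lost displacement is
    reported as truncated mass.
    """

    x_min: float
    x_max: float
    birth_state: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max):
            raise ConfigError(f"x_min must be < x_max, got [{self.x_min}, {self.x_max}]")
        if self.birth_state is not None and not (
            self.x_min <= self.birth_state <= self.x_max
        ):
            raise ConfigError(
                f"birth state {self.birth_state} outside [{self.x_min}, {self.x_max}]"
            )
        if self.birth_state is None and self.x_min <= 0:
            raise ConfigError("fission models require x_min > 0")

    def contains(self, x: float) -> bool:
        return self.x_min <= x <= self.x_max

    def clip(self, x):
        return np.clip(x, self.x_min, self.x_max)


class Environment:
    """Scalar environmental condition.

    ``prescribed`` environments are known functions of time.  ``feedback``
    environments evolve by an ODE coupled to population outputs (the
    chemostat); their trajectory becomes available only after a coupled
    simulation has been run and attached.
    """

    mode: str

    def at(self, t):  # pragma: no cover - abstract
        raise NotImplementedError


class PrescribedEnvironment(Environment):
    mode = "prescribed"

    def __init__(self, value: float | Callable[[float], float]):
        if callable(value):
            self._fn = value
        else:
            v = float(value)
            self._fn = lambda t: v

    def at(self, t):
        return self._fn(t)


class FeedbackEnvironment(Environment):
    """Environment driven by a feedback ODE (chemostat substrate).

    Holds the chemostat configuration and the initial value; the realized
    trajectory is attached by the coupled simulator, after which ``at``
    interpolates it.
    """

    mode = "feedback"

    def __init__(self, chemostat, S0: float):
        if S0 < 0:
            raise ConfigError("initial substrate must be non-negative")
        self.chemostat = chemostat
        self.S0 = float(S0)
        self._t = None
        self._S = None

    def attach_trajectory(self, t_grid, S_values) -> None:
        t = np.asarray(t_grid, dtype=float)
        S = np.asarray(S_values, dtype=float)
        if t.shape != S.shape:
            raise ConfigError("trajectory grids must have equal length")
        self._t, self._S = t, S

    def at(self, t):
        if self._t is None:
            raise ModelError(
                "feedback environment has no realized trajectory yet; "
                "run a coupled simulation first"
            )
        return np.interp(t, self._t, self._S)


def constant_environment(value: float) -> PrescribedEnvironment:
    return PrescribedEnvironment(float(value))


# --------------------------------------------------------------------------
# birth kernels
# --------------------------------------------------------------------------

class BirthKernel:
    """Rate measure ``beta(x, E, .)`` of offspring production.

    The kernel is exposed through three views used by different layers:

    * ``atoms(x, E)`` — list of ``(location, rate)`` atoms of the positive
      part of the measure (scalar ``x``),
    * vectorized ``offspring(x_array, E)`` for the cohort engine,
    * ``pairing(w, x, E)`` — the closed form of ``<w, beta>(x, E)``,
      including any negative (mother-removal) part,
    * ``extra_removal(x, E)`` — removal rate carried inside the kernel
      rather than inside ``mu`` (nonzero only for the net fission form
      ``2 delta_{x/2} - delta_x``).
    """

    def atoms(self, x: float, E: float) -> list[tuple[float, float]]:
        locs, rates = self.offspring(np.atleast_1d(float(x)), E)
        return [(float(l), float(r)) for l, r in zip(locs[:, 0], rates[:, 0])]

    def offspring(self, x, E):  # pragma: no cover - abstract
        """Return (locations, rates), each of shape (n_atoms, len(x))."""
        raise NotImplementedError

    def pairing(self, w, x, E):  # pragma: no cover - abstract
        raise NotImplementedError

    def extra_removal(self, x, E):
        return np.zeros_like(np.asarray(x, dtype=float))


class ZeroKernel(BirthKernel):
    """No reproduction (pure transport-degradation model)."""

    def offspring(self, x, E):
        x = np.asarray(x, dtype=float)
        return np.zeros((0, x.size)), np.zeros((0, x.size))

    def pairing(self, w, x, E):
        return np.zeros_like(np.asarray(x, dtype=float))


class PointBirthKernel(BirthKernel):
    """Single state-at-birth: ``beta(x, E, .) = beta0(x, E) delta_{x_b}``."""

    def __init__(self, beta0: Callable[[float, float], float], x_b: float):
        self.beta0 = beta0
        self.x_b = float(x_b)

    def offspring(self, x, E):
        x = np.asarray(x, dtype=float)
        rates = np.asarray(self.beta0(x, E), dtype=float) * np.ones_like(x)
        return np.full((1, x.size), self.x_b), rates[None, :]

    def pairing(self, w, x, E):
        x = np.asarray(x, dtype=float)
        return np.asarray(w(np.full_like(x, self.x_b)), dtype=float) * self.beta0(x, E)


class FissionKernel(BirthKernel):
    """Binary fission into equal halves with success probability ``p``.

    ``beta(x, E, .) = 2 p(x, E) beta0(x, E) delta_{x/2}``; an unsuccessful
    division kills the mother without offspring.  Mother removal (at the
    full attempt rate ``beta0``) is accounted for in the model's death
    rate, not here.
    """

    def __init__(self, beta0, p=None):
        self.beta0 = beta0
        self.p = p if p is not None else (lambda x, E: np.ones_like(np.asarray(x, float)))

    def offspring(self, x, E):
        x = np.asarray(x, dtype=float)
        p = np.asarray(self.p(x, E), dtype=float) * np.ones_like(x)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ModelError("fission success probability outside [0, 1]")
        rates = 2.0 * p * np.asarray(self.beta0(x, E), dtype=float) * np.ones_like(x)
        return (x / 2.0)[None, :], rates[None, :]

    def pairing(self, w, x, E):
        x = np.asarray(x, dtype=float)
        p = np.asarray(self.p(x, E), dtype=float) * np.ones_like(x)
        return 2.0 * p * np.asarray(self.beta0(x, E), dtype=float) * w(x / 2.0)


class FissionNetKernel(BirthKernel):
    """Net fission kernel ``beta0(x, E) (2 delta_{x/2} - delta_x)``.

    The disappearance of the mother is part of the kernel itself; for
    simulation it is handled as an extra removal rate ``beta0`` so that all
    transported masses stay non-negative.
    """

    def __init__(self, beta0):
        self.beta0 = beta0

    def offspring(self, x, E):
        x = np.asarray(x, dtype=float)
        rates = 2.0 * np.asarray(self.beta0(x, E), dtype=float) * np.ones_like(x)
        return (x / 2.0)[None, :], rates[None, :]

    def pairing(self, w, x, E):
        x = np.asarray(x, dtype=float)
        b0 = np.asarray(self.beta0(x, E), dtype=float) * np.ones_like(x)
        return (2.0 * np.asarray(w(x / 2.0), dtype=float) - np.asarray(w(x), dtype=float)) * b0

    def extra_removal(self, x, E):
        x = np.asarray(x, dtype=float)
        return np.asarray(self.beta0(x, E), dtype=float) * np.ones_like(x)


class SeparableKernel(BirthKernel):
    """Finite-sum kernel ``beta(x, E, .) = sum_j beta_j(E, .) w_j(x)``.

    Each component measure ``beta_j(E, .)`` is a list of atoms with fixed
    locations in the birth-state set and E-dependent masses.
    """

    def __init__(self, components: Sequence[tuple[Callable, Sequence[tuple[float, Callable]]]]):
        # components: [(w_j, [(location, mass_fn_of_E), ...]), ...]
        self.components = [
            (wj, [(float(loc), mfn) for loc, mfn in atoms]) for wj, atoms in components
        ]

    def offspring(self, x, E):
        x = np.asarray(x, dtype=float)
        locs, rates = [], []
        for wj, atoms in self.components:
            wx = np.asarray(wj(x), dtype=float) * np.ones_like(x)
            for loc, mfn in atoms:
                locs.append(np.full(x.size, loc))
                rates.append(float(mfn(E)) * wx)
        if not locs:
            return np.zeros((0, x.size)), np.zeros((0, x.size))
        return np.stack(locs), np.stack(rates)

    def pairing(self, w, x, E):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for wj, atoms in self.components:
            wx = np.asarray(wj(x), dtype=float) * np.ones_like(x)
            s = sum(float(mfn(E)) * float(w(np.asarray(loc))) for loc, mfn in atoms)
            out = out + s * wx
        return out


# --------------------------------------------------------------------------
# rate set and model bundle
# --------------------------------------------------------------------------

@dataclass
class RateSet:
    """Growth rate, death rate and birth kernel of a structured model."""

    g: Callable[[np.ndarray, float], np.ndarray]
    mu: Callable[[np.ndarray, float], np.ndarray]
    beta: BirthKernel

    def mu_effective(self, x, E):
        """Death rate including any mother removal carried by the kernel."""
        x = np.asarray(x, dtype=float)
        return (
            np.asarray(self.mu(x, E), dtype=float) * np.ones_like(x)
            + self.beta.extra_removal(x, E)
        )

    def validate(self, space: IStateSpace, E_samples: Sequence[float]) -> None:
        xs = np.linspace(space.x_min, space.x_max, 17)
        for E in E_samples:
            gv = np.asarray(self.g(xs, E), dtype=float) * np.ones_like(xs)
            mv = np.asarray(self.mu(xs, E), dtype=float) * np.ones_like(xs)
            if not np.all(np.isfinite(gv)):
                raise ModelError(f"growth rate non-finite at E={E}")
            if not np.all(np.isfinite(mv)):
                raise ModelError(f"death rate non-finite at E={E}")
            if np.any(mv < 0):
                raise ModelError(f"negative death rate at E={E}")


@dataclass
class StructuredModel:
    """Full ingredient list of a physiologically structured model."""

    space: IStateSpace
    rates: RateSet
    name: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self, E_samples: Sequence[float] = (1.0,)) -> "StructuredModel":
        self.rates.validate(self.space, E_samples)
        return self


# --------------------------------------------------------------------------
# flow, survival, generation kernel
# --------------------------------------------------------------------------

@dataclass
class FlowResult:
    """i-state trajectory ``X_E(t, s, xi)`` on a time grid."""

    t: np.ndarray
    x: np.ndarray
    s: float
    xi: float
    exited: bool = False

    def at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.x))


def flow(
    g: Callable,
    environment: Environment,
    s: float,
    xi: float,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    space: IStateSpace | None = None,
) -> FlowResult:
    """Solve dx/dtau = g(x, E(tau)), x(s) = xi on ``t_grid``.

    The trajectory is clipped to the i-state interval (when given) and
    flagged, never silently truncated.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != s:
        raise ConfigError("t_grid[0] must equal the start time s")
    if np.any(np.diff(t_grid) < 0):
        raise ConfigError("t_grid must be sorted")
    if space is not None and not space.contains(xi):
        raise ConfigError(f"start state {xi} outside the i-state interval")

    def rhs(t, y):
        v = g(y[0], environment.at(t))
        if not np.isfinite(v):
            raise ModelError(f"growth rate non-finite at x={y[0]}, t={t}")
        return [v]

    if t_grid[-1] == s:
        return FlowResult(t=t_grid, x=np.full_like(t_grid, xi), s=s, xi=xi)
    sol = solve_ivp(rhs, (s, t_grid[-1]), [xi], t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise ModelError(f"flow integration failed: {sol.message}")
    x = sol.y[0]
    exited = False
    if space is not None:
        if np.any(x < space.x_min - 1e-12) or np.any(x > space.x_max + 1e-12):
            exited = True
            x = space.clip(x)
    return FlowResult(t=t_grid, x=x, s=s, xi=xi, exited=exited)


def survival(
    mu: Callable,
    environment: Environment,
    s: float,
    xi: float,
    t: float,
    flow_trajectory: FlowResult,
    include_extra: Callable | None = None,
) -> float:
    """Survival probability exp(-int_s^t mu(X(tau), E(tau)) dtau).

    Quadrature is trapezoidal on the flow's time grid restricted to
    ``[s, t]``.  ``include_extra`` adds a further removal rate (used for
    net fission kernels that carry mother removal inside the kernel).
    """
    prof = survival_profile(mu, environment, flow_trajectory, include_extra)
    if t < s or t > flow_trajectory.t[-1] + 1e-12:
        raise ConfigError("requested time outside the flow trajectory")
    return float(np.interp(t, flow_trajectory.t, prof))


def survival_profile(
    mu: Callable,
    environment: Environment,
    flow_trajectory: FlowResult,
    include_extra: Callable | None = None,
) -> np.ndarray:
    """Cumulative survival along the whole flow grid."""
    tg, xg = flow_trajectory.t, flow_trajectory.x
    Ev = np.array([environment.at(ti) for ti in tg])
    mv = np.array(
        [float(mu(xg[i], Ev[i])) for i in range(tg.size)], dtype=float
    )
    if include_extra is not None:
        mv = mv + np.array([float(include_extra(xg[i], Ev[i])) for i in range(tg.size)])
    if np.any(mv < 0):
        raise ModelError("negative death rate encountered along trajectory")
    integral = np.concatenate(
        ([0.0], np.cumsum(0.5 * (mv[1:] + mv[:-1]) * np.diff(tg)))
    )
    return np.exp(-integral)


def generation_kernel(
    rates: RateSet,
    environment: Environment,
    s: float,
    xi: float,
    t: float,
    flow_trajectory: FlowResult | None = None,
    space: IStateSpace | None = None,
) -> list[tuple[float, float]]:
    """Atoms of ``lambda_E(t, s)(xi, .) = beta(X, E(t), .) F_E(t, s, xi)``.

    For net fission kernels the mother-removal part of the kernel is folded
    into the survival factor, so all returned atom masses are >= 0.
    """
    if flow_trajectory is None:
        n = max(16, int(math.ceil((t - s) / 0.05)) + 1)
        flow_trajectory = flow(
            rates.g, environment, s, xi, np.linspace(s, t, n), space=space
        )
    X = flow_trajectory.at(t)
    F = survival(
        rates.mu, environment, s, xi, t, flow_trajectory,
        include_extra=rates.beta.extra_removal,
    )
    E_t = environment.at(t)
    return [(loc, rate * F) for loc, rate in rates.beta.atoms(X, E_t)]
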