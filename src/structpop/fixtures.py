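"""Initial-history fixtures and environment scripts.

Birth histories are discretized into weighted atoms; densities are
sampled at atom midpoints and normalized exactly, so the realized total
mass matches the specification to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigError, PrescribedEnvironment
from .renewal import BirthHistory, HistoryAtom


@dataclass
class FixtureSpec:
    """Shape of an initial population / birth history.

    shapes: ``point`` (single cohort at ``state``), ``uniform_band``
    (``n_atoms`` equal cohorts spread over [state_lo, state_hi]),
    ``gaussian`` (truncated-Gaussian density over states, discretized
    into ``n_atoms`` midpoint cells).
    """

    shape: str = "point"
    total_mass: float = 1.0
    s: float = 0.0
    state: float = 1.0
    state_lo: float = 0.5
    state_hi: float = 2.0
    mean: float = 1.0
    sigma: float = 0.25
    n_atoms: int = 100

    def __post_init__(self):
        if self.total_mass < 0:
            raise ConfigError("total mass must be non-negative")


def make_history(spec: FixtureSpec) -> BirthHistory:
    if spec.shape == "point":
        return BirthHistory(spec.s, [HistoryAtom(spec.s, spec.state, spec.total_mass)])
    if spec.shape == "uniform_band":
        xs = np.linspace(spec.state_lo, spec.state_hi, spec.n_atoms)
        m = spec.total_mass / spec.n_atoms
        return BirthHistory(spec.s, [HistoryAtom(spec.s, float(x), m) for x in xs])
    if spec.shape == "gaussian":
        edges = np.linspace(spec.state_lo, spec.state_hi, spec.n_atoms + 1)
        mids = 0.5 * (edges[1:] + edges[:-1])
        dens = np.exp(-0.5 * ((mids - spec.mean) / spec.sigma) ** 2)
        w = dens * np.diff(edges)
        w = w * (spec.total_mass / w.sum())  # exact normalization
        return BirthHistory(
            spec.s, [HistoryAtom(spec.s, float(x), float(m)) for x, m in zip(mids, w)]
        )
    raise ConfigError(f"unknown fixture shape {spec.shape!r}")


@dataclass
class EnvironmentScript:
    """Prescribed environment: constant, step, or a stored trajectory."""

    kind: str = "constant"
    value: float = 1.0
    value_after: float = 1.0
    t_step: float = 0.0
    t_values: np.ndarray | None = None
    E_values: np.ndarray | None = None


def make_environment(script: EnvironmentScript) -> PrescribedEnvironment:
    if script.kind == "constant":
        return PrescribedEnvironment(script.value)
    if script.kind == "step":
        v0, v1, ts = script.value, script.value_after, script.t_step
        return PrescribedEnvironment(lambda t: v0 if t < ts else v1)
    if script.kind == "stored":
        if script.t_values is None or script.E_values is None:
            raise ConfigError("stored environment needs t_values and E_values")
        t = np.asarray(script.t_values, dtype=float)
        E = np.asarray(script.E_values, dtype=float)
        return PrescribedEnvironment(lambda tt: float(np.interp(tt, t, E)))
    raise ConfigError(f"unknown environment script {script.kind!r}")
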