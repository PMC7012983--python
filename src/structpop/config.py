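"""Declarative model configuration.

Models, chemostats and run settings are described in YAML with rate
expressions in a restricted arithmetic grammar (variables ``x`` and ``E``
— alias ``S`` — plus named parameters and standard elementary functions).
Expressions are parsed once with sympy and compiled to vectorized
callables; derivatives needed by the reducibility machinery are obtained
symbolically, so the expression path and the callable path of the library
agree to rounding.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import sympy as sp
import yaml
from sympy.parsing.sympy_parser import parse_expr

from .core import (
    ConfigError,
    Environment,
    FeedbackEnvironment,
    FissionKernel,
    FissionNetKernel,
    IStateSpace,
    PointBirthKernel,
    PrescribedEnvironment,
    RateSet,
    SeparableKernel,
    StructuredModel,
    ZeroKernel,
)
from .weights import Weight
from .zoo import ChemostatConfig

_ALLOWED_FUNCS = {
    name: getattr(sp, name)
    for name in (
        "sin", "cos", "tan", "asin", "acos", "atan", "sinh", "cosh", "tanh",
        "exp", "log", "sqrt", "Abs", "Min", "Max", "sign", "pi", "E",
    )
    if hasattr(sp, name)
}
_ALLOWED_FUNCS["pi"] = sp.pi
# constructors the sympy parser itself emits; not user-callable names
_PARSER_GLOBALS = {
    "Symbol": sp.Symbol, "Integer": sp.Integer, "Float": sp.Float,
    "Rational": sp.Rational,
}


def parse_expression(text: str, variables: tuple[str, ...], params: dict | None = None) -> sp.Expr:
    """Parse an arithmetic expression over the given variables and
    parameters; any other name is rejected (no arbitrary code execution)."""
    params = params or {}
    local = {v: sp.Symbol(v) for v in variables}
    if "E" in variables:
        local.setdefault("S", local["E"])  # substrate alias
    try:
        expr = parse_expr(str(text), local_dict=local,
                          global_dict={**_PARSER_GLOBALS, **_ALLOWED_FUNCS})
    except Exception as exc:
        raise ConfigError(f"cannot parse expression {text!r}: {exc}") from exc
    expr = expr.subs({sp.Symbol(k): sp.Float(v) for k, v in params.items()})
    extra = expr.free_symbols - {local[v] for v in variables}
    if extra:
        names = ", ".join(sorted(str(s) for s in extra))
        raise ConfigError(f"unknown names in expression {text!r}: {names}")
    return expr


def compile_rate(text: str, params: dict | None = None,
                 variables: tuple[str, ...] = ("x", "E")) -> Callable:
    """Compile an expression in (x, E) to a vectorized callable."""
    expr = parse_expression(text, variables, params)
    syms = [sp.Symbol(v) for v in variables]
    fn = sp.lambdify(syms, expr, modules="numpy")

    if len(variables) == 1:
        def wrapped(x, *_unused, _fn=fn):
            x = np.asarray(x, dtype=float)
            return np.asarray(_fn(x), dtype=float) * np.ones_like(x)
    else:
        def wrapped(x, E=0.0, _fn=fn):
            x = np.asarray(x, dtype=float)
            return np.asarray(_fn(x, E), dtype=float) * np.ones_like(x)

    return wrapped


def compile_scalar(text: str, params: dict | None = None, variable: str = "t") -> Callable:
    expr = parse_expression(text, (variable,), params)
    fn = sp.lambdify(sp.Symbol(variable), expr, modules="numpy")
    return lambda v, _fn=fn: float(_fn(v))


def parse_weight(text: str, params: dict | None = None) -> Weight:
    """Weight function from an expression in x, with symbolic derivative."""
    expr = parse_expression(text, ("x",), params)
    xsym = sp.Symbol("x")
    fn = sp.lambdify(xsym, expr, modules="numpy")
    dfn = sp.lambdify(xsym, sp.diff(expr, xsym), modules="numpy")

    def w(x, _fn=fn):
        x = np.asarray(x, dtype=float)
        return np.asarray(_fn(x), dtype=float) * np.ones_like(x)

    def dw(x, _fn=dfn):
        x = np.asarray(x, dtype=float)
        return np.asarray(_fn(x), dtype=float) * np.ones_like(x)

    return Weight(w, dw, name=str(text))


def parse_weight_list(text: str, params: dict | None = None) -> list[Weight]:
    """Comma-separated weight expressions, split at top-level commas."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return [parse_weight(p.strip(), params) for p in parts if p.strip()]


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Solver settings for a simulation run (the solvers themselves are
    deterministic; the seed only drives randomized fixtures/tests)."""

    horizon: float = 10.0
    dt: float = 0.005
    tol_gen: float = 1e-8
    max_generations: int = 200
    merge_dx: float | None = 2e-3
    grid_points: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.horizon <= 0 or self.tol_gen <= 0:
            raise ConfigError("horizon, dt and tol_gen must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class ModelBundle:
    model: StructuredModel
    environment: Environment | None
    chemostat: ChemostatConfig | None
    run: RunConfig
    raw: dict
    text_hash: str
    initial: dict = field(default_factory=dict)


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_yaml(source) -> tuple[dict, str]:
    if isinstance(source, (str, Path)) and Path(source).exists():
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    elif isinstance(source, dict):
        text = yaml.safe_dump(source, sort_keys=True)
    else:
        raise ConfigError(f"cannot read configuration from {source!r}")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    return data, text


def load_chemostat(source) -> ChemostatConfig:
    data, _ = _load_yaml(source)
    d = data.get("chemostat", data)
    try:
        return ChemostatConfig(
            D=float(d["D"]), S_ext=float(d["S_ext"]), gamma=float(d["gamma"]),
            a=float(d["a"]), b=float(d["b"]),
        )
    except KeyError as exc:
        raise ConfigError(f"chemostat section missing key {exc}") from exc


def _build_kernel(section: dict | None, params: dict, space: IStateSpace):
    if not section or section.get("form", "none") == "none":
        return ZeroKernel()
    form = section["form"]
    if form == "point":
        if space.birth_state is None:
            raise ConfigError("point-birth kernels need istate.birth_state")
        return PointBirthKernel(compile_rate(section["beta0"], params), space.birth_state)
    if form == "fission":
        p = compile_rate(section["p"], params) if "p" in section else None
        return FissionKernel(compile_rate(section["beta0"], params), p)
    if form == "fission_net":
        return FissionNetKernel(compile_rate(section["beta0"], params))
    if form == "separable":
        comps = []
        for comp in section["components"]:
            wj = compile_rate(comp["w"], params, variables=("x",))
            atoms = [
                (float(at["loc"]), compile_scalar(str(at["mass"]), params, variable="E"))
                for at in comp["atoms"]
            ]
            comps.append((lambda x, _w=wj: _w(x), atoms))
        return SeparableKernel(comps)
    raise ConfigError(f"unknown birth kernel form {form!r}")


def load_model(source) -> ModelBundle:
    """Build a structured model (and environment) from a config mapping."""
    data, text = _load_yaml(source)
    params = {k: float(v) for k, v in (data.get("params") or {}).items()}
    try:
        ist = data["istate"]
        space = IStateSpace(
            x_min=float(ist["x_min"]), x_max=float(ist["x_max"]),
            birth_state=(float(ist["birth_state"]) if ist.get("birth_state") is not None else None),
        )
    except KeyError as exc:
        raise ConfigError(f"istate section missing key {exc}") from exc

    if "catalogue" in data:
        model = _catalogue_model(data, params, space)
    else:
        try:
            rates_sec = data["rates"]
            g = compile_rate(rates_sec["g"], params)
            mu = compile_rate(rates_sec["mu"], params)
        except KeyError as exc:
            raise ConfigError(f"rates section missing key {exc}") from exc
        beta = _build_kernel(data.get("birth_kernel"), params, space)
        model = StructuredModel(space=space, rates=RateSet(g=g, mu=mu, beta=beta),
                                name=str(data.get("name", "")))

    chem = None
    if "chemostat" in data:
        chem = load_chemostat({"chemostat": data["chemostat"]})
        # feedback coupling: substrate consumed at gamma * rate(S) * int w dm;
        # defaults to Michaelis-Menten uptake weighted by biomass
        from .weights import Weight, w_x
        from .zoo import ChemostatCoupling

        coup = data.get("coupling") or {}
        if "weight" in coup:
            uw = parse_weight(coup["weight"], params)
        else:
            uw = w_x
        if "rate" in coup:
            ur_fn = compile_rate(coup["rate"], params, variables=("E",))
            ur = lambda S, _f=ur_fn: float(_f(np.asarray(S, dtype=float)))
        else:
            ur = chem.monod
        model.meta.setdefault("coupling", ChemostatCoupling(uptake_weight=uw,
                                                            uptake_rate=ur))
        model.meta.setdefault("chemostat", chem)

    env = None
    env_sec = data.get("environment")
    if env_sec:
        mode = env_sec.get("mode", "prescribed")
        if mode == "prescribed":
            env = PrescribedEnvironment(compile_scalar(str(env_sec["value"]), params, "t"))
        elif mode == "feedback":
            if chem is None:
                raise ConfigError("feedback environment requires a chemostat section")
            env = FeedbackEnvironment(chem, float(env_sec.get("S0", chem.S_ext)))
        else:
            raise ConfigError(f"unknown environment mode {mode!r}")

    if "catalogue" not in data:
        # catalogue constructions may carry negative rates by design
        # (positivity is reported, not enforced)
        model.validate(E_samples=[env.S0] if isinstance(env, FeedbackEnvironment) else [1.0])
    run = RunConfig.from_dict(data.get("run") or {})
    return ModelBundle(
        model=model, environment=env, chemostat=chem, run=run, raw=data,
        text_hash=config_hash(text), initial=data.get("initial") or {},
    )


def _catalogue_model(data: dict, params: dict, space: IStateSpace) -> StructuredModel:
    """Rebuild a catalogue-family model from its parameter expressions."""
    from .catalogue import F2Params, F3Params, f2_build, f3_build

    sec = data["catalogue"]
    family = str(sec["family"]).upper()
    k = int(sec["k"])

    def fx(key, default=None):
        if key not in sec:
            if default is None:
                raise ConfigError(f"catalogue section missing {key!r}")
            return default
        return compile_rate(sec[key], params, variables=("x",))

    def fE(key, default=None):
        if key not in sec:
            if default is None:
                raise ConfigError(f"catalogue section missing {key!r}")
            return default
        return compile_scalar(str(sec[key]), params, variable="E")

    x_b = float(sec.get("x_b", space.x_min))
    common = dict(k=k, gamma0=fx("gamma0", lambda x: np.zeros_like(np.asarray(x, float))),
                  mu0=fE("mu0", lambda E: 0.0), v0=fx("v0"),
                  x_b=x_b, x_lo=space.x_min, x_hi=space.x_max)
    if family == "F2":
        p = F2Params(v1=fE("v1"), Lam=np.asarray(sec["Lam"], dtype=float),
                     w_xb=np.asarray(sec["w_xb"], dtype=float), **common)
        cm = f2_build(p)
    elif family == "F3":
        p = F3Params(v1=fE("v1"), v2=fE("v2", lambda E: 0.0), v3=fE("v3", lambda E: 0.0),
                     **common)
        cm = f3_build(p)
    else:
        raise ConfigError(f"unknown catalogue family {family!r}")
    model = StructuredModel(space=space, rates=RateSet(g=cm.g, mu=cm.mu, beta=ZeroKernel()),
                            name=f"catalogue_{family}", meta={"catalogue": cm})
    return model
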