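"""Catalogue of transport-degradation models with exact finite-dimensional
state representation.

Two families of growth/death-rate pairs admit a k-vector of output weights
``w`` and a matrix ``H(E)`` solving the reduction identity

    g(x,E) w'(x) - mu(x,E) w(x) = H(E) w(x):

* ``F2`` ("physiological age"): g separates as v0(x) v1(E); the weights are
  a matrix exponential of the rescaled i-state zeta(x) = int_{x_b}^x dy/v0.
* ``F3`` ("generalised von Bertalanffy growth"): g is v0 times a quadratic
  polynomial in zeta with E-dependent coefficients; the weights are powers
  of zeta.

Both are verified numerically on construction.  The identity extends to
full models with reproduction whenever all weight components are conserved
in the reproduction process (then mu is replaced by mu - beta0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import expm

from .core import ModelError, StructuredModel
from .weights import Weight, WeightFamily

VERIFY_TOL = 1e-10


# --------------------------------------------------------------------------
# quadrature helpers
# --------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)


def _segment_integral(f: Callable, a: float, b: float, n_sub: int = 4) -> float:
    """Composite 12-point Gauss-Legendre integral of f over [a, b]."""
    edges = np.linspace(a, b, n_sub + 1)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        total += half * float(np.sum(_GL_WEIGHTS * np.asarray(f(mid + half * _GL_NODES), dtype=float)))
    return total


def cumulative_integral(f: Callable, x0: float, xs) -> np.ndarray:
    """int_{x0}^{x} f(y) dy for each x in xs (xs need not be sorted).

    The base point is inserted into the sorted sequence so that every
    quadrature segment stays short (one long jump from x0 would
    concentrate the error)."""
    xs = np.asarray(xs, dtype=float)
    order = np.argsort(xs)
    pts = np.concatenate((xs[order], [x0]))
    pts = np.unique(pts)
    segs = np.array(
        [_segment_integral(f, pts[i], pts[i + 1]) for i in range(len(pts) - 1)]
    )
    cum = np.concatenate(([0.0], np.cumsum(segs)))
    cum = cum - np.interp(x0, pts, cum)  # anchor F(x0) = 0
    out = np.empty_like(xs)
    out[order] = np.interp(xs[order], pts, cum)
    return out


def tabulated_antiderivative(f: Callable, x0: float, x_lo: float, x_hi: float, n: int = 800):
    """Smooth cached antiderivative F(x) = int_{x0}^x f on [x_lo, x_hi]."""
    grid = np.linspace(x_lo, x_hi, n)
    vals = cumulative_integral(f, x0, grid)
    return CubicSpline(grid, vals)


# --------------------------------------------------------------------------
# parameter bundles
# --------------------------------------------------------------------------

@dataclass
class F2Params:
    """Physiological-age family parameters.

    g = v0(x) v1(E); mu = gamma0(x) g + mu0(E);
    w(x) = exp(int gamma0) expm(zeta(x) Lam) w_xb;  H = v1 Lam - mu0 I.
    """

    k: int
    gamma0: Callable
    mu0: Callable
    v0: Callable
    v1: Callable
    Lam: np.ndarray
    w_xb: np.ndarray
    x_b: float
    x_lo: float
    x_hi: float

    def __post_init__(self):
        self.Lam = np.asarray(self.Lam, dtype=float)
        self.w_xb = np.asarray(self.w_xb, dtype=float)
        if self.k < 2:
            raise ModelError("catalogue families require k >= 2")
        if self.Lam.shape != (self.k, self.k) or self.w_xb.shape != (self.k,):
            raise ModelError("Lam must be k x k and w_xb of length k")


@dataclass
class F3Params:
    """Generalised von Bertalanffy family parameters.

    g = v0 (v1 + v2 zeta + v3 zeta^2);
    mu = gamma0 g + mu0 + (k-1) v3 zeta;  w_j = exp(int gamma0) zeta^{j-1}.
    """

    k: int
    gamma0: Callable
    mu0: Callable
    v0: Callable
    v1: Callable
    v2: Callable
    v3: Callable
    x_b: float
    x_lo: float
    x_hi: float

    def __post_init__(self):
        if self.k < 2:
            raise ModelError("catalogue families require k >= 2")


@dataclass
class CatalogueModel:
    """Constructed rates, weights and H for a catalogue family member."""

    family: str
    k: int
    g: Callable  # (x, E) -> array
    mu: Callable
    w: Callable  # x -> (k, n_x)
    dw: Callable
    H: Callable  # E -> (k, k)
    zeta: Callable
    weights: WeightFamily
    params: object
    verification_residual: float = np.nan
    meta: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# verification
# --------------------------------------------------------------------------

def verify_eq61(g, mu, w, dw, H, x_grid, E_samples) -> float:
    """Max scaled residual of g w' - mu w - H(E) w on the grid.

    The scale is the sup of |w| over the grid (at least 1), so a
    perturbation of mu by eps produces a residual of about eps.
    """
    x = np.asarray(x_grid, dtype=float)
    worst = 0.0
    for E in np.atleast_1d(E_samples):
        W = np.atleast_2d(w(x))
        dW = np.atleast_2d(dw(x))
        gv = np.asarray(g(x, E), dtype=float) * np.ones_like(x)
        mv = np.asarray(mu(x, E), dtype=float) * np.ones_like(x)
        R = gv[None, :] * dW - mv[None, :] * W - np.asarray(H(E)) @ W
        scale = max(1.0, float(np.abs(W).max()))
        worst = max(worst, float(np.abs(R).max()) / scale)
    return worst


def _positivity_flags(g, mu, x_grid, E_samples) -> dict:
    x = np.asarray(x_grid, dtype=float)
    neg_g = neg_mu = 0
    for E in np.atleast_1d(E_samples):
        neg_g += int(np.sum(np.asarray(g(x, E)) * np.ones_like(x) < 0))
        neg_mu += int(np.sum(np.asarray(mu(x, E)) * np.ones_like(x) < 0))
    total = x.size * np.atleast_1d(E_samples).size
    return {"negative_g_fraction": neg_g / total, "negative_mu_fraction": neg_mu / total}


# --------------------------------------------------------------------------
# F2 construction
# --------------------------------------------------------------------------

def _expm_stack(zeta_vals: np.ndarray, Lam: np.ndarray) -> np.ndarray:
    """expm(zeta Lam) per grid point, shape (n, k, k)."""
    return np.stack([expm(z * Lam) for z in zeta_vals])


def f2_build(
    params: F2Params,
    x_grid=None,
    E_samples=(0.5, 1.0, 2.0),
    verify_tol: float = VERIFY_TOL,
    zeta_fn: Callable | None = None,
) -> CatalogueModel:
    """Build and verify a physiological-age (F2) catalogue model."""
    p = params
    if x_grid is None:
        x_grid = np.linspace(p.x_lo, p.x_hi, 200)
    x_grid = np.asarray(x_grid, dtype=float)
    v0g = np.asarray(p.v0(x_grid), dtype=float) * np.ones_like(x_grid)
    if np.any(v0g <= 0):
        raise ModelError("v0 must be positive on the i-state interval")
    zeta = zeta_fn if zeta_fn is not None else tabulated_antiderivative(
        lambda y: 1.0 / np.asarray(p.v0(y), dtype=float), p.x_b, p.x_lo, p.x_hi
    )
    Gam = tabulated_antiderivative(
        lambda y: np.asarray(p.gamma0(y), dtype=float) * np.ones_like(np.asarray(y, float)),
        p.x_b, p.x_lo, p.x_hi,
    )

    def g(x, E):
        x = np.asarray(x, dtype=float)
        return np.asarray(p.v0(x), dtype=float) * np.ones_like(x) * float(p.v1(E))

    def mu(x, E):
        x = np.asarray(x, dtype=float)
        return np.asarray(p.gamma0(x), dtype=float) * np.ones_like(x) * g(x, E) + float(p.mu0(E))

    def w(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pre = np.exp(Gam(x))
        M = _expm_stack(np.asarray(zeta(x), dtype=float), p.Lam)  # (n, k, k)
        return (pre[:, None] * (M @ p.w_xb)).T  # (k, n)

    def dw(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pre = np.exp(Gam(x))
        M = _expm_stack(np.asarray(zeta(x), dtype=float), p.Lam)
        gam = np.asarray(p.gamma0(x), dtype=float) * np.ones_like(x)
        v0v = np.asarray(p.v0(x), dtype=float) * np.ones_like(x)
        base = (pre[:, None] * (M @ p.w_xb)).T
        extra = (pre[:, None] / v0v[:, None] * (M @ (p.Lam @ p.w_xb))).T
        return gam[None, :] * base + extra

    def H(E):
        return float(p.v1(E)) * p.Lam - float(p.mu0(E)) * np.eye(p.k)

    comps = [
        Weight(lambda x, i=i: w(x)[i], lambda x, i=i: dw(x)[i], name=f"f2_w{i + 1}")
        for i in range(p.k)
    ]
    fam = WeightFamily(comps)
    fam.check_rank(x_grid)
    res = verify_eq61(g, mu, w, dw, H, x_grid, E_samples)
    if not res < verify_tol:
        raise ModelError(f"F2 construction failed verification: residual {res:.3e}")
    return CatalogueModel(
        family="F2", k=p.k, g=g, mu=mu, w=w, dw=dw, H=H, zeta=zeta,
        weights=fam, params=p, verification_residual=res,
        meta=_positivity_flags(g, mu, x_grid, E_samples),
    )


# --------------------------------------------------------------------------
# F3 construction
# --------------------------------------------------------------------------

def f3_H0(k: int, v1: float, v2: float, v3: float) -> np.ndarray:
    """The F3 coupling matrix H0: row j has (j-1) v1 on the subdiagonal,
    (j-1) v2 on the diagonal and -(k-j) v3 on the superdiagonal."""
    H0 = np.zeros((k, k))
    for j in range(1, k + 1):
        i = j - 1
        if i - 1 >= 0:
            H0[i, i - 1] = (j - 1) * v1
        H0[i, i] = (j - 1) * v2
        if i + 1 < k:
            H0[i, i + 1] = -(k - j) * v3
    return H0


def f3_build(
    params: F3Params,
    x_grid=None,
    E_samples=(0.5, 1.0, 2.0),
    verify_tol: float = VERIFY_TOL,
    zeta_fn: Callable | None = None,
) -> CatalogueModel:
    """Build and verify a generalised von Bertalanffy (F3) catalogue model."""
    p = params
    if x_grid is None:
        x_grid = np.linspace(p.x_lo, p.x_hi, 200)
    x_grid = np.asarray(x_grid, dtype=float)
    v0g = np.asarray(p.v0(x_grid), dtype=float) * np.ones_like(x_grid)
    if np.any(v0g <= 0):
        raise ModelError("v0 must be positive on the i-state interval")
    zeta = zeta_fn if zeta_fn is not None else tabulated_antiderivative(
        lambda y: 1.0 / np.asarray(p.v0(y), dtype=float), p.x_b, p.x_lo, p.x_hi
    )
    Gam = tabulated_antiderivative(
        lambda y: np.asarray(p.gamma0(y), dtype=float) * np.ones_like(np.asarray(y, float)),
        p.x_b, p.x_lo, p.x_hi,
    )
    k = p.k

    def g(x, E):
        x = np.asarray(x, dtype=float)
        z = np.asarray(zeta(x), dtype=float)
        v0v = np.asarray(p.v0(x), dtype=float) * np.ones_like(x)
        return v0v * (float(p.v1(E)) + float(p.v2(E)) * z + float(p.v3(E)) * z ** 2)

    def mu(x, E):
        x = np.asarray(x, dtype=float)
        z = np.asarray(zeta(x), dtype=float)
        gam = np.asarray(p.gamma0(x), dtype=float) * np.ones_like(x)
        return gam * g(x, E) + float(p.mu0(E)) + (k - 1) * float(p.v3(E)) * z

    def w(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pre = np.exp(Gam(x))
        z = np.asarray(zeta(x), dtype=float)
        return np.stack([pre * z ** (j - 1) for j in range(1, k + 1)])

    def dw(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pre = np.exp(Gam(x))
        z = np.asarray(zeta(x), dtype=float)
        gam = np.asarray(p.gamma0(x), dtype=float) * np.ones_like(x)
        v0v = np.asarray(p.v0(x), dtype=float) * np.ones_like(x)
        rows = []
        for j in range(1, k + 1):
            row = gam * pre * z ** (j - 1)
            if j >= 2:
                row = row + pre * (j - 1) * z ** (j - 2) / v0v
            rows.append(row)
        return np.stack(rows)

    def H(E):
        return f3_H0(k, float(p.v1(E)), float(p.v2(E)), float(p.v3(E))) - float(
            p.mu0(E)
        ) * np.eye(k)

    comps = [
        Weight(lambda x, i=i: w(x)[i], lambda x, i=i: dw(x)[i], name=f"f3_w{i + 1}")
        for i in range(k)
    ]
    fam = WeightFamily(comps)
    fam.check_rank(x_grid)
    res = verify_eq61(g, mu, w, dw, H, x_grid, E_samples)
    if not res < verify_tol:
        raise ModelError(f"F3 construction failed verification: residual {res:.3e}")
    return CatalogueModel(
        family="F3", k=k, g=g, mu=mu, w=w, dw=dw, H=H, zeta=zeta,
        weights=fam, params=p, verification_residual=res,
        meta=_positivity_flags(g, mu, x_grid, E_samples),
    )


# --------------------------------------------------------------------------
# conserved reproduction
# --------------------------------------------------------------------------

@dataclass
class ConservedReproductionResult:
    success: bool
    beta0: Callable | None
    max_spread: float

    def __bool__(self):
        return self.success


def conserved_reproduction_check(
    model: StructuredModel,
    weights: WeightFamily | Sequence[Weight],
    x_grid,
    E_samples=(1.0,),
    tol: float = 1e-8,
) -> ConservedReproductionResult:
    """Test whether all weight components are conserved in reproduction:
    <w, beta>(x, E) = beta0(x, E) w(x) for a common scalar factor beta0.

    On success the catalogue identity applies to the full model with mu
    replaced by mu - beta0."""
    if not isinstance(weights, WeightFamily):
        weights = WeightFamily(weights)
    x = np.asarray(x_grid, dtype=float)
    weights.check_rank(x)
    max_spread = 0.0
    for E in np.atleast_1d(E_samples):
        W = weights.values(x)
        P = np.stack([model.rates.beta.pairing(wi, x, E) for wi in weights])
        scale = max(1.0, float(np.abs(P).max()))
        # least-squares per-(x, E) common factor, then componentwise spread
        denom = np.sum(W * W, axis=0)
        b0 = np.sum(W * P, axis=0) / np.where(denom > 0, denom, 1.0)
        spread = np.abs(P - b0[None, :] * W).max() / scale
        max_spread = max(max_spread, float(spread))
    if max_spread >= tol:
        return ConservedReproductionResult(False, None, max_spread)

    w1 = weights[0]

    def beta0(xx, E):
        xx = np.asarray(xx, dtype=float)
        return model.rates.beta.pairing(w1, xx, E) / w1(xx)

    return ConservedReproductionResult(True, beta0, max_spread)


# --------------------------------------------------------------------------
# seeded random family draws (verification battery)
# --------------------------------------------------------------------------

def _random_poly(rng, lo, hi, degree=2, positive=False):
    if positive:
        c = rng.uniform(0.3, 1.0, size=degree + 1)
        c[1:] *= 0.3
        return lambda y, c=c: np.polyval(c[::-1], np.asarray(y, dtype=float))
    c = rng.uniform(lo, hi, size=degree + 1)
    return lambda y, c=c: np.polyval(c[::-1], np.asarray(y, dtype=float))


def random_f2_params(rng: np.random.Generator, k: int, x_lo=0.1, x_hi=2.0) -> F2Params:
    """Seeded random F2 parameter draw with v0 > 0 on the interval."""
    Lam = rng.uniform(-0.6, 0.6, size=(k, k))
    w_xb = rng.uniform(0.2, 1.0, size=k)
    return F2Params(
        k=k,
        gamma0=_random_poly(rng, -0.4, 0.4),
        mu0=_random_poly(rng, 0.0, 0.5, degree=1),
        v0=_random_poly(rng, 0, 0, positive=True),
        v1=_random_poly(rng, 0.2, 1.0, degree=1),
        Lam=Lam,
        w_xb=w_xb,
        x_b=x_lo,
        x_lo=x_lo,
        x_hi=x_hi,
    )


def random_f3_params(rng: np.random.Generator, k: int, x_lo=0.1, x_hi=2.0) -> F3Params:
    """Seeded random F3 parameter draw with v0 > 0 on the interval."""
    return F3Params(
        k=k,
        gamma0=_random_poly(rng, -0.4, 0.4),
        mu0=_random_poly(rng, 0.0, 0.5, degree=1),
        v0=_random_poly(rng, 0, 0, positive=True),
        v1=_random_poly(rng, 0.2, 1.0, degree=1),
        v2=_random_poly(rng, -0.5, 0.5, degree=1),
        v3=_random_poly(rng, -0.5, 0.5, degree=1),
        x_b=x_lo,
        x_lo=x_lo,
        x_hi=x_hi,
    )


def challenge_growth_rate(v1: float, v2: float, v3: float):
    """The trigonometric growth rate v1 (1+cos x) + v2 sin x + v3 (1-cos x).

    Despite appearances this is an F3 growth rate: with v0(x) = 1 + cos x
    and x_b = 0 the rescaled i-state is zeta(x) = tan(x/2), and
    v0 (v1 + v2 zeta + v3 zeta^2) collapses to the expression above via
    the half-angle identities."""
    return lambda x: (
        v1 * (1.0 + np.cos(x)) + v2 * np.sin(x) + v3 * (1.0 - np.cos(x))
    )


def challenge_f3_params(v1: float, v2: float, v3: float, margin: float = 0.1) -> F3Params:
    """F3 parameters realizing the trigonometric challenge growth rate on
    x in (-pi + margin, pi - margin)."""
    return F3Params(
        k=2,
        gamma0=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        mu0=lambda E: 0.0,
        v0=lambda x: 1.0 + np.cos(np.asarray(x, dtype=float)),
        v1=lambda E: v1,
        v2=lambda E: v2,
        v3=lambda E: v3,
        x_b=0.0,
        x_lo=-np.pi + margin,
        x_hi=np.pi - margin,
    )


def challenge_zeta(x):
    """Closed-form rescaled i-state for the challenge example."""
    return np.tan(np.asarray(x, dtype=float) / 2.0)
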