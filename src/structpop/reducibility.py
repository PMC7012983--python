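"""Deciding exact ODE reducibility of structured population models.

A k-vector of output weights ``w`` closes into an ODE ``dN/dt = K(E) N``
precisely when the reducibility condition

    g(x,E) w'(x) - mu(x,E) w(x) + <w, beta>(x,E) = K(E) w(x)

holds identically in ``x`` for some k x k matrix ``K(E)``.  This module
evaluates the condition residual on grids, fits ``K(E)`` by least squares,
runs the scalar (k = 1) test, implements the systematic weight-extension
procedure for finding additional output components, and inverts the k = 2
relations to construct growth and death rates from prescribed weights and
matrix entries.

All verdicts are numeric-on-grid; tolerances are relative residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .core import FissionKernel, FissionNetKernel, ModelError, StructuredModel
from .weights import Weight, WeightFamily

#: default verdict tolerance for analytically specified rates
DEFAULT_TOL = 1e-8
#: singular-value ratio below which a residual counts as rank one in (x, E)
RANK1_TOL = 1e-6


def default_E_samples(lo: float = 0.1, hi: float = 10.0, n: int = 8) -> np.ndarray:
    """Default environmental sample set: log-spaced substrate values."""
    return np.geomspace(lo, hi, n)


# --------------------------------------------------------------------------
# condition evaluation
# --------------------------------------------------------------------------

def _pairings(model: StructuredModel, weights: WeightFamily, x, E) -> np.ndarray:
    """Matrix <w_i, beta>(x, E) of shape (k, n_x)."""
    x = np.asarray(x, dtype=float)
    return np.stack([model.rates.beta.pairing(w, x, E) for w in weights])


def condition_lhs(model: StructuredModel, weights: WeightFamily, x, E) -> np.ndarray:
    """Left-hand side g w' - mu w + <w, beta>, shape (k, n_x)."""
    x = np.asarray(x, dtype=float)
    g = np.asarray(model.rates.g(x, E), dtype=float) * np.ones_like(x)
    mu = np.asarray(model.rates.mu(x, E), dtype=float) * np.ones_like(x)
    return g[None, :] * weights.derivs(x) - mu[None, :] * weights.values(x) + _pairings(
        model, weights, x, E
    )


def condition_residual(
    model: StructuredModel,
    weights: WeightFamily | Sequence[Weight],
    K: np.ndarray,
    x_grid,
    E_value: float,
) -> np.ndarray:
    """Residual R(x) = g w' - mu w + <w, beta> - K(E) w, shape (k, n_x).

    An identically zero residual certifies that the reducibility condition
    holds at the grid points for the given ``K``.
    """
    if not isinstance(weights, WeightFamily):
        weights = WeightFamily(weights)
    x = np.asarray(x_grid, dtype=float)
    K = np.atleast_2d(np.asarray(K, dtype=float))
    return condition_lhs(model, weights, x, E_value) - K @ weights.values(x)


# --------------------------------------------------------------------------
# K fitting
# --------------------------------------------------------------------------

@dataclass
class ReductionMatrix:
    """K(E) tabulated at sample environmental values."""

    E_samples: np.ndarray
    K_table: np.ndarray  # (n_E, k, k)
    residuals: np.ndarray  # relative residual per E sample

    def at(self, E: float) -> np.ndarray:
        """K at a sampled E (interpolated linearly between samples)."""
        i = np.searchsorted(self.E_samples, E)
        if i == 0:
            return self.K_table[0]
        if i >= self.E_samples.size:
            return self.K_table[-1]
        t = (E - self.E_samples[i - 1]) / (self.E_samples[i] - self.E_samples[i - 1])
        return (1 - t) * self.K_table[i - 1] + t * self.K_table[i]


@dataclass
class ReducibilityReport:
    verdict: bool
    tol: float
    reduction: ReductionMatrix
    max_residual: float
    weights: WeightFamily
    extension_trace: list = field(default_factory=list)

    def __bool__(self):
        return self.verdict


def fit_K(
    model: StructuredModel,
    weights: WeightFamily | Sequence[Weight],
    x_grid,
    E_samples=None,
    tol: float = DEFAULT_TOL,
) -> ReducibilityReport:
    """Least-squares fit of K(E) to the reducibility condition per E sample.

    The verdict is "reducible" iff the worst relative residual
    ||R|| / ||LHS|| over the E samples is below ``tol``.  Where a closed
    form K exists the fit reproduces it (the least-squares problem is then
    consistent).
    """
    if not isinstance(weights, WeightFamily):
        weights = WeightFamily(weights)
    x = np.asarray(x_grid, dtype=float)
    k = len(weights)
    if x.size < 2 * k:
        raise ModelError(f"need at least {2 * k} grid points for k={k}")
    weights.check_rank(x)
    E_samples = default_E_samples() if E_samples is None else np.asarray(E_samples, dtype=float)
    W = weights.values(x)  # (k, n_x)
    Ks, residuals = [], []
    for E in E_samples:
        L = condition_lhs(model, weights, x, E)  # (k, n_x)
        K_E, *_ = np.linalg.lstsq(W.T, L.T, rcond=None)
        K_E = K_E.T  # (k, k)
        R = L - K_E @ W
        scale = max(np.linalg.norm(L), 1e-300)
        residuals.append(np.linalg.norm(R) / scale if np.linalg.norm(L) > 0 else 0.0)
        Ks.append(K_E)
    residuals = np.asarray(residuals)
    red = ReductionMatrix(E_samples=E_samples, K_table=np.stack(Ks), residuals=residuals)
    max_res = float(residuals.max()) if residuals.size else 0.0
    return ReducibilityReport(
        verdict=max_res < tol, tol=tol, reduction=red, max_residual=max_res, weights=weights
    )


# --------------------------------------------------------------------------
# scalar (k = 1) test
# --------------------------------------------------------------------------

@dataclass
class K1Report:
    verdict: bool
    tol: float
    E_samples: np.ndarray
    K_values: np.ndarray
    variations: np.ndarray  # (max - min) of the test expression per E

    def K(self, E: float) -> float:
        return float(np.interp(E, self.E_samples, self.K_values))


def k1_test(
    model: StructuredModel,
    w: Weight,
    x_grid,
    E_samples=None,
    tol: float = DEFAULT_TOL,
) -> K1Report:
    """Scalar reducibility test: (g w' + <w, beta>) / w - mu must be
    independent of x; the common value is K(E)."""
    x = np.asarray(x_grid, dtype=float)
    wx = w(x)
    if np.abs(wx).min() < 1e-12 * max(np.abs(wx).max(), 1e-300):
        raise ModelError("scalar weight vanishes on the grid")
    E_samples = default_E_samples() if E_samples is None else np.asarray(E_samples, dtype=float)
    Kv, var = [], []
    for E in E_samples:
        g = np.asarray(model.rates.g(x, E), dtype=float) * np.ones_like(x)
        mu = np.asarray(model.rates.mu(x, E), dtype=float) * np.ones_like(x)
        pair = model.rates.beta.pairing(w, x, E)
        vals = (g * w.d(x) + pair) / wx - mu
        Kv.append(float(vals.mean()))
        var.append(float(vals.max() - vals.min()))
    Kv, var = np.asarray(Kv), np.asarray(var)
    scale = max(1.0, float(np.max(np.abs(Kv)))) if Kv.size else 1.0
    return K1Report(
        verdict=bool(np.max(var) < tol * scale) if var.size else True,
        tol=tol,
        E_samples=E_samples,
        K_values=Kv,
        variations=var,
    )


# --------------------------------------------------------------------------
# weight extension
# --------------------------------------------------------------------------

@dataclass
class ExtensionResult:
    success: bool
    weights: WeightFamily
    report: ReducibilityReport | None
    trace: list
    message: str = ""

    def __bool__(self):
        return self.success


def _needs_half_mask(model: StructuredModel) -> bool:
    return isinstance(model.rates.beta, (FissionKernel, FissionNetKernel))


def extend_weights(
    model: StructuredModel,
    initial: WeightFamily | Sequence[Weight],
    E_samples=None,
    x_grid=None,
    k_max: int = 6,
    tol: float = 1e-6,
    rank1_tol: float = RANK1_TOL,
) -> ExtensionResult:
    """Systematic search for additional output components.

    Per pass: evaluate the condition LHS for each current component,
    remove its projection onto the span of the current components (with
    E-dependent coefficients, fitted per E sample), test whether the
    remaining residual factorizes as (function of E) x (function of x)
    (rank-one test by singular-value ratio), and append the extracted
    x-profiles as new components (sup-norm normalized, orthogonalized
    against the current family).  Terminates with success when the
    residual is below ``tol`` (the family then closes under the condition)
    or with failure when k exceeds ``k_max`` or a residual is not
    separable.

    For halving (fission) kernels, pairings evaluate components at x/2;
    profiles of appended components are only known on the grid, so all
    projections and rank decisions are restricted to x >= 2 * min(grid)
    where interpolated components are evaluated inside their support.
    """
    weights = WeightFamily(list(initial if not isinstance(initial, WeightFamily) else initial.components))
    if x_grid is None:
        x_grid = np.geomspace(
            max(model.space.x_min, 1e-6), model.space.x_max, 400
        )
    x = np.asarray(x_grid, dtype=float)
    E_samples = default_E_samples() if E_samples is None else np.asarray(E_samples, dtype=float)
    mask = x >= 2.0 * x.min() if _needs_half_mask(model) else np.ones_like(x, dtype=bool)
    trace = []
    n_ext = 0

    for pass_no in range(k_max + 1):
        k = len(weights)
        W = weights.values(x)
        Wm = W[:, mask]
        L = np.stack([condition_lhs(model, weights, x, E) for E in E_samples])  # (nE, k, nx)
        res = np.empty_like(L)
        for e in range(E_samples.size):
            coef, *_ = np.linalg.lstsq(Wm.T, L[e][:, mask].T, rcond=None)
            res[e] = L[e] - coef.T @ W
        scale = max(float(np.abs(L[:, :, mask]).max()), 1e-300)
        max_res = float(np.abs(res[:, :, mask]).max()) / scale
        trace.append({"pass": pass_no, "k": k, "residual": max_res, "added": []})
        if max_res < tol:
            report = fit_K(model, weights, x[mask], E_samples, tol=max(tol, DEFAULT_TOL))
            return ExtensionResult(True, weights, report, trace,
                                   message=f"closed at k={k} after {pass_no} extension passes")
        if k >= k_max:
            return ExtensionResult(False, weights, None, trace,
                                   message=f"not reducible within k_max={k_max}")
        new_profiles = []
        for i in range(k):
            Ri = res[:, i, :]  # (nE, nx)
            Rm = Ri[:, mask]
            nrm = np.linalg.norm(Rm)
            if nrm < tol * scale:
                continue
            U, s, Vt = np.linalg.svd(Rm, full_matrices=False)
            if s.size > 1 and s[1] > rank1_tol * s[0]:
                return ExtensionResult(
                    False, weights, None, trace,
                    message=f"residual of component {weights[i].name!r} is not "
                            "separable as (function of E) x (function of x)",
                )
            # profile on the full grid via the dominant E-direction
            profile = U[:, 0] @ Ri
            new_profiles.append(profile)
        if not new_profiles:
            return ExtensionResult(False, weights, None, trace,
                                   message="residual above tolerance but no extractable profile")
        added = []
        for profile in new_profiles:
            # orthogonalize against the current family in the grid inner product
            q = profile.copy()
            for row in weights.values(x):
                q = q - (q[mask] @ row[mask]) / (row[mask] @ row[mask]) * row
            for prev in added:
                pv = prev(x)
                q = q - (q[mask] @ pv[mask]) / (pv[mask] @ pv[mask]) * pv
            sup = np.abs(q[mask]).max()
            if sup < 1e-10 * np.abs(profile[mask]).max():
                continue
            q = q / sup
            n_ext += 1
            spline = CubicSpline(x, q)
            dspline = spline.derivative()
            added.append(Weight(spline, dspline, name=f"ext{n_ext}"))
        if not added:
            return ExtensionResult(False, weights, None, trace,
                                   message="extracted profiles already in the current span")
        weights = WeightFamily(list(weights.components) + added)
        trace[-1]["added"] = [a.name for a in added]

    return ExtensionResult(False, weights, None, trace, message="pass limit reached")


# --------------------------------------------------------------------------
# reproduction as part of the output
# --------------------------------------------------------------------------

@dataclass
class ReproductionMatrixResult:
    success: bool
    E_samples: np.ndarray
    M_table: np.ndarray | None
    max_residual: float

    def __bool__(self):
        return self.success

    def at(self, E: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.E_samples - E)))
        return self.M_table[i]


def reproduction_output_matrix(
    model: StructuredModel,
    weights: WeightFamily | Sequence[Weight],
    x_grid,
    E_samples=None,
    tol: float = DEFAULT_TOL,
) -> ReproductionMatrixResult:
    """Fit M(E) with <w, beta> = M(E) w ("reproduction is part of the
    output"); for separable kernels this holds by construction."""
    if not isinstance(weights, WeightFamily):
        weights = WeightFamily(weights)
    x = np.asarray(x_grid, dtype=float)
    weights.check_rank(x)
    E_samples = default_E_samples() if E_samples is None else np.asarray(E_samples, dtype=float)
    W = weights.values(x)
    Ms, res = [], []
    for E in E_samples:
        P = _pairings(model, weights, x, E)
        M_E, *_ = np.linalg.lstsq(W.T, P.T, rcond=None)
        M_E = M_E.T
        R = P - M_E @ W
        scale = max(np.linalg.norm(P), np.linalg.norm(W), 1e-300)
        res.append(np.linalg.norm(R) / scale)
        Ms.append(M_E)
    res = np.asarray(res)
    ok = bool(res.max() < tol) if res.size else True
    return ReproductionMatrixResult(
        success=ok, E_samples=E_samples, M_table=np.stack(Ms), max_residual=float(res.max())
    )


# --------------------------------------------------------------------------
# k = 2 inversion: rates from weights
# --------------------------------------------------------------------------

def _as_E_callable(c):
    return c if callable(c) else (lambda E, _c=float(c): _c)


@dataclass
class GMuConstruction:
    g: Callable
    mu: Callable
    roundtrip_residual: float
    negative_g_fraction: float
    negative_mu_fraction: float


def solve_g_mu_from_weights(
    w1: Weight,
    w2: Weight,
    pairing1: Callable,
    pairing2: Callable,
    k11, k12, k21, k22,
    x_grid,
    E_samples=(1.0,),
    wronskian_tol: float = 1e-12,
) -> GMuConstruction:
    """Invert the two reducibility equations for (g, mu).

    Given two linearly independent weights, their kernel pairings
    ``<w_i, beta>(x, E)`` and the four entries of K(E), the two components
    of the condition form a linear system in (g, mu) whose solution is

        g  = (k21 + (k22 - k11) v - k12 v^2 + v <w1,b>/w1 - <w2,b>/w1) / v'
        mu = (w1'/w1) g - k11 - k12 v + <w1,b>/w1,      v = w2 / w1.

    The Wronskian w1' w2 - w1 w2' must not vanish on the grid (it may
    vanish only at isolated points, which must be excluded from the grid).
    Regions where the constructed g or mu are negative are surfaced in the
    result, never clipped.
    """
    x = np.asarray(x_grid, dtype=float)
    k11, k12, k21, k22 = map(_as_E_callable, (k11, k12, k21, k22))
    wr = w1.d(x) * w2(x) - w1(x) * w2.d(x)
    scale = max(float(np.abs(wr).max()), 1e-300)
    if np.any(np.abs(wr) < wronskian_tol * scale):
        raise ModelError(
            "Wronskian w1'w2 - w1 w2' vanishes on a grid cell; weights must be "
            "linearly independent away from isolated points"
        )

    def v(xx):
        return w2(xx) / w1(xx)

    def vprime(xx):
        return (w2.d(xx) * w1(xx) - w2(xx) * w1.d(xx)) / w1(xx) ** 2

    def g(xx, E):
        xx = np.asarray(xx, dtype=float)
        vv = v(xx)
        return (
            k21(E)
            + (k22(E) - k11(E)) * vv
            - k12(E) * vv ** 2
            + vv * np.asarray(pairing1(xx, E), dtype=float) / w1(xx)
            - np.asarray(pairing2(xx, E), dtype=float) / w1(xx)
        ) / vprime(xx)

    def mu(xx, E):
        xx = np.asarray(xx, dtype=float)
        return (
            w1.d(xx) / w1(xx) * g(xx, E)
            - k11(E)
            - k12(E) * v(xx)
            + np.asarray(pairing1(xx, E), dtype=float) / w1(xx)
        )

    # round trip: both rows of the condition must be satisfied
    worst = 0.0
    neg_g = neg_mu = 0
    total = 0
    for E in np.atleast_1d(E_samples):
        gv, mv = g(x, E), mu(x, E)
        r1 = gv * w1.d(x) - mv * w1(x) + pairing1(x, E) - (k11(E) * w1(x) + k12(E) * w2(x))
        r2 = gv * w2.d(x) - mv * w2(x) + pairing2(x, E) - (k21(E) * w1(x) + k22(E) * w2(x))
        sc = max(1.0, float(np.abs(gv).max()), float(np.abs(mv).max()))
        worst = max(worst, float(np.abs(r1).max() / sc), float(np.abs(r2).max() / sc))
        neg_g += int(np.sum(gv < 0))
        neg_mu += int(np.sum(mv < 0))
        total += x.size
    return GMuConstruction(
        g=g,
        mu=mu,
        roundtrip_residual=worst,
        negative_g_fraction=neg_g / total,
        negative_mu_fraction=neg_mu / total,
    )
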