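"""Reducibility condition, K fitting, weight extension, k=2 inversion."""

import numpy as np
import pytest

import structpop as sp
from structpop.reducibility import condition_residual, default_E_samples

CBRT2 = 2.0 ** (1.0 / 3.0)


def _zero_rate(x, E):
    return np.zeros_like(np.asarray(x, float))


@pytest.fixture(scope="module")
def surface(chemostat):
    model, _ = sp.build_surface_model(chemostat, k21=1.0, span=64)
    return model


@pytest.fixture(scope="module")
def nonreducible():
    """g = S x^2, mu = 0, no births: not reducible with w = x."""
    return sp.StructuredModel(
        sp.IStateSpace(0.1, 10.0, birth_state=0.1),
        sp.RateSet(g=lambda x, E: E * np.asarray(x, float) ** 2, mu=_zero_rate,
                   beta=sp.ZeroKernel()),
    )


class TestConditionResidual:
    def test_monod_model_residual_vanishes_with_closed_form_K(self, chemostat, x_grid):
        model, _ = sp.build_monod_fission(chemostat, beta0=0.5, span=64)
        for S in (0.5, 1.0, 2.0):
            K = np.array([[chemostat.monod(S) - chemostat.D]])
            R = condition_residual(model, [sp.w_x], K, x_grid, S)
            assert np.abs(R).max() < 1e-12

    def test_zero_rates_zero_K(self, x_grid):
        model = sp.StructuredModel(
            sp.IStateSpace(0.1, 10.0, birth_state=0.1),
            sp.RateSet(g=_zero_rate, mu=_zero_rate, beta=sp.ZeroKernel()))
        R = condition_residual(model, [sp.w_x], np.zeros((1, 1)), x_grid, 1.0)
        assert np.abs(R).max() == 0.0

    def test_nonreducible_residual_bounded_below(self, nonreducible, x_grid):
        # brute-force oracle: least-squares optimum over scalar K on the grid
        L = 1.0 * x_grid ** 2
        W = x_grid
        K_star = np.dot(W, L) / np.dot(W, W)
        best = np.abs(L - K_star * W).max()
        # any other K does worse; the fitted residual matches the optimum
        fit = sp.fit_K(nonreducible, [sp.w_x], x_grid, E_samples=[1.0])
        R = condition_residual(nonreducible, [sp.w_x],
                               fit.reduction.K_table[0], x_grid, 1.0)
        assert np.abs(R).max() >= 0.99 * best
        assert best > 1.0  # genuinely far from reducible on this grid


class TestFitK:
    def test_surface_model_recovers_closed_form_K(self, surface, chemostat, x_grid):
        fit = sp.fit_K(surface, [sp.w_x, sp.w_x23], x_grid, E_samples=[0.5, 1.0, 2.0])
        assert fit.verdict and fit.max_residual < 1e-8
        for i, S in enumerate([0.5, 1.0, 2.0]):
            expected = np.array([[-chemostat.D, chemostat.monod(S)],
                                 [1.0, -chemostat.D]])
            assert np.allclose(fit.reduction.K_table[i], expected, atol=1e-10)

    def test_monod_scalar_K(self, chemostat, x_grid):
        model, _ = sp.build_monod_fission(chemostat, beta0=0.5, span=64)
        fit = sp.fit_K(model, [sp.w_x], x_grid, E_samples=[1.0])
        assert fit.verdict
        assert fit.reduction.K_table[0][0, 0] == pytest.approx(
            chemostat.monod(1.0) - chemostat.D, abs=1e-12)

    def test_nonreducible_verdict_matches_bruteforce_bound(self, nonreducible, x_grid):
        fit = sp.fit_K(nonreducible, [sp.w_x], x_grid, E_samples=[1.0])
        assert not fit.verdict
        # independent optimum via explicit normal equations
        L = x_grid ** 2
        K_star = np.dot(x_grid, L) / np.dot(x_grid, x_grid)
        oracle = np.linalg.norm(L - K_star * x_grid) / np.linalg.norm(L)
        assert fit.max_residual == pytest.approx(oracle, rel=1e-10)

    def test_rank_deficient_weights_error_names_component(self, surface, x_grid):
        w_dup = sp.Weight(lambda x: 2.0 * x, lambda x: 2.0 * np.ones_like(x), "2x")
        with pytest.raises(sp.ModelError, match="2x"):
            sp.fit_K(surface, [sp.w_x, w_dup], x_grid)

    def test_residual_stable_under_grid_refinement_for_reducible_model(self, surface):
        fits = [sp.fit_K(surface, [sp.w_x, sp.w_x23], np.geomspace(0.1, 10, n),
                         E_samples=[1.0]) for n in (100, 400)]
        assert all(f.max_residual < 1e-10 for f in fits)


class TestK1:
    def test_monod_p1_zero_variation(self, chemostat, x_grid):
        model, _ = sp.build_monod_fission(chemostat, beta0=0.5, span=64)
        rep = sp.k1_test(model, sp.w_x, x_grid, E_samples=[0.5, 1.0, 2.0])
        assert rep.verdict
        assert rep.K(1.0) == pytest.approx(chemostat.monod(1.0) - chemostat.D, abs=1e-10)

    def test_unsuccessful_divisions_compensated_in_growth(self, chemostat, x_grid):
        # p < 1 with the compensated growth rate: variation stays zero and
        # K is unchanged
        p = lambda x, S: np.full_like(np.asarray(x, float), 0.5)
        b0 = lambda x, S: 0.85 + 0.3 * np.asarray(x, float) / (1 + np.asarray(x, float))
        model, _ = sp.build_monod_fission(chemostat, p=p, beta0=b0,
                                          compensate=True, span=64)
        rep = sp.k1_test(model, sp.w_x, x_grid, E_samples=[0.5, 1.0, 2.0])
        assert rep.verdict
        assert rep.K(2.0) == pytest.approx(chemostat.monod(2.0) - chemostat.D, abs=1e-10)

    def test_uncompensated_variation_positive(self, chemostat, x_grid):
        # p(x, S) = x / (1 + x) without compensation: x-dependence survives
        p = lambda x, S: np.asarray(x, float) / (1 + np.asarray(x, float))
        model, _ = sp.build_monod_fission(chemostat, p=p, beta0=1.0,
                                          compensate=False, span=64)
        rep = sp.k1_test(model, sp.w_x, x_grid)
        assert not rep.verdict
        assert rep.variations.max() > 0.1

    def test_vanishing_weight_rejected(self, chemostat, x_grid):
        model, _ = sp.build_monod_fission(chemostat, span=64)
        w0 = sp.Weight(lambda x: x - 1.0, lambda x: np.ones_like(x), "x-1")
        with pytest.raises(sp.ModelError):
            sp.k1_test(model, w0, np.linspace(0.5, 2.0, 16))  # grid hits x = 1


class TestExtendWeights:
    def test_surface_model_closes_at_k2_with_x23_direction(self, surface):
        grid = np.geomspace(0.05, 10.0, 500)
        ext = sp.extend_weights(surface, [sp.w_x], E_samples=[0.5, 1.0, 2.0],
                                x_grid=grid, k_max=4, tol=1e-6)
        assert ext.success
        assert len(ext.weights) == 2
        # the new direction is x^(2/3) modulo the starting component:
        # regression of the added component on {x, x^(2/3)} is exact with a
        # nonzero x^(2/3) coefficient
        xs = np.geomspace(0.12, 9.0, 200)
        prof = ext.weights[1](xs)
        A = np.stack([xs, xs ** (2.0 / 3.0)], axis=1)
        coef, res, *_ = np.linalg.lstsq(A, prof, rcond=None)
        rel = np.abs(prof - A @ coef).max() / np.abs(prof).max()
        assert rel < 1e-6
        assert abs(coef[1]) > 1e-3

    def test_already_closed_family_needs_zero_passes(self, surface):
        ext = sp.extend_weights(surface, [sp.w_x, sp.w_x23],
                                E_samples=[0.5, 1.0, 2.0],
                                x_grid=np.geomspace(0.05, 10, 400), tol=1e-6)
        assert ext.success
        assert ext.trace[0]["pass"] == 0 and ext.trace[-1]["k"] == 2
        assert len(ext.trace) == 1  # closed immediately

    def test_nonreducible_powers_fail_at_k_max(self, nonreducible):
        ext = sp.extend_weights(nonreducible, [sp.w_x], E_samples=[0.5, 1.0, 2.0],
                                x_grid=np.geomspace(0.1, 10, 300), k_max=4, tol=1e-8)
        assert not ext.success
        # each pass appends another power of x
        assert ext.trace[-1]["k"] >= 4


class TestReproductionOutputMatrix:
    def test_separable_kernel_exact(self, x_grid):
        kernel = sp.SeparableKernel([
            (lambda x: x, [(0.5, lambda E: E)]),
            (lambda x: x ** 2, [(1.5, lambda E: 0.2)]),
        ])
        model = sp.StructuredModel(
            sp.IStateSpace(0.1, 10.0, birth_state=0.5),
            sp.RateSet(g=_zero_rate, mu=_zero_rate, beta=kernel))
        w2 = sp.Weight(lambda x: x ** 2, lambda x: 2 * x, "x**2")
        rep = sp.reproduction_output_matrix(model, [sp.w_x, w2], x_grid,
                                            E_samples=[1.0, 2.0])
        assert rep.success and rep.max_residual < 1e-12

    def test_zero_kernel_M_zero(self, x_grid):
        model = sp.StructuredModel(
            sp.IStateSpace(0.1, 10.0, birth_state=0.1),
            sp.RateSet(g=_zero_rate, mu=_zero_rate, beta=sp.ZeroKernel()))
        rep = sp.reproduction_output_matrix(model, [sp.w_x], x_grid)
        assert rep.success
        assert np.abs(rep.M_table).max() == 0.0

    def test_net_fission_volume_surface_structure(self, surface, chemostat, x_grid):
        # <x, beta> = 0 and <x^(2/3), beta> = k21 x
        rep = sp.reproduction_output_matrix(surface, [sp.w_x, sp.w_x23], x_grid,
                                            E_samples=[1.0])
        assert rep.success
        M = rep.M_table[0]
        assert np.allclose(M, [[0.0, 0.0], [1.0, 0.0]], atol=1e-10)


class TestSolveGMu:
    def test_surface_model_rates_recovered(self, chemostat):
        c = 1.0 / (CBRT2 - 1.0)
        kern = sp.FissionNetKernel(lambda x, E: c * np.asarray(x, float) ** (1 / 3))
        xg = np.geomspace(0.1, 10, 200)
        gm = sp.solve_g_mu_from_weights(
            sp.w_x, sp.w_x23,
            lambda x, E: kern.pairing(sp.w_x, x, E),
            lambda x, E: kern.pairing(sp.w_x23, x, E),
            k11=-chemostat.D, k12=chemostat.monod, k21=1.0, k22=-chemostat.D,
            x_grid=xg, E_samples=[0.5, 1.0, 2.0])
        S = 1.0
        assert np.allclose(gm.g(xg, S), 3 * chemostat.monod(S) * xg ** (2 / 3), rtol=1e-10)
        assert np.allclose(gm.mu(xg, S),
                           chemostat.D + 2 * chemostat.monod(S) * xg ** (-1 / 3), rtol=1e-10)
        assert gm.roundtrip_residual < 1e-10

    def test_no_births_diagonal_K_gives_zero_growth(self):
        zk = sp.ZeroKernel()
        w2 = sp.Weight(lambda x: x ** 2, lambda x: 2 * x, "x**2")
        xg = np.geomspace(0.2, 5, 100)
        gm = sp.solve_g_mu_from_weights(
            sp.w_x, w2, lambda x, E: zk.pairing(sp.w_x, x, E),
            lambda x, E: zk.pairing(w2, x, E), 0.7, 0.0, 0.0, 0.7, xg)
        assert np.abs(gm.g(xg, 1.0)).max() == 0.0
        assert np.allclose(gm.mu(xg, 1.0), -0.7)
        assert gm.negative_mu_fraction == 1.0  # negativity surfaced, not clipped

    def test_roundtrip_identity_for_random_K(self):
        rng = np.random.default_rng(3)
        k11, k12, k21, k22 = rng.normal(size=4)
        zk = sp.ZeroKernel()
        w2 = sp.Weight(lambda x: np.sqrt(x), lambda x: 0.5 / np.sqrt(x), "sqrt")
        xg = np.geomspace(0.3, 4, 150)
        gm = sp.solve_g_mu_from_weights(
            sp.w_x, w2, lambda x, E: zk.pairing(sp.w_x, x, E),
            lambda x, E: zk.pairing(w2, x, E), k11, k12, k21, k22, xg)
        assert gm.roundtrip_residual < 1e-10

    def test_vanishing_wronskian_rejected(self):
        w2 = sp.Weight(lambda x: 3.0 * x, lambda x: 3.0 * np.ones_like(x), "3x")
        zk = sp.ZeroKernel()
        with pytest.raises(sp.ModelError):
            sp.solve_g_mu_from_weights(
                sp.w_x, w2, lambda x, E: zk.pairing(sp.w_x, x, E),
                lambda x, E: zk.pairing(w2, x, E), 0, 0, 0, 0,
                np.geomspace(0.1, 10, 50))

    def test_roundtrip_with_fit_K(self, chemostat):
        # rates generated from (w, K) are certified reducible with the same K
        zk = sp.ZeroKernel()
        w2 = sp.Weight(lambda x: x ** 2, lambda x: 2 * x, "x**2")
        xg = np.geomspace(0.2, 5, 200)
        gm = sp.solve_g_mu_from_weights(
            sp.w_x, w2, lambda x, E: zk.pairing(sp.w_x, x, E),
            lambda x, E: zk.pairing(w2, x, E), -0.1, 0.4, 0.2, -0.3, xg)
        model = sp.StructuredModel(
            sp.IStateSpace(0.2, 5.0, birth_state=0.2),
            sp.RateSet(g=gm.g, mu=gm.mu, beta=zk))
        fit = sp.fit_K(model, [sp.w_x, w2], xg, E_samples=[1.0])
        assert fit.verdict
        assert np.allclose(fit.reduction.K_table[0],
                           [[-0.1, 0.4], [0.2, -0.3]], atol=1e-9)
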