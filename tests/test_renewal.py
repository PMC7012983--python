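"""Renewal solver: generation expansion, p-state reconstruction, outputs."""

import numpy as np
import pytest

import structpop as sp

ENV = sp.constant_environment(1.0)


def _const_rates(beta=None, mu=0.0, g=0.0):
    return sp.RateSet(
        g=lambda x, E: g * np.ones_like(np.asarray(x, float)),
        mu=lambda x, E: mu * np.ones_like(np.asarray(x, float)),
        beta=beta if beta is not None else sp.ZeroKernel(),
    )


class TestInitialForcing:
    def _model(self, beta0=0.8, mu=0.3):
        space = sp.IStateSpace(0.0, 50.0, birth_state=0.0)
        kernel = sp.PointBirthKernel(
            lambda x, E: beta0 * np.ones_like(np.asarray(x, float)), 0.0)
        return sp.StructuredModel(space, _const_rates(kernel, mu=mu, g=1.0))

    def test_empty_history_gives_zero_measure(self):
        model = self._model()
        hist = sp.BirthHistory.empty(0.0)
        assert sp.initial_forcing(hist, model, ENV, 2.0) == []

    def test_single_atom_point_birth_closed_form(self):
        beta0, mu = 0.8, 0.3
        model = self._model(beta0, mu)
        hist = sp.BirthHistory(0.0, [sp.HistoryAtom(-1.0, 0.0, 2.0)])
        atoms = sp.initial_forcing(hist, model, ENV, 1.5)
        (loc, mass), = atoms
        assert loc == 0.0
        assert mass == pytest.approx(2.0 * beta0 * np.exp(-mu * 2.5), rel=1e-6)

    def test_additivity_in_history_atoms(self):
        model = self._model()
        a1 = sp.BirthHistory(0.0, [sp.HistoryAtom(-1.0, 0.0, 1.0)])
        a2 = sp.BirthHistory(0.0, [sp.HistoryAtom(-0.5, 0.0, 0.7)])
        both = a1 + a2
        m1 = sum(m for _, m in sp.initial_forcing(a1, model, ENV, 2.0))
        m2 = sum(m for _, m in sp.initial_forcing(a2, model, ENV, 2.0))
        mb = sum(m for _, m in sp.initial_forcing(both, model, ENV, 2.0))
        assert mb == pytest.approx(m1 + m2, rel=1e-12)


class TestSolveRenewal:
    def test_zero_kernel_birth_rate_is_the_forcing(self):
        space = sp.IStateSpace(0.0, 10.0, birth_state=0.0)
        model = sp.StructuredModel(space, _const_rates(mu=0.2, g=1.0))
        hist = sp.BirthHistory.point_cohort(0.0, [0.0], [1.0])
        sol = sp.solve_renewal(model, ENV, hist, 2.0, 0.05)
        assert sol.generations == 0
        assert sol.total_rate().max() == 0.0

    def test_generation_masses_decrease_eventually_and_sum_is_positive(self, age_model):
        hist = sp.BirthHistory.point_cohort(0.0, [0.0], [1.0])
        sol = sp.solve_renewal(age_model, ENV, hist, 6.0, 0.02)
        masses = np.asarray(sol.generation_masses)
        assert np.all(masses >= 0)
        assert masses[-1] <= 1e-8 * masses.sum()
        assert sol.converged

    def test_linearity_in_the_initial_history(self, age_model):
        h1 = sp.BirthHistory.point_cohort(0.0, [0.0], [1.0])
        h2 = sp.BirthHistory.point_cohort(0.0, [0.0], [0.5])
        s1 = sp.solve_renewal(age_model, ENV, h1, 4.0, 0.02)
        s2 = sp.solve_renewal(age_model, ENV, h2, 4.0, 0.02)
        s12 = sp.solve_renewal(age_model, ENV, h1 + h2, 4.0, 0.02)
        assert np.allclose(s12.total_rate(), s1.total_rate() + s2.total_rate(),
                           rtol=1e-9, atol=1e-12)

    def test_euler_lotka_growth_rate(self, age_model):
        # constant-rate age model: late-time growth rate is beta - mu
        hist = sp.BirthHistory.point_cohort(0.0, [0.0], [1.0])
        sol = sp.solve_renewal(age_model, ENV, hist, 10.0, 0.01, tol_gen=1e-10)
        r = sp.fit_exponential_rate(sol.t_grid, sol.total_rate(), window=(0.6, 1.0))
        assert r == pytest.approx(age_model.meta["beta"] - age_model.meta["mu"], abs=2e-4)

    def test_nonconvergence_raises_with_diagnostics(self, age_model):
        hist = sp.BirthHistory.point_cohort(0.0, [0.0], [1.0])
        with pytest.raises(sp.RenewalConvergenceError) as err:
            sp.solve_renewal(age_model, ENV, hist, 10.0, 0.05, max_generations=3)
        assert len(err.value.generation_masses) > 0

    def test_agrees_with_direct_time_stepping_for_fission(self):
        ch = sp.ChemostatConfig(D=0.5, S_ext=2.0, gamma=1.0, a=1.0, b=1.0)
        model, _ = sp.build_monod_fission(ch, beta0=0.5, span=64)
        env = sp.PrescribedEnvironment(lambda t: 1.0 + 0.3 * np.sin(t))
        hist = sp.BirthHistory.point_cohort(0.0, [1.0], [1.0])
        sol = sp.solve_renewal(model, env, hist, 4.0, 0.01, merge_dx=1e-3)
        out = sp.compute_output(sol, sp.OutputSpec([sp.w_x, sp.w_one]), env)
        direct = sp.simulate_structured(model, env, hist, 4.0, 0.01,
                                        outputs=sp.OutputSpec([sp.w_x, sp.w_one]),
                                        merge_dx=1e-3)
        assert np.abs(out["N"] - direct.N).max() < 2e-4


class TestPStateReconstruction:
    def test_conservation_without_deaths_or_births(self):
        space = sp.IStateSpace(0.1, 100.0, birth_state=0.1)
        model = sp.StructuredModel(space, sp.RateSet(
            g=lambda x, E: x, mu=lambda x, E: 0.0 * np.asarray(x, float),
            beta=sp.ZeroKernel()))
        hist = sp.BirthHistory.point_cohort(0.0, [0.5, 1.0], [0.4, 0.6])
        sol = sp.solve_renewal(model, ENV, hist, 3.0, 0.05)
        ps = sp.reconstruct_pstate(sol, model, ENV, 3.0)
        assert ps.total_number() == pytest.approx(1.0, rel=1e-12)

    def test_pure_death_decay(self):
        m = 0.4
        space = sp.IStateSpace(0.0, 10.0, birth_state=0.0)
        model = sp.StructuredModel(space, _const_rates(mu=m, g=1.0))
        hist = sp.BirthHistory.point_cohort(0.0, [1.0], [2.0])
        sol = sp.solve_renewal(model, ENV, hist, 3.0, 0.05)
        ps = sp.reconstruct_pstate(sol, model, ENV, 3.0)
        assert ps.total_number() == pytest.approx(2.0 * np.exp(-m * 3.0), rel=1e-9)

    def test_biomass_balance_under_mass_conserving_fission(self):
        # 2 (x/2) = x: biomass changes only through growth, d/dt int x m = int g m
        space = sp.IStateSpace(1e-4, 100.0, birth_state=None)
        model = sp.StructuredModel(space, sp.RateSet(
            g=lambda x, E: 0.3 * x,
            mu=lambda x, E: 0.0 * np.asarray(x, float),
            beta=sp.FissionNetKernel(lambda x, E: 0.8 * np.ones_like(np.asarray(x, float)))))
        env = ENV
        hist = sp.BirthHistory.point_cohort(0.0, [1.0], [1.0])
        res = sp.simulate_structured(model, env, hist, 2.0, 0.005, merge_dx=1e-3)
        # independent balance oracle: biomass solves dX/dt = 0.3 X exactly
        assert np.allclose(res.total_biomass, np.exp(0.3 * res.t), rtol=2e-5)

    def test_window_mass_sums_contained_cohorts(self):
        ps = sp.PopulationMeasure(t=0.0, x=np.array([0.5, 1.0, 2.0]),
                                  m=np.array([1.0, 2.0, 3.0]))
        assert ps.window_mass(0.7, 2.5) == 5.0
        assert ps.moment(lambda x: x) == pytest.approx(0.5 + 2.0 + 6.0)


class TestComputeOutput:
    def test_unit_weight_counts_population(self, age_model):
        hist = sp.BirthHistory.point_cohort(0.0, [0.0], [1.0])
        sol = sp.solve_renewal(age_model, ENV, hist, 3.0, 0.02)
        out = sp.compute_output(sol, sp.OutputSpec([sp.w_one]), ENV)
        assert np.allclose(out["N"][:, 0], out["total_number"], rtol=1e-12)

    def test_Q_matrix_applied_to_N(self, age_model):
        hist = sp.BirthHistory.point_cohort(0.0, [0.0], [1.0])
        sol = sp.solve_renewal(age_model, ENV, hist, 2.0, 0.02)
        spec = sp.OutputSpec([sp.w_one], Q=lambda E: np.array([[2.0 * E]]))
        out = sp.compute_output(sol, spec, ENV)
        assert np.allclose(out["O"], 2.0 * out["N"])

    def test_refinement_is_at_least_first_order(self):
        ch = sp.ChemostatConfig(D=0.5, S_ext=2.0, gamma=1.0, a=1.0, b=1.0)
        model, _ = sp.build_monod_fission(ch, beta0=0.5, span=256)
        env = sp.constant_environment(1.0)
        hist = sp.BirthHistory.point_cohort(0.0, [1.0], [1.0])
        vals = []
        for dt in (0.04, 0.02, 0.01):
            r = sp.simulate_structured(model, env, hist, 4.0, dt,
                                       outputs=sp.OutputSpec([sp.w_x]), merge_dx=1e-3)
            vals.append(r.N[-1, 0])
        e1, e2 = abs(vals[0] - vals[2]), abs(vals[1] - vals[2])
        assert e2 < 0.6 * e1  # empirical order >= 1


class TestHistories:
    def test_negative_mass_rejected(self):
        with pytest.raises(sp.ConfigError):
            sp.BirthHistory(0.0, [sp.HistoryAtom(0.0, 1.0, -1.0)])

    def test_future_atom_rejected(self):
        with pytest.raises(sp.ConfigError):
            sp.BirthHistory(0.0, [sp.HistoryAtom(1.0, 1.0, 1.0)])


class TestCohortMerging:
    def test_merge_conserves_number_and_first_moment(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.5, 2.0, 500)
        m = rng.uniform(0.0, 1.0, 500)
        xm, mm = sp.renewal.merge_atoms(x, m, 0.05, log_bins=True, x_ref=0.1)
        assert mm.sum() == pytest.approx(m.sum(), rel=1e-12)
        assert (xm * mm).sum() == pytest.approx((x * m).sum(), rel=1e-12)
        assert xm.size < x.size
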