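import numpy as np
import pytest

from demrisk.demography_core import (
    DemographyError,
    PopulationVector,
    SpeciesParams,
    build_leslie,
    initial_population,
)
from demrisk.dynamics import (
    SimConfig,
    apply_catastrophe,
    calibrate_feedback,
    density_feedback,
    deterministic_projection,
    project,
    quasi_extinction_probability,
    round_half_up,
    step_stochastic,
)
from demrisk.scenarios import PerturbationSetting


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(2.4, 2), (2.5, 3), (2.6, 3), (0.2, 1), (10.49, 10)]
    )
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestSimConfig:
    def test_defaults(self):
        cfg = SimConfig()
        assert cfg.iterations == 10_000
        assert cfg.eq_threshold_females == 50
        assert cfg.horizon_generations == 40
        assert cfg.burnin_generations == 1
        assert cfg.area_km2 == 250_000
        assert cfg.cat_severity == 0.5

    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(iterations=0)
        with pytest.raises(ValueError):
            SimConfig(cat_severity=1.5)


class TestStepStochastic:
    def test_absorbing_extinction(self, toy_model):
        dead = SpeciesParams(
            "dead", "extant", "carnivore", 1.0, 1, 3,
            np.zeros(4), np.zeros(4), 0.1, terminal_self_loop=False,
        )
        from demrisk.demography_core import leslie_matrix
        from demrisk.demography_core import LeslieModel

        model = LeslieModel(
            matrix=leslie_matrix(dead), lam=0.0, w=np.full(4, 0.25), G=float("nan"),
            R0=0.0, params=dead,
        )
        rng = np.random.default_rng(0)
        out = step_stochastic(PopulationVector(np.array([10.0, 5, 3, 1])), model, 1.0, rng)
        assert out.total == 0.0

    def test_certain_survival_shift(self):
        p = SpeciesParams(
            "immortal", "extant", "carnivore", 1.0, 1, 3,
            np.ones(4), np.zeros(4), 0.1, terminal_self_loop=False,
        )
        model = build_leslie(p)
        rng = np.random.default_rng(0)
        out = step_stochastic(PopulationVector(np.array([4.0, 3, 2, 1])), model, 1.0, rng)
        assert np.array_equal(out.n, [0, 4, 3, 2])

    def test_rejects_negative(self, toy_model):
        rng = np.random.default_rng(0)
        pv = PopulationVector(np.ones(4))
        object.__setattr__(pv, "n", np.array([1.0, -2.0, 1.0, 1.0]))
        with pytest.raises(DemographyError):
            step_stochastic(pv, toy_model, 1.0, rng)

    def test_feedback_multiplier_range(self, toy_model):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            step_stochastic(PopulationVector(np.ones(4)), toy_model, 0.0, rng)

    def test_expectation_matches_matrix_product(self, toy_params, toy_model):
        # mean of replicate stochastic steps equals M @ n within 3 MC SE
        n = np.array([400.0, 250, 120, 60])
        reps = 10_000
        rng = np.random.default_rng(42)
        acc = np.zeros((reps, 4))
        for i in range(reps):
            acc[i] = step_stochastic(PopulationVector(n), toy_model, 1.0, rng).n
        mean = acc.mean(axis=0)
        se = acc.std(axis=0, ddof=1) / np.sqrt(reps)
        expected = toy_model.matrix @ n
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-9)


class TestDensityFeedback:
    def test_no_crowding(self):
        assert density_feedback(0.0, 1000.0, c=0.5) == 1.0

    def test_monotone_decreasing(self):
        K = 1000.0
        m0 = density_feedback(0.0, K, c=0.3)
        m1 = density_feedback(K, K, c=0.3)
        m2 = density_feedback(2 * K, K, c=0.3)
        assert m2 < m1 < m0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            density_feedback(10.0, 0.0, c=0.3)

    def test_calibration_stationary_at_k(self, species_table):
        # deterministic realized growth rate at N = K equals 1 within 1e-6
        for sp in species_table:
            c = calibrate_feedback(sp)
            mult = density_feedback(sp.density * 250_000, sp.density * 250_000, c)
            scaled = sp.with_rates(survival=np.clip(sp.survival * mult, 0, 1))
            assert build_leslie(scaled).lam == pytest.approx(1.0, abs=1e-6)

    def test_declining_species_gets_zero_strength(self):
        p = SpeciesParams(
            "declining", "extant", "carnivore", 1.0, 1, 2,
            [0.3, 0.4, 0.0], [0, 0.5, 0.5], 0.1, terminal_self_loop=False,
        )
        assert build_leslie(p).lam < 1
        assert calibrate_feedback(p) == 0.0


class TestApplyCatastrophe:
    def test_total_annihilation(self):
        rng = np.random.default_rng(1)
        out = apply_catastrophe(PopulationVector(np.array([50.0, 20, 10])), 1.0, 1.0, rng)
        assert out.total == 0.0

    def test_no_event_unchanged(self):
        rng = np.random.default_rng(1)
        n = PopulationVector(np.array([50.0, 20, 10]))
        out = apply_catastrophe(n, 0.0, 0.5, rng)
        assert np.array_equal(out.n, n.n)

    def test_event_frequency_binomial_ci(self):
        # empirical event frequency over many trials within binomial 95% CI
        prob = 0.14
        trials = 10_000
        rng = np.random.default_rng(7)
        n = PopulationVector(np.array([1_000_000.0]))
        events = 0
        for _ in range(trials):
            out = apply_catastrophe(n, prob, 0.5, rng)
            events += out.total < n.total
        se = np.sqrt(prob * (1 - prob) / trials)
        assert abs(events / trials - prob) < 1.96 * se + 1e-12

    def test_severity_halves_on_average(self):
        rng = np.random.default_rng(3)
        n = PopulationVector(np.array([1_000_000.0]))
        out = apply_catastrophe(n, 1.0, 0.5, rng)
        assert out.total == pytest.approx(500_000, rel=0.01)


class TestProject:
    def test_seed_determinism(self, toy_params, fast_config):
        r1 = project(toy_params, fast_config, None, return_result=True)
        r2 = project(toy_params, fast_config, None, return_result=True)
        assert np.array_equal(r1.totals, r2.totals)
        assert np.array_equal(r1.finals, r2.finals)

    def test_trajectory_length_contract(self, toy_params, toy_model, fast_config):
        gen = round_half_up(toy_model.G)
        trajs = project(toy_params, fast_config.updated(iterations=5), None)
        expected = fast_config.horizon_generations * gen - gen
        assert all(len(t.totals) == expected for t in trajs)
        for t in trajs:
            assert t.quasi_extinct == (t.final_total < fast_config.eq_threshold_females)

    def test_healthy_species_persists(self, toy_params, fast_config):
        pr = quasi_extinction_probability(toy_params, fast_config, None)
        assert pr <= 0.02

    def test_full_survival_reduction_is_lethal(self, toy_params, fast_config):
        pr = quasi_extinction_probability(
            toy_params, fast_config, PerturbationSetting("all_survival", 1.0)
        )
        assert pr == 1.0

    def test_deterministic_limit_matches_matrix_powers(self, toy_params, toy_model):
        cfg = SimConfig(
            iterations=2,
            seed=0,
            horizon_generations=5,
            demographic_stochasticity=False,
            density_feedback_on=False,
            catastrophes_on=False,
        )
        res = project(toy_params, cfg, None, return_result=True)
        years = res.horizon_years
        seq = deterministic_projection(toy_params, cfg, years)
        gen = res.burnin_years
        # recorded totals start after burn-in; index t in totals is year gen+t+1
        expected = seq[gen + 1 :]
        assert np.allclose(res.totals[0], expected, rtol=1e-10)
        assert np.allclose(res.totals[1], expected, rtol=1e-10)

    def test_empty_population_fails_with_name(self, toy_params):
        from dataclasses import replace

        p = replace(toy_params, density=0.0)
        cfg = SimConfig(iterations=2, seed=0)
        with pytest.warns(UserWarning):
            with pytest.raises(DemographyError, match="toy"):
                project(p, cfg, None)

    def test_branching_process_oracle(self):
        """Simulated extinction probability vs probability-generating-function
        iteration for a small founding population without feedback."""
        p = SpeciesParams(
            "branchy", "extant", "carnivore", 1.0, 1, 1,
            [0.9, 0.0], [0.0, 1.0], 40.0 / 250_000, terminal_self_loop=False,
        )
        model = build_leslie(p)
        cfg = SimConfig(
            iterations=2000,
            seed=5,
            eq_threshold_females=1,  # final < 1 female == true extinction
            density_feedback_on=False,
            catastrophes_on=False,
        )
        res = project(p, cfg, None, return_result=True)
        # pgf iteration: type-x individual leaves Poisson(row0[x]) newborns
        # plus a Bernoulli(S_x) survivor of the next class
        M = model.matrix
        s = p.survival
        horizon = res.horizon_years
        q = np.zeros(2)
        for _ in range(horizon):
            nq = np.empty(2)
            nq[0] = np.exp(M[0, 0] * (q[0] - 1.0)) * (1 - s[0] + s[0] * q[1])
            nq[1] = np.exp(M[0, 1] * (q[0] - 1.0)) * 1.0  # no exit from class 1
            q = nq
        n0 = np.round(initial_population(p, model, cfg.area_km2).n)
        analytic = float(np.prod(q ** n0))
        se = np.sqrt(max(analytic * (1 - analytic), 1e-6) / cfg.iterations)
        assert res.pr_eq == pytest.approx(analytic, abs=3 * se)


class TestMonotoneRisk:
    def test_paired_seed_monotonicity_toy(self, toy_params):
        cfg = SimConfig(iterations=300, seed=21, horizon_generations=10)
        prs = [
            quasi_extinction_probability(
                toy_params, cfg, PerturbationSetting("all_survival", x)
            )
            for x in np.linspace(0, 1, 11)
        ]
        diffs = np.diff(prs)
        assert np.all(diffs >= -0.06)  # 3 MC SE at 300 iterations
        assert prs[0] <= 0.02 and prs[-1] == 1.0
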