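"""Model fitting, AICc arithmetic, model comparison, and the free-gamma approach."""

import math

import numpy as np
import pytest

from lymphokin import (
    EventTimeDistribution,
    FitBudget,
    LabelingDataset,
    PopulationSpec,
    TABLE1_GAMMA_MODELS,
    aicc,
    compare_models,
    expected_labeling_curve,
    fit_model,
    fit_unconstrained_gamma,
    hazard_trajectory_ensemble,
    median_lifespan,
    objective_cost,
)
from lymphokin.fitting import LOGNORMAL_MODELS, FitResult, ParadigmModel
from lymphokin.event_time import Paradigm
from lymphokin.synthetic import default_schedule

from conftest import LEAN_BUDGET

MODELS = {m.name: m for m in TABLE1_GAMMA_MODELS}


def _noiseless(spec, protocol, schedule):
    curve = expected_labeling_curve(spec, protocol, schedule)
    return LabelingDataset(times=schedule, fraction_labeled=curve.fraction_labeled)


class TestAicc:
    def test_hand_computed_example(self):
        # 11 ln(0.011/11) + 2*11*1/9
        assert aicc(0.011, 11, 1) == pytest.approx(11 * math.log(0.001) + 22 / 9, abs=1e-10)
        assert aicc(0.011, 11, 1) == pytest.approx(-73.5409, abs=5e-4)

    def test_doubling_ssr_adds_n_log_two(self):
        assert aicc(0.02, 11, 2) - aicc(0.01, 11, 2) == pytest.approx(11 * math.log(2), rel=1e-12)

    def test_parameter_penalty_difference(self):
        # same ssr, k=5 vs k=1 at n=11: 2*11*5/5 - 2*11*1/9
        diff = aicc(0.01, 11, 5) - aicc(0.01, 11, 1)
        assert diff == pytest.approx(22.0 - 22.0 / 9.0, abs=1e-10)
        assert diff == pytest.approx(19.556, abs=1e-3)

    def test_undefined_for_small_samples(self):
        with pytest.raises(ValueError):
            aicc(0.01, 3, 2)

    def test_zero_ssr_sentinel_with_warning(self):
        with pytest.warns(UserWarning, match="-inf"):
            assert aicc(0.0, 11, 1) == -math.inf

    def test_matches_independent_formula_on_random_triples(self, rng):
        for _ in range(1000):
            ssr = float(rng.uniform(1e-6, 10.0))
            k = int(rng.integers(1, 6))
            n = int(rng.integers(k + 2, 60))
            independent = n * math.log(ssr / n) + (2.0 * n * k) / (n - k - 1)
            assert abs(aicc(ssr, n, k) - independent) < 1e-12


class TestFreeParameterCounts:
    @pytest.mark.parametrize(
        "name,k",
        [
            ("age_independent_homogeneous_exponential", 1),
            ("age_independent_heterogeneous_exponential", 3),
            ("cyton_homogeneous_gamma", 2),
            ("cyton_heterogeneous_gamma", 5),
            ("risk_homogeneous_gamma", 2),
            ("risk_heterogeneous_gamma", 5),
        ],
    )
    def test_gamma_set(self, name, k):
        assert MODELS[name].k == k

    @pytest.mark.parametrize("model", LOGNORMAL_MODELS)
    def test_lognormal_set(self, model):
        assert model.k == (2 if model.heterogeneity == "homogeneous" else 5)

    def test_exponential_family_is_age_independent_only(self):
        with pytest.raises(ValueError):
            ParadigmModel(paradigm=Paradigm.RISK, heterogeneity="homogeneous", family="exponential")


class TestObjectiveCost:
    def test_self_cost_is_zero(self, exp_spec, heavy_water, schedule11):
        data = _noiseless(exp_spec, heavy_water, schedule11)
        assert objective_cost(exp_spec, heavy_water, data) < 1e-12

    def test_expected_cost_under_noise(self, exp_spec, heavy_water, schedule11):
        """E[ssr] at the true parameters is m * sigma^2."""
        base = _noiseless(exp_spec, heavy_water, schedule11)
        rng = np.random.default_rng(8)
        costs = []
        for _ in range(300):
            noisy = LabelingDataset(
                times=schedule11,
                fraction_labeled=base.fraction_labeled + rng.normal(0, 0.025, 11),
            )
            costs.append(objective_cost(exp_spec, heavy_water, noisy))
        expected = 11 * 0.025**2
        # chi^2_11 mean with relative SE sqrt(2/11)/sqrt(300)
        assert np.mean(costs) == pytest.approx(expected, rel=0.06)

    def test_stochastic_median_of_seeds(self, exp_spec, heavy_water, schedule11):
        data = _noiseless(exp_spec, heavy_water, schedule11)
        per_seed = [
            objective_cost(
                exp_spec, heavy_water, data, engine="stochastic",
                n_seeds=1, base_seed=s, n_cells=1000,
            )
            for s in range(5)
        ]
        med = objective_cost(
            exp_spec, heavy_water, data, engine="stochastic",
            n_seeds=5, base_seed=0, n_cells=1000,
        )
        assert med == pytest.approx(np.median(per_seed), rel=1e-9)
        assert med >= min(per_seed)

    def test_infeasible_point_gets_penalty_cost(self, heavy_water, schedule11):
        from lymphokin.fitting import LOGNORMAL_MODELS, PENALTY_COST, _cost_from_vector

        data = _noiseless(
            PopulationSpec.homogeneous(EventTimeDistribution.exponential(200.0)),
            heavy_water, schedule11,
        )
        ln_cyton = next(
            m for m in LOGNORMAL_MODELS
            if m.heterogeneity == "homogeneous" and m.paradigm is Paradigm.CYTON
        )
        # mode 5000 d with sigma 2.5 implies a mean event time far above 5000 d
        bad = np.array([math.log(5000.0), 2.5])
        assert _cost_from_vector(ln_cyton, bad, heavy_water, data) == PENALTY_COST


class TestFitModel:
    def test_refuses_unsupportable_parameter_count(self, heavy_water, exp_spec):
        sched = default_schedule(6)
        data = _noiseless(exp_spec, heavy_water, sched)
        with pytest.raises(ValueError, match="AICc undefined"):
            fit_model(MODELS["cyton_heterogeneous_gamma"], data, heavy_water, rng=0)

    def test_noiseless_self_fit_recovers_exponential(self, heavy_water, schedule11, exp_spec):
        data = _noiseless(exp_spec, heavy_water, schedule11)
        fit = fit_model(
            MODELS["age_independent_homogeneous_exponential"], data, heavy_water,
            budget=LEAN_BUDGET, rng=1,
        )
        assert fit.ssr < 1e-8
        assert fit.params["mean"] == pytest.approx(200.0, rel=1e-3)

    def test_generating_model_never_beaten_at_equal_complexity(self, heavy_water, schedule11, cyton_spec):
        """On noiseless self-generated data the generating model's optimum is global."""
        data = _noiseless(cyton_spec, heavy_water, schedule11)
        cy = fit_model(MODELS["cyton_homogeneous_gamma"], data, heavy_water, budget=LEAN_BUDGET, rng=1)
        rk = fit_model(MODELS["risk_homogeneous_gamma"], data, heavy_water, budget=LEAN_BUDGET, rng=1)
        assert cy.ssr <= rk.ssr + 1e-12

    def test_deterministic_given_seed(self, heavy_water, schedule11, risk_spec):
        data = _noiseless(risk_spec, heavy_water, schedule11)
        f1 = fit_model(MODELS["risk_homogeneous_gamma"], data, heavy_water, budget=LEAN_BUDGET, rng=7)
        f2 = fit_model(MODELS["risk_homogeneous_gamma"], data, heavy_water, budget=LEAN_BUDGET, rng=7)
        assert f1.params == f2.params
        assert f1.ssr == f2.ssr

    @pytest.mark.parametrize(
        "name,spec_builder",
        [
            (
                "age_independent_homogeneous_exponential",
                lambda: PopulationSpec.homogeneous(EventTimeDistribution.exponential(200.0)),
            ),
            (
                "cyton_homogeneous_gamma",
                lambda: PopulationSpec.homogeneous(EventTimeDistribution.gamma(8.0, 150.0 / 8.0)),
            ),
            (
                "risk_homogeneous_gamma",
                lambda: PopulationSpec.homogeneous(EventTimeDistribution.gamma(0.3, 200.0 / 0.3)),
            ),
            (
                "age_independent_heterogeneous_exponential",
                lambda: PopulationSpec.heterogeneous(
                    EventTimeDistribution.exponential(50.0),
                    EventTimeDistribution.exponential(500.0),
                    0.3,
                ),
            ),
        ],
    )
    def test_noiseless_self_recovery_of_median_lifespan(
        self, heavy_water, schedule11, name, spec_builder
    ):
        """Fitting the generating model to its own expectation curve recovers the
        median lifespan within 2%."""
        spec = spec_builder()
        data = _noiseless(spec, heavy_water, schedule11)
        fit = fit_model(MODELS[name], data, heavy_water, budget=LEAN_BUDGET, rng=3)
        assert median_lifespan(fit.spec) == pytest.approx(median_lifespan(spec), rel=0.02)


class TestCompareModels:
    def test_winner_has_zero_normalized_aicc(self, heavy_water, schedule11, cyton_spec, rng):
        y = expected_labeling_curve(cyton_spec, heavy_water, schedule11).fraction_labeled
        data = LabelingDataset(
            times=schedule11, fraction_labeled=y + rng.normal(0, 0.025, 11)
        )
        table = compare_models(data, heavy_water, budget=LEAN_BUDGET, seed=2)
        winner_entry = table.entry(table.winner)
        assert winner_entry.normalized_aicc == 0.0
        assert all(e.normalized_aicc >= 0.0 for e in table.entries)

    def test_duplicate_models_get_identical_aicc(self, heavy_water, schedule11, exp_spec):
        data = _noiseless(exp_spec, heavy_water, schedule11)
        m = MODELS["risk_homogeneous_gamma"]
        table = compare_models(data, heavy_water, model_set=(m, m), budget=LEAN_BUDGET, seed=5)
        assert table.entries[0].aicc == table.entries[1].aicc

    def test_sparse_data_excludes_five_parameter_models(self, heavy_water, exp_spec, caplog):
        sched = default_schedule(6)
        data = _noiseless(exp_spec, heavy_water, sched)
        import logging

        with caplog.at_level(logging.INFO, logger="lymphokin.fitting"):
            table = compare_models(data, heavy_water, budget=LEAN_BUDGET, seed=1)
        fitted = {e.model.name for e in table.entries}
        assert "cyton_heterogeneous_gamma" not in fitted
        assert "risk_heterogeneous_gamma" not in fitted
        assert any("excluding" in r.message for r in caplog.records)


class TestUnconstrainedGamma:
    def test_cyton_data_yields_shape_above_one(self, heavy_water, schedule11, cyton_spec):
        data = _noiseless(cyton_spec, heavy_water, schedule11)
        res = fit_unconstrained_gamma(data, heavy_water, budget=LEAN_BUDGET, rng=2, n_boot=30)
        assert res.shape == pytest.approx(8.0, rel=0.15)
        assert res.shape_ci[0] > 1.0

    def test_exponential_data_ci_covers_shape_one(self, heavy_water, schedule11, exp_spec):
        """Shape CI contains 1 for most noisy age-independent datasets."""
        base = expected_labeling_curve(exp_spec, heavy_water, schedule11).fraction_labeled
        rng = np.random.default_rng(31)
        covered = 0
        n_rep = 8
        for _ in range(n_rep):
            data = LabelingDataset(
                times=schedule11, fraction_labeled=base + rng.normal(0, 0.025, 11)
            )
            res = fit_unconstrained_gamma(
                data, heavy_water, budget=LEAN_BUDGET, rng=rng, n_boot=40, boot_maxfev=80
            )
            if res.shape_ci[0] <= 1.0 <= res.shape_ci[1]:
                covered += 1
        assert covered >= 6  # >= 75% coverage at this replicate count

    def test_matches_constrained_fit_when_optimum_interior(self, heavy_water, schedule11, cyton_spec):
        data = _noiseless(cyton_spec, heavy_water, schedule11)
        free = fit_unconstrained_gamma(data, heavy_water, budget=LEAN_BUDGET, rng=2, n_boot=5)
        constrained = fit_model(
            MODELS["cyton_homogeneous_gamma"], data, heavy_water, budget=LEAN_BUDGET, rng=2
        )
        assert free.fit.ssr <= constrained.ssr + 1e-9


class TestHazardTrajectories:
    def _fit_with_se(self, se):
        model = MODELS["age_independent_homogeneous_exponential"]
        spec = PopulationSpec.homogeneous(EventTimeDistribution.exponential(200.0))
        return FitResult(
            model=model, spec=spec, params={"mean": 200.0}, ssr=0.01, aicc=-50.0,
            n_obs=11, param_se={"mean": se},
        )

    def test_zero_standard_errors_give_identical_curves(self):
        ages, curves = hazard_trajectory_ensemble(self._fit_with_se(0.0), n_draws=20, rng=0)
        assert curves.shape == (20, ages.size)
        assert np.allclose(curves, curves[0])

    def test_exponential_trajectories_are_horizontal(self):
        _, curves = hazard_trajectory_ensemble(self._fit_with_se(20.0), n_draws=100, rng=1)
        assert curves.shape[0] == 100
        assert np.allclose(curves, curves[:, :1])  # constant in age

    def test_missing_standard_errors_rejected(self):
        from dataclasses import replace

        fit = replace(self._fit_with_se(0.0), param_se=None)
        with pytest.raises(ValueError, match="standard errors"):
            hazard_trajectory_ensemble(fit, rng=0)
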