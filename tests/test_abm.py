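"""Stochastic ABM and deterministic expectation engine."""

import numpy as np
import pytest

from lymphokin import (
    EmptyClassError,
    EventTimeDistribution,
    GlucoseProtocol,
    Population,
    PopulationSpec,
    SimulationConfig,
    advance_day,
    annexin_snapshot,
    expected_labeling_curve,
    initialize_population,
    label_fractions_by_annexin,
    run_labeling_simulation,
)

CONSTANT_LABEL = GlucoseProtocol(U=1.0, tau=1e6)  # normalized availability ≡ 1


def _two_cell_population(spec, ages, t_div, t_die, labels):
    return Population(
        spec=spec,
        age=np.asarray(ages, dtype=float),
        t_div=np.asarray(t_div, dtype=float),
        t_die=np.asarray(t_die, dtype=float),
        label=np.asarray(labels, dtype=float),
        subpop=np.zeros(len(ages), dtype=np.int8),
    )


class TestAdvanceDay:
    @pytest.fixture
    def spec(self):
        return PopulationSpec.homogeneous(EventTimeDistribution.exponential(200.0))

    def test_daughters_unlabeled_without_availability(self, spec, rng):
        pop = _two_cell_population(spec, [0.2], [0.5], [5.0], [0.0])
        advance_day(pop, 0.0, rng)
        assert pop.size == 2
        assert np.all(pop.label == 0.0)
        assert np.all(pop.age == 0.0)

    def test_reset_daughters_carry_full_availability(self, spec, rng):
        pop = _two_cell_population(spec, [0.2], [0.5], [5.0], [0.0])
        advance_day(pop, 1.0, rng, division_labeling="reset")
        assert np.all(pop.label == 1.0)

    def test_semiconservative_daughters_carry_half(self, spec, rng):
        # one of the two strands is newly synthesized at availability 1
        pop = _two_cell_population(spec, [0.2], [0.5], [5.0], [0.0])
        advance_day(pop, 1.0, rng, division_labeling="semiconservative")
        assert np.all(pop.label == 0.5)

    def test_smaller_clock_wins_when_both_crossed(self, spec, rng):
        dying = _two_cell_population(spec, [0.2], [0.9], [0.5], [0.0])
        advance_day(dying, 1.0, rng)
        assert dying.size == 0  # death clock was smaller
        dividing = _two_cell_population(spec, [0.2], [0.5], [0.9], [0.0])
        advance_day(dividing, 1.0, rng)
        assert dividing.size == 2

    def test_label_never_exceeds_mother_or_availability(self, spec):
        """No operation creates label beyond max(mother label, availability)."""
        rng = np.random.default_rng(5)
        pop = initialize_population(spec, SimulationConfig(n_cells=2000), rng)
        for day in range(1, 40):
            avail = 0.7 if day <= 20 else 0.0
            before_max = max(pop.label.max(), avail)
            advance_day(pop, avail, rng)
            assert pop.label.max() <= before_max + 1e-12

    def test_invalid_availability_rejected(self, spec, rng):
        pop = initialize_population(spec, SimulationConfig(n_cells=100), rng)
        with pytest.raises(ValueError):
            advance_day(pop, 1.5, rng)


class TestInitialization:
    def test_subpopulation_counts_deterministic_rounding(self):
        spec = PopulationSpec.heterogeneous(
            EventTimeDistribution.exponential(50.0),
            EventTimeDistribution.exponential(500.0),
            0.3,
        )
        pop = initialize_population(spec, SimulationConfig(n_cells=10_000), np.random.default_rng(0))
        assert int((pop.subpop == 0).sum()) == 3000
        assert int((pop.subpop == 1).sum()) == 7000
        assert np.all(pop.label == 0.0)

    def test_mean_initial_age_matches_stationary_theory(self, exp_spec):
        # exponential clocks: stationary ages are Exp(2λ), mean scale/2 = 100 d
        pop = initialize_population(exp_spec, SimulationConfig(n_cells=40_000), np.random.default_rng(1))
        se = pop.age.std() / np.sqrt(pop.size)
        assert abs(pop.age.mean() - 100.0) < 4 * se

    def test_minimum_population_size_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cells=50)


class TestCriticality:
    @pytest.mark.parametrize(
        "dist",
        [
            EventTimeDistribution.exponential(200.0),
            EventTimeDistribution.gamma(8.0, 150.0 / 8.0),
            EventTimeDistribution.gamma(0.3, 200.0 / 0.3),
        ],
        ids=["age_independent", "cyton", "risk"],
    )
    def test_population_size_stays_near_initial(self, dist):
        """Identical death/division clocks make the branching process critical."""
        spec = PopulationSpec.homogeneous(dist)
        rng = np.random.default_rng(17)
        pop = initialize_population(spec, SimulationConfig(n_cells=10_000), rng)
        for _ in range(300):
            advance_day(pop, 0.0, rng)
        assert 8_500 < pop.size < 11_500


class TestLabelingSimulation:
    def test_zero_availability_curve_identically_zero(self, exp_spec):
        zero = GlucoseProtocol(U=1e-9, tau=1e-9)  # normalized pulse over by day 1
        days = np.array([5.0, 20.0, 60.0])
        sim = run_labeling_simulation(exp_spec, zero, days, SimulationConfig(n_cells=1000, seed=0))
        det = expected_labeling_curve(exp_spec, zero, days)
        assert np.allclose(sim.fraction_labeled, 0.0, atol=1e-6)
        assert np.allclose(det.fraction_labeled[det.times > 1], 0.0, atol=1e-9)

    def test_nonmonotone_sample_days_rejected(self, exp_spec):
        with pytest.raises(ValueError):
            run_labeling_simulation(
                exp_spec, CONSTANT_LABEL, np.array([5.0, 3.0]), SimulationConfig(n_cells=100)
            )


class TestDeterministicEngineClosedForms:
    """The exponential model is solvable in closed form — the decisive oracle."""

    GRID = np.arange(1.0, 351.0)

    def test_reset_labeling_matches_double_rate_exponential(self, exp_spec):
        lam = 1.0 / 200.0
        curve = expected_labeling_curve(exp_spec, CONSTANT_LABEL, self.GRID, "reset")
        expected = 1.0 - np.exp(-2.0 * lam * self.GRID)
        assert np.max(np.abs(curve.fraction_labeled - expected) / expected) < 0.01

    def test_semiconservative_labeling_matches_single_rate_exponential(self, exp_spec):
        lam = 1.0 / 200.0
        curve = expected_labeling_curve(exp_spec, CONSTANT_LABEL, self.GRID, "semiconservative")
        expected = 1.0 - np.exp(-lam * self.GRID)
        assert np.max(np.abs(curve.fraction_labeled - expected) / expected) < 0.01

    def test_delabeling_decay_rates(self, exp_spec):
        """After withdrawal: e^{-2λt} (reset: death + re-division) vs e^{-λt} (death only)."""
        lam = 1.0 / 200.0
        pulse = GlucoseProtocol(U=1.0, tau=63.0)
        tail = np.arange(64.0, 351.0)
        for mode, rate in [("reset", 2.0 * lam), ("semiconservative", lam)]:
            grid = np.concatenate([[63.0], tail])
            c = expected_labeling_curve(exp_spec, pulse, grid, mode).fraction_labeled
            expected = c[0] * np.exp(-rate * (tail - 63.0))
            assert np.max(np.abs(c[1:] - expected) / expected) < 0.02

    def test_interpolates_at_fractional_days(self, exp_spec):
        c = expected_labeling_curve(exp_spec, CONSTANT_LABEL, np.array([10.0, 10.5, 11.0]))
        assert c.fraction_labeled[0] < c.fraction_labeled[1] < c.fraction_labeled[2]
        mid = 0.5 * (c.fraction_labeled[0] + c.fraction_labeled[2])
        assert c.fraction_labeled[1] == pytest.approx(mid, rel=1e-9)


class TestEngineEquivalence:
    @pytest.mark.parametrize(
        "dist",
        [
            EventTimeDistribution.gamma(8.0, 150.0 / 8.0),
            EventTimeDistribution.gamma(0.3, 200.0 / 0.3),
        ],
        ids=["cyton", "risk"],
    )
    def test_stochastic_mean_matches_expectation(self, dist, heavy_water):
        spec = PopulationSpec.homogeneous(dist)
        days = np.array([7.0, 21.0, 63.0, 105.0, 210.0])
        det = expected_labeling_curve(spec, heavy_water, days).fraction_labeled
        sims = np.array(
            [
                run_labeling_simulation(
                    spec, heavy_water, days, SimulationConfig(n_cells=10_000, seed=s)
                ).fraction_labeled
                for s in range(4)
            ]
        )
        mean = sims.mean(axis=0)
        se = np.maximum(
            sims.std(axis=0, ddof=1) / 2.0, np.sqrt(np.maximum(mean * (1 - mean), 1e-6) / 40_000)
        )
        assert np.all(np.abs(mean - det) < 3.5 * se)


class TestAnnexinSnapshot:
    def _labeled_population(self, spec, rng, n=5000):
        pop = initialize_population(spec, SimulationConfig(n_cells=n), rng)
        pulse = GlucoseProtocol(U=1.0, tau=1.0)
        for day in range(1, 4):
            advance_day(pop, float(pulse.normalized(day)), rng)
        return pop

    def test_zero_window_gives_zero_fractions(self, risk_spec, rng):
        pop = self._labeled_population(risk_spec, rng, n=50_000)
        pos_lab, pos_unl = annexin_snapshot(pop, window=0.0)
        assert pos_lab == 0.0 and pos_unl == 0.0

    def test_empty_label_class_raises(self, exp_spec, rng):
        pop = initialize_population(exp_spec, SimulationConfig(n_cells=1000), rng)
        with pytest.raises(EmptyClassError):
            annexin_snapshot(pop)  # nothing labeled yet

    def test_risk_population_shows_signature_at_day_3(self, risk_spec):
        rng = np.random.default_rng(21)
        pop = self._labeled_population(risk_spec, rng, n=100_000)
        pos_lab, pos_unl = annexin_snapshot(pop, window=1.0)
        assert pos_lab > pos_unl

    def test_label_fraction_view_consistent_with_snapshot(self, risk_spec):
        rng = np.random.default_rng(22)
        pop = self._labeled_population(risk_spec, rng, n=100_000)
        g_pos, g_neg, p = label_fractions_by_annexin(pop)
        assert 0.0 < p < 1.0
        assert g_pos > g_neg  # same direction, sorted view

    def test_death_only_lifetime_mode(self, risk_spec):
        rng = np.random.default_rng(23)
        pop = self._labeled_population(risk_spec, rng, n=50_000)
        pos_lab_fe, _ = annexin_snapshot(pop, mode="first_event")
        pos_lab_d, _ = annexin_snapshot(pop, mode="death")
        assert pos_lab_d <= pos_lab_fe  # death-only windows are a subset
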