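"""Gamma risk growth, logistic hospitalization, Poisson stays, queue policies."""

import numpy as np
import pandas as pd
import pytest

import biopriority as bp
from biopriority.simulate import risk_shape


def series(values, name="x"):
    return pd.Series(
        values, index=pd.Index([f"P{i}" for i in range(len(values))], name="patient_id")
    )


class TestRiskModel:
    def test_constant_shape_mean_matches_gamma_closed_form(self):
        config = bp.SimulationConfig(alpha0=2.0, beta0=1.0, delta=0.0, risk_cap=1e9)
        rng = np.random.default_rng(0)
        draws = bp.sample_risk(np.zeros(100_000), config, rng)
        se = np.sqrt(2.0) / np.sqrt(len(draws))  # Var Gamma(2, 1) = 2
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_zero_growth_rate_makes_shape_time_invariant(self):
        config = bp.SimulationConfig(alpha0=2.0, delta=0.5, lambda_t=0.0)
        assert risk_shape(0, config) == pytest.approx(2.5)
        assert risk_shape(365, config) == pytest.approx(2.5)

    def test_expected_risk_strictly_increasing_in_wait(self):
        config = bp.SimulationConfig()
        t = np.arange(0, 200, 10)
        shapes = risk_shape(t, config)
        assert (np.diff(shapes) > 0).all()

    def test_truncation_bounds_all_samples(self):
        config = bp.SimulationConfig()
        rng = np.random.default_rng(1)
        draws = bp.sample_risk(np.full(5000, 400.0), config, rng)
        assert draws.max() <= 10.0
        # at long waits the untruncated mean dwarfs the cap: mass piles at 10
        assert np.mean(draws >= 10.0 - 1e-9) > 0.99

    def test_mean_sampled_risk_nondecreasing_in_elapsed_wait(self):
        config = bp.SimulationConfig()
        rng = np.random.default_rng(2)
        means = [
            bp.sample_risk(np.full(20_000, t), config, rng).mean()
            for t in (0.0, 20.0, 40.0, 60.0)
        ]
        assert (np.diff(means) > 0).all()


class TestHospitalizationModel:
    def test_logistic_midpoint_at_theta_over_gamma(self):
        assert bp.hospitalization_prob(4.5 / 1.8, 1.8, 4.5) == pytest.approx(0.5)

    def test_reference_calibration_values(self):
        assert bp.hospitalization_prob(4.5, 1.8, 4.5) == pytest.approx(
            1 / (1 + np.exp(-3.6)), abs=1e-12
        )
        assert bp.hospitalization_prob(0.0, 1.8, 4.5) == pytest.approx(
            1 / (1 + np.exp(4.5)), abs=1e-12
        )

    def test_strictly_increasing_in_risk(self):
        r = np.linspace(0, 10, 50)
        p = bp.hospitalization_prob(r, 1.8, 4.5)
        assert (np.diff(p) > 0).all()

    def test_empirical_hospitalization_rate_matches_binomial_law(self):
        # gamma -> 0 makes the per-day probability constant 1/(1+e^theta)
        config = bp.SimulationConfig(gamma=1e-12, theta=1.0, horizon=1, capacity=1)
        n = 4000
        entry = series(np.zeros(n, dtype=int))
        scores = series(np.zeros(n))
        rng = np.random.default_rng(3)
        traj = bp.simulate_policy(entry, scores, "chronological", config, rng)
        p = 1 / (1 + np.exp(1.0))
        rate = traj["hospitalized"].mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 3 * se


class TestBedDays:
    def test_poisson_equidispersion_at_baseline_rate(self):
        config = bp.SimulationConfig()
        rng = np.random.default_rng(4)
        draws = bp.sample_bed_days(100_000, config, rng)
        se_mean = np.sqrt(3.8 / len(draws))
        assert abs(draws.mean() - 3.8) < 3 * se_mean
        assert draws.var() == pytest.approx(3.8, rel=0.05)


class TestQueuePolicies:
    def test_instant_clearance_with_ample_capacity(self):
        config = bp.SimulationConfig(capacity=10, horizon=5)
        entry = series([0, 0, 0])
        scores = series([0.1, 0.5, 0.9])
        traj = bp.simulate_policy(entry, scores, "prioritized", config,
                                  np.random.default_rng(0))
        assert (traj["wait"] == 0).all()
        assert not traj["hospitalized"].any()
        assert not traj["censored"].any()

    def test_prioritized_operates_highest_score_first(self):
        config = bp.SimulationConfig(capacity=1, horizon=3, gamma=1e-12, theta=30.0)
        entry = series([0, 0])
        scores = series([0.2, 0.8])
        traj = bp.simulate_policy(entry, scores, "prioritized", config,
                                  np.random.default_rng(0))
        assert traj.loc["P1", "surgery_day"] == 0
        assert traj.loc["P0", "surgery_day"] == 1

    def test_chronological_operates_earliest_entry_first(self):
        config = bp.SimulationConfig(capacity=1, horizon=3, gamma=1e-12, theta=30.0)
        entry = series([-5, -20])
        scores = series([0.9, 0.1])
        traj = bp.simulate_policy(entry, scores, "chronological", config,
                                  np.random.default_rng(0))
        assert traj.loc["P1", "surgery_day"] == 0  # longest waiter first

    def test_undercapacity_censors_remaining_patients(self):
        config = bp.SimulationConfig(capacity=1, horizon=2, gamma=1e-12, theta=30.0)
        entry = series([0, 0, 0])
        scores = series([0.3, 0.2, 0.1])
        traj = bp.simulate_policy(entry, scores, "prioritized", config,
                                  np.random.default_rng(0))
        assert traj["censored"].sum() == 1
        assert traj.loc["P2", "wait"] == 2  # horizon - entry

    def test_escalation_moves_hospitalized_to_front(self):
        # force certain hospitalization: theta very negative -> p ~ 1
        config = bp.SimulationConfig(capacity=1, horizon=4, gamma=1.8, theta=-30.0)
        entry = series([0, 0, 0])
        scores = series([0.9, 0.5, 0.1])
        traj = bp.simulate_policy(entry, scores, "prioritized", config,
                                  np.random.default_rng(0))
        # day 0: P0 operated, P1 and P2 hospitalized; escalation keeps
        # policy order among escalated -> P1 then P2
        assert traj.loc["P0", "surgery_day"] == 0
        assert traj.loc["P1", "surgery_day"] == 1
        assert traj.loc["P2", "surgery_day"] == 2
        assert traj.loc["P1", "hospitalized"] and traj.loc["P2", "hospitalized"]

    def test_at_most_one_admission_per_patient(self):
        config = bp.SimulationConfig(capacity=1, horizon=30, theta=-30.0,
                                     escalate_hospitalized=False)
        entry = series([0] * 5)
        scores = series(np.linspace(0, 1, 5))
        traj = bp.simulate_policy(entry, scores, "chronological", config,
                                  np.random.default_rng(0))
        assert (traj["hosp_day"].dropna() >= 0).all()
        assert traj["hospitalized"].sum() == 4  # all but the day-0 surgery


@pytest.fixture(scope="module")
def backlog(scored_cohort):
    cohort, _, _, scores = scored_cohort
    from biopriority.synth import entry_days_from_cohort

    entry = entry_days_from_cohort(cohort)
    labels = bp.assign_priority_labels(scores).labels
    return entry, scores, labels == "High"


class TestMonteCarlo:
    def test_fixed_seed_reproduces_summary_bitwise(self, backlog):
        entry, scores, high = backlog
        config = bp.SimulationConfig(seed=7, n_iterations=5)
        a = bp.monte_carlo_compare(entry, scores, high, config)
        b = bp.monte_carlo_compare(entry, scores, high, config)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_equivalent_policies_agree_under_common_random_numbers(self, backlog):
        entry, _, high = backlog
        # scores that reproduce the chronological order exactly
        scores = (-entry).astype(float)
        config = bp.SimulationConfig(seed=8, n_iterations=4)
        summary = bp.monte_carlo_compare(entry, scores, high, config)
        chron = summary.table.loc["chronological"]
        prio = summary.table.loc["prioritized"]
        np.testing.assert_allclose(chron["mean"], prio["mean"])

    def test_prioritized_shortens_high_priority_wait(self, backlog):
        entry, scores, high = backlog
        config = bp.SimulationConfig(seed=9, n_iterations=20)
        summary = bp.monte_carlo_compare(entry, scores, high, config)
        reps = summary.replicates.pivot(
            index="replicate", columns="policy", values="mean_wait_high_priority"
        )
        diff = reps["prioritized"] - reps["chronological"]
        assert (diff <= 0).mean() >= 0.95
        assert diff.mean() < 0

    def test_mean_bed_days_recover_poisson_rate(self, backlog):
        entry, scores, high = backlog
        config = bp.SimulationConfig(seed=10, n_iterations=25)
        summary = bp.monte_carlo_compare(entry, scores, high, config)
        val = summary.table.loc[("chronological", "mean_bed_days_per_hospitalized"), "mean"]
        assert val == pytest.approx(3.8, rel=0.05)

    def test_single_iteration_has_no_confidence_interval(self, backlog):
        entry, scores, high = backlog
        with pytest.raises(ValueError, match="n_iterations"):
            bp.monte_carlo_compare(entry, scores, high,
                                   bp.SimulationConfig(seed=1, n_iterations=1))

    def test_invalid_config_parameters_rejected(self):
        with pytest.raises(ValueError):
            bp.SimulationConfig(lambda_d=0.0)
        with pytest.raises(ValueError):
            bp.SimulationConfig(horizon=0)
        with pytest.raises(ValueError):
            bp.SimulationConfig(alpha0=-1.0)
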