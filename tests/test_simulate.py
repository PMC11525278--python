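"""Tests for the model-based simulator, GLS and ML estimation."""

import numpy as np
import pandas as pd
import pytest

from crxo import (
    CorrelationParams,
    DesignSpec,
    FixedEffects,
    TreatmentSequence,
    aggregate_cluster_periods,
    gls_estimate,
    ml_fit,
    monte_carlo_variance,
    sequence_design_matrix,
    simulate_trial,
    treatment_variance,
)


@pytest.fixture
def small_design() -> DesignSpec:
    return DesignSpec(sequence=TreatmentSequence("ABBA"), K=8, m=5)


@pytest.fixture
def effects() -> FixedEffects:
    return FixedEffects(mu=1.0, beta=(0.2, -0.1, 0.3), theta=0.5)


class TestSimulateTrial:
    def test_record_count_and_schema(self, small_design, effects):
        trial = simulate_trial(small_design, CorrelationParams(0.1, 0.9), effects, seed=7)
        assert len(trial.records) == 8 * 4 * 5
        assert list(trial.records.columns) == [
            "cluster", "arm", "period", "subject", "treatment", "outcome",
        ]
        # within one cluster-period every subject shares the treatment
        per_cell = trial.records.groupby(["cluster", "period"])["treatment"].nunique()
        assert (per_cell == 1).all()
        # arms split K/2 / K/2 with mirrored exposure patterns
        arm_sizes = trial.records.groupby("arm")["cluster"].nunique()
        assert list(arm_sizes) == [4, 4]

    def test_seed_determinism(self, small_design, effects):
        params = CorrelationParams(0.1, 0.9)
        a = simulate_trial(small_design, params, effects, seed=42)
        b = simulate_trial(small_design, params, effects, seed=42)
        c = simulate_trial(small_design, params, effects, seed=43)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert not a.records["outcome"].equals(c.records["outcome"])

    def test_adding_clusters_preserves_existing_draws(self, effects):
        params = CorrelationParams(0.1, 0.9)
        small = DesignSpec(sequence=TreatmentSequence("ABBA"), K=8, m=5)
        large = DesignSpec(sequence=TreatmentSequence("ABBA"), K=12, m=5)
        a = simulate_trial(small, params, effects, seed=3).records
        b = simulate_trial(large, params, effects, seed=3).records
        for arm in (0, 1):
            arm_a = a[a["arm"] == arm]["outcome"].to_numpy()
            arm_b = b[b["arm"] == arm]["outcome"].to_numpy()
            np.testing.assert_array_equal(arm_a, arm_b[: len(arm_a)])

    def test_noiseless_limit_recovers_fixed_effects(self, small_design, effects):
        params = CorrelationParams(0.5, 0.9, total_variance=1e-12)
        trial = simulate_trial(small_design, params, effects, seed=1)
        X = sequence_design_matrix(small_design.sequence)
        expected_arm0 = X @ effects.gamma()
        arm0 = trial.records[(trial.records["arm"] == 0) & (trial.records["cluster"] == 0)]
        np.testing.assert_allclose(
            arm0.groupby("period")["outcome"].mean().to_numpy(), expected_arm0, atol=1e-5
        )


class TestAggregation:
    def test_shape_and_constant_outcomes(self, small_design, effects):
        trial = simulate_trial(small_design, CorrelationParams(0.1, 0.9), effects, seed=5)
        means = aggregate_cluster_periods(trial)
        assert len(means) == 8 * 4
        constant = trial.records.assign(outcome=3.25)
        trial_const = type(trial)(records=constant, design=trial.design, seed=trial.seed)
        assert (aggregate_cluster_periods(trial_const)["mean_outcome"] == 3.25).all()

    def test_cluster_period_mean_variance(self, effects):
        # var of a cluster-period mean = sigma2_eps/m + sigma2_cp
        design = DesignSpec(sequence=TreatmentSequence("AB"), K=300, m=4)
        params = CorrelationParams(0.2, 0.9, total_variance=2.0)
        trial = simulate_trial(design, params, FixedEffects.null(2), seed=11)
        means = aggregate_cluster_periods(trial)
        observed = means.groupby(["arm", "period"])["mean_outcome"].var(ddof=1).mean()
        expected = params.sigma2_eps / 4 + params.sigma2_cp
        assert observed == pytest.approx(expected, rel=0.25)


class TestGLS:
    def test_noiseless_interpolation(self, small_design, effects):
        params = CorrelationParams(0.5, 0.9, total_variance=1e-12)
        trial = simulate_trial(small_design, params, effects, seed=2)
        gamma_hat, _ = gls_estimate(aggregate_cluster_periods(trial), small_design, params)
        np.testing.assert_allclose(gamma_hat, effects.gamma(), atol=1e-6)

    def test_reported_covariance_equals_analytic(self, small_design, effects):
        params = CorrelationParams(0.1, 0.9)
        trial = simulate_trial(small_design, params, effects, seed=2)
        _, cov = gls_estimate(aggregate_cluster_periods(trial), small_design, params)
        analytic = treatment_variance(small_design, params)
        np.testing.assert_allclose(cov.matrix, analytic.matrix, rtol=1e-10)

    def test_matches_subject_level_gls(self, effects):
        # GLS on cluster-period means equals GLS on the full individual model.
        design = DesignSpec(sequence=TreatmentSequence("ABA"), K=6, m=3)
        params = CorrelationParams(0.15, 0.8)
        eff = FixedEffects(mu=1.0, beta=(0.2, -0.1), theta=0.5)
        trial = simulate_trial(design, params, eff, seed=9)
        gamma_means, _ = gls_estimate(aggregate_cluster_periods(trial), design, params)

        T, m = 3, 3
        lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        Sigma = np.kron(params.sigma2_cp * params.r**lag, np.ones((m, m)))
        Sigma += params.sigma2_eps * np.eye(T * m)
        Sigma_inv = np.linalg.inv(Sigma)
        info = np.zeros((T + 1, T + 1))
        score = np.zeros(T + 1)
        for cluster, group in trial.records.groupby("cluster"):
            group = group.sort_values(["period", "subject"])
            labels = "".join(
                "B" if x else "A"
                for x in group.groupby("period")["treatment"].first()
            )
            Z = np.kron(sequence_design_matrix(labels), np.ones((m, 1)))
            info += Z.T @ Sigma_inv @ Z
            score += Z.T @ Sigma_inv @ group["outcome"].to_numpy()
        gamma_subject = np.linalg.solve(info, score)
        np.testing.assert_allclose(gamma_means, gamma_subject, rtol=1e-8, atol=1e-10)

    def test_unbiased_over_replicates(self):
        design = DesignSpec(sequence=TreatmentSequence("ABAB"), K=20, m=5)
        params = CorrelationParams(0.1, 0.9)
        result = monte_carlo_variance(design, params, n_replicates=300, seed=17)
        mc_se = np.sqrt(result["analytic_var"] / 300)
        assert abs(result["theta_hat_mean"] - result["theta_true"]) < 3 * mc_se

    def test_empirical_variance_tracks_analytic(self):
        design = DesignSpec(sequence=TreatmentSequence("ABAB"), K=20, m=5)
        params = CorrelationParams(0.1, 0.9)
        result = monte_carlo_variance(design, params, n_replicates=300, seed=23)
        # 99% chi-square band at 300 replicates is roughly +-20%
        assert 0.8 < result["ratio"] < 1.25


@pytest.fixture(scope="module")
def fitted():
    design = DesignSpec(sequence=TreatmentSequence("ABAB"), K=200, m=25)
    params = CorrelationParams(0.1, 0.95)
    eff = FixedEffects.null(4, theta=0.5)
    trial = simulate_trial(design, params, eff, seed=31)
    means = aggregate_cluster_periods(trial)
    return design, params, eff, means, ml_fit(means, design)


class TestMLFit:
    def test_recovers_parameters_roughly(self, fitted):
        design, params, eff, means, fit = fitted
        assert fit.converged
        assert abs(fit.r_hat - 0.95) < 0.15
        assert abs(fit.rho_hat - 0.10) < 0.08
        assert abs(fit.theta_hat - 0.5) < 0.1

    def test_loglik_at_fit_beats_truth(self, fitted):
        design, params, eff, means, fit = fitted
        from crxo.simulate import _negloglik, _stacked_means

        Y, arms = _stacked_means(means, design)
        eta_true = np.array(
            [
                np.log(params.sigma2_cp),
                np.log(params.sigma2_eps / design.m),
                np.log(params.r / (1 - params.r)),
            ]
        )
        assert fit.loglik >= -_negloglik(eta_true, Y, arms, design) - 1e-6

    def test_profiling_identity(self, fitted):
        design, params, eff, means, fit = fitted
        fitted_components = CorrelationParams(
            rho=fit.rho_hat,
            r=fit.r_hat,
            total_variance=fit.sigma2_cp_hat + fit.sigma2_eps_hat,
        )
        gamma_gls, _ = gls_estimate(means, design, fitted_components)
        np.testing.assert_allclose(fit.gamma_hat, gamma_gls, rtol=1e-8, atol=1e-10)
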