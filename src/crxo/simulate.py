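"""Model-based simulator and estimation: an independent Monte-Carlo check of
the analytic variance of the treatment-effect estimator.

Trials are generated from the same mixed model the variance engine assumes:
per cluster a length-T vector of cluster-period effects drawn from
``N(0, sigma2_cp * R)`` with exponential-decay correlation ``R``, plus
independent subject-level noise.  Estimation works on cluster-period means
(whose covariance is the engine's ``V``), either by GLS with known variance
components or by maximum likelihood over (sigma2_cp, sigma2_eps/m, r) with
the fixed effects profiled out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import InvalidParameterError, SingularCovarianceError
from .variance import (
    CorrelationParams,
    DesignSpec,
    FixedEffectsCovariance,
    cluster_period_covariance,
    exp_decay_correlation,
    sequence_design_matrix,
    treatment_variance,
)

__all__ = [
    "FixedEffects",
    "SimulatedTrial",
    "MLFit",
    "simulate_trial",
    "aggregate_cluster_periods",
    "gls_estimate",
    "ml_fit",
    "monte_carlo_variance",
]

RECORD_COLUMNS = ["cluster", "arm", "period", "subject", "treatment", "outcome"]


@dataclass(frozen=True)
class FixedEffects:
    """Fixed effects of the outcome model: overall mean, period effects
    beta_2..beta_T (beta_1 = 0) and the treatment effect theta."""

    mu: float
    beta: tuple[float, ...]
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))

    def gamma(self) -> np.ndarray:
        """Stacked coefficient vector (mu, beta_2..beta_T, theta)."""
        return np.array([self.mu, *self.beta, self.theta])

    @classmethod
    def null(cls, n_periods: int, theta: float = 0.0) -> "FixedEffects":
        """Zero mean and period effects; handy for variance validation."""
        return cls(mu=0.0, beta=(0.0,) * (n_periods - 1), theta=theta)


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated trial: a record per subject plus its provenance."""

    records: pd.DataFrame = field(repr=False)
    design: DesignSpec
    seed: int

    def __post_init__(self) -> None:
        expected = self.design.K * self.design.n_periods * self.design.m
        if len(self.records) != expected:
            raise InvalidParameterError(
                f"expected {expected} records, got {len(self.records)}"
            )

    def to_csv(self, path) -> None:
        """Export one row per subject for external mixed-model software."""
        self.records.to_csv(path, index=False)


@dataclass(frozen=True)
class MLFit:
    """Maximum-likelihood fit of the cluster-period means model."""

    gamma_hat: np.ndarray
    sigma2_cp_hat: float
    sigma2_eps_hat: float
    r_hat: float
    loglik: float
    converged: bool
    at_boundary: bool = False

    @property
    def rho_hat(self) -> float:
        total = self.sigma2_cp_hat + self.sigma2_eps_hat
        return self.sigma2_cp_hat / total if total > 0 else float("nan")

    @property
    def theta_hat(self) -> float:
        return float(self.gamma_hat[-1])


def _arm_effects(effects: FixedEffects, design: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Period-level mean response for each arm (without random effects)."""
    X1 = sequence_design_matrix(design.sequence)
    X2 = sequence_design_matrix(design.sequence.mirror())
    gamma = effects.gamma()
    if len(gamma) != design.n_periods + 1:
        raise InvalidParameterError(
            f"effects imply {len(gamma) - 1} periods, design has {design.n_periods}"
        )
    return X1 @ gamma, X2 @ gamma


def simulate_trial(
    design: DesignSpec,
    params: CorrelationParams,
    effects: FixedEffects,
    seed: int,
) -> SimulatedTrial:
    """Draw one trial from the mixed model.

    Each cluster gets its own random stream keyed by (seed, arm, cluster), so
    enlarging the trial leaves previously drawn clusters untouched.  Within a
    cluster, the length-T vector of cluster-period effects is ``L z`` with
    ``L`` the Cholesky factor of ``sigma2_cp * R``, and each subject adds an
    independent ``N(0, sigma2_eps)`` error.
    """
    T, m, K = design.n_periods, design.m, design.K
    arm_means = _arm_effects(effects, design)
    arm_seqs = (design.sequence, design.sequence.mirror())
    if params.sigma2_cp > 0.0:
        L = np.linalg.cholesky(
            params.sigma2_cp * exp_decay_correlation(params.r, T)
            + 1e-14 * params.sigma2_cp * np.eye(T)
        )
    else:
        L = np.zeros((T, T))
    sd_eps = np.sqrt(params.sigma2_eps)

    outcomes = np.empty((K, T, m))
    cluster_id = 0
    arm_of_cluster = np.empty(K, int)
    for arm in (0, 1):
        for c in range(K // 2):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(arm, c)))
            cp = L @ rng.standard_normal(T)
            eps = sd_eps * rng.standard_normal((T, m))
            outcomes[cluster_id] = arm_means[arm][:, None] + cp[:, None] + eps
            arm_of_cluster[cluster_id] = arm
            cluster_id += 1
    treat = np.stack([arm_seqs[a].indicator.astype(int) for a in (0, 1)])
    records = pd.DataFrame(
        {
            "cluster": np.repeat(np.arange(K), T * m),
            "arm": np.repeat(arm_of_cluster, T * m),
            "period": np.tile(np.repeat(np.arange(1, T + 1), m), K),
            "subject": np.tile(np.arange(1, m + 1), K * T),
            "treatment": np.repeat(treat[arm_of_cluster], m, axis=1).ravel(),
            "outcome": outcomes.ravel(),
        }
    )[RECORD_COLUMNS]
    return SimulatedTrial(records=records, design=design, seed=seed)


def aggregate_cluster_periods(trial: SimulatedTrial) -> pd.DataFrame:
    """Cluster-period means: K*T rows with arm, period and treatment carried.

    Requires a balanced trial (every cluster-period cell with exactly m
    subjects), which :func:`simulate_trial` guarantees.
    """
    grouped = trial.records.groupby(["cluster", "arm", "period", "treatment"], sort=True)
    sizes = grouped.size()
    if len(sizes) != trial.design.K * trial.design.n_periods:
        raise InvalidParameterError("missing cluster-period cells: design must be balanced")
    if not (sizes == trial.design.m).all():
        raise InvalidParameterError("unequal cluster-period sizes are not supported")
    means = grouped["outcome"].mean().rename("mean_outcome").reset_index()
    return means


def _stacked_means(means: pd.DataFrame, design: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Means as a (K, T) array plus each cluster's arm index, period-sorted."""
    T = design.n_periods
    pivot = means.sort_values(["cluster", "period"])
    Y = pivot["mean_outcome"].to_numpy().reshape(design.K, T)
    arms = pivot.groupby("cluster", sort=True)["arm"].first().to_numpy()
    return Y, arms


def _profile_gls(
    Y: np.ndarray, arms: np.ndarray, design: DesignSpec, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed effects and their covariance for given V; used directly and
    inside the ML profile likelihood."""
    X = [sequence_design_matrix(design.sequence), sequence_design_matrix(design.sequence.mirror())]
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(f"V is singular: {exc}") from exc
    info = np.zeros((design.n_periods + 1,) * 2)
    score = np.zeros(design.n_periods + 1)
    for arm in (0, 1):
        Xa = X[arm]
        XtVi = Xa.T @ Vinv
        n_arm = int((arms == arm).sum())
        info += n_arm * (XtVi @ Xa)
        score += XtVi @ Y[arms == arm].sum(axis=0)
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    return cov @ score, cov


def gls_estimate(
    means: pd.DataFrame,
    design: DesignSpec,
    params: CorrelationParams,
) -> tuple[np.ndarray, FixedEffectsCovariance]:
    """GLS estimate of the fixed effects with known variance components.

    The reported covariance is the same matrix the design-stage variance
    engine produces, so this is the estimator whose var(theta_hat) the
    analytic formula predicts.
    """
    Y, arms = _stacked_means(means, design)
    V = cluster_period_covariance(params, design.m, design.n_periods)
    gamma_hat, cov = _profile_gls(Y, arms, design, V)
    analytic = treatment_variance(design, params)
    scale = np.abs(analytic.matrix).max()
    if not np.allclose(cov, analytic.matrix, rtol=1e-8, atol=1e-10 * scale):
        raise SingularCovarianceError("GLS covariance disagrees with the analytic formula")
    return gamma_hat, analytic


def _negloglik(
    eta: np.ndarray, Y: np.ndarray, arms: np.ndarray, design: DesignSpec
) -> float:
    """Profile negative log-likelihood at eta = (log s2_cp, log s2_eff, logit r)."""
    T = design.n_periods
    s2_cp, s2_eff = np.exp(eta[0]), np.exp(eta[1])
    r = 1.0 / (1.0 + np.exp(-eta[2]))
    V = s2_eff * np.eye(T) + s2_cp * exp_decay_correlation(r, T)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return np.inf
    try:
        gamma, _ = _profile_gls(Y, arms, design, V)
    except SingularCovarianceError:
        return np.inf
    X = [sequence_design_matrix(design.sequence), sequence_design_matrix(design.sequence.mirror())]
    Vinv = np.linalg.inv(V)
    resid = Y - np.stack([X[a] @ gamma for a in arms])
    quad = float(np.einsum("kt,ts,ks->", resid, Vinv, resid))
    K = design.K
    return 0.5 * (K * T * np.log(2.0 * np.pi) + K * logdet + quad)


def _moment_start(Y: np.ndarray, arms: np.ndarray, total: float) -> np.ndarray:
    """Method-of-moments starting point from the pooled residual covariance.

    Lag-1 and lag-2 autocovariances of the cluster-period means identify
    (sigma2_cp, r); the remaining lag-0 variance goes to sigma2_eff.
    """
    E = Y.copy()
    for arm in (0, 1):
        mask = arms == arm
        if mask.any():
            E[mask] -= Y[mask].mean(axis=0)
    S = E.T @ E / max(len(Y) - 2, 1)
    T = S.shape[0]
    lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    v0 = float(np.mean(np.diag(S)))
    c1 = float(S[lag == 1].mean())
    c2 = float(S[lag == 2].mean()) if T > 2 else c1 * 0.9
    floor = 1e-4 * total
    if c1 <= floor:
        return np.array([np.log(total / 2.0), np.log(total / 2.0), 1.0])
    r0 = np.clip(c2 / c1, 0.05, 0.99)
    s2_cp0 = np.clip(c1 / r0, floor, max(v0 - floor, floor))
    s2_eff0 = max(v0 - s2_cp0, floor)
    return np.array([np.log(s2_cp0), np.log(s2_eff0), np.log(r0 / (1.0 - r0))])


def ml_fit(
    means: pd.DataFrame,
    design: DesignSpec,
    *,
    xtol: float = 1e-8,
    max_iter: int = 2000,
) -> MLFit:
    """Maximum-likelihood fit of the cluster-period means model.

    Optimizes the multivariate-normal log-likelihood over
    ``(log sigma2_cp, log sigma2_eff, logit r)`` — where ``sigma2_eff`` is the
    means-level residual variance ``sigma2_eps / m`` — with the fixed effects
    profiled out by GLS at every point (Nelder-Mead; constraints are implicit
    in the parameterization).  Non-convergence is flagged, not raised.
    """
    Y, arms = _stacked_means(means, design)
    total = float(Y.var(ddof=1))
    if total <= 0.0:
        total = 1e-8
    starts = [np.array([np.log(total / 2.0), np.log(total / 2.0), 0.0])]
    starts.append(_moment_start(Y, arms, total))
    result = None
    for start in starts:
        candidate = minimize(
            _negloglik,
            start,
            args=(Y, arms, design),
            method="Nelder-Mead",
            options={"xatol": xtol, "fatol": xtol, "maxiter": max_iter},
        )
        if result is None or candidate.fun < result.fun:
            result = candidate
    s2_cp, s2_eff = np.exp(result.x[0]), np.exp(result.x[1])
    r_hat = float(1.0 / (1.0 + np.exp(-result.x[2])))
    V = s2_eff * np.eye(design.n_periods) + s2_cp * exp_decay_correlation(
        r_hat, design.n_periods
    )
    gamma_hat, _ = _profile_gls(Y, arms, design, V)
    at_boundary = bool(
        s2_cp < 1e-10 * (s2_cp + s2_eff) or r_hat < 1e-8 or r_hat > 1.0 - 1e-8
    )
    return MLFit(
        gamma_hat=gamma_hat,
        sigma2_cp_hat=float(s2_cp),
        sigma2_eps_hat=float(s2_eff * design.m),
        r_hat=r_hat,
        loglik=-float(result.fun),
        converged=bool(result.success),
        at_boundary=at_boundary,
    )


def monte_carlo_variance(
    design: DesignSpec,
    params: CorrelationParams,
    n_replicates: int,
    seed: int,
    effects: FixedEffects | None = None,
) -> dict:
    """Empirical variance of theta_hat across replicated trials.

    Runs the full pipeline (simulate -> aggregate to cluster-period means ->
    GLS with known components) ``n_replicates`` times and compares the
    spread of theta_hat with the analytic var(theta_hat).
    """
    if effects is None:
        effects = FixedEffects.null(design.n_periods, theta=0.5)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    estimates = np.empty(n_replicates)
    for i, s in enumerate(rep_seeds):
        trial = simulate_trial(design, params, effects, int(s))
        means = aggregate_cluster_periods(trial)
        gamma_hat, _ = gls_estimate(means, design, params)
        estimates[i] = gamma_hat[-1]
    analytic = treatment_variance(design, params).var_theta
    return {
        "theta_hat_mean": float(estimates.mean()),
        "theta_hat_var": float(estimates.var(ddof=1)),
        "analytic_var": float(analytic),
        "ratio": float(estimates.var(ddof=1) / analytic),
        "n_replicates": n_replicates,
        "theta_true": effects.theta,
    }
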