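"""Variance of the treatment-effect estimator in a two-arm cluster randomized
crossover (CRXO) trial.

The outcome of subject ``i`` enrolled in period ``t`` of cluster ``k`` is
modelled by the linear mixed model

    Y_kti = mu + beta_t + theta * X_kt + CP_kt + eps_kti,

with ``beta_1 = 0`` for identifiability, treatment indicator ``X_kt`` in
{0, 1}, random cluster-period effects ``CP_kt ~ N(0, sigma2_cp)`` whose
correlation decays exponentially with period lag,
``cov(CP_kt, CP_kt') = sigma2_cp * r**|t - t'|``, and i.i.d. subject error
``eps_kti ~ N(0, sigma2_eps)``.  Collapsing to cluster-period means gives a
length-``T`` response per cluster with covariance

    V = (sigma2_eps / m) * I + sigma2_cp * R,      R[t, t'] = r**|t - t'|,

where ``m`` is the cluster-period size.  With ``K/2`` clusters following a
treatment sequence and ``K/2`` its mirror, generalized least squares yields

    var(gamma_hat) = ( (K/2) X1' V^-1 X1 + (K/2) X2' V^-1 X2 )^-1

for the fixed effects gamma = (mu, beta_2, ..., beta_T, theta)'.  The last
diagonal entry, var(theta_hat), is the design criterion minimized by the
optimal design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import InvalidParameterError, SingularCovarianceError, SmallSampleWarning

__all__ = [
    "CorrelationParams",
    "TreatmentSequence",
    "DesignSpec",
    "FixedEffectsCovariance",
    "correlation_decay",
    "exp_decay_correlation",
    "cluster_period_covariance",
    "sequence_design_matrix",
    "treatment_variance",
]

#: Default upper bound on the number of time periods considered in design
#: searches (roughly a year of monthly periods, or a quarter of weekly ones).
MAX_PERIODS = 12


@dataclass(frozen=True)
class CorrelationParams:
    """Variance components of the cluster-period model.

    Parameters
    ----------
    rho : float
        Intraclass correlation, the proportion of total outcome variance at
        the cluster-period level, ``sigma2_cp / (sigma2_cp + sigma2_eps)``.
        In [0, 1].
    r : float
        Cluster autocorrelation: the correlation of cluster-period effects
        one period apart; at lag ``l`` the correlation is ``r**l``.  In [0, 1].
    total_variance : float, default 1.0
        Total outcome variance ``sigma2_cp + sigma2_eps``.  Every relative
        efficiency is invariant to this scale, so the default of 1 is the
        natural design-stage choice.
    """

    rho: float
    r: float
    total_variance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise InvalidParameterError(f"rho must be in [0, 1], got {self.rho}")
        if not 0.0 <= self.r <= 1.0:
            raise InvalidParameterError(f"r must be in [0, 1], got {self.r}")
        if not self.total_variance > 0.0:
            raise InvalidParameterError(
                f"total_variance must be positive, got {self.total_variance}"
            )
        if self.rho == 1.0 and self.r == 1.0:
            raise InvalidParameterError(
                "rho = 1 with r = 1 makes the cluster-period covariance singular"
            )

    @property
    def sigma2_cp(self) -> float:
        """Cluster-period effect variance, ``rho * total_variance``."""
        return self.rho * self.total_variance

    @property
    def sigma2_eps(self) -> float:
        """Subject-level error variance, ``(1 - rho) * total_variance``."""
        return (1.0 - self.rho) * self.total_variance


@dataclass(frozen=True)
class TreatmentSequence:
    """Ordered treatment labels over {A, B} for one arm of the trial.

    The second arm always follows the mirror sequence (A and B swapped at
    every period), so one sequence determines the whole two-arm design.
    """

    labels: str

    def __post_init__(self) -> None:
        labels = "".join(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise InvalidParameterError("a treatment sequence needs at least 2 periods")
        if set(labels) - {"A", "B"}:
            raise InvalidParameterError(
                f"sequence may contain only labels 'A' and 'B', got {labels!r}"
            )

    @property
    def n_periods(self) -> int:
        return len(self.labels)

    @property
    def switches(self) -> int:
        """Number of adjacent periods with different treatments (0..T-1)."""
        return sum(a != b for a, b in zip(self.labels, self.labels[1:]))

    @property
    def indicator(self) -> np.ndarray:
        """Treatment indicator per period: 0 for A (control), 1 for B."""
        return np.fromiter((1.0 if c == "B" else 0.0 for c in self.labels), float)

    def mirror(self) -> "TreatmentSequence":
        """The opposite arm: A and B swapped at every period."""
        return TreatmentSequence("".join("B" if c == "A" else "A" for c in self.labels))

    def reverse(self) -> "TreatmentSequence":
        """The sequence read backwards in time."""
        return TreatmentSequence(self.labels[::-1])

    @classmethod
    def alternating(cls, n_periods: int) -> "TreatmentSequence":
        """The sequence ABAB... with a treatment switch at every period."""
        if n_periods < 2:
            raise InvalidParameterError("alternating sequence needs at least 2 periods")
        return cls("AB" * (n_periods // 2) + "A" * (n_periods % 2))

    def __str__(self) -> str:
        return self.labels


def as_sequence(sequence: "TreatmentSequence | str") -> TreatmentSequence:
    """Coerce a plain string of labels to a :class:`TreatmentSequence`."""
    if isinstance(sequence, TreatmentSequence):
        return sequence
    return TreatmentSequence(sequence)


@dataclass(frozen=True)
class DesignSpec:
    """A complete two-arm CRXO design.

    ``K/2`` clusters follow ``sequence`` and ``K/2`` its mirror; each cluster
    enrols ``m`` fresh subjects per period (cross-sectional design).
    """

    sequence: TreatmentSequence
    K: int
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", as_sequence(self.sequence))
        if self.K < 2 or self.K % 2 != 0:
            raise InvalidParameterError(f"K must be an even integer >= 2, got {self.K}")
        if self.m < 1:
            raise InvalidParameterError(f"m must be a positive integer, got {self.m}")
        if self.K < 20:
            warnings.warn(
                f"K = {self.K} clusters; random cluster effects are not recommended "
                "below 20 clusters",
                SmallSampleWarning,
                stacklevel=2,
            )

    @property
    def n_periods(self) -> int:
        return self.sequence.n_periods


@dataclass(frozen=True)
class FixedEffectsCovariance:
    """GLS covariance of the fixed effects (mu, beta_2..beta_T, theta).

    ``var_theta`` is the last diagonal entry: the variance of the
    treatment-effect estimator, the design optimality criterion.
    """

    matrix: np.ndarray = field(repr=False)
    var_theta: float

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, float)
        object.__setattr__(self, "matrix", mat)
        scale = np.abs(mat).max()
        if not np.allclose(mat, mat.T, rtol=0.0, atol=1e-10 * scale):
            raise SingularCovarianceError("fixed-effects covariance is not symmetric")
        if np.any(np.diag(mat) <= 0.0):
            raise SingularCovarianceError("fixed-effects covariance has a nonpositive variance")
        if self.var_theta != mat[-1, -1]:
            raise InvalidParameterError("var_theta must equal the last diagonal entry")


def correlation_decay(r: float, lag: int) -> float:
    """Decay in correlation between cluster-periods ``lag`` periods apart.

    Returns ``1 - r**lag``; the decay between the first and last of ``T``
    periods is obtained at ``lag = T - 1``.
    """
    if not 0.0 <= r <= 1.0:
        raise InvalidParameterError(f"r must be in [0, 1], got {r}")
    if lag < 0:
        raise InvalidParameterError(f"lag must be nonnegative, got {lag}")
    return 1.0 - float(r) ** lag


def exp_decay_correlation(r: float, n_periods: int) -> np.ndarray:
    """Exponential-decay correlation matrix ``R[t, t'] = r**|t - t'|``."""
    if not 0.0 <= r <= 1.0:
        raise InvalidParameterError(f"r must be in [0, 1], got {r}")
    if n_periods < 1:
        raise InvalidParameterError(f"n_periods must be >= 1, got {n_periods}")
    idx = np.arange(n_periods)
    return float(r) ** np.abs(idx[:, None] - idx[None, :])


def cluster_period_covariance(
    params: CorrelationParams, m: int, n_periods: int
) -> np.ndarray:
    """Covariance ``V`` of the ``T`` cluster-period mean responses of one cluster.

    ``V = (sigma2_eps / m) I + sigma2_cp R`` with ``R`` the exponential-decay
    correlation matrix.  Positive definite for every admissible parameter
    combination (the joint boundary rho = 1, r = 1 is rejected by
    :class:`CorrelationParams`).
    """
    if m < 1:
        raise InvalidParameterError(f"m must be a positive integer, got {m}")
    if n_periods < 2:
        raise InvalidParameterError(f"n_periods must be >= 2, got {n_periods}")
    R = exp_decay_correlation(params.r, n_periods)
    return (params.sigma2_eps / m) * np.eye(n_periods) + params.sigma2_cp * R


def sequence_design_matrix(sequence: "TreatmentSequence | str") -> np.ndarray:
    """Design matrix of one arm at the cluster-period level.

    Row ``t`` is ``[1, d_2(t), ..., d_T(t), X_t]``: intercept, period dummies
    for periods 2..T (period 1 is the reference, beta_1 = 0) and the treatment
    indicator (A -> 0, B -> 1).  Shape (T, T+1), columns ordered as
    gamma = (mu, beta_2, ..., beta_T, theta)'.
    """
    seq = as_sequence(sequence)
    T = seq.n_periods
    X = np.zeros((T, T + 1))
    X[:, 0] = 1.0
    X[np.arange(1, T), np.arange(1, T)] = 1.0
    X[:, T] = seq.indicator
    return X


def _spd_solve(mat: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    """Solve ``mat @ x = rhs`` for symmetric positive-definite ``mat``."""
    try:
        factor = cho_factor(mat, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(f"{what} is not positive definite: {exc}") from exc
    return cho_solve(factor, rhs)


def treatment_variance(design: DesignSpec, params: CorrelationParams) -> FixedEffectsCovariance:
    """GLS covariance of the fixed effects for a mirrored two-arm design.

    Computes ``((K/2) X1' V^-1 X1 + (K/2) X2' V^-1 X2)^-1`` where ``X1`` is
    the design matrix of ``design.sequence`` and ``X2`` that of its mirror.
    Raises :class:`SingularCovarianceError` when either ``V`` or the
    information matrix fails a Cholesky factorization.
    """
    T = design.n_periods
    V = cluster_period_covariance(params, design.m, T)
    X1 = sequence_design_matrix(design.sequence)
    X2 = sequence_design_matrix(design.sequence.mirror())
    half = design.K / 2.0
    info = half * (X1.T @ _spd_solve(V, X1, "cluster-period covariance V"))
    info += half * (X2.T @ _spd_solve(V, X2, "cluster-period covariance V"))
    cov = _spd_solve(info, np.eye(T + 1), "information matrix")
    cov = (cov + cov.T) / 2.0
    return FixedEffectsCovariance(matrix=cov, var_theta=float(cov[-1, -1]))
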