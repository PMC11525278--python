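import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crxo import CorrelationParams, CostStructure

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def base_params() -> CorrelationParams:
    """Reference scenario correlation parameters (rho=0.1, r=0.95)."""
    return CorrelationParams(rho=0.1, r=0.95)


@pytest.fixture
def base_costs() -> CostStructure:
    """Reference scenario costs: 2500 per cluster, 25 per subject, 250 per switch."""
    return CostStructure(c_c=2500, c_s=25, c_x=250, budget=250_000)


def individual_level_var_theta(
    sequence: str, rho: float, r: float, m: int, K: int, total_variance: float = 1.0
) -> float:
    """Brute-force oracle: GLS variance from the full mT x mT subject-level model.

    Builds the subject-level covariance of one cluster directly —
    cov(Y_ti, Y_t'i') = sigma2_cp * r**|t-t'| + sigma2_eps * [t=t', i=i'] —
    and inverts the resulting information matrix.  Shares no code with the
    cluster-period-mean engine.
    """
    T = len(sequence)
    s2_cp = rho * total_variance
    s2_eps = (1.0 - rho) * total_variance
    lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    Sigma = np.kron(s2_cp * r**lag, np.ones((m, m))) + s2_eps * np.eye(T * m)
    Sigma_inv = np.linalg.inv(Sigma)

    def subject_design(labels: str) -> np.ndarray:
        Z = np.zeros((T * m, T + 1))
        for t in range(T):
            rows = slice(t * m, (t + 1) * m)
            Z[rows, 0] = 1.0
            if t > 0:
                Z[rows, t] = 1.0
            Z[rows, T] = 1.0 if labels[t] == "B" else 0.0
        return Z

    mirror = "".join("B" if c == "A" else "A" for c in sequence)
    info = np.zeros((T + 1, T + 1))
    for labels in (sequence, mirror):
        Z = subject_design(labels)
        info += (K / 2.0) * (Z.T @ Sigma_inv @ Z)
    return float(np.linalg.inv(info)[-1, -1])
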