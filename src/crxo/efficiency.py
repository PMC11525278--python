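"""Design-space evaluation: relative efficiency, optimal designs, period
sweeps and sequence comparison tables.

The optimality criterion is var(theta_hat), the GLS variance of the
treatment-effect estimator.  The relative efficiency of a design xi against
the best design xi* in the evaluated space is

    RE = var(theta_hat)_{xi*} / var(theta_hat)_{xi}  in (0, 1],

and ``100 * (1/RE - 1)`` percent extra replication of xi would be needed to
match xi*.  Each sweep or table normalizes by the best design within its own
requested space, so at least one entry always has RE = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import norm

from .designs import (
    CostStructure,
    alternating_sequence,
    clusters_under_budget,
    enumerate_mirror_pairs,
    trial_cost,
)
from .exceptions import InfeasibleDesignError, InvalidParameterError
from .variance import (
    MAX_PERIODS,
    CorrelationParams,
    DesignSpec,
    TreatmentSequence,
    treatment_variance,
)

__all__ = [
    "DesignEvaluation",
    "DesignSpaceRequest",
    "relative_efficiency",
    "extra_replication_pct",
    "wald_power",
    "evaluate_design_space",
    "find_optimal",
    "period_sweep",
    "sequence_table",
    "FOUR_PERIOD_REFERENCE_ORDER",
]

logger = logging.getLogger(__name__)

#: Conventional presentation order (and arm orientation) for the eight
#: four-period two-arm designs, as used in the crossover-design literature:
#: sorted by switch count, sequences with one treatment in the minority shown
#: from the B-starting arm.
FOUR_PERIOD_REFERENCE_ORDER = (
    "AAAA",
    "BAAA",
    "BBAA",
    "BBBA",
    "ABAA",
    "AABA",
    "ABBA",
    "BABA",
)


@dataclass(frozen=True)
class DesignEvaluation:
    """One evaluated design: its variance, cost and relative efficiency."""

    design: DesignSpec
    var_theta: float
    relative_efficiency: float
    switches: int
    cost: Fraction | None = None

    @property
    def n_periods(self) -> int:
        return self.design.n_periods


@dataclass(frozen=True)
class DesignSpaceRequest:
    """Specification of a design space to evaluate.

    Parameters
    ----------
    mode : {"fixed_k", "budget"}
        ``fixed_k`` evaluates all candidates at the same number of clusters
        ``K`` (space Omega_K); ``budget`` derives each candidate's ``K`` from
        the budgetary constraint (space Omega_B).
    periods : tuple of int
        Period counts to consider, each within ``[2, max_periods]``.
    scope : {"alternating", "all_pairs"}
        ``alternating`` considers only the switch-every-period sequence at
        each period count; ``all_pairs`` enumerates every mirror pair, which
        requires a single period count.
    params : CorrelationParams
    m : int
        Subjects per cluster-period.
    K : int, optional
        Total clusters; required in ``fixed_k`` mode.
    costs : CostStructure, optional
        Required in ``budget`` mode.
    """

    mode: str
    periods: tuple[int, ...]
    scope: str
    params: CorrelationParams
    m: int
    K: int | None = None
    costs: CostStructure | None = None
    max_periods: int = MAX_PERIODS

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(int(t) for t in self.periods))
        if self.mode not in ("fixed_k", "budget"):
            raise InvalidParameterError(f"mode must be 'fixed_k' or 'budget', got {self.mode!r}")
        if self.scope not in ("alternating", "all_pairs"):
            raise InvalidParameterError(
                f"scope must be 'alternating' or 'all_pairs', got {self.scope!r}"
            )
        if not self.periods:
            raise InvalidParameterError("at least one period count is required")
        for t in self.periods:
            if not 2 <= t <= self.max_periods:
                raise InvalidParameterError(
                    f"period count {t} outside [2, {self.max_periods}]"
                )
        if self.scope == "all_pairs" and len(self.periods) != 1:
            raise InvalidParameterError("scope 'all_pairs' requires a single period count")
        if self.mode == "fixed_k":
            if self.K is None:
                raise InvalidParameterError("fixed_k mode requires K")
            if self.costs is not None:
                raise InvalidParameterError("fixed_k mode does not take a cost structure")
        else:
            if self.costs is None:
                raise InvalidParameterError("budget mode requires a cost structure")
            if self.K is not None:
                raise InvalidParameterError("budget mode derives K; do not supply it")
        if self.m < 1:
            raise InvalidParameterError(f"m must be a positive integer, got {self.m}")


def relative_efficiency(var_optimal: float, var_alternative: float) -> float:
    """RE of an alternative design against the optimal one, in (0, 1]."""
    if var_optimal <= 0.0 or var_alternative <= 0.0:
        raise InvalidParameterError("variances must be strictly positive")
    ratio = var_optimal / var_alternative
    if ratio > 1.0 + 1e-9:
        raise InvalidParameterError(
            f"var_optimal ({var_optimal}) exceeds var_alternative ({var_alternative}); "
            "arguments reversed?"
        )
    return min(ratio, 1.0)


def extra_replication_pct(re: float) -> float:
    """Percent additional replication an alternative design needs: 100*(1/RE - 1)."""
    if not 0.0 < re <= 1.0:
        raise InvalidParameterError(f"relative efficiency must be in (0, 1], got {re}")
    return 100.0 * (1.0 / re - 1.0)


def wald_power(var_theta: float, theta: float, alpha: float = 0.05) -> float:
    """Power of the two-sided Wald z-test for the treatment effect.

    ``Phi(|theta|/sqrt(var) - z) + Phi(-|theta|/sqrt(var) - z)`` with
    ``z = z_{1-alpha/2}``; equals ``alpha`` at ``theta = 0``.
    """
    if var_theta <= 0.0:
        raise InvalidParameterError("var_theta must be strictly positive")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    z = norm.ppf(1.0 - alpha / 2.0)
    shift = abs(theta) / np.sqrt(var_theta)
    return float(norm.cdf(shift - z) + norm.cdf(-shift - z))


def _candidate_sequences(request: DesignSpaceRequest) -> list[TreatmentSequence]:
    if request.scope == "alternating":
        return [alternating_sequence(t) for t in request.periods]
    (t,) = request.periods
    return [p.canonical for p in enumerate_mirror_pairs(t, request.max_periods)]


def evaluate_design_space(request: DesignSpaceRequest) -> list[DesignEvaluation]:
    """Evaluate every candidate design in the requested space.

    In budget mode a candidate that cannot afford two clusters is dropped
    with a logged warning; an empty feasible set raises
    :class:`InfeasibleDesignError`.
    """
    raw: list[tuple[DesignSpec, float, Fraction | None]] = []
    for seq in _candidate_sequences(request):
        T, S = seq.n_periods, seq.switches
        if request.mode == "fixed_k":
            K, cost = request.K, None
        else:
            try:
                K = clusters_under_budget(T, request.m, S, request.costs)
            except InfeasibleDesignError as exc:
                logger.warning("dropping infeasible candidate %s: %s", seq, exc)
                continue
            cost = trial_cost(K, T, request.m, S, request.costs)
        design = DesignSpec(sequence=seq, K=K, m=request.m)
        var = treatment_variance(design, request.params).var_theta
        raw.append((design, var, cost))
    if not raw:
        raise InfeasibleDesignError("no feasible design in the requested space")
    best = min(var for _, var, _ in raw)
    return [
        DesignEvaluation(
            design=design,
            var_theta=var,
            relative_efficiency=relative_efficiency(best, var),
            switches=design.sequence.switches,
            cost=cost,
        )
        for design, var, cost in raw
    ]


def find_optimal(evaluations: list[DesignEvaluation]) -> DesignEvaluation:
    """The evaluation with minimal var(theta_hat).

    Exact ties (to 1e-12 relative) are broken by fewer periods, then fewer
    switches, then canonical sequence order.
    """
    if not evaluations:
        raise InvalidParameterError("cannot pick an optimum from an empty list")
    vmin = min(e.var_theta for e in evaluations)
    ties = [e for e in evaluations if e.var_theta <= vmin * (1.0 + 1e-12)]
    return min(ties, key=lambda e: (e.n_periods, e.switches, e.design.sequence.labels))


def period_sweep(
    params: CorrelationParams,
    m: int,
    mode: str = "budget",
    *,
    K: int | None = None,
    costs: CostStructure | None = None,
    periods: "tuple[int, ...] | range" = range(2, MAX_PERIODS + 1),
    max_periods: int = MAX_PERIODS,
) -> pd.DataFrame:
    """Relative efficiency of alternating designs as a function of T.

    Returns one row per period count with columns ``T``, ``sequence``,
    ``switches``, ``K``, ``cost``, ``var_theta``, ``relative_efficiency``;
    RE is normalized to the best design within this sweep.
    """
    request = DesignSpaceRequest(
        mode=mode,
        periods=tuple(periods),
        scope="alternating",
        params=params,
        m=m,
        K=K,
        costs=costs,
        max_periods=max_periods,
    )
    return evaluations_frame(evaluate_design_space(request))


def evaluations_frame(evaluations: list[DesignEvaluation]) -> pd.DataFrame:
    """Tabulate evaluations with a stable column order."""
    return pd.DataFrame(
        {
            "sequence": [e.design.sequence.labels for e in evaluations],
            "T": [e.n_periods for e in evaluations],
            "switches": [e.switches for e in evaluations],
            "K": [e.design.K for e in evaluations],
            "cost": [None if e.cost is None else float(e.cost) for e in evaluations],
            "var_theta": [e.var_theta for e in evaluations],
            "relative_efficiency": [e.relative_efficiency for e in evaluations],
        }
    )


def sequence_table(
    n_periods: int,
    params: CorrelationParams,
    m: int,
    costs: CostStructure | None = None,
    *,
    K: int = 20,
    reference_order: bool = False,
    max_periods: int = MAX_PERIODS,
) -> pd.DataFrame:
    """Compare every mirror-pair sequence at a fixed number of periods.

    Columns: ``label`` (1-based row number), ``sequence``, ``switches``,
    ``re_fixed_k`` (relative efficiency at a fixed K; invariant to K), and —
    when ``costs`` is given — ``K``, ``cost`` and ``re_budget`` under the
    budgetary constraint.  With ``reference_order=True`` and four periods the
    rows follow :data:`FOUR_PERIOD_REFERENCE_ORDER`, including its arm
    orientation (relative efficiency is invariant to which arm is displayed).
    """
    fixed = evaluate_design_space(
        DesignSpaceRequest(
            mode="fixed_k",
            periods=(n_periods,),
            scope="all_pairs",
            params=params,
            m=m,
            K=K,
            max_periods=max_periods,
        )
    )
    rows = {
        e.design.sequence.labels: {
            "sequence": e.design.sequence.labels,
            "switches": e.switches,
            "re_fixed_k": e.relative_efficiency,
        }
        for e in fixed
    }
    if costs is not None:
        budget = evaluate_design_space(
            DesignSpaceRequest(
                mode="budget",
                periods=(n_periods,),
                scope="all_pairs",
                params=params,
                m=m,
                costs=costs,
                max_periods=max_periods,
            )
        )
        for e in budget:
            rows[e.design.sequence.labels].update(
                K=e.design.K,
                cost=float(e.cost),
                re_budget=e.relative_efficiency,
            )
    order = [e.design.sequence.labels for e in fixed]
    display = dict(zip(order, order))
    if reference_order:
        if n_periods != 4:
            raise InvalidParameterError("reference ordering is defined for 4 periods only")
        display = {
            min(s, TreatmentSequence(s).mirror().labels): s
            for s in FOUR_PERIOD_REFERENCE_ORDER
        }
        order = list(display)
    table = pd.DataFrame([rows[s] for s in order])
    table.insert(0, "label", range(1, len(order) + 1))
    table["sequence"] = [display[s] for s in order]
    return table
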