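"""Design-space primitives: sequence enumeration, switch counting, trial cost
and the number of clusters affordable under a budget.

Two design spaces are supported downstream.  With a fixed number of clusters
(``Omega_K``) every candidate shares ``K``.  Under a budgetary constraint
(``Omega_B``) each candidate's ``K`` is the largest even integer whose total
cost

    C = c_c * K + c_s * K * T * m + c_x * K * S

does not exceed the budget, where ``S`` is the candidate's number of
treatment switches.  Costs are held as exact fractions so that budget
comparisons never hinge on floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational

from .exceptions import InfeasibleDesignError, InvalidParameterError
from .variance import MAX_PERIODS, TreatmentSequence, as_sequence

__all__ = [
    "CostStructure",
    "MirrorPair",
    "mirror_sequence",
    "count_switches",
    "enumerate_mirror_pairs",
    "alternating_sequence",
    "trial_cost",
    "clusters_under_budget",
]


def _exact(value: "float | int | str | Rational", name: str) -> Fraction:
    """Convert a money amount to an exact Fraction.

    Floats go through their shortest decimal repr, so 0.1 means one tenth.
    """
    if isinstance(value, Rational):
        return Fraction(value)
    try:
        return Fraction(str(value))
    except (ValueError, ZeroDivisionError) as exc:
        raise InvalidParameterError(f"{name} is not a valid amount: {value!r}") from exc


@dataclass(frozen=True)
class CostStructure:
    """Unit costs and total budget of a trial.

    Parameters
    ----------
    c_c : money
        Cost to recruit one cluster.
    c_s : money
        Cost to include, treat and measure one subject.
    c_x : money
        Cost of one treatment switch (in either direction) in one cluster.
    budget : money
        Total budget available.
    """

    c_c: Fraction
    c_s: Fraction
    c_x: Fraction
    budget: Fraction

    def __post_init__(self) -> None:
        for name in ("c_c", "c_s", "c_x", "budget"):
            object.__setattr__(self, name, _exact(getattr(self, name), name))
        if self.c_c < 0 or self.c_s < 0 or self.c_x < 0:
            raise InvalidParameterError("unit costs must be nonnegative")
        if self.budget <= 0:
            raise InvalidParameterError("budget must be strictly positive")

    def per_cluster(self, n_periods: int, m: int, switches: int) -> Fraction:
        """Cost of running one cluster for ``n_periods`` periods with ``switches`` switches."""
        return self.c_c + self.c_s * n_periods * m + self.c_x * switches


@dataclass(frozen=True)
class MirrorPair:
    """A treatment sequence together with its mirror (the other arm)."""

    canonical: TreatmentSequence
    mirror: TreatmentSequence
    switches: int

    def __post_init__(self) -> None:
        if self.mirror != self.canonical.mirror():
            raise InvalidParameterError("mirror is not the complement of canonical")
        if self.switches != self.canonical.switches:
            raise InvalidParameterError("switch count does not match the sequence")


def mirror_sequence(sequence: "TreatmentSequence | str") -> TreatmentSequence:
    """Swap A and B at every period (the second arm of the design)."""
    return as_sequence(sequence).mirror()


def count_switches(sequence: "TreatmentSequence | str") -> int:
    """Number of adjacent periods with different treatments."""
    return as_sequence(sequence).switches


def alternating_sequence(n_periods: int) -> TreatmentSequence:
    """The sequence ABAB... that switches treatment at every period."""
    return TreatmentSequence.alternating(n_periods)


def enumerate_mirror_pairs(n_periods: int, max_periods: int = MAX_PERIODS) -> list[MirrorPair]:
    """All distinct two-arm designs with ``n_periods`` periods.

    Of the ``2**T`` label strings, each design is counted once because the two
    arms are mirrors of each other: the canonical member of each pair is the
    lexicographically smaller of the two complements (hence starts with 'A'),
    giving ``2**(T-1)`` pairs.  Pairs are ordered by switch count, then by the
    canonical sequence's binary value with A = 0.
    """
    if not 2 <= n_periods <= max_periods:
        raise InvalidParameterError(
            f"n_periods must be in [2, {max_periods}], got {n_periods}"
        )
    pairs = []
    for code in range(2 ** (n_periods - 1)):
        # Fixing the first label to 'A' enumerates exactly one member per pair.
        bits = [(code >> (n_periods - 1 - t)) & 1 for t in range(1, n_periods)]
        seq = TreatmentSequence("A" + "".join("AB"[b] for b in bits))
        pairs.append(MirrorPair(seq, seq.mirror(), seq.switches))
    pairs.sort(key=lambda p: (p.switches, p.canonical.indicator.tolist()))
    return pairs


def trial_cost(
    K: int,
    n_periods: int,
    m: int,
    switches: int,
    costs: CostStructure,
) -> Fraction:
    """Total cost ``c_c*K + c_s*K*T*m + c_x*K*S`` of a two-arm design."""
    if K < 2 or K % 2 != 0:
        raise InvalidParameterError(f"K must be an even integer >= 2, got {K}")
    if not 0 <= switches <= n_periods - 1:
        raise InvalidParameterError(
            f"switches must be in [0, {n_periods - 1}], got {switches}"
        )
    return costs.per_cluster(n_periods, m, switches) * K


def clusters_under_budget(
    n_periods: int,
    m: int,
    switches: int,
    costs: CostStructure,
) -> int:
    """Largest even number of clusters affordable under the budget.

    ``K = budget / (c_c + c_s*T*m + c_x*S)`` rounded down to an even integer,
    so that both mirrored arms get the same number of clusters.
    """
    per_cluster = costs.per_cluster(n_periods, m, switches)
    if per_cluster <= 0:
        raise InvalidParameterError(
            "per-cluster cost is zero: the number of clusters is unbounded"
        )
    K = int(costs.budget / per_cluster)
    K -= K % 2
    if K < 2:
        raise InfeasibleDesignError(
            f"budget {costs.budget} cannot afford 2 clusters at {per_cluster} each"
        )
    return K
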