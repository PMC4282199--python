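"""Cost-effectiveness arithmetic: cost per live birth, ICERs, dominance.

Conventions follow standard practice in assisted-reproduction economic
evaluations. The incremental cost-effectiveness ratio (ICER) between an
ordered pair is Δcost / Δeffect with deltas taken comparator − reference;
it is reported only when the comparator buys extra effect at extra (or
equal) cost. A comparator that is cheaper *and* more effective dominates
the reference; a comparator that is less effective is reported as
dominated and its ICER suppressed rather than printing a ratio that would
invite misreading (cost-saving-but-less-effective trade-offs are flagged
the same way, mirroring how dominated rows appear in published tornado
tables).

Monetary ratios are computed at full precision; :func:`round_euros`
applies half-up rounding to whole euros for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .cohort import StrategyOutcome

__all__ = [
    "ComparisonStatus",
    "Comparison",
    "Frontier",
    "round_euros",
    "cost_per_live_birth",
    "icer",
    "frontier",
]


class ComparisonStatus(str, Enum):
    ICER = "icer"
    COMPARATOR_DOMINANT = "comparator_dominant"
    COMPARATOR_DOMINATED = "comparator_dominated"
    EQUAL_EFFECT = "equal_effect"


@dataclass(frozen=True)
class Comparison:
    """Incremental comparison of an ordered strategy pair."""

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    status: ComparisonStatus


@dataclass(frozen=True)
class Frontier:
    """Outcomes ordered by effect with sequential and pairwise comparisons."""

    ordered: tuple[StrategyOutcome, ...]
    dominated: tuple[str, ...]
    sequential: tuple[Comparison, ...]
    pairwise: tuple[Comparison, ...]


def round_euros(value: float) -> int:
    """Round half-up to whole euros (0.5 always rounds away from zero)."""
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def cost_per_live_birth(outcome: StrategyOutcome) -> float:
    """Expected cost per couple divided by expected live births.

    A strategy with zero effectiveness has no finite cost per live birth;
    ``inf`` is returned so reporting can flag it without halting.
    """
    if outcome.live_births == 0:
        return math.inf
    return outcome.expected_cost / outcome.live_births


def icer(reference: StrategyOutcome, comparator: StrategyOutcome) -> Comparison:
    """Incremental comparison of ``comparator`` against ``reference``."""
    if reference.strategy == comparator.strategy:
        raise ValueError(f"self-comparison of strategy {reference.strategy!r}")
    delta_cost = comparator.expected_cost - reference.expected_cost
    delta_effect = comparator.live_births - reference.live_births

    if delta_effect > 0:
        if delta_cost >= 0:
            status, ratio = ComparisonStatus.ICER, delta_cost / delta_effect
        else:
            status, ratio = ComparisonStatus.COMPARATOR_DOMINANT, None
    elif delta_effect == 0:
        status, ratio = ComparisonStatus.EQUAL_EFFECT, None
    else:
        status, ratio = ComparisonStatus.COMPARATOR_DOMINATED, None

    return Comparison(
        reference=reference.strategy,
        comparator=comparator.strategy,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=ratio,
        status=status,
    )


def _strictly_dominated(a: StrategyOutcome, others: Sequence[StrategyOutcome]) -> bool:
    return any(
        b.expected_cost < a.expected_cost and b.live_births > a.live_births
        for b in others
        if b.strategy != a.strategy
    )


def frontier(outcomes: Sequence[StrategyOutcome]) -> Frontier:
    """Effect-ordered comparisons across two or more strategies.

    Strictly dominated strategies (some other strategy is both cheaper
    and more effective) are flagged and excluded from the sequential
    chain; sequential ICERs are computed between the remaining neighbours
    in order of increasing effect. All ordered pairwise comparisons
    (lower effect as reference) are also emitted.
    """
    if len(outcomes) < 2:
        raise ValueError("frontier needs at least two strategy outcomes")
    ordered = tuple(sorted(outcomes, key=lambda o: (o.live_births, o.expected_cost)))
    dominated = tuple(
        o.strategy for o in ordered if _strictly_dominated(o, ordered)
    )
    survivors = [o for o in ordered if o.strategy not in dominated]
    sequential = tuple(
        icer(survivors[i], survivors[i + 1]) for i in range(len(survivors) - 1)
    )
    pairwise = tuple(
        icer(ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    )
    return Frontier(ordered, dominated, sequential, pairwise)
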