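"""Cohort evaluation of the two-cycle embryo-transfer decision tree.

Every couple starts one fresh IVF cycle. The fresh transfer either leads
to an ongoing pregnancy or fails; a failing couple proceeds to a single
frozen (cryo) transfer cycle with probability ``p_frozen_available``
(when the horizon allows a second cycle). Each ongoing pregnancy splits
into twin vs singleton, then complicated vs uncomplicated antenatal care,
and finally live delivery vs loss. Costs accumulate along the path:
fresh-cycle components (plus the diagnostic-test price for the tested
fraction of couples), the frozen-cycle cost when attempted, the pregnancy
stratum cost for every ongoing pregnancy, and the delivery cost on live
delivery only.

:func:`run_cohort` computes the expectation in closed form;
:func:`pathway_enumerate` walks the tree exhaustively and serves as a
brute-force oracle — the two must agree to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import CostTable, StrategyParams, TwinCounting

__all__ = ["StrategyOutcome", "TerminalPath", "run_cohort", "pathway_enumerate"]


class UnsupportedHorizonError(ValueError):
    """The model covers one fresh plus at most one frozen cycle."""


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected cost and live births per couple for one strategy."""

    strategy: str
    expected_cost: float
    live_births: float
    trace: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class TerminalPath:
    """One mutually-exclusive terminal path through the decision tree."""

    labels: tuple[str, ...]
    probability: float
    cost: float
    births: float


def _check_cycles(cycles: int) -> None:
    if cycles not in (1, 2):
        raise UnsupportedHorizonError(
            f"cycles must be 1 (fresh only) or 2 (fresh + frozen), got {cycles}"
        )


def _pregnancy_cost(strategy: StrategyParams, costs: CostTable, twin: bool) -> float:
    """Expected downstream cost of one ongoing pregnancy of known plurality."""
    if twin:
        compl, uncompl, delivery = (
            costs.pregnancy_twin_complicated,
            costs.pregnancy_twin_uncomplicated,
            costs.delivery_twin,
        )
    else:
        compl, uncompl, delivery = (
            costs.pregnancy_singleton_complicated,
            costs.pregnancy_singleton_uncomplicated,
            costs.delivery_singleton,
        )
    pc = strategy.p_complication
    return pc * compl + (1 - pc) * uncompl + strategy.p_live_given_ongoing * delivery


def _births_per_ongoing(strategy: StrategyParams, twin_prob: float) -> float:
    per_delivery = 1.0
    if strategy.count_twins_as is TwinCounting.CHILDREN:
        per_delivery = 1.0 + twin_prob
    elif twin_prob:
        per_delivery = 1.0  # a twin delivery is still one delivery event
    return strategy.p_live_given_ongoing * per_delivery


def run_cohort(
    strategy: StrategyParams, costs: CostTable, cycles: int = 2
) -> StrategyOutcome:
    """Closed-form expected cost and live births per couple.

    Deterministic: identical inputs give bit-identical outputs. The
    diagnostic test is a fixed per-couple cost charged to the tested
    fraction; it buys nothing in the frozen cycle, where the strategy's
    ``p_ongoing_frozen`` applies regardless of testing.
    """
    _check_cycles(cycles)

    p_of = strategy.p_ongoing_fresh
    p_fail = 1.0 - p_of
    p_fa = strategy.p_frozen_available if cycles == 2 else 0.0
    p_frozen_ongoing = p_fail * p_fa * strategy.p_ongoing_frozen

    cost = costs.fresh_cycle_total
    cost += strategy.tested_fraction * costs.diagnostic_test
    cost += p_fail * p_fa * costs.frozen_cycle

    births = 0.0
    arms = (
        (p_of, strategy.p_twin_given_ongoing, "fresh"),
        (p_frozen_ongoing, strategy.twin_prob_frozen, "frozen"),
    )
    trace_arms = {}
    for p_arm, twin_prob, label in arms:
        exp_cost = twin_prob * _pregnancy_cost(strategy, costs, twin=True) + (
            1 - twin_prob
        ) * _pregnancy_cost(strategy, costs, twin=False)
        cost += p_arm * exp_cost
        arm_births = _births_per_ongoing(strategy, twin_prob)
        births += p_arm * arm_births
        trace_arms[label] = {
            "p_ongoing": p_arm,
            "twin_prob": twin_prob,
            "expected_pregnancy_cost": exp_cost,
            "births_per_ongoing": arm_births,
        }

    trace = {
        "cycles": cycles,
        "fresh_cycle_cost": costs.fresh_cycle_total,
        "diagnostic_cost": strategy.tested_fraction * costs.diagnostic_test,
        "p_frozen_attempt": p_fail * p_fa,
        "arms": trace_arms,
    }
    return StrategyOutcome(strategy.name, cost, births, trace)


def pathway_enumerate(
    strategy: StrategyParams, costs: CostTable, cycles: int = 2
) -> list[TerminalPath]:
    """Exhaustively enumerate terminal paths with their probabilities.

    Zero-probability branches are pruned, so a fully degenerate strategy
    (all probabilities 0 or 1) yields a single path of probability 1.
    Probabilities over the returned paths sum to 1 for any valid input.
    """
    _check_cycles(cycles)
    paths: list[TerminalPath] = []

    def branch(options):
        """Keep only options with positive probability."""
        return [(lbl, p) for lbl, p in options if p > 0.0]

    def pregnancy_subtree(prefix, p_prefix, cost_prefix, twin_prob):
        for twin_lbl, p_twin in branch(
            [("twin", twin_prob), ("singleton", 1 - twin_prob)]
        ):
            twin = twin_lbl == "twin"
            for compl_lbl, p_compl in branch(
                [
                    ("complicated", strategy.p_complication),
                    ("uncomplicated", 1 - strategy.p_complication),
                ]
            ):
                if twin:
                    preg_cost = (
                        costs.pregnancy_twin_complicated
                        if compl_lbl == "complicated"
                        else costs.pregnancy_twin_uncomplicated
                    )
                    delivery_cost = costs.delivery_twin
                else:
                    preg_cost = (
                        costs.pregnancy_singleton_complicated
                        if compl_lbl == "complicated"
                        else costs.pregnancy_singleton_uncomplicated
                    )
                    delivery_cost = costs.delivery_singleton
                for del_lbl, p_del in branch(
                    [
                        ("live_delivery", strategy.p_live_given_ongoing),
                        ("loss", 1 - strategy.p_live_given_ongoing),
                    ]
                ):
                    live = del_lbl == "live_delivery"
                    if live and twin and strategy.count_twins_as is TwinCounting.CHILDREN:
                        births = 2.0
                    else:
                        births = 1.0 if live else 0.0
                    paths.append(
                        TerminalPath(
                            labels=prefix + (twin_lbl, compl_lbl, del_lbl),
                            probability=p_prefix * p_twin * p_compl * p_del,
                            cost=cost_prefix
                            + preg_cost
                            + (delivery_cost if live else 0.0),
                            births=births,
                        )
                    )

    p_fa = strategy.p_frozen_available if cycles == 2 else 0.0
    for tested_lbl, p_tested in branch(
        [("tested", strategy.tested_fraction), ("untested", 1 - strategy.tested_fraction)]
    ):
        base_cost = costs.fresh_cycle_total + (
            costs.diagnostic_test if tested_lbl == "tested" else 0.0
        )
        for fresh_lbl, p_fresh in branch(
            [
                ("fresh_ongoing", strategy.p_ongoing_fresh),
                ("fresh_failure", 1 - strategy.p_ongoing_fresh),
            ]
        ):
            prefix = (tested_lbl, fresh_lbl)
            p_here = p_tested * p_fresh
            if fresh_lbl == "fresh_ongoing":
                pregnancy_subtree(prefix, p_here, base_cost, strategy.p_twin_given_ongoing)
                continue
            for froz_lbl, p_froz in branch(
                [("frozen_attempt", p_fa), ("stop", 1 - p_fa)]
            ):
                if froz_lbl == "stop":
                    paths.append(
                        TerminalPath(prefix + ("stop",), p_here * p_froz, base_cost, 0.0)
                    )
                    continue
                froz_cost = base_cost + costs.frozen_cycle
                for out_lbl, p_out in branch(
                    [
                        ("frozen_ongoing", strategy.p_ongoing_frozen),
                        ("frozen_failure", 1 - strategy.p_ongoing_frozen),
                    ]
                ):
                    p2 = p_here * p_froz * p_out
                    if out_lbl == "frozen_failure":
                        paths.append(
                            TerminalPath(
                                prefix + (froz_lbl, out_lbl), p2, froz_cost, 0.0
                            )
                        )
                    else:
                        pregnancy_subtree(
                            prefix + (froz_lbl, out_lbl),
                            p2,
                            froz_cost,
                            strategy.twin_prob_frozen,
                        )
    return paths
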