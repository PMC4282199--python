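"""One-way (±20%) sensitivity analysis and threshold (crossover) search.

``one_way`` reruns the cohort model with a single parameter scaled to
0.8× and 1.2× its base value (probabilities clipped to [0, 1]) and
reports the ICER — or a dominance flag — for each requested strategy
pair, tornado-table style.

``threshold_search`` finds the parameter value at which two strategies'
cost-per-live-birth curves intersect: a coarse grid scan brackets every
sign change of the difference, then bisection refines each bracket to
the requested resolution. The default resolutions (€1 for costs, 0.001
for probabilities) match the granularity at which such crossovers are
typically reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .cohort import run_cohort
from .economics import ComparisonStatus, cost_per_live_birth, icer
from .parameters import ModelConfig, get_parameter, perturb, set_parameter

__all__ = ["SensitivityRow", "ThresholdResult", "one_way", "threshold_search"]

#: Default ±20% factors used in the one-way analysis.
LOW_FACTOR, HIGH_FACTOR = 0.8, 1.2


@dataclass(frozen=True)
class SensitivityRow:
    """One tornado-table row: one parameter, one ordered strategy pair."""

    parameter: str
    reference: str
    comparator: str
    low_input: float
    high_input: float
    low_icer: Optional[float]
    high_icer: Optional[float]
    low_status: ComparisonStatus
    high_status: ComparisonStatus
    difference: Optional[float]  # |high − low| when both ICERs are defined


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    pair: tuple[str, str]
    crossing_value: Optional[float]
    tolerance: float
    all_crossings: tuple[float, ...]
    degenerate: bool = False  # difference identically zero over the range


def _pair_icer(config: ModelConfig, pair: tuple[str, str], cycles: int):
    ref = run_cohort(config.strategy(pair[0]), config.costs, cycles)
    comp = run_cohort(config.strategy(pair[1]), config.costs, cycles)
    return icer(ref, comp)


def one_way(
    config: ModelConfig,
    parameter: str,
    pairs: Sequence[tuple[str, str]],
    cycles: int = 2,
) -> list[SensitivityRow]:
    """±20% one-way sensitivity of pairwise ICERs to one parameter.

    The base config is never modified; each run perturbs only the target
    parameter. Pairs are (reference, comparator) strategy names.
    """
    low_cfg = perturb(config, parameter, LOW_FACTOR)
    high_cfg = perturb(config, parameter, HIGH_FACTOR)
    low_input = get_parameter(low_cfg, parameter)
    high_input = get_parameter(high_cfg, parameter)

    rows = []
    for pair in pairs:
        lo = _pair_icer(low_cfg, pair, cycles)
        hi = _pair_icer(high_cfg, pair, cycles)
        difference = (
            abs(hi.icer - lo.icer) if lo.icer is not None and hi.icer is not None else None
        )
        rows.append(
            SensitivityRow(
                parameter=parameter,
                reference=pair[0],
                comparator=pair[1],
                low_input=low_input,
                high_input=high_input,
                low_icer=lo.icer,
                high_icer=hi.icer,
                low_status=lo.status,
                high_status=hi.status,
                difference=difference,
            )
        )
    return rows


def _cplb_difference(
    config: ModelConfig, parameter: str, pair: tuple[str, str], cycles: int
) -> Callable[[float], float]:
    def diff(value: float) -> float:
        cfg = set_parameter(config, parameter, value)
        a = run_cohort(cfg.strategy(pair[0]), cfg.costs, cycles)
        b = run_cohort(cfg.strategy(pair[1]), cfg.costs, cycles)
        return cost_per_live_birth(a) - cost_per_live_birth(b)

    return diff


def _bisect(f: Callable[[float], float], a: float, b: float, tol: float) -> float:
    fa = f(a)
    while b - a > tol:
        mid = 0.5 * (a + b)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if (fa < 0) != (fm < 0):
            b = mid
        else:
            a, fa = mid, fm
    return 0.5 * (a + b)


def threshold_search(
    config: ModelConfig,
    parameter: str,
    pair: tuple[str, str],
    search_range: tuple[float, float],
    tolerance: float,
    cycles: int = 1,
    grid_points: int = 65,
) -> ThresholdResult:
    """Locate where the pair's cost-per-live-birth curves cross.

    Deterministic: a ``grid_points``-point scan over ``search_range``
    brackets sign changes of the difference, each refined by bisection to
    within ``tolerance``. With no sign change the result has
    ``crossing_value=None``; identical curves (difference zero across the
    whole grid) are reported as degenerate since no unique crossing
    exists. When several crossings fall in range the smallest is reported
    and all are returned.
    """
    low, high = search_range
    if not low < high:
        raise ValueError(f"invalid range [{low}, {high}]: need low < high")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    diff = _cplb_difference(config, parameter, pair, cycles)
    xs = [low + (high - low) * i / (grid_points - 1) for i in range(grid_points)]
    fs = [diff(x) for x in xs]

    if all(f == 0.0 for f in fs):
        return ThresholdResult(parameter, tuple(pair), None, tolerance, (), degenerate=True)

    crossings: list[float] = []
    for i in range(len(xs) - 1):
        f0, f1 = fs[i], fs[i + 1]
        if f0 == 0.0:
            crossings.append(xs[i])
        elif (f0 < 0) != (f1 < 0):
            crossings.append(_bisect(diff, xs[i], xs[i + 1], tolerance))
    if fs[-1] == 0.0:
        crossings.append(xs[-1])

    crossings = sorted(set(crossings))
    return ThresholdResult(
        parameter=parameter,
        pair=tuple(pair),
        crossing_value=crossings[0] if crossings else None,
        tolerance=tolerance,
        all_crossings=tuple(crossings),
    )
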