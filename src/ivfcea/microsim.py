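"""Patient-level Monte-Carlo counterpart of the cohort expectation.

Each simulated couple traverses the identical decision tree with
Bernoulli draws at every branch, accumulating the same unit costs the
cohort model charges in expectation. By the law of large numbers the
sample mean cost and births converge to :func:`ivfcea.cohort.run_cohort`
outputs, which makes the simulator an independent empirical oracle for
the analytic engine (and a generator of synthetic couple-level datasets).

Randomness comes from a counter-based Philox generator: couple *i*
always consumes the same fixed block of seven uniforms, so trajectory
*i* is identical whether 10 or 10^6 couples are simulated with the same
seed, and partial reruns reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .parameters import CostTable, StrategyParams, TwinCounting

__all__ = ["MicrosimSummary", "simulate_cohort", "iter_trajectories", "write_trajectories"]

#: Uniform draws consumed per couple (one per potential branch point).
_DRAWS_PER_COUPLE = 7

TRAJECTORY_COLUMNS = {
    "couple": "0-based couple index (stable under the seed)",
    "tested": "1 if the couple received the embryo diagnostic test",
    "fresh_ongoing": "1 if the fresh transfer led to an ongoing pregnancy",
    "frozen_attempt": "1 if a frozen transfer cycle was attempted",
    "frozen_ongoing": "1 if the frozen transfer led to an ongoing pregnancy",
    "twin": "1 if the ongoing pregnancy was a twin pregnancy",
    "complicated": "1 if the pregnancy fell in the complicated cost stratum",
    "live_delivery": "1 if the pregnancy ended in live delivery",
    "births": "live births credited (0, 1, or 2 under children counting)",
    "total_cost": "euros accumulated along the realized path",
}


@dataclass(frozen=True)
class MicrosimSummary:
    strategy: str
    n: int
    mean_cost: float
    se_cost: float
    mean_births: float
    se_births: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "n": self.n,
            "mean_cost": self.mean_cost,
            "se_cost": self.se_cost,
            "mean_births": self.mean_births,
            "se_births": self.se_births,
            "seed": self.seed,
        }


def _simulate_block(
    strategy: StrategyParams, costs: CostTable, u: np.ndarray, start: int
) -> pd.DataFrame:
    """Vectorised traversal of the tree for a block of couples."""
    n = u.shape[0]
    tested = u[:, 0] < strategy.tested_fraction
    fresh_ongoing = u[:, 1] < strategy.p_ongoing_fresh
    frozen_attempt = ~fresh_ongoing & (u[:, 2] < strategy.p_frozen_available)
    frozen_ongoing = frozen_attempt & (u[:, 3] < strategy.p_ongoing_frozen)
    ongoing = fresh_ongoing | frozen_ongoing

    twin_prob = np.where(
        fresh_ongoing, strategy.p_twin_given_ongoing, strategy.twin_prob_frozen
    )
    twin = ongoing & (u[:, 4] < twin_prob)
    complicated = ongoing & (u[:, 5] < strategy.p_complication)
    live = ongoing & (u[:, 6] < strategy.p_live_given_ongoing)

    pregnancy_cost = np.select(
        [
            ongoing & twin & complicated,
            ongoing & twin & ~complicated,
            ongoing & ~twin & complicated,
            ongoing & ~twin & ~complicated,
        ],
        [
            costs.pregnancy_twin_complicated,
            costs.pregnancy_twin_uncomplicated,
            costs.pregnancy_singleton_complicated,
            costs.pregnancy_singleton_uncomplicated,
        ],
        default=0.0,
    )
    delivery_cost = np.where(
        live, np.where(twin, costs.delivery_twin, costs.delivery_singleton), 0.0
    )
    total = (
        costs.fresh_cycle_total
        + tested * costs.diagnostic_test
        + frozen_attempt * costs.frozen_cycle
        + pregnancy_cost
        + delivery_cost
    )
    if strategy.count_twins_as is TwinCounting.CHILDREN:
        births = live * (1 + twin.astype(int))
    else:
        births = live.astype(int)

    return pd.DataFrame(
        {
            "couple": np.arange(start, start + n),
            "tested": tested.astype(int),
            "fresh_ongoing": fresh_ongoing.astype(int),
            "frozen_attempt": frozen_attempt.astype(int),
            "frozen_ongoing": frozen_ongoing.astype(int),
            "twin": twin.astype(int),
            "complicated": complicated.astype(int),
            "live_delivery": live.astype(int),
            "births": births,
            "total_cost": total,
        }
    )


def iter_trajectories(
    strategy: StrategyParams,
    costs: CostTable,
    n: int,
    seed: int,
    chunk: int = 100_000,
) -> Iterator[pd.DataFrame]:
    """Yield trajectory blocks of at most ``chunk`` couples.

    Streaming keeps memory flat for large n; concatenating the blocks
    gives the exact frame a single-shot run would produce.
    """
    if n < 1:
        raise ValueError(f"need at least one couple, got n={n}")
    rng = np.random.Generator(np.random.Philox(seed))
    done = 0
    while done < n:
        m = min(chunk, n - done)
        u = rng.random((m, _DRAWS_PER_COUPLE))
        yield _simulate_block(strategy, costs, u, start=done)
        done += m


def simulate_cohort(
    strategy: StrategyParams,
    costs: CostTable,
    n: int,
    seed: int,
    return_trajectories: bool = False,
):
    """Simulate ``n`` couples; summarise mean cost and births with SEs.

    Standard errors are sample standard deviation (ddof=1) over √n; for a
    fully degenerate strategy every trajectory is identical and both SEs
    are exactly zero. Same seed → bit-identical output.

    Returns the :class:`MicrosimSummary`, or ``(summary, DataFrame)``
    when ``return_trajectories`` is set.
    """
    frames = list(iter_trajectories(strategy, costs, n, seed))
    df = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]

    def se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan

    summary = MicrosimSummary(
        strategy=strategy.name,
        n=n,
        mean_cost=float(df["total_cost"].mean()),
        se_cost=se(df["total_cost"]),
        mean_births=float(df["births"].mean()),
        se_births=se(df["births"]),
        seed=seed,
    )
    if return_trajectories:
        return summary, df
    return summary


def write_trajectories(trajectories, path: str | Path) -> int:
    """Write trajectories to CSV; returns the number of data rows.

    Accepts a DataFrame or an iterable of DataFrame blocks (as produced
    by :func:`iter_trajectories`); blocks are appended so memory stays
    flat. An empty input produces a header-only file.
    """
    if isinstance(trajectories, pd.DataFrame):
        trajectories = [trajectories]
    path = Path(path)
    rows = 0
    wrote_header = False
    try:
        with open(path, "w", newline="") as fh:
            for block in trajectories:
                block.to_csv(fh, index=False, header=not wrote_header)
                wrote_header = True
                rows += len(block)
            if not wrote_header:
                fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing trajectories to {path}: {exc}") from exc
    return rows
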