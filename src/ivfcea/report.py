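"""Tabular emitters and run manifests.

Currency columns hold full-precision values; the ``*_rounded`` companions
carry the whole-euro figures used in published tables. Every CLI run
writes a manifest so each output file is traceable to the exact config,
seed and package version that produced it.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cohort import StrategyOutcome
from .economics import Comparison, cost_per_live_birth, frontier, round_euros
from .sensitivity import SensitivityRow, ThresholdResult

__all__ = [
    "outcomes_table",
    "comparisons_table",
    "sensitivity_table",
    "threshold_json",
    "write_manifest",
]


def _fmt_icer(c: Comparison) -> object:
    return round_euros(c.icer) if c.icer is not None else c.status.value


def outcomes_table(outcomes: Sequence[StrategyOutcome]) -> pd.DataFrame:
    """Per-strategy cost/effect table in the shape of a published CEA table.

    Rows are ordered by increasing live births; the incremental cost is
    taken against the previous row. One ICER column is added per other
    strategy (pairwise, lower-effect strategy as reference).
    """
    fr = frontier(outcomes) if len(outcomes) >= 2 else None
    ordered = fr.ordered if fr else tuple(outcomes)
    rows = []
    for i, o in enumerate(ordered):
        cplb = cost_per_live_birth(o)
        rows.append(
            {
                "strategy": o.strategy,
                "expected_cost": o.expected_cost,
                "expected_cost_rounded": round_euros(o.expected_cost),
                "incremental_cost": (
                    o.expected_cost - ordered[i - 1].expected_cost if i else math.nan
                ),
                "live_births": o.live_births,
                "cost_per_live_birth": cplb,
                "cost_per_live_birth_rounded": (
                    round_euros(cplb) if math.isfinite(cplb) else "undefined"
                ),
            }
        )
    df = pd.DataFrame(rows)
    if fr:
        for o in ordered:
            col = f"icer_vs_{o.strategy}"
            df[col] = [
                next(
                    (
                        _fmt_icer(c)
                        for c in fr.pairwise
                        if c.reference == o.strategy and c.comparator == other.strategy
                    ),
                    None,
                )
                for other in ordered
            ]
    return df


def comparisons_table(comparisons: Sequence[Comparison]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(c) for c in comparisons])
    df["status"] = [c.status.value for c in comparisons]
    df["icer_rounded"] = [_fmt_icer(c) for c in comparisons]
    return df


def sensitivity_table(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    """Tornado-style table: one row per (parameter, pair)."""
    out = []
    for r in rows:
        out.append(
            {
                "parameter": r.parameter,
                "reference": r.reference,
                "comparator": r.comparator,
                "low_input": r.low_input,
                "high_input": r.high_input,
                "low_icer": round_euros(r.low_icer) if r.low_icer is not None else r.low_status.value,
                "high_icer": round_euros(r.high_icer) if r.high_icer is not None else r.high_status.value,
                "difference": round_euros(r.difference) if r.difference is not None else None,
            }
        )
    return pd.DataFrame(out)


def threshold_json(result: ThresholdResult) -> dict:
    return {
        "parameter": result.parameter,
        "pair": list(result.pair),
        "crossing_value": result.crossing_value,
        "all_crossings": list(result.all_crossings),
        "tolerance": result.tolerance,
        "degenerate": result.degenerate,
    }


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    config_path: Optional[str | Path],
    outputs: Sequence[str],
    seed: Optional[int] = None,
    cycles: Optional[int] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write a JSON manifest tying outputs to their provenance."""
    out_dir = Path(out_dir)
    config_hash = None
    if config_path is not None:
        config_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = {
        "subcommand": subcommand,
        "config_path": str(config_path) if config_path else None,
        "config_sha256": config_hash,
        "seed": seed,
        "cycles": cycles,
        "outputs": list(outputs),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"manifest_{subcommand}.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
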