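"""Housekeeping-based high-expression threshold and boolean calls.

For each of three housekeeping genes the upper limit of its expression
variation is mean + 2 x sample SD of its AU row across tissues; the species
threshold is the arithmetic mean of the three uppers. A gene-tissue AU
strictly larger than the threshold is called highly expressed. The published
values derived from the original EST profiles (3.63 human, 4.12 mouse) are
available as config defaults, not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AngiogenicPanel
from .profiles import RelativeExpression

__all__ = [
    "PUBLISHED_THRESHOLDS",
    "ThresholdModel",
    "HighExpressionCalls",
    "housekeeping_upper",
    "build_threshold",
    "call_high",
]

#: published species defaults (mean of the three housekeeping uppers on the
#: original 22-/18-tissue EST profiles)
PUBLISHED_THRESHOLDS = {"human": 3.63, "mouse": 4.12}


@dataclass(frozen=True)
class ThresholdModel:
    per_gene_upper: dict[str, float]
    threshold: float
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if len(self.per_gene_upper) != 3:
            raise ValueError("threshold requires exactly three housekeeping uppers")


@dataclass
class HighExpressionCalls:
    calls: pd.DataFrame  # boolean gene x tissue
    threshold_used: float
    species: str


def housekeeping_upper(au_row, ddof: int = 1) -> float:
    """mean + 2 x SD (sample SD by default) of a housekeeping AU row."""
    row = np.asarray(au_row, dtype=float)
    if row.size < 2:
        raise ValueError("housekeeping upper needs at least 2 tissues")
    return float(row.mean() + 2.0 * row.std(ddof=ddof))


def build_threshold(rel: RelativeExpression, panel: AngiogenicPanel,
                    sd_ddof: int = 1,
                    housekeeping: tuple[str, ...] | None = None) -> ThresholdModel:
    hk = tuple(housekeeping or panel.housekeeping_symbols)
    uppers = {}
    for sym in hk:
        if sym not in rel.au.index:
            raise ValueError(f"missing housekeeping row {sym!r}")
        uppers[sym] = housekeeping_upper(rel.au.loc[sym].to_numpy(), ddof=sd_ddof)
    return ThresholdModel(per_gene_upper=uppers,
                          threshold=float(np.mean(list(uppers.values()))),
                          sd_ddof=sd_ddof)


def call_high(rel: RelativeExpression, threshold: float,
              species: str = "human") -> HighExpressionCalls:
    """Strict AU > threshold calls; unexpressed-flagged genes are never high."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    calls = rel.au.gt(threshold)
    if rel.unexpressed is not None:
        calls.loc[rel.unexpressed[rel.unexpressed].index] = False
    return HighExpressionCalls(calls=calls, threshold_used=float(threshold),
                               species=species)
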