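"""Per-tissue angiogenic potential (AP), tissue tiers and group composition.

AP is the percentage of the 163-gene panel called highly expressed in a
tissue. Tissues are ranked by descending AP and split into three contiguous
tiers (6/6/6 for the 18-tissue registry); the composition of a tissue's
highly expressed genes is broken down by the four functional groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import pandas as pd

from .panel import FUNCTIONAL_GROUPS, AngiogenicPanel
from .thresholding import HighExpressionCalls

__all__ = ["APReport", "tissue_ap", "tier_tissues", "high_gene_composition", "ap_report"]

TIERS = ("high", "middle", "low")


@dataclass
class APReport:
    per_tissue_ap: pd.Series                  # percent, 0-100
    tiers: pd.Series                          # tier label per tissue
    composition: pd.DataFrame                 # tissue x group high counts
    composition_pct: pd.DataFrame             # percent of that tissue's highs
    group_ap: pd.DataFrame                    # percent high within each group
    empty_tissues: pd.Series                  # True where a tissue has no highs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"ap_percent": self.per_tissue_ap, "tier": self.tiers})
        for g in FUNCTIONAL_GROUPS:
            df[f"{g.lower()}_count"] = self.composition[g]
        return df


def _panel_calls(calls: HighExpressionCalls, panel: AngiogenicPanel,
                 denominator: str = "panel") -> tuple[pd.DataFrame, int]:
    """Boolean calls restricted to panel genes; absent genes count not-high."""
    present = [s for s in panel.symbols if s in calls.calls.index]
    sub = calls.calls.loc[present]
    if denominator == "panel":
        denom = len(panel.entries)
    elif denominator == "observed":
        denom = len(present)
    else:
        raise ValueError("denominator must be 'panel' or 'observed'")
    return sub, denom


def tissue_ap(calls: HighExpressionCalls, panel: AngiogenicPanel,
              denominator: str = "panel") -> pd.Series:
    """Percent of panel genes highly expressed per tissue (denominator 163)."""
    sub, denom = _panel_calls(calls, panel, denominator)
    if denom == 0:
        raise ValueError("no panel genes observed")
    return 100.0 * sub.sum(axis=0) / denom


def tier_tissues(ap: pd.Series) -> pd.Series:
    """Partition tissues into high/middle/low AP tiers.

    Tissues are ranked by descending AP (ties broken by tissue name
    ascending) and split into contiguous blocks of sizes ceil(n/3) then a
    balanced remainder — 6/6/6 at n=18.
    """
    n = len(ap)
    if n < 3:
        raise ValueError("tiering needs at least 3 tissues")
    first = ceil(n / 3)
    rest = n - first
    second = ceil(rest / 2)
    sizes = [first, second, rest - second]
    ranked = sorted(ap.index, key=lambda t: (-ap[t], t))
    labels = {}
    pos = 0
    for tier, size in zip(TIERS, sizes):
        for t in ranked[pos:pos + size]:
            labels[t] = tier
        pos += size
    return pd.Series(labels, index=ap.index, name="tier")


def high_gene_composition(calls: HighExpressionCalls, panel: AngiogenicPanel
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of high genes per functional group and percent-of-high.

    Tissues with zero high genes report 0 percent for every group (flagged
    via the report's ``empty_tissues``).
    """
    sub, _ = _panel_calls(calls, panel)
    groups = {s: panel.get(s).functional_group for s in sub.index}
    counts = pd.DataFrame(0, index=calls.calls.columns, columns=list(FUNCTIONAL_GROUPS))
    for g in FUNCTIONAL_GROUPS:
        rows = [s for s, grp in groups.items() if grp == g]
        counts[g] = sub.loc[rows].sum(axis=0) if rows else 0
    totals = counts.sum(axis=1)
    pct = counts.div(totals.where(totals > 0), axis=0).fillna(0.0) * 100.0
    return counts, pct


def group_ap(calls: HighExpressionCalls, panel: AngiogenicPanel) -> pd.DataFrame:
    """AP computed within each functional group (denominator = group size)."""
    sub, _ = _panel_calls(calls, panel)
    sizes = panel.group_counts()
    out = pd.DataFrame(index=calls.calls.columns, columns=list(FUNCTIONAL_GROUPS),
                       dtype=float)
    for g in FUNCTIONAL_GROUPS:
        rows = [s for s in sub.index if panel.get(s).functional_group == g]
        out[g] = 100.0 * (sub.loc[rows].sum(axis=0) if rows else 0) / sizes[g]
    return out


def ap_report(calls: HighExpressionCalls, panel: AngiogenicPanel,
              denominator: str = "panel") -> APReport:
    ap = tissue_ap(calls, panel, denominator)
    counts, pct = high_gene_composition(calls, panel)
    return APReport(
        per_tissue_ap=ap,
        tiers=tier_tissues(ap),
        composition=counts,
        composition_pct=pct,
        group_ap=group_ap(calls, panel),
        empty_tissues=counts.sum(axis=1).eq(0))
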