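"""Rule-based pathway activity and cytokine/chemokine response calls.

A pathway is active in a tissue when at least one third of its member genes
are highly expressed there (exact integer rule: 3 x high_count >= size). A
tissue has active angiogenic signalling when strictly more than two of the
seven pathways are active. A C/C is "abundant" when it is highly expressed
in strictly more tissues than the median over all 27 C/Cs; a tissue has a
"high angiogenic C/C response" when strictly more C/Cs are high there than
the median over all tissues. Medians include zero-count rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .panel import AngiogenicPanel
from .thresholding import HighExpressionCalls

__all__ = ["PathwayActivity", "CCResponse", "pathway_activity",
           "tissue_signaling", "cc_response"]


@dataclass
class PathwayActivity:
    fraction_high: pd.DataFrame          # pathway-name x tissue, Fraction entries
    active: pd.DataFrame                 # boolean pathway-name x tissue
    tissue_signaling_active: pd.Series   # boolean per tissue


@dataclass
class CCResponse:
    tissues_high_per_cc: pd.Series   # count of tissues per C/C
    abundant: pd.Series              # boolean per C/C
    ccs_high_per_tissue: pd.Series   # count of C/Cs per tissue
    high_response: pd.Series         # boolean per tissue
    cc_median: float
    tissue_median: float


def pathway_activity(calls: HighExpressionCalls, panel: AngiogenicPanel
                     ) -> PathwayActivity:
    """Exact-rational one-third rule per pathway and tissue."""
    tissues = list(calls.calls.columns)
    frac_rows, active_rows, names = [], [], []
    for pw in panel.pathways:
        if not pw.genes:
            raise ValueError(f"empty pathway definition {pw.name}")
        present = [g for g in pw.genes if g in calls.calls.index]
        high = calls.calls.loc[present].sum(axis=0) if present else \
            pd.Series(0, index=tissues)
        names.append(pw.name)
        frac_rows.append([Fraction(int(h), pw.size) for h in high])
        active_rows.append([3 * int(h) >= pw.size for h in high])
    fraction = pd.DataFrame(frac_rows, index=names, columns=tissues, dtype=object)
    active = pd.DataFrame(active_rows, index=names, columns=tissues)
    return PathwayActivity(
        fraction_high=fraction, active=active,
        tissue_signaling_active=tissue_signaling_from_active(active))


def tissue_signaling_from_active(active: pd.DataFrame) -> pd.Series:
    return active.sum(axis=0) > 2


def tissue_signaling(activity: PathwayActivity) -> pd.Series:
    """Active angiogenic signalling: strictly more than 2 of 7 pathways active."""
    if activity.active.shape[0] != 7:
        raise ValueError("tissue signalling requires all seven pathways")
    return tissue_signaling_from_active(activity.active)


def cc_response(calls: HighExpressionCalls, panel: AngiogenicPanel,
                median_scope: str = "all") -> CCResponse:
    """Abundant-C/C and high-response-tissue calls (strict greater-than-median).

    All panel C/Cs are evaluated; a C/C absent from the table counts as high
    in zero tissues. ``median_scope='category'`` computes the abundance
    median within each pro/anti/bi category instead of across all 27.
    """
    tissues = list(calls.calls.columns)
    ccs = panel.cc_symbols()
    per_cc = pd.Series(
        {s: int(calls.calls.loc[s].sum()) if s in calls.calls.index else 0
         for s in ccs})
    if median_scope == "all":
        med_cc = float(np.median(per_cc.to_numpy()))
        abundant = per_cc > med_cc
    elif median_scope == "category":
        abundant = pd.Series(False, index=per_cc.index)
        meds = []
        for cat in ("pro", "anti", "bi"):
            members = list(panel.cc_symbols(cat))
            med = float(np.median(per_cc[members].to_numpy()))
            meds.append(med)
            abundant[members] = per_cc[members] > med
        med_cc = float(np.median(meds))
    else:
        raise ValueError("median_scope must be 'all' or 'category'")
    present = [s for s in ccs if s in calls.calls.index]
    per_tissue = calls.calls.loc[present].sum(axis=0) if present else \
        pd.Series(0, index=tissues)
    per_tissue = per_tissue.astype(int)
    med_t = float(np.median(per_tissue.to_numpy()))
    return CCResponse(
        tissues_high_per_cc=per_cc, abundant=abundant,
        ccs_high_per_tissue=per_tissue, high_response=per_tissue > med_t,
        cc_median=med_cc, tissue_median=med_t)
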