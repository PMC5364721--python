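"""Simple linear regression of candidate master genes against tissue AP.

Expression in AU (response) is regressed on tissue AP in percent
(predictor) by ordinary least squares; r^2 is the squared Pearson
correlation and the p-value comes from the t statistic on the slope with
n - 2 degrees of freedom. Significant genes (p < 0.05) are tiered by r^2:
high (>= 0.4 by default), low (< 0.3 by default), middle in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import FUNCTIONAL_GROUPS, AngiogenicPanel
from .ap_scoring import group_ap
from .profiles import RelativeExpression
from .thresholding import HighExpressionCalls

__all__ = ["TierCutoffs", "RegressionResult", "regress_gene", "assign_tier",
           "group_ap_regression"]


@dataclass(frozen=True)
class TierCutoffs:
    high_cut: float = 0.4
    low_cut: float = 0.3
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.high_cut <= self.low_cut:
            raise ValueError("high_cut must exceed low_cut")


@dataclass
class RegressionResult:
    symbol: str
    slope: float
    intercept: float
    r2: float
    p: float
    n: int
    tier: str = "not_significant"


def regress_gene(rel: RelativeExpression, ap: pd.Series, symbol: str,
                 cutoffs: TierCutoffs = TierCutoffs()) -> RegressionResult:
    """OLS of AU[symbol] on AP, with significance-gated r^2 tier."""
    if symbol not in rel.au.index:
        raise ValueError(f"missing gene row {symbol!r}")
    y = rel.au.loc[symbol, ap.index].to_numpy(dtype=float)
    x = ap.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 tissues")
    if np.ptp(x) == 0:
        raise ValueError("constant AP predictor")
    if np.ptp(y) == 0:
        # constant response: zero slope explains nothing
        res = RegressionResult(symbol, 0.0, float(y[0]), 0.0, 1.0, x.size)
    else:
        fit = stats.linregress(x, y)
        res = RegressionResult(symbol, float(fit.slope), float(fit.intercept),
                               float(fit.rvalue) ** 2, float(fit.pvalue), x.size)
    res.tier = assign_tier(res, cutoffs)
    return res


def assign_tier(result: RegressionResult, cutoffs: TierCutoffs = TierCutoffs()) -> str:
    if result.p >= cutoffs.alpha:
        return "not_significant"
    if result.r2 >= cutoffs.high_cut:
        return "high"
    if result.r2 < cutoffs.low_cut:
        return "low"
    return "middle"


def group_ap_regression(rel: RelativeExpression, calls: HighExpressionCalls,
                        panel: AngiogenicPanel, symbol: str,
                        cutoffs: TierCutoffs = TierCutoffs()
                        ) -> dict[str, RegressionResult]:
    """Regress one gene's AU against the AP of each functional group.

    Groups whose AP is constant across tissues (e.g. no high genes anywhere)
    are omitted from the result rather than failing the others.
    """
    gap = group_ap(calls, panel)
    out: dict[str, RegressionResult] = {}
    for g in FUNCTIONAL_GROUPS:
        ap = gap[g]
        if np.ptp(ap.to_numpy(dtype=float)) == 0:
            continue
        out[g] = regress_gene(rel, ap, symbol, cutoffs)
    return out


def regression_frame(results) -> pd.DataFrame:
    rows = [{"symbol": r.symbol, "slope": r.slope, "intercept": r.intercept,
             "r2": r.r2, "p": r.p, "n": r.n, "tier": r.tier} for r in results]
    return pd.DataFrame(rows)
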