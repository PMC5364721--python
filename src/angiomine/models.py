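"""Model/Results objects orchestrating the pipeline stages.

`TissueAngiogenesisModel` wraps the physiological arm (normalisation,
thresholding, AP scoring, pathway activity, C/C response); its `fit()`
returns a `TissueAngiogenesisResults` carrying every intermediate and a
text `summary()`. `DifferentialExpressionModel` wraps the pathological arm
(two-group testing, classification, rollups). `APRegressionModel` regresses
candidate master genes on the fitted APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import activity as _activity
from . import ap_scoring as _ap
from . import determinants as _det
from . import differential as _diff
from . import profiles as _profiles
from . import thresholding as _thr
from .panel import AngiogenicPanel, load_builtin_panel

__all__ = ["TissueAngiogenesisModel", "TissueAngiogenesisResults",
           "DifferentialExpressionModel", "DifferentialResults",
           "APRegressionModel"]


class TissueAngiogenesisModel:
    """Tissue angiogenic-potential model over an expression table and panel."""

    def __init__(self, table: _profiles.ExpressionTable,
                 panel: AngiogenicPanel | None = None):
        self.table = table
        self.panel = panel or load_builtin_panel(table.species)

    @classmethod
    def from_tsv(cls, path, species: str, panel: AngiogenicPanel | None = None):
        return cls(_profiles.read_expression_tsv(path, species), panel)

    def fit(self, threshold: float | None = None, sd_ddof: int = 1,
            denominator: str = "panel", cc_median_scope: str = "all"
            ) -> "TissueAngiogenesisResults":
        rel = _profiles.relative_expression(self.table)
        if threshold is None:
            tm = _thr.build_threshold(rel, self.panel, sd_ddof=sd_ddof)
        else:
            tm = None
        thr = tm.threshold if tm is not None else float(threshold)
        calls = _thr.call_high(rel, thr, species=self.table.species)
        report = _ap.ap_report(calls, self.panel, denominator=denominator)
        pathway = _activity.pathway_activity(calls, self.panel)
        ccr = _activity.cc_response(calls, self.panel, median_scope=cc_median_scope)
        return TissueAngiogenesisResults(
            model=self, relative=rel, threshold_model=tm, threshold=thr,
            calls=calls, ap_report=report, pathway_activity=pathway,
            cc_response=ccr)


@dataclass
class TissueAngiogenesisResults:
    model: TissueAngiogenesisModel
    relative: _profiles.RelativeExpression
    threshold_model: _thr.ThresholdModel | None
    threshold: float
    calls: _thr.HighExpressionCalls
    ap_report: _ap.APReport
    pathway_activity: _activity.PathwayActivity
    cc_response: _activity.CCResponse

    @property
    def ap(self) -> pd.Series:
        return self.ap_report.per_tissue_ap

    def summary(self) -> str:
        rep = self.ap_report
        lines = [
            "Tissue angiogenic potential",
            "===========================",
            f"species: {self.model.table.species}   "
            f"tissues: {len(rep.per_tissue_ap)}   "
            f"panel genes: {len(self.model.panel.entries)}",
            f"high-expression threshold (AU): {self.threshold:.4g}"
            + ("" if self.threshold_model else " [override]"),
            "",
            f"{'tissue':<16}{'AP %':>8}  {'tier':<8}{'signaling':<10}{'C/C resp'}",
        ]
        sig = self.pathway_activity.tissue_signaling_active
        for t in rep.per_tissue_ap.sort_values(ascending=False).index:
            lines.append(
                f"{t:<16}{rep.per_tissue_ap[t]:>8.2f}  {rep.tiers[t]:<8}"
                f"{'active' if sig[t] else '-':<10}"
                f"{'high' if self.cc_response.high_response[t] else '-'}")
        return "\n".join(lines)


class APRegressionModel:
    """OLS of candidate master-gene AU on tissue AP."""

    def __init__(self, results: TissueAngiogenesisResults,
                 cutoffs: _det.TierCutoffs = _det.TierCutoffs()):
        self.results = results
        self.cutoffs = cutoffs

    def fit(self, symbols) -> pd.DataFrame:
        out = [_det.regress_gene(self.results.relative, self.results.ap, s,
                                 self.cutoffs) for s in symbols]
        return _det.regression_frame(out)

    def fit_groups(self, symbol: str) -> dict[str, _det.RegressionResult]:
        return _det.group_ap_regression(
            self.results.relative, self.results.calls,
            self.results.model.panel, symbol, self.cutoffs)


class DifferentialExpressionModel:
    """Two-group disease-vs-control comparison restricted to the panel."""

    def __init__(self, comparison: _diff.GroupComparison,
                 panel: AngiogenicPanel | None = None):
        self.comparison = comparison
        self.panel = panel or load_builtin_panel("human")

    def fit(self, test: str = "welch", d0: float = 4.0,
            fdr: str | None = None) -> "DifferentialResults":
        changes, absent = _diff.classify_changes(
            self.comparison, self.panel, test=test, d0=d0, fdr=fdr)
        return DifferentialResults(
            model=self, changes=changes, absent=absent,
            summary_rollup=_diff.summarize_changes(changes, self.panel),
            test=test)


@dataclass
class DifferentialResults:
    model: DifferentialExpressionModel
    changes: list[_diff.GeneChange]
    absent: list[str] = field(default_factory=list)
    summary_rollup: _diff.ChangeSummary = None
    test: str = "welch"

    def to_frame(self) -> pd.DataFrame:
        return _diff.changes_frame(self.changes)

    def summary(self) -> str:
        s = self.summary_rollup
        lines = [
            "Differential panel expression (case vs control)",
            "===============================================",
            f"test: {self.test}   genes tested: {len(self.changes)}   "
            f"absent from platform: {len(self.absent)}",
            f"up (p<0.05, FC>=2): {len(s.up)}   down (p<0.05, FC<=0.5): {len(s.down)}",
            "",
            "pathway rollup (up / down):",
        ]
        for name, ud in s.per_pathway.items():
            if ud["up"] or ud["down"]:
                lines.append(f"  {name:<10} up: {', '.join(ud['up']) or '-'}"
                             f"   down: {', '.join(ud['down']) or '-'}")
        lines.append("C/C categories (up of size):")
        for cat, d in s.per_cc_category.items():
            lines.append(f"  {cat:<5} {d['n_up']} of {d['denominator']} up, "
                         f"{d['n_down']} down")
        if s.ec_dominance_defined:
            lines.append(
                f"EC-specific pathway share of significant changes: "
                f"{s.ec_dominance:.2f}"
                f" ({'dominant' if s.ec_dominant else 'not dominant'};"
                " package convention, threshold 0.5)")
        if s.receptor_profile:
            rp = ", ".join(f"{k}: {v}" for k, v in sorted(s.receptor_profile.items()))
            lines.append(f"receptor classes among up genes: {rp}")
        return "\n".join(lines)
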