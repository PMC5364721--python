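"""Two-group disease-vs-control comparison of panel genes.

Reimplements the GEO2R-style workflow: per-gene two-sample test on log2
intensities (Welch's t by default, with an optional moderated variant that
shrinks per-gene variances toward the across-gene mean), linear fold change
2^(mean_case - mean_control), and the three-way classification
up (p < 0.05 and FC >= 2), down (p < 0.05 and FC <= 0.5), else unchanged —
followed by pathway, C/C-category and receptor-class rollups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import EC_SPECIFIC_PATHWAY_IDS, AngiogenicPanel

__all__ = [
    "GroupComparison", "GeneChange", "ChangeSummary",
    "detect_scale", "test_gene", "classify_changes", "summarize_changes",
    "read_series_matrix",
]

ALPHA = 0.05
FC_UP = 2.0
FC_DOWN = 0.5
LINEAR_PSEUDOCOUNT = 1.0


@dataclass
class GroupComparison:
    values: pd.DataFrame            # gene x sample
    group_labels: dict[str, str]    # sample -> 'case' | 'control'
    scale: str = "auto"             # 'linear' | 'log2' | 'auto'

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        for grp in ("case", "control"):
            if len(self.samples(grp)) < 3:
                raise ValueError(
                    f"{grp} group has fewer than 3 samples (at least 3 required)")
        if self.scale == "auto":
            self.scale = detect_scale(self.values)

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_labels.get(s) == group]

    def log2_values(self) -> pd.DataFrame:
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + LINEAR_PSEUDOCOUNT)


@dataclass
class GeneChange:
    symbol: str
    fold_change: float
    log2fc: float
    p: float
    klass: str = "unchanged"   # 'up' | 'down' | 'unchanged'

    @staticmethod
    def classify(fold_change: float, p: float) -> str:
        if p < ALPHA and fold_change >= FC_UP:
            return "up"
        if p < ALPHA and fold_change <= FC_DOWN:
            return "down"
        return "unchanged"


@dataclass
class ChangeSummary:
    per_pathway: dict[str, dict[str, list[str]]]       # name -> {'up': [...], 'down': [...]}
    per_cc_category: dict[str, dict[str, object]]      # cat -> counts & denominator
    ec_dominance: float
    ec_dominant: bool
    ec_dominance_defined: bool
    receptor_profile: dict[str, int]                   # among up genes
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)


def detect_scale(values: pd.DataFrame) -> str:
    """Heuristic: log2 when the 99th percentile is < 30 with no values < -30."""
    arr = values.to_numpy(dtype=float)
    if arr.size == 0:
        raise ValueError("empty matrix")
    if np.percentile(arr, 99) < 30 and arr.min() > -30:
        return "log2"
    return "linear"


def _moderated_s2(log2: pd.DataFrame, case: list[str], ctrl: list[str],
                  d0: float) -> tuple[pd.Series, float]:
    """Shrunken pooled variances s~^2 = (d0*s0^2 + d*s^2)/(d0 + d)."""
    n1, n2 = len(case), len(ctrl)
    d = n1 + n2 - 2
    v1 = log2[case].var(axis=1, ddof=1)
    v2 = log2[ctrl].var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    s0_2 = float(s2.mean())
    return (d0 * s0_2 + d * s2) / (d0 + d), float(d)


def test_gene(comparison: GroupComparison, symbol: str,
              test: str = "welch", d0: float = 4.0) -> GeneChange:
    """Per-gene two-sample test and fold change on log2 values."""
    if symbol not in comparison.values.index:
        raise ValueError(f"missing gene {symbol!r}")
    log2 = comparison.log2_values()
    case = comparison.samples("case")
    ctrl = comparison.samples("control")
    x = log2.loc[symbol, case].to_numpy(dtype=float)
    y = log2.loc[symbol, ctrl].to_numpy(dtype=float)
    l2fc = float(x.mean() - y.mean())
    p = _p_value(x, y, log2, case, ctrl, symbol, test, d0)
    fc = float(2.0 ** l2fc)
    return GeneChange(symbol=symbol, fold_change=fc, log2fc=l2fc, p=p,
                      klass=GeneChange.classify(fc, p))


def _p_value(x, y, log2, case, ctrl, symbol, test, d0) -> float:
    if test == "welch":
        t = stats.ttest_ind(x, y, equal_var=False)
        p = float(t.pvalue)
    elif test == "student":
        t = stats.ttest_ind(x, y, equal_var=True)
        p = float(t.pvalue)
    elif test == "moderated":
        s2_tilde, d = _moderated_s2(log2, case, ctrl, d0)
        se = np.sqrt(float(s2_tilde[symbol]) * (1 / len(case) + 1 / len(ctrl)))
        if se == 0:
            return 1.0 if x.mean() == y.mean() else 0.0
        tstat = (x.mean() - y.mean()) / se
        p = float(2 * stats.t.sf(abs(tstat), df=d0 + d))
    else:
        raise ValueError(f"unknown test {test!r}")
    if np.isnan(p):  # zero variance in both groups
        p = 1.0 if x.mean() == y.mean() else 0.0
    return p


def classify_changes(comparison: GroupComparison, panel: AngiogenicPanel,
                     test: str = "welch", d0: float = 4.0,
                     fdr: str | None = None) -> tuple[list[GeneChange], list[str]]:
    """GeneChange per panel gene found in the matrix.

    Returns ``(changes, absent_symbols)``; panel genes missing from the
    platform are reported absent, not unchanged. ``fdr='bh'`` replaces raw
    p-values with Benjamini-Hochberg adjusted ones before classification.
    """
    changes, absent = [], []
    index_upper = {str(i).upper(): i for i in comparison.values.index}
    for sym in panel.symbols:
        row = index_upper.get(sym.upper())
        if row is None:
            absent.append(sym)
            continue
        gc = test_gene(comparison, row, test=test, d0=d0)
        gc.symbol = sym
        changes.append(gc)
    if fdr == "bh" and changes:
        adj = _bh_adjust(np.array([c.p for c in changes]))
        for c, q in zip(changes, adj):
            c.p = float(q)
            c.klass = GeneChange.classify(c.fold_change, c.p)
    return changes, absent


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def summarize_changes(changes: list[GeneChange], panel: AngiogenicPanel
                      ) -> ChangeSummary:
    """Pathway / C/C-category / receptor-class rollups of a change set.

    ``ec_dominance`` is the fraction of significant pathway-member changes
    falling in the EC-specific pathways (HIF-VEGF or ANG-TIE); a comparison
    with no significant pathway-member changes reports 0 with the defined
    flag cleared. This operationalisation of "EC-dominated" is a convention
    of this package, flagged as such in reports.
    """
    by_class = {"up": [], "down": []}
    for c in sorted(changes, key=lambda c: c.symbol):
        if c.klass in by_class:
            by_class[c.klass].append(c.symbol)
    per_pathway = {}
    for pw in panel.pathways:
        per_pathway[pw.name] = {
            "up": [s for s in pw.genes if s in by_class["up"]],
            "down": [s for s in pw.genes if s in by_class["down"]]}
    per_cc = {}
    for cat in ("pro", "anti", "bi"):
        members = set(panel.cc_symbols(cat))
        per_cc[cat] = {
            "up": sorted(members & set(by_class["up"])),
            "down": sorted(members & set(by_class["down"])),
            "n_up": len(members & set(by_class["up"])),
            "n_down": len(members & set(by_class["down"])),
            "denominator": len(members)}
    sig_pathway, sig_ec = 0, 0
    for c in changes:
        if c.klass == "unchanged":
            continue
        entry = panel.get(c.symbol)
        if entry and entry.pathway_ids:
            sig_pathway += 1
            if entry.pathway_ids & EC_SPECIFIC_PATHWAY_IDS:
                sig_ec += 1
    defined = sig_pathway > 0
    dominance = sig_ec / sig_pathway if defined else 0.0
    receptor = {}
    for s in by_class["up"]:
        entry = panel.get(s)
        rc = entry.receptor_class if entry else "none"
        if rc != "none":
            receptor[rc] = receptor.get(rc, 0) + 1
    return ChangeSummary(
        per_pathway=per_pathway, per_cc_category=per_cc,
        ec_dominance=dominance, ec_dominant=defined and dominance > 0.5,
        ec_dominance_defined=defined, receptor_profile=receptor,
        up=by_class["up"], down=by_class["down"])


def read_series_matrix(path, probe_map_path,
                       group_labels: dict[str, str] | None = None,
                       scale: str = "auto") -> GroupComparison | pd.DataFrame:
    """Read a GEO series-matrix table and collapse probes to gene symbols.

    Parses the ``!series_matrix_table_begin`` ... ``!series_matrix_table_end``
    block; probes map to symbols through a two-column TSV and, per symbol,
    the probe with the highest mean expression across samples is kept.
    Unknown probes are dropped with a warning. When ``group_labels`` is
    given a GroupComparison is returned, otherwise the collapsed matrix.
    """
    lines = []
    inside = False
    with open(path) as fh:
        for ln in fh:
            s = ln.rstrip("\n")
            if s.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if s.startswith("!series_matrix_table_end"):
                inside = False
                break
            if inside:
                lines.append(s)
    if not lines:
        raise ValueError("no series_matrix_table block found")
    header = [c.strip('"') for c in lines[0].split("\t")]
    recs = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = [c.strip('"') for c in ln.split("\t")]
        recs.append([parts[0]] + [float(v) if v != "" else np.nan for v in parts[1:]])
    mat = pd.DataFrame(recs, columns=header).set_index(header[0])
    pmap = pd.read_csv(probe_map_path, sep="\t", header=None, dtype=str,
                       names=["probe", "symbol"]).dropna()
    probe_to_sym = dict(zip(pmap["probe"], pmap["symbol"]))
    unknown = [p for p in mat.index if p not in probe_to_sym]
    if unknown:
        warnings.warn(f"dropped {len(unknown)} unmapped probes")
    mat = mat.loc[[p for p in mat.index if p in probe_to_sym]]
    if mat.empty:
        raise ValueError("no probes map to gene symbols")
    mat = mat.assign(_symbol=[probe_to_sym[p] for p in mat.index],
                     _mean=mat.mean(axis=1))
    keep = mat.sort_values("_mean", ascending=False).drop_duplicates("_symbol")
    collapsed = keep.set_index("_symbol").drop(columns="_mean").sort_index()
    collapsed.index.name = "symbol"
    if group_labels is None:
        return collapsed
    return GroupComparison(values=collapsed, group_labels=group_labels, scale=scale)


def changes_frame(changes: list[GeneChange]) -> pd.DataFrame:
    rows = [{"symbol": c.symbol, "fold_change": c.fold_change,
             "log2fc": c.log2fc, "p": c.p, "class": c.klass} for c in changes]
    return pd.DataFrame(rows)
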