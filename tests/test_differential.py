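"""Two-group testing, fold-change classification, rollups, series-matrix I/O."""

import numpy as np
import pandas as pd
import pytest

from angiomine.differential import (GeneChange, GroupComparison,
                                    classify_changes, detect_scale,
                                    read_series_matrix, summarize_changes)
from angiomine.differential import test_gene as compare_gene
from angiomine.synthetic_data import THROMBUS_UP_GENES, DiffSimSpec, \
    simulate_group_comparison


def make_comparison(case_rows, ctrl_rows, genes, scale="log2"):
    case = np.asarray(case_rows, dtype=float)
    ctrl = np.asarray(ctrl_rows, dtype=float)
    cols = [f"case{i}" for i in range(case.shape[1])] + \
           [f"ctrl{i}" for i in range(ctrl.shape[1])]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=cols)
    labels = {c: ("case" if c.startswith("case") else "control") for c in cols}
    return GroupComparison(values=values, group_labels=labels, scale=scale)


class TestScaleDetection:
    def test_log2_band(self):
        v = pd.DataFrame(np.random.default_rng(0).uniform(2, 14.2, (50, 6)))
        assert detect_scale(v) == "log2"

    def test_linear_band(self):
        v = pd.DataFrame(np.random.default_rng(0).uniform(10, 20000, (50, 6)))
        assert detect_scale(v) == "linear"

    def test_declared_scale_wins(self):
        v = pd.DataFrame(np.random.default_rng(0).uniform(10, 20000, (3, 6)),
                         index=list("abc"))
        labels = {c: ("case" if i < 3 else "control")
                  for i, c in enumerate(v.columns)}
        comp = GroupComparison(values=v, group_labels=labels, scale="log2")
        assert comp.scale == "log2"
        assert comp.log2_values().equals(v)


class TestTestGene:
    def test_identical_groups_null(self):
        comp = make_comparison([[5, 5, 5, 5]], [[5, 5, 5, 5]], ["g"])
        gc = compare_gene(comp, "g")
        assert gc.fold_change == pytest.approx(1.0)
        assert gc.klass == "unchanged"

    def test_noise_free_shift_of_two_log2(self):
        comp = make_comparison([[7, 7, 7, 7]], [[5, 5, 5, 5]], ["g"])
        gc = compare_gene(comp, "g")
        assert gc.fold_change == pytest.approx(4.0)
        assert gc.klass == "up"

    def test_group_below_three_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            make_comparison([[7, 7]], [[5, 5, 5]], ["g"])

    def test_missing_gene_rejected(self):
        comp = make_comparison([[5, 5, 5]], [[5, 5, 5]], ["g"])
        with pytest.raises(ValueError, match="missing gene"):
            compare_gene(comp, "nope")

    def test_linear_scale_uses_pseudocount_log(self):
        comp = make_comparison([[127, 127, 127]], [[31, 31, 31]], ["g"],
                               scale="linear")
        gc = compare_gene(comp, "g")  # log2(128) - log2(32) = 2
        assert gc.log2fc == pytest.approx(2.0)

    def test_moderated_matches_student_as_d0_vanishes(self):
        rng = np.random.default_rng(9)
        comp = make_comparison(rng.normal(8, 1, (20, 4)),
                               rng.normal(8, 1, (20, 4)),
                               [f"g{i}" for i in range(20)])
        for sym in ["g0", "g7", "g19"]:
            a = compare_gene(comp, sym, test="student")
            b = compare_gene(comp, sym, test="moderated", d0=1e-12)
            assert b.p == pytest.approx(a.p, abs=1e-9)

    def test_moderated_shrinks_extreme_variances(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(8, 1, (50, 8))
        rows[0, :4] = [8.0, 8.001, 7.999, 8.0]  # tiny variance, tiny shift
        rows[0, 4:] = [7.9, 7.901, 7.899, 7.9]
        genes = [f"g{i}" for i in range(50)]
        comp = make_comparison(rows[:, :4], rows[:, 4:], genes)
        welch = compare_gene(comp, "g0", test="welch")
        mod = compare_gene(comp, "g0", test="moderated", d0=4.0)
        assert mod.p > welch.p  # shrinkage tempers the near-zero variance


class TestClassification:
    @pytest.mark.parametrize("l2fc,p,klass", [
        (1.0, 0.001, "up"),        # FC exactly 2.0, inclusive
        (0.85, 0.001, "unchanged"),  # FC 1.8 fails the gate
        (-1.0, 0.001, "down"),     # FC exactly 0.5, inclusive
        (2.0, 0.2, "unchanged"),   # significance gate
    ])
    def test_fc_and_p_gates(self, l2fc, p, klass):
        assert GeneChange.classify(2.0 ** l2fc, p) == klass

    def test_noise_free_planted_partition_recovered(self, human_panel):
        genes = list(human_panel.symbols)
        base = np.full((len(genes), 4), 8.0)
        case = base.copy()
        up = genes[:5]
        down = genes[5:8]
        case[:5] += 1.5
        case[5:8] -= 1.5
        comp = make_comparison(case, base, genes)
        changes, absent = classify_changes(comp, human_panel)
        assert absent == []
        got_up = sorted(c.symbol for c in changes if c.klass == "up")
        got_down = sorted(c.symbol for c in changes if c.klass == "down")
        assert got_up == sorted(up)
        assert got_down == sorted(down)

    def test_absent_panel_genes_reported_absent(self, human_panel):
        comp = make_comparison([[8, 8, 8]], [[8, 8, 8]], ["VEGFA"])
        changes, absent = classify_changes(comp, human_panel)
        assert len(changes) == 1
        assert len(absent) == 162

    def test_mirror_symmetry_under_label_swap(self, human_panel):
        rng = np.random.default_rng(21)
        genes = list(human_panel.symbols[:30])
        case = rng.normal(8, 0.3, (30, 4))
        ctrl = rng.normal(8, 0.3, (30, 4))
        case[:4] += 2.0
        comp = make_comparison(case, ctrl, genes)
        swapped = GroupComparison(
            values=comp.values,
            group_labels={s: ("control" if g == "case" else "case")
                          for s, g in comp.group_labels.items()},
            scale="log2")
        a, _ = classify_changes(comp, human_panel)
        b, _ = classify_changes(swapped, human_panel)
        for ca, cb in zip(a, b):
            assert cb.fold_change == pytest.approx(1 / ca.fold_change)
            assert cb.p == pytest.approx(ca.p, abs=1e-12)
            mirror = {"up": "down", "down": "up", "unchanged": "unchanged"}
            assert cb.klass == mirror[ca.klass]

    def test_sample_order_invariance(self, human_panel):
        rng = np.random.default_rng(8)
        genes = list(human_panel.symbols[:10])
        comp = make_comparison(rng.normal(8, 0.5, (10, 4)),
                               rng.normal(8, 0.5, (10, 4)), genes)
        perm = comp.values[list(reversed(comp.values.columns))]
        comp2 = GroupComparison(values=perm, group_labels=comp.group_labels,
                                scale="log2")
        a, _ = classify_changes(comp, human_panel)
        b, _ = classify_changes(comp2, human_panel)
        assert [c.klass for c in a] == [c.klass for c in b]


class TestSummaries:
    def _changes_for(self, symbols, klass="up"):
        return [GeneChange(s, 4.0 if klass == "up" else 0.25,
                           2.0 if klass == "up" else -2.0, 0.001, klass)
                for s in symbols]

    def test_thrombus_up_set_receptor_profile(self, human_panel):
        s = summarize_changes(self._changes_for(THROMBUS_UP_GENES), human_panel)
        assert s.receptor_profile["ec_surface"] == 7
        assert s.receptor_profile["transcription_factor"] == 3
        assert s.receptor_profile["secreted_factor"] == 5
        assert s.ec_dominance == pytest.approx(12 / 15)
        assert s.ec_dominant

    def test_no_significant_changes(self, human_panel):
        s = summarize_changes(
            [GeneChange("VEGFA", 1.0, 0.0, 0.9, "unchanged")], human_panel)
        assert not s.ec_dominance_defined
        assert s.ec_dominance == 0.0
        assert s.up == [] and s.down == []

    def test_all_up_in_hif_vegf_is_fully_dominant(self, human_panel):
        genes = list(human_panel.pathway("HIF-VEGF").genes[:4])
        s = summarize_changes(self._changes_for(genes), human_panel)
        assert s.ec_dominance == 1.0 and s.ec_dominant

    def test_cc_category_rollup_counts(self, human_panel):
        pro = list(human_panel.cc_symbols("pro")[:8])
        anti = list(human_panel.cc_symbols("anti")[:3])
        s = summarize_changes(self._changes_for(pro) +
                              self._changes_for(anti, "down"), human_panel)
        assert s.per_cc_category["pro"]["n_up"] == 8
        assert s.per_cc_category["pro"]["denominator"] == 14
        assert s.per_cc_category["anti"]["n_down"] == 3
        assert s.per_cc_category["anti"]["denominator"] == 7
        assert s.per_cc_category["bi"]["denominator"] == 6


SERIES = """!some_header\t"x"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"\t"GSM4"\t"GSM5"\t"GSM6"
"p1"\t8.0\t8.1\t8.2\t5.0\t5.1\t5.2
"p2"\t1.0\t1.1\t1.0\t1.2\t1.1\t1.0
"p3"\t9.0\t9.1\t9.0\t9.2\t9.1\t9.0
"p4"\t2.0\t2.0\t2.0\t2.0\t2.0\t2.0
!series_matrix_table_end
"""


class TestSeriesMatrix:
    def _write(self, tmp_path, text=SERIES, pmap="p1\tVEGFA\np2\tKDR\np3\tKDR\n"):
        m = tmp_path / "series.txt"
        m.write_text(text)
        pm = tmp_path / "map.tsv"
        pm.write_text(pmap)
        return m, pm

    def test_collapse_keeps_highest_mean_probe(self, tmp_path):
        m, pm = self._write(tmp_path)
        with pytest.warns(UserWarning, match="unmapped"):
            mat = read_series_matrix(m, pm)
        assert sorted(mat.index) == ["KDR", "VEGFA"]
        assert mat.loc["KDR", "GSM1"] == 9.0  # p3 outranks p2

    def test_missing_sentinels_rejected(self, tmp_path):
        m, pm = self._write(tmp_path, text="no\tblock\nhere\t1\n")
        with pytest.raises(ValueError, match="series_matrix_table"):
            read_series_matrix(m, pm)

    def test_zero_resolvable_probes_rejected(self, tmp_path):
        m, pm = self._write(tmp_path, pmap="zzz\tVEGFA\n")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no probes"):
                read_series_matrix(m, pm)

    def test_group_labels_build_comparison(self, tmp_path):
        m, pm = self._write(tmp_path)
        labels = {f"GSM{i}": ("case" if i <= 3 else "control")
                  for i in range(1, 7)}
        with pytest.warns(UserWarning):
            comp = read_series_matrix(m, pm, group_labels=labels)
        assert isinstance(comp, GroupComparison)
        gc = compare_gene(comp, "VEGFA")
        assert gc.klass == "up"


def test_null_type_one_error_is_calibrated():
    """Fraction of null genes with p < 0.05 at n=4+4 stays near nominal."""
    comp, _ = simulate_group_comparison(
        DiffSimSpec(n_genes=2000, n_per_group=4, noise_sd=0.25, seed=123))
    ps = np.array([compare_gene(comp, g).p for g in comp.values.index])
    frac = float((ps < 0.05).mean())
    assert 0.03 < frac < 0.07
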