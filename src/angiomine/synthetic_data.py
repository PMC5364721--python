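"""Synthetic inputs with known truth for every pipeline stage.

Two generators emulate the statistical structure the analysis assumes:

* EST-style tissue tables — expected tag counts per gene and tissue are
  Poisson-sampled at a configurable library size; housekeeping rows carry a
  controlled across-tissue dispersion so the expected high-expression
  threshold has the closed form 1 + 2 * hk_cv; selected (gene, tissue)
  pairs are boosted to plant known high-expression truth.
* Two-group log2 matrices with planted fold-change effects under Gaussian
  noise, emulating the microarray disease-control comparisons.

Housekeeping dispersion is a symmetric truncated-normal multiplier whose
variance is calibrated so the TOTAL across-tissue coefficient of variation
(multiplier plus Poisson tag sampling, including the shared beta-actin
denominator) equals ``hk_cv``; a symmetric mean-one multiplier keeps the
median normalisation unbiased, which is what makes the 1 + 2c closed form
exact rather than approximate. All randomness flows through one explicit
seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AngiogenicPanel
from .profiles import ExpressionTable
from .differential import GroupComparison

__all__ = ["ESTSimSpec", "DiffSimSpec", "simulate_est_table",
           "simulate_group_comparison", "paperlike_fixture"]


@dataclass
class ESTSimSpec:
    n_tissues: int = 22
    tissues: list[str] | None = None
    library_size: int = 100_000
    actin_tpm: float = 5_000.0
    baseline_ratio: float = 0.1
    hk_ratio: float = 1.0
    boost_factor: float = 10.0
    hk_cv: float = 0.2
    planted_high: set[tuple[str, str]] = field(default_factory=set)
    seed: int = 0


@dataclass
class DiffSimSpec:
    n_genes: int = 1000
    n_per_group: int = 4
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.25
    planted: dict[str, float] = field(default_factory=dict)
    gene_names: list[str] | None = None
    seed: int = 0


def _expected_threshold(spec: ESTSimSpec) -> tuple[float, float]:
    """(expected threshold, multiplier SD) for the housekeeping model.

    Poisson tag sampling of the housekeeping and actin counts contributes
    variance 1/E[n_hk] + 1/E[n_actin] to the squared ratio CV; the
    multiplier SD absorbs the remainder of hk_cv^2. When hk_cv is too small
    to absorb the sampling floor the multiplier is zero and the expected
    threshold reflects the sampling CV alone.
    """
    n_act = spec.actin_tpm * spec.library_size / 1e6
    n_hk = spec.hk_ratio * spec.actin_tpm * spec.library_size / 1e6
    sampling_var = 1.0 / n_hk + 1.0 / n_act
    mult_var = spec.hk_cv ** 2 - sampling_var
    if mult_var > 0:
        return 1.0 + 2.0 * spec.hk_cv, float(np.sqrt(mult_var))
    return 1.0 + 2.0 * float(np.sqrt(sampling_var)), 0.0


def simulate_est_table(spec: ESTSimSpec, panel: AngiogenicPanel
                       ) -> tuple[ExpressionTable, dict]:
    """Poisson EST table with planted high truth and analytic threshold.

    Returns ``(table, truth)`` where truth carries the planted pairs and the
    generator's expected threshold. Raises for an infeasible spec whose
    boost does not clear the expected threshold.
    """
    rng = np.random.default_rng(spec.seed)
    tissues = list(spec.tissues) if spec.tissues else \
        [f"tissue{i + 1:02d}" for i in range(spec.n_tissues)]
    if len(tissues) != len(set(tissues)):
        raise ValueError("duplicate tissue names")
    exp_thr, mult_sd = _expected_threshold(spec)
    if spec.planted_high and spec.boost_factor <= exp_thr:
        raise ValueError(
            f"infeasible spec: boost_factor {spec.boost_factor} does not exceed "
            f"the expected threshold {exp_thr:.3f}")
    genes = list(panel.symbols)
    hk = list(panel.housekeeping_symbols)
    nt = len(tissues)
    per_gene_planted = {}
    for g, t in spec.planted_high:
        per_gene_planted.setdefault(g, set()).add(t)
        if t not in tissues:
            raise ValueError(f"planted tissue {t!r} not in tissue list")
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not in panel")
    for g, ts in per_gene_planted.items():
        if len(ts) > nt // 2:
            raise ValueError(
                f"gene {g!r} planted in more than half the tissues; "
                "its median would absorb the boost")

    # expected TPM per gene x tissue
    expected = np.full((len(genes), nt), spec.baseline_ratio * spec.actin_tpm)
    t_index = {t: j for j, t in enumerate(tissues)}
    g_index = {g: i for i, g in enumerate(genes)}
    for g, t in spec.planted_high:
        expected[g_index[g], t_index[t]] *= spec.boost_factor
    # housekeeping rows: controlled multiplicative dispersion (truncated at 0)
    hk_expected = np.empty((3, nt))
    for i in range(3):
        mult = 1.0 + mult_sd * rng.standard_normal(nt) if mult_sd > 0 else np.ones(nt)
        hk_expected[i] = np.clip(mult, 0.0, None) * spec.hk_ratio * spec.actin_tpm
    actin_expected = np.full(nt, spec.actin_tpm)

    all_expected = np.vstack([expected, hk_expected, actin_expected])
    counts = rng.poisson(all_expected * spec.library_size / 1e6)
    tpm = counts.astype(float) / spec.library_size * 1e6
    # actin must stay strictly positive; at default sizes a zero draw is
    # practically impossible but guard the invariant anyway
    actin_row = tpm[-1]
    actin_row[actin_row == 0] = 1e6 / spec.library_size
    index = genes + hk + [panel.actin_symbol]
    values = pd.DataFrame(tpm, index=index, columns=tissues)
    table = ExpressionTable(species=panel.species, values=values,
                            actin_symbol=panel.actin_symbol,
                            housekeeping_symbols=tuple(hk))
    truth = {"planted_high": set(spec.planted_high),
             "expected_threshold": exp_thr,
             "hk_multiplier_sd": mult_sd}
    return table, truth


def simulate_group_comparison(spec: DiffSimSpec
                              ) -> tuple[GroupComparison, dict[str, str]]:
    """Log2-scale two-group matrix with planted shifts; returns truth labels."""
    if spec.n_per_group < 3:
        raise ValueError("n_per_group must be at least 3")
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_names) if spec.gene_names else \
        [f"gene{i + 1:05d}" for i in range(spec.n_genes)]
    missing = [g for g in spec.planted if g not in genes]
    if missing:
        raise ValueError(f"planted symbols not in gene set: {missing}")
    n = spec.n_per_group
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd,
                          size=len(genes))
    effect = np.array([spec.planted.get(g, 0.0) for g in genes])
    case = baseline[:, None] + effect[:, None] + \
        rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    ctrl = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    samples = [f"case{i + 1}" for i in range(n)] + [f"ctrl{i + 1}" for i in range(n)]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=samples)
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}
    comparison = GroupComparison(values=values, group_labels=labels, scale="log2")
    truth = {g: ("up" if e >= 1.0 else "down" if e <= -1.0 else "unchanged")
             for g, e in zip(genes, effect)}
    return comparison, truth


#: the 15 regulators upregulated in thrombus vs peripheral-blood leukocytes
THROMBUS_UP_GENES = (
    "FLT1", "NRP1", "ANGPTL4", "NRP2", "VEGFA", "EPAS1", "JAG1", "TEK", "JUN",
    "NOTCH3", "TIE1", "KDR", "HIF1A", "ANGPT2", "PGF",
)

_FIXTURE_SEED = 20170323 % (2 ** 31)


def paperlike_fixture(seed: int = _FIXTURE_SEED) -> dict:
    """Seeded end-to-end bundle shaped like the published study.

    Human panel; a 22-tissue EST table planted so muscle, heart, eye,
    lymph node and pancreas land in the high-AP tier (muscle highest); and a
    thrombus-vs-blood comparison whose planted up set is exactly the 15
    reported regulators. Regeneration with the same seed is bit-identical.
    """
    from .panel import load_builtin_panel, builtin_tissues

    panel = load_builtin_panel("human")
    tissues = builtin_tissues("human")
    # planted high counts per tissue: five focal tissues on top, graded tail
    focal = ["muscle", "heart", "eye", "lymph node", "pancreas"]
    n_high = {"muscle": 60, "heart": 55, "eye": 52, "lymph node": 50,
              "pancreas": 48}
    others = [t for t in tissues if t not in focal]
    for k, t in enumerate(others):
        n_high[t] = max(30 - 2 * k, 2)
    planted: set[tuple[str, str]] = set()
    syms = list(panel.symbols)
    cursor = 0
    for t in tissues:
        for _ in range(n_high[t]):
            planted.add((syms[cursor % len(syms)], t))
            cursor += 1
    est_spec = ESTSimSpec(tissues=tissues, hk_cv=0.2, boost_factor=12.0,
                          planted_high=planted, seed=seed)
    table, est_truth = simulate_est_table(est_spec, panel)

    gene_names = list(panel.symbols)
    diff_spec = DiffSimSpec(
        n_per_group=4, noise_sd=0.25, gene_names=gene_names,
        planted={g: 2.0 for g in THROMBUS_UP_GENES}, seed=seed + 1)
    comparison, diff_truth = simulate_group_comparison(diff_spec)
    return {"panel": panel, "est_table": table, "est_truth": est_truth,
            "est_spec": est_spec, "comparison": comparison,
            "diff_truth": diff_truth, "seed": seed}
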