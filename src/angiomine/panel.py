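"""Curated registry of the 163 angiogenesis-regulatory genes.

The panel covers four functional groups — transcription regulators (TR, 26),
growth factors and receptors (GFR, 64), cytokines and chemokines (CC, 27) and
proteases/inhibitors/others (PI, 46) — together with seven pro-angiogenic
pathway gene sets (MAPK, PI3K-AKT, NOTCH, NF-kB, JAK-STAT, HIF-VEGF, ANG-TIE),
the three-way pro/anti/bi-functional C/C classification (14/7/6 members) and
receptor-class annotations for the thrombus-leukocyte phenotype summary.

The registry is shipped as versioned TSV fixtures (one per species) and is the
single source of truth for every downstream scoring stage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PanelEntry",
    "PathwayDef",
    "AngiogenicPanel",
    "load_builtin_panel",
    "panel_composition",
    "classify_gene",
    "read_panel_tsv",
    "write_panel_tsv",
    "builtin_tissues",
]

FUNCTIONAL_GROUPS = ("TR", "GFR", "CC", "PI")
CC_CATEGORIES = ("pro", "anti", "bi", "none")
TR_CATEGORIES = ("inflammatory", "homeostatic", "ec_specific", "none")
RECEPTOR_CLASSES = ("ec_surface", "transcription_factor", "secreted_factor", "other", "none")

PATHWAY_NAMES = {
    1: "MAPK", 2: "PI3K-AKT", 3: "NOTCH", 4: "NF-kB",
    5: "JAK-STAT", 6: "HIF-VEGF", 7: "ANG-TIE",
}
#: expected pathway sizes in pathway-id order
PATHWAY_SIZES = (6, 8, 10, 5, 4, 14, 6)

#: EC-specific pathways (hypoxia/VEGF signalling and angiopoietin-TIE axis)
EC_SPECIFIC_PATHWAY_IDS = frozenset({6, 7})

HOUSEKEEPING = {"human": ("GAPDH", "HPRT1", "GUSB"), "mouse": ("Gapdh", "Hprt", "Gusb")}
ACTIN = {"human": "ACTB", "mouse": "Actb"}

# punctuated/legacy aliases -> canonical symbols (upper-case keys)
_ALIASES = {
    "IL-6": "IL6", "IL-15": "IL15", "IL-18": "IL18", "IL-4": "IL4", "IL-10": "IL10",
    "IL-13": "IL13", "IL-1B": "IL1B", "IL8": "CXCL8", "IL-8": "CXCL8",
    "CXCL4": "PF4", "VEGFR1": "FLT1", "VEGFR2": "KDR", "VEGFR3": "FLT4",
    "VEGFD": "FIGF", "PHD2": "EGLN1", "HIF1B": "ARNT", "HIF2A": "EPAS1",
    "OCT4": "POU5F1", "B-ACTIN": "ACTB", "BETA-ACTIN": "ACTB",
}


@dataclass(frozen=True)
class PanelEntry:
    symbol: str
    functional_group: str
    cc_category: str = "none"
    tr_category: str = "none"
    receptor_class: str = "none"
    pathway_ids: frozenset[int] = field(default_factory=frozenset)
    provenance: str = "curated"

    def __post_init__(self) -> None:
        if self.functional_group not in FUNCTIONAL_GROUPS:
            raise ValueError(f"unknown functional group {self.functional_group!r}")
        if (self.cc_category != "none") != (self.functional_group == "CC"):
            raise ValueError(
                f"{self.symbol}: cc_category must be set iff the gene is a C/C")


@dataclass(frozen=True)
class PathwayDef:
    id: int
    name: str
    genes: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.genes)


class UnknownGene:
    """Distinguishable not-in-panel lookup result (falsy singleton)."""

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "<not in panel>"


NOT_IN_PANEL = UnknownGene()


@dataclass(frozen=True)
class AngiogenicPanel:
    species: str
    entries: tuple[PanelEntry, ...]
    pathways: tuple[PathwayDef, ...]
    housekeeping_symbols: tuple[str, str, str]
    actin_symbol: str

    def __post_init__(self) -> None:
        syms = [e.symbol.upper() for e in self.entries]
        if len(set(syms)) != len(syms):
            raise ValueError("duplicate symbols in panel")
        if len(self.housekeeping_symbols) != 3:
            raise ValueError("exactly three housekeeping symbols required")

    # -- lookup -------------------------------------------------------------
    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(e.symbol for e in self.entries)

    def _index(self) -> dict[str, PanelEntry]:
        # lazily built case-insensitive index, aliases folded in
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {e.symbol.upper(): e for e in self.entries}
            for alias, target in _ALIASES.items():
                if target.upper() in idx and alias not in idx:
                    idx[alias] = idx[target.upper()]
            object.__setattr__(self, "_idx", idx)
        return idx

    def get(self, symbol: str):
        key = symbol.strip().upper()
        idx = self._index()
        if key in idx:
            return idx[key]
        bare = key.replace("-", "")
        return idx.get(bare, NOT_IN_PANEL)

    def pathway(self, ref: int | str) -> PathwayDef:
        for p in self.pathways:
            if p.id == ref or p.name == ref:
                return p
        raise KeyError(f"unknown pathway {ref!r}")

    def group_symbols(self, group: str) -> tuple[str, ...]:
        return tuple(e.symbol for e in self.entries if e.functional_group == group)

    def group_counts(self) -> dict[str, int]:
        out = {g: 0 for g in FUNCTIONAL_GROUPS}
        for e in self.entries:
            out[e.functional_group] += 1
        return out

    def cc_symbols(self, category: str | None = None) -> tuple[str, ...]:
        return tuple(
            e.symbol for e in self.entries
            if e.functional_group == "CC"
            and (category is None or e.cc_category == category))


def _round_half_away(x: float) -> int:
    import math
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def panel_composition(panel: AngiogenicPanel) -> dict[str, int]:
    """Percent of panel genes in each functional group (half-away rounding).

    Percents are reported per group and need not sum to 100 after rounding.
    """
    total = len(panel.entries)
    if total == 0:
        raise ValueError("empty panel")
    counts = panel.group_counts()
    return {g: _round_half_away(100.0 * c / total) for g, c in counts.items()}


def classify_gene(panel: AngiogenicPanel, symbol: str):
    """Case-insensitive panel lookup; absence returns NOT_IN_PANEL, not an error."""
    return panel.get(symbol)


# -- fixture I/O ------------------------------------------------------------

_COLUMNS = ["symbol", "group", "cc_category", "tr_category",
            "receptor_class", "pathway_ids", "provenance"]


def read_panel_tsv(path, species: str,
                   housekeeping: Iterable[str] | None = None,
                   actin: str | None = None) -> AngiogenicPanel:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel fixture missing columns: {missing}")
    entries = []
    pw_members: dict[int, list[str]] = {i: [] for i in PATHWAY_NAMES}
    for rec in df.itertuples(index=False):
        pids = frozenset(int(t) for t in rec.pathway_ids.split(";") if t)
        entries.append(PanelEntry(
            symbol=rec.symbol, functional_group=rec.group,
            cc_category=rec.cc_category or "none",
            tr_category=rec.tr_category or "none",
            receptor_class=rec.receptor_class or "none",
            pathway_ids=pids, provenance=rec.provenance or "curated"))
        for pid in sorted(pids):
            pw_members[pid].append(rec.symbol)
    pathways = tuple(PathwayDef(i, PATHWAY_NAMES[i], tuple(pw_members[i]))
                     for i in sorted(PATHWAY_NAMES))
    hk = tuple(housekeeping) if housekeeping else HOUSEKEEPING[species]
    return AngiogenicPanel(species=species, entries=tuple(entries),
                           pathways=pathways, housekeeping_symbols=hk,
                           actin_symbol=actin or ACTIN[species])


def write_panel_tsv(panel: AngiogenicPanel, path) -> None:
    rows = []
    for e in panel.entries:
        rows.append({
            "symbol": e.symbol, "group": e.functional_group,
            "cc_category": e.cc_category, "tr_category": e.tr_category,
            "receptor_class": e.receptor_class,
            "pathway_ids": ";".join(str(i) for i in sorted(e.pathway_ids)),
            "provenance": e.provenance})
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def _data_path(name: str):
    return importlib.resources.files("angiomine").joinpath("data", name)


def load_builtin_panel(species: str) -> AngiogenicPanel:
    """Load the curated built-in panel for ``species`` ('human' or 'mouse')."""
    if species not in ("human", "mouse"):
        raise ValueError(f"unknown species code {species!r}; expected 'human' or 'mouse'")
    with importlib.resources.as_file(_data_path(f"panel_{species}.tsv")) as p:
        return read_panel_tsv(p, species)


def builtin_tissues(species: str) -> list[str]:
    """Built-in tissue registry (22 human / 18 mouse tissues, display order)."""
    if species not in ("human", "mouse"):
        raise ValueError(f"unknown species code {species!r}")
    with importlib.resources.as_file(_data_path(f"tissues_{species}.txt")) as p:
        return [ln for ln in Path(p).read_text().splitlines() if ln.strip()]
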