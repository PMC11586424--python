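"""Marker panels and cell-type vocabularies.

A :class:`Panel` declares the markers measured on each cell, the cell-type
vocabulary, and the expected marker signature of every type.  The cell-type
vocabulary is panel-driven rather than hard-coded so that the compact 7-type
clinical panel and the extended 16-type discovery panel run on the same
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

import pandas as pd

#: reserved label for cells no signature claims with enough confidence
OTHER = "other"

#: expected intensity of a "high" marker, in arbitrary units (low = 0).
#: Positive cells in amplified multiplex stains sit well above background;
#: 2.0 against the generator's default noise SD of 0.5 emulates a clean
#: stain (signal-to-noise 4).
HIGH = 2.0


@dataclass(frozen=True)
class Panel:
    """Declared markers, cell types, and type-by-marker expected signatures.

    Parameters
    ----------
    name:
        Short identifier for the panel.
    markers:
        Ordered marker names; cell tables with intensities carry one column
        per marker.
    types:
        Ordered cell-type names (final vocabulary, after any PD-L1 split).
    signature:
        ``len(types) x len(markers)`` DataFrame of expected expression in
        arbitrary intensity units (``HIGH`` = expressed, 0 = background;
        continuous values are allowed).  Rows must be pairwise distinct.
    pdl1_split:
        Mapping ``lineage -> (pdl1_pos_type, pdl1_neg_type)`` applied after
        lineage gating; the two split types must differ only in the PD-L1
        column of ``signature``.
    priority:
        Lineage names in descending tie-break priority for gating.
    tumor_types:
        Types counted as tumor (excluded from the "non-tumor" interaction
        pairs of the feature table).
    """

    name: str
    markers: Tuple[str, ...]
    types: Tuple[str, ...]
    signature: pd.DataFrame
    pdl1_split: Mapping[str, Tuple[str, str]] = field(default_factory=dict)
    priority: Tuple[str, ...] = ()
    tumor_types: Tuple[str, ...] = ()
    pdl1_marker: str = "PDL1"

    def __post_init__(self) -> None:
        sig = self.signature
        if tuple(sig.index) != self.types or tuple(sig.columns) != self.markers:
            raise ValueError("signature must be indexed by types x markers")
        rows = [tuple(r) for r in sig.to_numpy()]
        if len(set(rows)) != len(rows):
            dupes = sig.index[pd.DataFrame(rows).duplicated(keep=False)].tolist()
            raise ValueError(f"signature rows must be distinct; duplicated: {dupes}")
        for lineage, (pos, neg) in self.pdl1_split.items():
            for t in (pos, neg):
                if t not in self.types:
                    raise ValueError(f"split type {t!r} not in panel types")

    @property
    def lineages(self) -> Tuple[str, ...]:
        """Gating lineages: panel types with each PD-L1 split collapsed.

        A split lineage appears once, at the position of its first member
        in the declared type order.
        """
        member_of = {
            t: lineage for lineage, pair in self.pdl1_split.items() for t in pair
        }
        ordered: list[str] = []
        for t in self.types:
            name = member_of.get(t, t)
            if name not in ordered:
                ordered.append(name)
        return tuple(ordered)

    def lineage_signature(self) -> pd.DataFrame:
        """Signature matrix over lineages, PD-L1 column dropped when split."""
        rows = {}
        for lineage in self.lineages:
            if lineage in self.pdl1_split:
                _, neg = self.pdl1_split[lineage]
                rows[lineage] = self.signature.loc[neg]
            else:
                rows[lineage] = self.signature.loc[lineage]
        sig = pd.DataFrame(rows).T.loc[list(self.lineages)]
        if self.pdl1_split and self.pdl1_marker in sig.columns:
            sig = sig.drop(columns=[self.pdl1_marker])
        return sig

    def resolve_split(self, lineage: str, pdl1_positive: bool) -> str:
        if lineage in self.pdl1_split:
            pos, neg = self.pdl1_split[lineage]
            return pos if pdl1_positive else neg
        return lineage

    @property
    def non_tumor_types(self) -> Tuple[str, ...]:
        return tuple(t for t in self.types if t not in self.tumor_types)


def clinical_panel() -> Panel:
    """The compact 7-marker / 7-type panel used for cohort-wide profiling.

    Markers CD4, CD8, CD20, CD11c, CD68, PD-L1 and panCK resolve T-helper
    cells (Th), cytotoxic T lymphocytes (CTL), B cells, dendritic cells (DC),
    PD-L1+ and PD-L1- macrophages, and tumor cells.
    """
    markers = ("CD4", "CD8", "CD20", "CD11c", "CD68", "PDL1", "panCK")
    types = ("Th", "CTL", "B", "DC", "PDL1+M", "PDL1-M", "Tumor")
    sig = pd.DataFrame(0.0, index=list(types), columns=list(markers))
    sig.loc["Th", "CD4"] = HIGH
    sig.loc["CTL", "CD8"] = HIGH
    sig.loc["B", "CD20"] = HIGH
    sig.loc["DC", "CD11c"] = HIGH
    sig.loc["PDL1+M", ["CD68", "PDL1"]] = HIGH
    sig.loc["PDL1-M", "CD68"] = HIGH
    sig.loc["Tumor", "panCK"] = HIGH
    return Panel(
        name="clinical-7",
        markers=markers,
        types=types,
        signature=sig,
        pdl1_split={"M": ("PDL1+M", "PDL1-M")},
        priority=("Tumor", "CTL", "Th", "DC", "M", "B"),
        tumor_types=("Tumor",),
    )


def extended_panel() -> Panel:
    """The 16-marker discovery panel resolving 15 lineage types plus Ki67.

    Includes stromal (fibroblast, FAP+ CAF, endothelial), myeloid
    (M1/M2 macrophage, monocyte, neutrophil, DC), lymphoid (Th, CTL, Treg,
    B, plasma cell) and tumor (PD-L1+/-) compartments.  Ki67 is modelled as
    a proliferation flag orthogonal to lineage, not a type.
    """
    markers = (
        "CD4", "CD8", "Foxp3", "CD20", "CD38", "CD11c", "CD68", "CD163",
        "CD14", "MPO", "CD31", "FAP", "aSMA", "PDL1", "panCK", "Ki67",
    )
    types = (
        "Th", "CTL", "Treg", "B", "Plasma", "DC", "M1", "M2", "Monocyte",
        "Neutrophil", "EC", "FAP+CAF", "Fb", "PDL1+TC", "PDL1-TC",
    )
    sig = pd.DataFrame(0.0, index=list(types), columns=list(markers))
    sig.loc["Th", "CD4"] = HIGH
    sig.loc["CTL", "CD8"] = HIGH
    sig.loc["Treg", ["CD4", "Foxp3"]] = HIGH
    sig.loc["B", "CD20"] = HIGH
    sig.loc["Plasma", "CD38"] = HIGH
    sig.loc["DC", "CD11c"] = HIGH
    sig.loc["M1", "CD68"] = HIGH
    sig.loc["M2", ["CD68", "CD163"]] = HIGH
    sig.loc["Monocyte", "CD14"] = HIGH
    sig.loc["Neutrophil", "MPO"] = HIGH
    sig.loc["EC", "CD31"] = HIGH
    sig.loc["FAP+CAF", ["FAP", "aSMA"]] = HIGH
    sig.loc["Fb", "aSMA"] = HIGH
    sig.loc["PDL1+TC", ["panCK", "PDL1"]] = HIGH
    sig.loc["PDL1-TC", "panCK"] = HIGH
    return Panel(
        name="discovery-16",
        markers=markers,
        types=types,
        signature=sig,
        pdl1_split={"TC": ("PDL1+TC", "PDL1-TC")},
        priority=(
            "TC", "Treg", "CTL", "Th", "M2", "M1", "DC", "Monocyte",
            "Neutrophil", "FAP+CAF", "Fb", "EC", "Plasma", "B",
        ),
        tumor_types=("PDL1+TC", "PDL1-TC"),
    )


def get_panel(name: str) -> Panel:
    factories = {"clinical-7": clinical_panel, "discovery-16": extended_panel}
    if name not in factories:
        raise KeyError(f"unknown panel {name!r}; available: {sorted(factories)}")
    return factories[name]()
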