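"""Marker panel and gated cellular phenotype definitions.

The default panel models a 35-antibody mass-cytometry panel: 22 lineage
markers used for clustering and landmark gating, and 13 activation /
functional markers used only for differential-activation statistics.
Fifteen cellular phenotypes are defined by hi/lo gates on lineage markers
(T-cell subsets, myeloid subsets, NK, granulocytes, tumor and stromal
compartments).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

LINEAGE_MARKERS: tuple[str, ...] = (
    "CD45", "CD3", "CD4", "CD8", "CD25", "FOXP3", "CD127", "PD1", "CTLA4",
    "HLADR", "CD14", "CD11b", "CD11c", "CD68", "CD123", "CD15", "CD56",
    "PanCK", "CD200", "Vimentin", "CD24", "EpCAM",
)

ACTIVATION_MARKERS: tuple[str, ...] = (
    "PDL1", "ICOS", "CD38", "CXCR4", "CD40", "CD86", "CD27", "CD28",
    "TIM3", "LAG3", "OX40", "CD137", "GranzymeB",
)

ALL_MARKERS: tuple[str, ...] = LINEAGE_MARKERS + ACTIVATION_MARKERS


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A gated cell phenotype: a name plus (marker, sign) requirements.

    ``gate`` lists ``(marker, "+")`` for required-high and ``(marker, "-")``
    for required-low markers; markers not listed are unconstrained.
    """

    name: str
    gate: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for marker, sign in self.gate:
            if sign not in ("+", "-"):
                raise ValueError(f"gate sign must be '+' or '-', got {sign!r}")

    @property
    def positive(self) -> tuple[str, ...]:
        return tuple(m for m, s in self.gate if s == "+")

    @property
    def negative(self) -> tuple[str, ...]:
        return tuple(m for m, s in self.gate if s == "-")


def _pd(name: str, *gate: str) -> PhenotypeDefinition:
    parsed = tuple((g[:-1], g[-1]) for g in gate)
    return PhenotypeDefinition(name=name, gate=parsed)


#: The 15 landmark phenotypes, gated on lineage markers.
DEFAULT_PHENOTYPES: tuple[PhenotypeDefinition, ...] = (
    _pd("CD4_T", "CD45+", "CD3+", "CD4+"),
    _pd("Treg", "CD45+", "CD3+", "CD4+", "CD25+", "FOXP3+", "CD127-"),
    _pd("CD8_T", "CD45+", "CD3+", "CD8+"),
    _pd("partially_exhausted_CD8", "CD45+", "CD3+", "CD8+", "PD1+", "CTLA4+"),
    _pd("monocyte", "CD45+", "CD3-", "HLADR+", "CD14+", "CD11c+"),
    _pd("TAM", "CD45+", "CD3-", "HLADR+", "CD68+", "CD11b+", "CD11c-", "CD123-"),
    _pd("pDC", "CD45+", "CD3-", "HLADR+", "CD11c-", "CD123+", "CD68-"),
    _pd("cDC", "CD45+", "CD3-", "HLADR+", "CD14-", "CD11c+"),
    _pd("neutrophil", "CD45+", "CD3-", "HLADR-", "CD15+", "CD56-"),
    _pd("NK", "CD45+", "CD3-", "HLADR-", "CD56+", "CD15-"),
    _pd("cancer", "CD45-", "PanCK+"),
    _pd("cancer_stem", "CD45-", "PanCK-", "CD200-", "Vimentin-", "CD24+", "EpCAM+"),
    _pd("CAF", "CD45-", "PanCK-", "Vimentin+", "CD200-"),
    _pd("mesothelial", "CD45-", "PanCK-", "CD200+", "Vimentin-"),
    _pd("stromal", "CD45-", "PanCK-", "CD200-", "Vimentin-", "CD24-", "EpCAM-"),
)

PHENOTYPE_NAMES: tuple[str, ...] = tuple(p.name for p in DEFAULT_PHENOTYPES)

#: Phenotype enriched in the good (subtype-I) immune microenvironment; used
#: to orient subtype labels after unsupervised clustering.
EXHAUSTED_CD8 = "partially_exhausted_CD8"

#: Activation programs: (phenotype -> markers) whose means rise in that
#: phenotype's cells in subtype-I samples (stimulatory axis: activated pDC,
#: armed exhausted CD8 T cells) or subtype-II samples (inhibitory axis:
#: ICOS-high Tregs, PD-L1-high macrophages, naive CXCR4+ CD8 T cells).
SUBTYPE_I_ACTIVATION_PROGRAM: dict[str, tuple[str, ...]] = {
    "pDC": ("CD40", "CD86"),
    "partially_exhausted_CD8": ("GranzymeB", "CD27", "CD28"),
}
SUBTYPE_II_ACTIVATION_PROGRAM: dict[str, tuple[str, ...]] = {
    "Treg": ("ICOS",),
    "TAM": ("PDL1",),
    "CD8_T": ("CXCR4", "TIM3", "LAG3"),
}

#: Phenotypes whose mixture weight tilts up (+1) in subtype I or subtype II
#: (-1); 0 elsewhere.  Encodes the direction of the reported compositional
#: differences (exhausted CD8 / pDC / HLA-DR+ cancer cells up in I; Treg,
#: neutrophil, cDC, CAF, TAM up in II).
SUBTYPE_TILT: dict[str, int] = {
    "partially_exhausted_CD8": +1,
    "pDC": +1,
    "cancer": +1,
    "Treg": -1,
    "neutrophil": -1,
    "cDC": -1,
    "CAF": -1,
    "TAM": -1,
}


def validate_phenotypes(
    defs: Sequence[PhenotypeDefinition], markers: Sequence[str]
) -> None:
    """Check gates reference only panel markers and names are unique."""
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("phenotype names must be unique")
    marker_set = set(markers)
    for d in defs:
        unknown = [m for m, _ in d.gate if m not in marker_set]
        if unknown:
            raise ValueError(f"phenotype {d.name!r} gates unknown markers {unknown}")
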