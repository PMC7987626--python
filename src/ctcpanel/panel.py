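"""Gene panel definition: target genes, reference gene, marker classes."""

from __future__ import annotations

from dataclasses import dataclass, field


EPITHELIAL = "epithelial"
MESENCHYMAL = "mesenchymal"
STEM = "stem"
OTHER = "other"

MARKER_CLASSES = (EPITHELIAL, MESENCHYMAL, STEM, OTHER)

_DEFAULT_CLASS_MAP = {
    "CDH1": EPITHELIAL,
    "EPCAM": EPITHELIAL,
    "KRT19": EPITHELIAL,
    "SNAI1": MESENCHYMAL,
    "VIM": MESENCHYMAL,
    "ZEB1": MESENCHYMAL,
    "ALDH1A1": STEM,
    "PROM1": STEM,
    "CCND1": OTHER,
    "CDK4": OTHER,
    "E2F4": OTHER,
    "RB1": OTHER,
    "KLK3": OTHER,
    "BCL2": OTHER,
    "MYC": OTHER,
    "MYCL": OTHER,
    "CTNNB1": OTHER,
    "GDF15": OTHER,
}


@dataclass(frozen=True)
class GenePanel:
    """A targeted qPCR panel.

    Parameters
    ----------
    genes:
        Target gene symbols (reference gene excluded).
    reference_gene:
        Housekeeping gene used for ddCt normalisation (default ``B2M``).
    class_map:
        Maps each target gene to one of ``epithelial``, ``mesenchymal``,
        ``stem`` or ``other``. Classes are disjoint by construction.
    """

    genes: tuple[str, ...] = tuple(_DEFAULT_CLASS_MAP)
    reference_gene: str = "B2M"
    class_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_CLASS_MAP))

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.reference_gene in self.genes:
            raise ValueError(
                f"reference gene {self.reference_gene!r} must not be a target gene"
            )
        if self.reference_gene in self.class_map:
            raise ValueError("reference gene carries no phenotype class")
        unknown = set(self.class_map) - set(self.genes)
        if unknown:
            raise ValueError(f"class_map genes not in panel: {sorted(unknown)}")
        bad = {g: c for g, c in self.class_map.items() if c not in MARKER_CLASSES}
        if bad:
            raise ValueError(f"unknown marker classes: {bad}")

    @property
    def all_genes(self) -> tuple[str, ...]:
        """Targets plus the reference gene (load-time vocabulary)."""
        return self.genes + (self.reference_gene,)

    def genes_of_class(self, marker_class: str) -> tuple[str, ...]:
        if marker_class not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class {marker_class!r}")
        return tuple(g for g in self.genes if self.class_map.get(g) == marker_class)

    @property
    def epithelial_genes(self) -> tuple[str, ...]:
        return self.genes_of_class(EPITHELIAL)

    @property
    def mesenchymal_genes(self) -> tuple[str, ...]:
        return self.genes_of_class(MESENCHYMAL)

    @property
    def stem_genes(self) -> tuple[str, ...]:
        return self.genes_of_class(STEM)

    @property
    def phenotype_genes(self) -> tuple[str, ...]:
        """The genes driving CTC-positivity calls (E + M + S markers)."""
        return (
            self.epithelial_genes + self.mesenchymal_genes + self.stem_genes
        )


#: Default 18-target panel with B2M reference. Epithelial: CDH1/EPCAM/KRT19;
#: mesenchymal: SNAI1/VIM/ZEB1; stem: ALDH1A1/PROM1; the remainder are cell
#: cycle, prostate and oncogenic markers.
DEFAULT_PANEL = GenePanel()
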