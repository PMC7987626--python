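"""CTC positivity, EMT/stem phenotype classes, signatures and prognostic groups.

A sample is CTC-positive when at least one epithelial (CDH1, EPCAM,
KRT19), one mesenchymal (SNAI1, VIM, ZEB1) or one stem (ALDH1A1, PROM1)
marker shows fold change >= tau (default 1.5) over the autologous PBMC
fraction. Samples expressing both epithelial and mesenchymal markers
carry the hybrid phenotype; the stricter epithelial+mesenchymal+stem
combination is tracked separately for survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ctcpanel.errors import EvaluationError, RangeError
from ctcpanel.panel import GenePanel, DEFAULT_PANEL
from ctcpanel.qpcr import DETECTED, PBMC_AT_LOD, UNDETECTED_IN_CTC

TAU_DEFAULT = 1.5


def tau_from_ddct_cycles(cycles: float) -> float:
    """Fold-change threshold equivalent to a ddCt threshold in cycles.

    The high-expression rule operates on fold change (FC >= 1.5 by
    default). Some groups state the threshold on the ddCt cycle scale
    instead; ``tau=tau_from_ddct_cycles(1.5)`` (= 2**1.5 ~ 2.83-fold)
    selects that interpretation for any function taking ``tau``.
    """
    return float(2.0**cycles)

# phenotype labels
NEGATIVE = "NEGATIVE"
EPITHELIAL_ONLY = "EPITHELIAL_ONLY"
MESENCHYMAL_ONLY = "MESENCHYMAL_ONLY"
HYBRID_EM = "HYBRID_EM"
STEM_ONLY = "STEM_ONLY"

# prognosis groups by CellSearch count
FAVORABLE = "FAVORABLE"
UNFAVORABLE = "UNFAVORABLE"
UNKNOWN = "UNKNOWN"

HIGH = "HIGH"
LOW = "LOW"


@dataclass(frozen=True)
class MarkerClassCall:
    """Per-sample marker-class positivity (which classes have a high gene)."""

    patient_id: str
    visit: str
    high_genes: frozenset[str]
    epithelial_pos: bool
    mesenchymal_pos: bool
    stem_pos: bool


@dataclass(frozen=True)
class PhenotypeCall:
    """CTC positivity plus the epithelial/mesenchymal axis class."""

    patient_id: str
    visit: str
    ctc_positive: bool
    phenotype: str
    hybrid_ems: bool
    high_genes: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class SignatureRule:
    """Ordered conjunction of (gene, HIGH|LOW) terms, e.g. the
    MYCL-high / SNAI1-high / KRT19-low overall-survival signature."""

    terms: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.terms]
        if len(set(genes)) != len(genes):
            raise ValueError("signature genes must be unique")
        for _, direction in self.terms:
            if direction not in (HIGH, LOW):
                raise ValueError(f"direction must be HIGH or LOW, got {direction!r}")


#: Composite signature associated with overall survival.
MYCL_SNAI1_KRT19_SIGNATURE = SignatureRule(
    terms=(("MYCL", HIGH), ("SNAI1", HIGH), ("KRT19", LOW))
)


def _is_high(row, tau: float) -> bool:
    return row.status in (DETECTED, PBMC_AT_LOD) and row.fold_change >= tau


def call_marker_classes(
    sample_rels: pd.DataFrame,
    panel: GenePanel = DEFAULT_PANEL,
    tau: float = TAU_DEFAULT,
) -> MarkerClassCall:
    """Call epithelial / mesenchymal / stem positivity for one sample.

    ``sample_rels`` holds the relative-expression rows of a single
    (patient, visit). A gene is high when its fold change is >= ``tau``
    with a quantifiable status; missing phenotype genes count as
    not-high.
    """
    samples = sample_rels[["patient_id", "visit"]].drop_duplicates()
    if len(samples) != 1:
        raise ValueError("call_marker_classes expects rows of exactly one sample")
    pid, visit = samples.iloc[0]
    high = frozenset(
        row.gene for row in sample_rels.itertuples(index=False) if _is_high(row, tau)
    )
    return MarkerClassCall(
        patient_id=pid,
        visit=visit,
        high_genes=high,
        epithelial_pos=bool(high & set(panel.epithelial_genes)),
        mesenchymal_pos=bool(high & set(panel.mesenchymal_genes)),
        stem_pos=bool(high & set(panel.stem_genes)),
    )


def call_phenotype(
    mc: MarkerClassCall, stem_extends_phenotype: bool = False
) -> PhenotypeCall:
    """Derive the phenotype class and positivity from marker-class calls.

    Epithelial and mesenchymal positivity define the axis: both ->
    ``HYBRID_EM``, one -> the exclusive class, neither -> ``NEGATIVE``.
    A stem-only sample is CTC-positive but keeps phenotype ``NEGATIVE``
    on the E/M axis; with ``stem_extends_phenotype`` it is reported as
    ``STEM_ONLY`` instead.
    """
    e, m, s = mc.epithelial_pos, mc.mesenchymal_pos, mc.stem_pos
    if e and m:
        phenotype = HYBRID_EM
    elif e:
        phenotype = EPITHELIAL_ONLY
    elif m:
        phenotype = MESENCHYMAL_ONLY
    elif s and stem_extends_phenotype:
        phenotype = STEM_ONLY
    else:
        phenotype = NEGATIVE
    ctc_positive = e or m or s
    return PhenotypeCall(
        patient_id=mc.patient_id,
        visit=mc.visit,
        ctc_positive=ctc_positive,
        phenotype=phenotype,
        hybrid_ems=e and m and s,
        high_genes=mc.high_genes,
    )


def call_all_phenotypes(
    rels: pd.DataFrame,
    panel: GenePanel = DEFAULT_PANEL,
    tau: float = TAU_DEFAULT,
) -> pd.DataFrame:
    """Phenotype-call table for every (patient, visit) sample in ``rels``."""
    rows = []
    for (_, _), sample in rels.groupby(["patient_id", "visit"], sort=True):
        pc = call_phenotype(call_marker_classes(sample, panel, tau))
        rows.append(
            {
                "patient_id": pc.patient_id,
                "visit": pc.visit,
                "ctc_positive": pc.ctc_positive,
                "phenotype": pc.phenotype,
                "hybrid_ems": pc.hybrid_ems,
                "high_genes": ";".join(sorted(pc.high_genes)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "visit", "ctc_positive", "phenotype", "hybrid_ems", "high_genes"],
    )


def evaluate_signature(
    sample_rels: pd.DataFrame,
    rule: SignatureRule,
    tau: float = TAU_DEFAULT,
) -> bool:
    """True iff the sample satisfies every term of the signature.

    HIGH terms need FC >= tau; LOW terms need FC < tau or non-detection
    in the CTC fraction (non-detection counts as negative expression).
    An empty rule is vacuously true.
    """
    by_gene = {row.gene: row for row in sample_rels.itertuples(index=False)}
    for gene, direction in rule.terms:
        if gene not in by_gene:
            raise EvaluationError(f"signature gene {gene!r} absent from sample data")
        row = by_gene[gene]
        high = _is_high(row, tau)
        if direction == HIGH and not high:
            return False
        if direction == LOW:
            low = row.status == UNDETECTED_IN_CTC or (
                row.status in (DETECTED, PBMC_AT_LOD) and row.fold_change < tau
            )
            if not low:
                return False
    return True


def prognosis_group(ctc_count, cutoff: int = 5) -> str:
    """CellSearch dichotomy: < cutoff CTCs/7.5 mL is FAVORABLE, >= cutoff
    UNFAVORABLE; missing counts give UNKNOWN."""
    if ctc_count is None or (isinstance(ctc_count, float) and np.isnan(ctc_count)):
        return UNKNOWN
    count = float(ctc_count)
    if count < 0:
        raise RangeError(f"CTC count must be >= 0, got {ctc_count}")
    return UNFAVORABLE if count >= cutoff else FAVORABLE


def dichotomize_expression(
    rels: pd.DataFrame, gene: str, tau: float = TAU_DEFAULT
) -> pd.Series:
    """HIGH/LOW label per sample for one gene.

    HIGH iff the gene is quantifiable with FC >= tau; everything else —
    FC below tau or non-detection in the CTC fraction — is LOW. Samples
    without any row for the gene (or with an invalid reference) get a
    missing label. Indexed by (patient_id, visit).
    """
    sub = rels[rels["gene"] == gene]
    idx = pd.MultiIndex.from_frame(sub[["patient_id", "visit"]])
    labels = []
    for row in sub.itertuples(index=False):
        if row.status in (DETECTED, PBMC_AT_LOD):
            labels.append(HIGH if row.fold_change >= tau else LOW)
        elif row.status == UNDETECTED_IN_CTC:
            labels.append(LOW)
        else:
            labels.append(None)
    return pd.Series(labels, index=idx, name=gene, dtype=object)
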