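"""Paired-fraction ddCt quantification of targeted qPCR panels.

Raw Ct tables hold one measurement per (patient, visit, fraction, gene).
For every target gene the Ct is first normalised to the reference gene
within its fraction (dCt), then the CTC-enriched fraction is relativised
to the autologous PBMC fraction (ddCt = dCt_CTC - dCt_PBMC), and the
fold change FC = 2**(-ddCt) expresses enrichment of the transcript in
the CTC fraction over the patient's own leukocyte background.

Fold changes are additionally mapped to the ordinal codes used for
heatmap display: undetected -> 0, FC < 1.5 -> -1, then 1 / 2 / 3 / 4 for
FC in (1.5, 5], (5, 20], (20, 100] and > 100.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from ctcpanel.errors import FormatError, IntegrityError, PairingError, RangeError
from ctcpanel.panel import GenePanel, DEFAULT_PANEL

# fraction labels
CTC_ENRICHED = "CTC_ENRICHED"
PBMC = "PBMC"
FRACTIONS = (CTC_ENRICHED, PBMC)

VISITS = ("V1", "V2", "V3")

# relative-expression status values
DETECTED = "DETECTED"
UNDETECTED_IN_CTC = "UNDETECTED_IN_CTC"
PBMC_AT_LOD = "PBMC_AT_LOD"
INVALID_REFERENCE = "INVALID_REFERENCE"

#: fold-change bin edges of the ordinal codification
CODE_BIN_EDGES = (1.5, 5.0, 20.0, 100.0)

#: Ct values above this are treated as non-detections on load
CT_CEILING = 45.0

_UNDETECTED_SENTINELS = {"", "NA", "N/A", "NAN", "UNDETERMINED", "UNDETECTED", "UD"}

CT_COLUMNS = ["patient_id", "visit", "fraction", "gene", "ct"]
REL_COLUMNS = [
    "patient_id",
    "visit",
    "gene",
    "dct_ctc",
    "dct_pbmc",
    "ddct",
    "fold_change",
    "status",
]


def _parse_ct(value: object, row_label: str) -> float:
    """Return a Ct in cycles, NaN for a non-detection sentinel."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    text = str(value).strip()
    if text.upper() in _UNDETECTED_SENTINELS:
        return np.nan
    try:
        ct = float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable Ct {value!r} at {row_label}") from exc
    if ct > CT_CEILING:
        return np.nan
    if not 0.0 < ct <= CT_CEILING:
        raise RangeError(f"Ct {ct} out of (0, {CT_CEILING}] at {row_label}")
    return ct


def load_ct_table(path, panel: GenePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Load and validate a long-format Ct table.

    The CSV must have columns ``patient_id,visit,fraction,gene,ct``;
    empty / ``NA`` / ``Undetermined`` Ct entries denote non-detection
    and Ct values above 45 cycles are likewise treated as undetected.

    Returns a DataFrame with one validated row per measurement, ``ct``
    as float with NaN marking non-detection.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"ct table is missing columns {missing}")
    df = raw[CT_COLUMNS].copy()
    return validate_ct_table(df, panel)


def validate_ct_table(df: pd.DataFrame, panel: GenePanel = DEFAULT_PANEL) -> pd.DataFrame:
    """Validate an in-memory Ct table (same contract as :func:`load_ct_table`)."""
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ct table is missing columns {missing}")
    df = df[CT_COLUMNS].copy()
    known = set(panel.all_genes)
    bad_genes = sorted(set(df["gene"]) - known)
    if bad_genes:
        raise FormatError(f"genes not in panel: {bad_genes}")
    bad_frac = sorted(set(df["fraction"]) - set(FRACTIONS))
    if bad_frac:
        raise FormatError(f"unknown fractions {bad_frac}; expected {list(FRACTIONS)}")
    bad_visit = sorted(set(df["visit"]) - set(VISITS))
    if bad_visit:
        raise FormatError(f"unknown visits {bad_visit}; expected {list(VISITS)}")

    cts = []
    for row in df.itertuples(index=True):
        label = f"row {row.Index} ({row.patient_id},{row.visit},{row.fraction},{row.gene})"
        cts.append(_parse_ct(row.ct, label))
    df["ct"] = cts

    key = ["patient_id", "visit", "fraction", "gene"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise IntegrityError(f"duplicate measurement key {tuple(first)}")
    return df.reset_index(drop=True)


def compute_relative_expression(
    measurements: pd.DataFrame,
    panel: GenePanel = DEFAULT_PANEL,
    lod_ct: float = 40.0,
) -> pd.DataFrame:
    """Compute per-sample ddCt fold changes against autologous PBMCs.

    For each (patient, visit) and each target gene ``g``::

        dCt_f  = Ct(g, f) - Ct(reference, f)      for fraction f
        ddCt   = dCt_CTC - dCt_PBMC
        FC     = 2 ** (-ddCt)

    Status rules:

    * gene undetected in the CTC fraction -> ``UNDETECTED_IN_CTC`` (no FC);
    * gene detected in CTC but undetected in PBMC -> PBMC Ct is
      substituted at the limit of detection ``lod_ct`` and the row is
      flagged ``PBMC_AT_LOD`` (FC finite, typically large);
    * reference gene undetected in either fraction -> every gene of the
      sample is ``INVALID_REFERENCE`` (nothing is quantifiable);
    * otherwise ``DETECTED``.

    Raises :class:`PairingError` if a sample lacks one fraction entirely.
    """
    df = measurements
    records: list[dict] = []
    gaps: list[tuple] = []
    for (pid, visit), sample in df.groupby(["patient_id", "visit"], sort=True):
        fracs = {f: g.set_index("gene")["ct"] for f, g in sample.groupby("fraction")}
        if CTC_ENRICHED not in fracs or PBMC not in fracs:
            present = sorted(fracs)
            raise PairingError(
                f"sample ({pid}, {visit}) has only fraction(s) {present}; "
                "both CTC_ENRICHED and PBMC are required"
            )
        ctc, pbmc = fracs[CTC_ENRICHED], fracs[PBMC]
        ref = panel.reference_gene
        ref_ctc = ctc.get(ref, np.nan)
        ref_pbmc = pbmc.get(ref, np.nan)
        ref_ok = np.isfinite(ref_ctc) and np.isfinite(ref_pbmc)
        for gene in panel.genes:
            if gene not in ctc.index:
                if gene in pbmc.index:
                    gaps.append((pid, visit, gene))
                continue
            rec = {"patient_id": pid, "visit": visit, "gene": gene,
                   "dct_ctc": np.nan, "dct_pbmc": np.nan,
                   "ddct": np.nan, "fold_change": np.nan}
            if not ref_ok:
                rec["status"] = INVALID_REFERENCE
                records.append(rec)
                continue
            ct_ctc = ctc[gene]
            if not np.isfinite(ct_ctc):
                rec["status"] = UNDETECTED_IN_CTC
                records.append(rec)
                continue
            ct_pbmc = pbmc.get(gene, np.nan)
            if np.isfinite(ct_pbmc):
                status = DETECTED
            else:
                ct_pbmc = lod_ct
                status = PBMC_AT_LOD
            dct_ctc = ct_ctc - ref_ctc
            dct_pbmc = ct_pbmc - ref_pbmc
            ddct = dct_ctc - dct_pbmc
            rec.update(
                dct_ctc=dct_ctc,
                dct_pbmc=dct_pbmc,
                ddct=ddct,
                fold_change=2.0 ** (-ddct),
                status=status,
            )
            records.append(rec)
    if gaps:
        warnings.warn(f"{len(gaps)} gene(s) measured only in PBMC fraction; skipped: "
                      f"{gaps[:5]}{'...' if len(gaps) > 5 else ''}")
    return pd.DataFrame.from_records(records, columns=REL_COLUMNS)


def codify(fold_change: float, status: str = DETECTED) -> int:
    """Map one relative-expression value to its ordinal display code.

    ``UNDETECTED_IN_CTC`` -> 0; FC < 1.5 -> -1; 1.5 <= FC <= 5 -> 1;
    5 < FC <= 20 -> 2; 20 < FC <= 100 -> 3; FC > 100 -> 4.
    """
    if status == INVALID_REFERENCE:
        raise ValueError("sample with invalid reference gene is not codifiable")
    if status == UNDETECTED_IN_CTC:
        return 0
    if status not in (DETECTED, PBMC_AT_LOD):
        raise ValueError(f"unknown status {status!r}")
    fc = float(fold_change)
    if not np.isfinite(fc) or fc <= 0:
        raise ValueError(f"fold change must be finite positive, got {fc}")
    lo, b1, b2, b3 = CODE_BIN_EDGES
    if fc < lo:
        return -1
    if fc <= b1:
        return 1
    if fc <= b2:
        return 2
    if fc <= b3:
        return 3
    return 4


def codify_table(rels: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`codify` over a relative-expression table.

    ``INVALID_REFERENCE`` rows yield missing codes (pandas NA).
    """
    codes = pd.array([np.nan] * len(rels), dtype="Int64")
    for i, (fc, status) in enumerate(zip(rels["fold_change"], rels["status"])):
        if status == INVALID_REFERENCE:
            continue
        codes[i] = codify(fc, status)
    return pd.Series(codes, index=rels.index, name="code")


def codify_matrix(
    rels: pd.DataFrame, panel: GenePanel = DEFAULT_PANEL
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the samples x genes ordinal code matrix plus a status mask.

    Rows are (patient, visit) samples; columns follow panel order. Cells
    never measured are missing (code NA, status ``MISSING``).
    """
    rels = rels.assign(code=codify_table(rels))
    idx = pd.MultiIndex.from_frame(
        rels[["patient_id", "visit"]].drop_duplicates().reset_index(drop=True)
    )
    codes = pd.DataFrame(
        pd.NA, index=idx, columns=list(panel.genes), dtype="Int64"
    )
    mask = pd.DataFrame("MISSING", index=idx, columns=list(panel.genes), dtype=object)
    for row in rels.itertuples(index=False):
        codes.at[(row.patient_id, row.visit), row.gene] = (
            row.code if row.code is not pd.NA else pd.NA
        )
        mask.at[(row.patient_id, row.visit), row.gene] = row.status
    return codes, mask


def write_relative_expression(rels: pd.DataFrame, path) -> None:
    """Write the relative-expression table (with codes) to CSV.

    Floats are serialised with full repr precision so a re-load
    reproduces the table bit-for-bit.
    """
    out = rels.assign(code=codify_table(rels))
    out.to_csv(path, index=False)


def read_relative_expression(path) -> pd.DataFrame:
    """Re-load a table written by :func:`write_relative_expression`."""
    df = pd.read_csv(path, dtype={"patient_id": str, "visit": str, "gene": str})
    df["code"] = df["code"].astype("Int64")
    return df
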