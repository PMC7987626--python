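"""Per-visit cohort orchestration: enumeration summaries, association
tables against the CellSearch count dichotomy, marker frequencies,
survival comparisons and heatmap-matrix export."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ctcpanel.errors import DegenerateDataError, FormatError
from ctcpanel.panel import GenePanel, DEFAULT_PANEL
from ctcpanel.phenotype import (
    FAVORABLE,
    HIGH,
    LOW,
    TAU_DEFAULT,
    UNFAVORABLE,
    SignatureRule,
    call_all_phenotypes,
    dichotomize_expression,
    evaluate_signature,
    prognosis_group,
)
from ctcpanel.stats import (
    ContingencyTable2x2,
    KMCurve,
    TestResult,
    fisher_exact_2x2,
    km_estimate,
    km_median_survival,
    logrank_test,
    median_split,
    truncate_p,
    wilcoxon_signed_rank,
)

CLINICAL_COLUMNS = [
    "patient_id", "age", "gleason", "castration_surgery", "prior_hormone_lines",
    "visceral_metastasis", "ldh", "alkp", "psa",
    "pfs_days", "pfs_event", "os_days", "os_event",
]

#: Table-1 style categories: label, (first-level name, second-level name),
#: and how the first level is defined. Continuous labs are dichotomized by
#: the cohort median over non-missing values (low = at or below).
AGE_CUTOFF = 75
GLEASON_CUTOFF = 7
PRIOR_LINES_CUTOFF = 2
CATEGORY_ORDER = ("age", "gleason", "castration", "prior_hormone",
                  "visceral", "ldh", "alkp", "psa")


def load_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table is missing columns {missing}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("castration_surgery", "visceral_metastasis", "pfs_event", "os_event"):
        df[col] = df[col].astype(bool)
    bad = df[(df["pfs_days"] > df["os_days"]) & df["pfs_days"].notna() & df["os_days"].notna()]
    if len(bad):
        raise FormatError(f"pfs_days exceeds os_days for {bad['patient_id'].tolist()}")
    return df


def load_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "visit", "ctc_count") if c not in df.columns]
    if missing:
        raise FormatError(f"counts table is missing columns {missing}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    if (df["ctc_count"].dropna() < 0).any():
        raise FormatError("ctc_count must be >= 0")
    return df


# ---------------------------------------------------------------------------
# enumeration


@dataclass(frozen=True)
class VisitSummary:
    """Patients per CellSearch category at one visit."""

    visit: str
    n_zero: int
    n_1to4: int
    n_ge5: int

    @property
    def n_total(self) -> int:
        return self.n_zero + self.n_1to4 + self.n_ge5


def enumeration_summary(
    counts: pd.DataFrame, visits: tuple[str, ...] = ("V1", "V2", "V3")
) -> tuple[list[VisitSummary], dict[tuple[str, str], TestResult]]:
    """Per-visit 0 / 1-4 / >=5 CTC categories plus paired Wilcoxon
    signed-rank comparisons (later minus earlier) between consecutive
    visits, restricted to patients measured at both."""
    present = [v for v in visits if v in set(counts["visit"])]
    wide = counts.pivot_table(
        index="patient_id", columns="visit", values="ctc_count", aggfunc="first"
    )
    summaries = []
    for v in present:
        c = wide[v].dropna()
        summaries.append(VisitSummary(
            visit=v,
            n_zero=int((c == 0).sum()),
            n_1to4=int(((c >= 1) & (c <= 4)).sum()),
            n_ge5=int((c >= 5).sum()),
        ))
    tests: dict[tuple[str, str], TestResult] = {}
    for earlier, later in zip(present, present[1:]):
        both = wide[[earlier, later]].dropna()
        if both.empty:
            warnings.warn(f"no patients measured at both {earlier} and {later}; skipped")
            continue
        tests[(earlier, later)] = wilcoxon_signed_rank(both[later] - both[earlier])
    return summaries, tests


# ---------------------------------------------------------------------------
# Table-1 style association testing


def _counts_at_visit(counts: pd.DataFrame, visit: str) -> pd.Series:
    sub = counts[counts["visit"] == visit]
    return sub.set_index("patient_id")["ctc_count"]


def _category_first_level(clinical: pd.DataFrame, category: str) -> tuple[pd.Series, str, str]:
    """Boolean 'is first level' per patient plus the two level names.

    Lab values (ldh/alkp/psa) are median-split over the whole cohort's
    non-missing values; patients missing the lab get a missing level.
    """
    c = clinical.set_index("patient_id")
    if category == "age":
        return c["age"] < AGE_CUTOFF, f"<{AGE_CUTOFF}", f">={AGE_CUTOFF}"
    if category == "gleason":
        return c["gleason"] <= GLEASON_CUTOFF, f"<={GLEASON_CUTOFF}", f">{GLEASON_CUTOFF}"
    if category == "castration":
        return ~c["castration_surgery"], "no_surgery", "surgery"
    if category == "prior_hormone":
        return (c["prior_hormone_lines"] <= PRIOR_LINES_CUTOFF,
                f"<={PRIOR_LINES_CUTOFF}", f">{PRIOR_LINES_CUTOFF}")
    if category == "visceral":
        return ~c["visceral_metastasis"], "no", "yes"
    if category in ("ldh", "alkp", "psa"):
        labels = median_split(c[category])
        lab = pd.Series(labels, index=c.index)
        first = lab.map({"LOW": True, "HIGH": False})
        return first, "low", "high"
    raise KeyError(f"unknown category {category!r}; known: {CATEGORY_ORDER}")


def build_contingency(
    clinical: pd.DataFrame,
    counts: pd.DataFrame,
    category: str,
    visit: str = "V1",
    cutoff: int = 5,
) -> ContingencyTable2x2:
    """Cross-classify a clinical category against the CellSearch count
    dichotomy (< cutoff vs >= cutoff) at one visit.

    Rows are the category levels (first level as printed first),
    columns (favorable, unfavorable). Patients missing either variable
    are excluded from this table only.
    """
    first, _, _ = _category_first_level(clinical, category)
    cts = _counts_at_visit(counts, visit)
    groups = cts.dropna().map(lambda v: prognosis_group(v, cutoff))
    idx = first.dropna().index.intersection(groups.index)
    f, g = first.loc[idx].astype(bool), groups.loc[idx]
    a = int((f & (g == FAVORABLE)).sum())
    b = int((f & (g == UNFAVORABLE)).sum())
    c_ = int((~f & (g == FAVORABLE)).sum())
    d = int((~f & (g == UNFAVORABLE)).sum())
    if (a + b == 0) or (c_ + d == 0):
        warnings.warn(f"category {category!r}: one level is empty (degenerate table)")
    return ContingencyTable2x2(a, b, c_, d)


def association_table(
    clinical: pd.DataFrame,
    counts: pd.DataFrame,
    visit: str = "V1",
    cutoff: int = 5,
    categories: tuple[str, ...] = CATEGORY_ORDER,
) -> pd.DataFrame:
    """Association of each clinical category with the count dichotomy.

    One row per category: level names, the 2x2 counts, the exact
    Fisher p-value and its 2-decimal truncation as reported.
    """
    rows = []
    for cat in categories:
        _, lvl1, lvl2 = _category_first_level(clinical, cat)
        t = build_contingency(clinical, counts, cat, visit, cutoff)
        res = fisher_exact_2x2(t)
        rows.append({
            "category": cat, "level1": lvl1, "level2": lvl2,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.n,
            "p_value": res.p_value, "p_reported": truncate_p(res.p_value),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker frequencies


def marker_frequency_summary(
    rels: pd.DataFrame,
    panel: GenePanel = DEFAULT_PANEL,
    tau: float = TAU_DEFAULT,
) -> dict:
    """Percentage of CTC-positive samples with each gene high, plus the
    epithelial-only / mesenchymal-only / hybrid split among positives
    classifiable on the E/M axis."""
    phen = call_all_phenotypes(rels, panel, tau)
    pos = phen[phen["ctc_positive"]]
    n_pos = len(pos)
    if n_pos == 0:
        return {"n_positive": 0, "gene_pct": {}, "phenotype_pct": {}}
    pos_keys = set(zip(pos["patient_id"], pos["visit"]))
    gene_pct = {}
    for gene in panel.genes:
        labels = dichotomize_expression(rels, gene, tau)
        labels = labels[[k in pos_keys for k in labels.index]]
        gene_pct[gene] = 100.0 * (labels == HIGH).sum() / n_pos
    em = pos[pos["phenotype"] != "NEGATIVE"]
    n_em = len(em)
    phenotype_pct = {
        p: (100.0 * (em["phenotype"] == p).sum() / n_em if n_em else float("nan"))
        for p in ("EPITHELIAL_ONLY", "MESENCHYMAL_ONLY", "HYBRID_EM")
    }
    return {"n_positive": n_pos, "gene_pct": gene_pct, "phenotype_pct": phenotype_pct}


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group survival comparison at one visit."""

    endpoint: str
    group_names: tuple[str, ...]
    group_sizes: dict[str, int]
    curves: dict[str, KMCurve]
    medians: dict[str, float]
    logrank: TestResult | None
    flags: tuple[str, ...] = ()


def marker_groups(
    rels: pd.DataFrame,
    counts: pd.DataFrame,
    visit: str,
    grouping,
    panel: GenePanel = DEFAULT_PANEL,
    tau: float = TAU_DEFAULT,
) -> pd.Series:
    """Patient -> group label at one visit.

    ``grouping`` is ``("gene", symbol)``, ``("phenotype", "hybrid_ems")``,
    ``("signature", SignatureRule)`` or ``("prognosis",)``.
    """
    kind = grouping[0]
    if kind == "gene":
        labels = dichotomize_expression(rels[rels["visit"] == visit], grouping[1], tau)
        return labels.droplevel("visit") if labels.index.nlevels > 1 else labels
    if kind == "phenotype":
        phen = call_all_phenotypes(rels[rels["visit"] == visit], panel, tau)
        return pd.Series(
            np.where(phen["hybrid_ems"], "HYBRID_EMS", "OTHER"),
            index=phen["patient_id"],
        )
    if kind == "signature":
        rule: SignatureRule = grouping[1]
        out = {}
        for pid, sample in rels[rels["visit"] == visit].groupby("patient_id"):
            out[pid] = "SIGNATURE" if evaluate_signature(sample, rule, tau) else "REST"
        return pd.Series(out)
    if kind == "prognosis":
        cts = _counts_at_visit(counts, visit).dropna()
        return cts.map(prognosis_group)
    raise KeyError(f"unknown grouping kind {kind!r}")


def survival_by_marker(
    clinical: pd.DataFrame,
    groups: pd.Series,
    endpoint: str = "PFS",
) -> SurvivalComparison:
    """Kaplan-Meier curves, median survival and the log-rank test for a
    two-level patient grouping.

    ``groups`` maps patient_id to a label (missing labels excluded).
    With a single represented group the test is skipped (curves are
    still returned)."""
    endpoint = endpoint.upper()
    if endpoint not in ("PFS", "OS"):
        raise KeyError("endpoint must be PFS or OS")
    tcol, ecol = (("pfs_days", "pfs_event") if endpoint == "PFS" else ("os_days", "os_event"))
    clin = clinical.set_index("patient_id")
    groups = groups.dropna()
    idx = clin.index.intersection(groups.index)
    sub = clin.loc[idx]
    g = groups.loc[idx]
    names = tuple(sorted(map(str, pd.unique(g))))
    flags: list[str] = []
    curves, medians, sizes = {}, {}, {}
    for name in names:
        m = (g == name).to_numpy(dtype=bool)
        sizes[name] = int(m.sum())
        curve = km_estimate(sub.loc[m, tcol], sub.loc[m, ecol])
        curves[name] = curve
        medians[name] = km_median_survival(curve)
    lr = None
    if len(names) == 2:
        events = sub[ecol].to_numpy(dtype=bool)
        if events.sum() == 0:
            flags.append("no_events")
        else:
            lr = logrank_test(g.to_numpy(), sub[tcol].to_numpy(float), events)
    else:
        flags.append("single_group")
    if flags:
        warnings.warn(f"survival comparison flags: {flags}")
    return SurvivalComparison(
        endpoint=endpoint, group_names=names, group_sizes=sizes,
        curves=curves, medians=medians, logrank=lr, flags=tuple(flags),
    )


def plot_survival(comparison: SurvivalComparison, path) -> None:
    """Write a Kaplan-Meier step plot of a two-group comparison."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name in comparison.group_names:
        curve = comparison.curves[name]
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival_prob])
        ax.step(t, s, where="post",
                label=f"{name} (n={comparison.group_sizes[name]})")
    title = comparison.endpoint
    if comparison.logrank is not None:
        title += f" — log-rank p = {comparison.logrank.p_value:.3g}"
    ax.set_title(title)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# heatmap export


def export_heatmap_matrix(
    codes: pd.DataFrame,
    annotations: pd.Series | None = None,
    cluster: bool = True,
) -> dict:
    """Order the ordinal code matrix for heatmap display.

    Agglomerative clustering (Euclidean distance, complete linkage,
    deterministic given input order) of rows and columns; missing codes
    are treated as 0 (no expression) for distances only. Returns the
    re-ordered matrix plus row/column orders and the aligned annotation
    row (CellSearch prognosis group per sample).
    """
    filled = codes.astype(float).fillna(0.0)
    row_order = list(range(len(codes)))
    col_order = list(range(codes.shape[1]))
    if cluster and len(codes) > 1:
        from scipy.cluster.hierarchy import complete, leaves_list
        from scipy.spatial.distance import pdist

        if np.unique(filled.to_numpy()).size > 1:
            rd = pdist(filled.to_numpy())
            if rd.max() > 0:
                row_order = [int(i) for i in leaves_list(complete(rd))]
            cd = pdist(filled.to_numpy().T)
            if codes.shape[1] > 1 and cd.max() > 0:
                col_order = [int(i) for i in leaves_list(complete(cd))]
    ordered = codes.iloc[row_order, col_order]
    ann = None
    if annotations is not None:
        ann = annotations.reindex(ordered.index)
    return {
        "matrix": ordered,
        "row_order": [codes.index[i] for i in row_order],
        "col_order": [codes.columns[i] for i in col_order],
        "annotations": ann,
    }
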