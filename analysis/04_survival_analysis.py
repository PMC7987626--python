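#!/usr/bin/env python
"""Per-visit survival comparisons and heatmap-matrix export.

Dichotomizes each marker of interest (HIGH: fold change >= 1.5 over
autologous PBMCs) at each visit and compares progression-free and
overall survival by log-rank; also evaluates the hybrid
epithelial-mesenchymal-stem phenotype and the composite
MYCL-high/SNAI1-high/KRT19-low signature. Exports the clustered
ordinal heatmap matrix. Writes results/survival_comparisons.csv and
results/heatmap_matrix.csv.
"""

import warnings

import pandas as pd

from ctcpanel.cohort import (
    export_heatmap_matrix,
    load_clinical,
    load_counts,
    marker_groups,
    survival_by_marker,
)
from ctcpanel.phenotype import MYCL_SNAI1_KRT19_SIGNATURE, prognosis_group
from ctcpanel.qpcr import codify_matrix, compute_relative_expression, load_ct_table

GENES = ("KRT19", "EPCAM", "ZEB1", "MYCL", "CTNNB1", "ALDH1A1")


def main() -> None:
    rels = compute_relative_expression(load_ct_table("results/cohort/ct_table.csv"))
    clinical = load_clinical("results/cohort/clinical.csv")
    counts = load_counts("results/cohort/cellsearch_counts.csv")

    groupings = [("gene", g) for g in GENES] + [
        ("phenotype", "hybrid_ems"),
        ("signature", MYCL_SNAI1_KRT19_SIGNATURE),
        ("prognosis",),
    ]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for visit in ("V1", "V2", "V3"):
            for grouping in groupings:
                name = grouping[1] if grouping[0] == "gene" else grouping[0]
                groups = marker_groups(rels, counts, visit, grouping)
                for endpoint in ("PFS", "OS"):
                    try:
                        cmp_ = survival_by_marker(clinical, groups, endpoint)
                    except Exception:
                        continue
                    rows.append({
                        "visit": visit, "grouping": name, "endpoint": endpoint,
                        "groups": "|".join(cmp_.group_names),
                        "sizes": "|".join(str(cmp_.group_sizes[g]) for g in cmp_.group_names),
                        "median_days": "|".join(f"{cmp_.medians[g]:g}" for g in cmp_.group_names),
                        "logrank_p": cmp_.logrank.p_value if cmp_.logrank else float("nan"),
                    })
    out = pd.DataFrame(rows)
    out.to_csv("results/survival_comparisons.csv", index=False)
    sig = out[out["logrank_p"] < 0.05].sort_values("logrank_p")
    print(f"{len(out)} survival comparisons; {len(sig)} with log-rank p < 0.05:")
    if len(sig):
        print(sig.to_string(index=False))

    codes, _ = codify_matrix(rels)
    v1 = counts[counts["visit"] == "V1"].set_index("patient_id")["ctc_count"]
    ann = pd.Series(
        [prognosis_group(v1.get(p, float("nan"))) for p, _ in codes.index],
        index=codes.index,
    )
    hm = export_heatmap_matrix(codes, ann, cluster=True)
    mat = hm["matrix"].copy()
    mat.insert(0, "prognosis_group", hm["annotations"])
    mat.to_csv("results/heatmap_matrix.csv")
    print(f"\nheatmap matrix: {hm['matrix'].shape[0]} samples x {hm['matrix'].shape[1]} genes, clustered")


if __name__ == "__main__":
    main()
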