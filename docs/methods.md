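# Methods

This note documents the models, conventions and numerical choices
behind `ctcpanel`, what the synthetic-cohort generator does and does
not emulate, and the limitations a user should keep in mind.

## Paired-fraction ΔΔCt quantification

CTC enrichment from blood is never pure: the enriched fraction is a
mixture of tumour cells and residual leukocytes. The analysis
therefore normalises twice. Within each fraction, Ct values are
referenced to *B2M* (ΔCt), removing input-amount differences; then the
CTC-enriched fraction is referenced to the patient's own PBMC fraction
(ΔΔCt = ΔCt_CTC − ΔCt_PBMC), so that transcripts shared with
leukocytes cancel and the fold change FC = 2^(−ΔΔCt) isolates
tumour-derived signal. This assumes perfect doubling efficiency for
every assay; no standard-curve or efficiency correction is applied,
and preamplification is assumed uniform across targets.

Conventions, chosen once and applied everywhere:

- **High expression**: FC ≥ 1.5, boundary inclusive. The threshold
  lives on the fold-change scale; `tau_from_ddct_cycles` converts a
  cycle-scale threshold for groups who state it that way
  (1.5 cycles ≡ 2.83-fold).
- **Non-detection in the CTC fraction** is a biological zero, not
  missing data: it codes 0, counts as LOW in dichotomizations, and
  satisfies LOW terms of composite signatures.
- **Detected in CTC, undetected in PBMC**: the PBMC Ct is substituted
  at the limit of detection (default 40 cycles, configurable), keeping
  FC finite and codifiable rather than infinite; such rows are flagged
  `PBMC_AT_LOD`.
- **Reference gene undetected** in either fraction invalidates the
  whole sample (`INVALID_REFERENCE`): nothing is quantifiable.
- Ct values above 45 cycles are treated as non-detections on load
  (standard qPCR practice).
- The ordinal display codes are fixed at non-detection → 0, FC < 1.5
  → −1, 1.5–5 → 1, >5–20 → 2, >20–100 → 3, >100 → 4.

## Phenotype and prognostic calling

Marker classes: epithelial {CDH1, EPCAM, KRT19}, mesenchymal {SNAI1,
VIM, ZEB1}, stem {ALDH1A1, PROM1}. A sample is CTC-positive if any
class has a high gene. The epithelial/mesenchymal axis defines the
phenotype (both → hybrid); because the analysis is bulk, "hybrid"
means the sample expresses both programmes, not that any single cell
does. Two hybrid definitions coexist deliberately: `HYBRID_EM` (E ∧ M)
for frequency analyses, and the stricter `hybrid_ems` (E ∧ M ∧ stem)
for survival grouping. Stem-only samples are CTC-positive with
phenotype `NEGATIVE` on the E/M axis by default (the three-way
phenotype split covers only the E/M axes); a `stem_extends_phenotype`
option labels them `STEM_ONLY` instead.

CellSearch counts dichotomize at <5 (favorable) vs ≥5 (unfavorable)
CTCs per 7.5 mL, the established mCRPC cutoff. Continuous labs (LDH,
ALK-P, PSA) are dichotomized at the cohort median over all non-missing
values — including patients later excluded from a given contingency
table for lacking the other variable — with values equal to the median
going LOW and strictly greater going HIGH (midpoint-of-order-statistics
median). Fixed clinical cutoffs: age 75, Gleason 7, prior hormone
lines 2.

## Statistics

All inference is implemented from first principles; scipy supplies
only distribution tail functions (chi-square, normal).

- **Fisher exact (2×2, two-sided)**: complete enumeration of the
  conditional hypergeometric support with binomial-coefficient weights
  kept as exact integers; the two-sided p sums point probabilities not
  exceeding the observed one, with a 1e−7 relative-tolerance band so
  ties broken by rounding fall inside the tail. A fully zero row or
  column yields p = 1.
- **Reported p-values** are truncated (floored) to two decimals, not
  rounded, with p = 1 reported as 1; this is the convention that
  matches published association tables of this design.
- **Wilcoxon signed-rank**: zero differences discarded; for n ≤ 20 the
  exact two-sided p comes from the full 2ⁿ sign-assignment
  distribution computed by a generating-function expansion on doubled
  mid-ranks (exact with or without tied magnitudes); for larger n, the
  tie-corrected normal approximation without continuity correction.
- **Kaplan–Meier**: product-limit; at tied times events precede
  censorings. Median survival is the first time S(t) ≤ 0.5 (NaN if
  never reached).
- **Log-rank (2 groups)**: observed-minus-expected with hypergeometric
  variance per distinct event time, ties pooled; χ² with 1 df.
- **Cox (univariate)**: Breslow tie handling, Newton iteration with
  step-halving safeguard; |β| running past 15 is declared monotone
  likelihood (perfect separation) and returns an infinite-hazard-ratio
  sentinel with `converged=False`. Wald CI and p. The score test at
  β = 0 equals the log-rank statistic on tie-free binary covariates,
  which is verified numerically in the tests. Cox is provided for
  completeness; the pipeline's survival claims rest on the log-rank.

## Synthetic cohorts

The generator emulates the study design end to end so that every
pipeline stage is testable without patient data. Each patient draws a
latent archetype — epithelial, mesenchymal, hybrid (E+M+stem), stem,
or negative — that switches marker classes on or off. Genes the
archetype expresses carry a per-patient log2 fold change
~ N(class mean, 0.8) (defaults: epithelial/mesenchymal 3.0, stem 2.5,
non-marker targets 1.0); genes it does not express draw
~ N(−1.0, 0.5), mildly depleted because enrichment replaces part of
the leukocyte background with tumour cells lacking the transcript.
The CTC-fraction Ct is the PBMC baseline minus this log2FC plus
N(0, 0.4) technical noise; the PBMC fraction never receives tumour
signal, so the ΔΔCt analysis is the generator's exact inverse up to
noise and label recovery is testable in closed form. Detection fails
mechanically whenever an implied Ct exceeds the limit of detection
(40 cycles); with the default baselines only near-LOD genes such as
KLK3 (PBMC Ct ≈ 38) drop out at an appreciable rate.

CellSearch counts follow a zero-inflated negative binomial whose log
mean rises by log 4 when the epithelial programme is on — mirroring
the EpCAM-based capture chemistry — scaled per visit (×0.3 after one
therapy cycle, ×1.5 at progression). Survival is Weibull (shape 1.3,
PFS scale 220 days) with log hazard Σ β_g·1[gene g truly HIGH] acting
on both progression and the subsequent death increment, plus
independent exponential censoring (mean 900 days). Clinical covariates
are drawn from plausible mCRPC marginals (age N(72, 8²), log-normal
LDH/ALK-P/PSA, Poisson prior hormone lines). Each patient has an
independent sub-stream seeded by (seed, patient index), so enlarging a
cohort never perturbs existing patients.

Three presets fix the study conditions: `paper-like` (20 patients,
3 visits with ~35% V3 drop-out, hybrid-dominated mixture, β_KRT19 =
log 2), `null` (60 patients, one visit, no marker–outcome association)
and `power` (200 patients, one visit, balanced epithelial/negative
mixture, β_KRT19 = log 2.5). `table1_cohort()` is different in kind:
a deterministic 20-patient clinical table constructed so that each
clinical variable reproduces the published 2×2 margins against the
count dichotomy, including one patient whose baseline count is missing
but whose labs still enter the cohort medians — without that patient
the printed ALK-P and PSA splits are arithmetically impossible under
the strictly-greater-than-median rule.

What the generator does **not** emulate: amplification-efficiency
differences between assays, preamplification bias, inter-plate batch
effects, correlated dropout, intra-patient correlation of expression
across visits beyond the shared archetype, and informative censoring.
Passing tests therefore demonstrate that the pipeline's logic and
statistics behave correctly under the assumed data-generating process,
not that the biological claims hold in real cohorts.

## Problem sizes and determinism

Operating characteristics are measured at 200 replicates for the
type-I error of the end-to-end log-rank (binomial 3-SE band around the
nominal 5%) and 100 replicates for power and label recovery under the
`power` preset; replicate seeds derive deterministically from a single
base seed. Hierarchical clustering for the heatmap export uses
Euclidean distance with complete linkage on the ordinal codes (missing
cells as 0 for distances only) and is deterministic given input order;
the published heatmap's exact ordering is not a target, since the
clustering settings behind it are not specified.

## Known limitations

- The exact Fisher enumeration is meant for cohort-scale tables
  (n up to a few hundred); it is not optimised for large counts.
- Wald-based Cox inference is poor near separation; the monotone-
  likelihood sentinel flags this rather than fixing it (no Firth
  correction).
- Survival medians and marker frequencies from the motivating cohort
  cannot be reproduced because patient-level data are not published;
  the property-based synthetic checks stand in for them.
- The composite-signature evaluator treats terms as a conjunction
  only; weighted or scored signatures are out of scope.
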