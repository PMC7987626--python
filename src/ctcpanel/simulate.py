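"""Synthetic liquid-biopsy cohorts for end-to-end pipeline testing.

No patient-level data accompany the study design this package
implements, so the generator produces complete cohorts with the same
statistical structure: paired-fraction Ct tables in which the
CTC-enriched fraction is PBMC background plus a tumour signal injected
on the Ct scale, CellSearch-style counts linked to the epithelial
latent score, clinical covariates, and Weibull survival whose log
hazard depends on configurable marker groups.

Each patient draws from latent *archetypes* (epithelial, mesenchymal,
hybrid, stem, negative) that switch marker classes on or off. Genes a
patient's tumour expresses get a positive log2 fold change over the
PBMC baseline; genes it does not express get a mildly negative one,
because enrichment replaces part of the leukocyte background with
tumour cells lacking the transcript. Tumour signal never enters the
PBMC fraction. Non-detections arise mechanically: any implied Ct above
the limit of detection is censored.

Because the signal is injected by subtracting log2-fold-change cycles,
the ddCt analysis is the generator's exact inverse up to noise, which
makes label recovery testable in closed form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ctcpanel.errors import ConfigError
from ctcpanel.panel import GenePanel, DEFAULT_PANEL, EPITHELIAL, MESENCHYMAL, STEM, OTHER
from ctcpanel.qpcr import CTC_ENRICHED, PBMC, CT_COLUMNS

ARCHETYPES = ("epithelial", "mesenchymal", "hybrid", "stem", "negative")

#: marker classes switched on by each archetype
ARCHETYPE_CLASSES: dict[str, frozenset[str]] = {
    "epithelial": frozenset({EPITHELIAL}),
    "mesenchymal": frozenset({MESENCHYMAL}),
    "hybrid": frozenset({EPITHELIAL, MESENCHYMAL, STEM}),
    "stem": frozenset({STEM}),
    "negative": frozenset(),
}

#: typical PBMC-fraction Ct per gene (cycles); unlisted genes fall back
#: to 28. VIM is abundant in leukocytes, KLK3 nearly absent.
DEFAULT_PBMC_CT_MEAN: dict[str, float] = {
    "CDH1": 31.0, "EPCAM": 32.0, "KRT19": 30.0,
    "SNAI1": 28.0, "VIM": 22.0, "ZEB1": 29.0,
    "ALDH1A1": 30.0, "PROM1": 33.0,
    "CCND1": 26.0, "CDK4": 26.5, "E2F4": 27.0, "RB1": 26.0,
    "KLK3": 38.0, "BCL2": 25.0, "MYC": 24.5, "MYCL": 29.0,
    "CTNNB1": 24.0, "GDF15": 30.0,
}


@dataclass
class SimulationConfig:
    """Full generative model for one synthetic cohort.

    Expression scale: a gene a patient's archetype expresses draws a
    per-patient log2 fold change ~ N(class mean, ``expressed_lfc_sd``);
    an unexpressed gene draws ~ N(``off_lfc_mean``, ``off_lfc_sd``).
    Every individual Ct also carries N(0, ``ct_noise_sd``) technical
    noise. Counts: zero-inflated negative binomial whose log mean
    rises by ``count_epithelial_coef`` when the epithelial class is on
    and is scaled per visit (therapy effect < 1 at V2, relapse > 1 at
    V3). Survival: Weibull baseline with log hazard
    ``sum(beta_g * 1[gene g truly HIGH])`` and independent exponential
    censoring.
    """

    n_patients: int = 20
    visits: tuple[str, ...] = ("V1", "V2", "V3")
    v3_dropout: float = 0.35
    seed: int = 0
    panel: GenePanel = field(default_factory=lambda: DEFAULT_PANEL)

    # qPCR model (cycles)
    pbmc_ct_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PBMC_CT_MEAN)
    )
    pbmc_ct_default: float = 28.0
    pbmc_ct_sd: float = 0.4
    ref_ct_mean: float = 18.0
    ref_ct_sd: float = 0.3
    ct_noise_sd: float = 0.4
    lod_ct: float = 40.0

    # tumour-signal model (log2 fold change over PBMC baseline)
    archetype_weights: dict[str, float] = field(
        default_factory=lambda: {
            "epithelial": 0.15, "mesenchymal": 0.08, "hybrid": 0.55,
            "stem": 0.07, "negative": 0.15,
        }
    )
    class_lfc_mean: dict[str, float] = field(
        default_factory=lambda: {EPITHELIAL: 3.0, MESENCHYMAL: 3.0, STEM: 2.5}
    )
    other_lfc_mean: float = 1.0
    expressed_lfc_sd: float = 0.8
    off_lfc_mean: float = -1.0
    off_lfc_sd: float = 0.5

    # CellSearch count model (counts per 7.5 mL)
    count_log_mean: float = float(np.log(3.0))
    count_epithelial_coef: float = float(np.log(4.0))
    count_dispersion: float = 1.5
    count_zero_inflation: float = 0.15
    count_visit_factors: dict[str, float] = field(
        default_factory=lambda: {"V1": 1.0, "V2": 0.3, "V3": 1.5}
    )

    # survival model (days)
    weibull_shape: float = 1.3
    weibull_scale_pfs: float = 220.0
    weibull_scale_os_extra: float = 300.0
    survival_betas: dict[str, float] = field(default_factory=dict)
    censoring_mean: float = 900.0

    # clinical covariates
    age_mean: float = 72.0
    age_sd: float = 8.0
    visceral_prob: float = 0.3
    surgery_prob: float = 0.2
    prior_lines_mean: float = 1.5

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if not self.visits:
            problems.append("visits must be non-empty")
        if not 0.0 <= self.v3_dropout < 1.0:
            problems.append("v3_dropout must be in [0, 1)")
        for name in ("pbmc_ct_sd", "ref_ct_sd", "ct_noise_sd",
                     "expressed_lfc_sd", "off_lfc_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        unknown = set(self.archetype_weights) - set(ARCHETYPES)
        if unknown:
            problems.append(f"unknown archetypes {sorted(unknown)}")
        wsum = sum(self.archetype_weights.values())
        if abs(wsum - 1.0) > 1e-9:
            problems.append(f"archetype weights sum to {wsum}, expected 1")
        if any(w < 0 for w in self.archetype_weights.values()):
            problems.append("archetype weights must be >= 0")
        if self.weibull_shape <= 0 or self.weibull_scale_pfs <= 0:
            problems.append("Weibull shape and scale must be > 0")
        if not 0.0 <= self.count_zero_inflation < 1.0:
            problems.append("count_zero_inflation must be in [0, 1)")
        bad_genes = set(self.survival_betas) - set(self.panel.genes)
        if bad_genes:
            problems.append(f"survival_betas genes not in panel: {sorted(bad_genes)}")
        if problems:
            raise ConfigError("; ".join(problems))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # per-patient sub-stream: adding patients never perturbs earlier ones
    return np.random.default_rng([int(seed), int(index)])


def _true_lfc(cfg: SimulationConfig, rng: np.random.Generator, archetype: str) -> dict[str, float]:
    """Per-patient latent log2FC for every target gene."""
    on_classes = ARCHETYPE_CLASSES[archetype]
    lfc = {}
    for gene in cfg.panel.genes:
        klass = cfg.panel.class_map.get(gene, OTHER)
        if klass in on_classes:
            mean, sd = cfg.class_lfc_mean.get(klass, 0.0), cfg.expressed_lfc_sd
        elif klass == OTHER and archetype != "negative":
            mean, sd = cfg.other_lfc_mean, cfg.expressed_lfc_sd
        else:
            mean, sd = cfg.off_lfc_mean, cfg.off_lfc_sd
        lfc[gene] = mean + sd * rng.standard_normal()
    return lfc


def generate_cohort(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Simulate one cohort; fully reproducible given (config, seed).

    Returns a dict of DataFrames: ``ct_table`` (long-format paired
    fractions), ``cellsearch_counts``, ``clinical`` and the
    ``ground_truth`` sidecar (archetype, true class flags, truly-HIGH
    genes, linear predictor).
    """
    cfg = config
    cfg.validate()
    names = sorted(cfg.archetype_weights)
    weights = np.array([cfg.archetype_weights[a] for a in names])
    weights = weights / weights.sum()

    ct_rows: list[tuple] = []
    count_rows: list[dict] = []
    clin_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.seed, i)
        pid = f"SP{i + 1:03d}"
        archetype = names[rng.choice(len(names), p=weights)]
        on_classes = ARCHETYPE_CLASSES[archetype]
        lfc = _true_lfc(cfg, rng, archetype)
        true_high = {g: lfc[g] >= np.log2(1.5) for g in cfg.panel.genes}

        visits = list(cfg.visits)
        if "V3" in visits and rng.random() < cfg.v3_dropout:
            visits.remove("V3")

        # --- paired-fraction Ct table -----------------------------------
        for visit in visits:
            for fraction in (PBMC, CTC_ENRICHED):
                ref_ct = cfg.ref_ct_mean + cfg.ref_ct_sd * rng.standard_normal()
                ct_rows.append((pid, visit, fraction, cfg.panel.reference_gene,
                                _censor(ref_ct, cfg.lod_ct)))
                for gene in cfg.panel.genes:
                    base = cfg.pbmc_ct_mean.get(gene, cfg.pbmc_ct_default)
                    ct = base + cfg.pbmc_ct_sd * rng.standard_normal()
                    if fraction == CTC_ENRICHED:
                        # tumour signal only in the enriched fraction
                        ct = ct - lfc[gene] + cfg.ct_noise_sd * rng.standard_normal()
                    ct_rows.append((pid, visit, fraction, gene, _censor(ct, cfg.lod_ct)))

        # --- CellSearch counts ------------------------------------------
        epi_on = EPITHELIAL in on_classes
        for visit in visits:
            factor = cfg.count_visit_factors.get(visit, 1.0)
            if rng.random() < cfg.count_zero_inflation:
                count = 0
            else:
                mu = float(np.exp(cfg.count_log_mean
                                  + cfg.count_epithelial_coef * epi_on)) * factor
                r = cfg.count_dispersion
                count = int(rng.negative_binomial(r, r / (r + mu)))
            count_rows.append({"patient_id": pid, "visit": visit, "ctc_count": count})

        # --- survival -----------------------------------------------------
        lp = sum(beta for g, beta in cfg.survival_betas.items() if true_high[g])
        k = cfg.weibull_shape
        pfs_t = cfg.weibull_scale_pfs * (-np.log(rng.random()) / np.exp(lp)) ** (1 / k)
        # the configured log-hazard acts on death as well as progression
        os_t = pfs_t + cfg.weibull_scale_os_extra * (
            -np.log(rng.random()) / np.exp(lp)
        ) ** (1 / k)
        cens = rng.exponential(cfg.censoring_mean)
        pfs_days = max(1.0, min(pfs_t, cens))
        os_days = max(pfs_days, min(os_t, cens))

        # --- clinical covariates -----------------------------------------
        clin_rows.append({
            "patient_id": pid,
            "age": int(np.clip(round(cfg.age_mean + cfg.age_sd * rng.standard_normal()), 45, 95)),
            "gleason": int(rng.choice([6, 7, 8, 9, 10], p=[0.1, 0.3, 0.3, 0.2, 0.1])),
            "castration_surgery": bool(rng.random() < cfg.surgery_prob),
            "prior_hormone_lines": int(rng.poisson(cfg.prior_lines_mean)),
            "visceral_metastasis": bool(rng.random() < cfg.visceral_prob),
            "ldh": float(np.round(np.exp(np.log(250) + 0.3 * rng.standard_normal()), 1)),
            "alkp": float(np.round(np.exp(np.log(90) + 0.4 * rng.standard_normal()), 1)),
            "psa": float(np.round(np.exp(np.log(50) + 1.0 * rng.standard_normal()), 2)),
            "pfs_days": float(np.round(pfs_days, 1)),
            "pfs_event": bool(pfs_t <= cens),
            "os_days": float(np.round(os_days, 1)),
            "os_event": bool(os_t <= cens),
        })

        truth_rows.append({
            "patient_id": pid,
            "archetype": archetype,
            "epithelial_on": EPITHELIAL in on_classes,
            "mesenchymal_on": MESENCHYMAL in on_classes,
            "stem_on": STEM in on_classes,
            "true_high_genes": ";".join(g for g in cfg.panel.genes if true_high[g]),
            "linear_predictor": float(lp),
            "n_visits": len(visits),
        })

    ct_table = pd.DataFrame(ct_rows, columns=CT_COLUMNS)
    ct_table["ct"] = [np.nan if v is None else round(v, 3) for v in ct_table["ct"]]
    return {
        "ct_table": ct_table,
        "cellsearch_counts": pd.DataFrame(count_rows),
        "clinical": pd.DataFrame(clin_rows),
        "ground_truth": pd.DataFrame(truth_rows),
    }


def _censor(ct: float, lod_ct: float):
    """Detection fails when the implied Ct exceeds the limit of detection."""
    return None if ct > lod_ct else float(ct)


def write_cohort(cohort: dict[str, pd.DataFrame], outdir) -> dict[str, str]:
    """Write the cohort file set; returns the paths written."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in cohort.items():
        path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named configurations covering the standard study conditions.

    * ``null`` — no marker-outcome association (type-I error checks).
    * ``paper-like`` — 20 patients, 3 visits with a reduced V3 subset,
      mixed archetypes dominated by the hybrid phenotype.
    * ``power`` — 200 patients, one visit, hazard ratio 2.5 on
      KRT19-high (power and label-recovery checks).
    """
    balanced = {
        "epithelial": 0.40, "mesenchymal": 0.05, "hybrid": 0.20,
        "stem": 0.05, "negative": 0.30,
    }
    return {
        "null": SimulationConfig(
            n_patients=60,
            visits=("V1",),
            archetype_weights=dict(balanced),
            survival_betas={},
        ),
        "paper-like": SimulationConfig(
            n_patients=20,
            visits=("V1", "V2", "V3"),
            v3_dropout=0.35,
            archetype_weights={
                "epithelial": 0.15, "mesenchymal": 0.08, "hybrid": 0.55,
                "stem": 0.07, "negative": 0.15,
            },
            survival_betas={"KRT19": float(np.log(2.0))},
        ),
        "power": SimulationConfig(
            n_patients=200,
            visits=("V1",),
            archetype_weights={
                "epithelial": 0.50, "mesenchymal": 0.0, "hybrid": 0.0,
                "stem": 0.0, "negative": 0.50,
            },
            survival_betas={"KRT19": float(np.log(2.5))},
        ),
    }


#: SimulationConfig fields serialised to/from the flat config document
#: (the gene panel itself is code, not configuration)
_SCALAR_FIELDS = tuple(
    f.name for f in dataclasses.fields(SimulationConfig) if f.name != "panel"
)


def config_to_yaml(cfg: SimulationConfig, path) -> None:
    """Write a config as a flat YAML document (panel excluded)."""
    import yaml

    doc = {}
    for name in _SCALAR_FIELDS:
        value = getattr(cfg, name)
        doc[name] = list(value) if isinstance(value, tuple) else value
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def config_from_yaml(path) -> SimulationConfig:
    """Load a config written by :func:`config_to_yaml`; unknown keys
    raise a validation error."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - set(_SCALAR_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("visits",):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    cfg = SimulationConfig(**doc)
    cfg.validate()
    return cfg


def get_preset(name: str) -> SimulationConfig:
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]


# ---------------------------------------------------------------------------
# deterministic reconstruction of the published association-table margins


def table1_cohort() -> dict[str, pd.DataFrame]:
    """Synthetic 20-patient clinical table matching the published
    association-table margins.

    Nineteen patients carry a baseline (V1) CellSearch count — six
    below 5 CTCs/7.5 mL, thirteen at or above — and one patient lacks
    the count (insufficient blood at baseline) yet still contributes to
    the cohort medians of LDH / ALK-P / PSA. Category assignments are
    chosen so that every clinical variable reproduces its published
    2x2 margins against the count dichotomy; the patients themselves
    are synthetic.
    """
    n = 20
    pid = [f"UM{i + 1:02d}" for i in range(n)]
    # index 0..5: <5 CTCs; 6..18: >=5 CTCs; 19: count missing
    counts = [2] * 6 + [8] * 13 + [None]

    age = [70 if i in {0, 1, 2, 3, 4, 6, 7, 8, 9, 10, 19} else 80 for i in range(n)]
    gleason = [7 if i in {0, 6, 7, 8, 9, 10, 11, 12, 13, 14, 19} else 9 for i in range(n)]
    surgery = [i in {4, 5, 17, 18} for i in range(n)]
    prior = [1 if i in {0, 1, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 19} else 3
             for i in range(n)]
    visceral = [i in {4, 5, 15, 16, 17, 18} for i in range(n)]
    # LDH: present for 16 patients (8 low / 8 high); missing for 4, 5, 18*, 19
    ldh_present = set(range(n)) - {4, 5, 18, 19}
    ldh_low = {0, 1, 2, 6, 7, 8, 9, 10}
    ldh = [None if i not in ldh_present
           else (180.0 + i if i in ldh_low else 320.0 + i) for i in range(n)]
    # ALK-P: all 20 present; 10 low / 10 high, the count-missing patient low
    alkp_low = {0, 1, 2, 3, 4, 6, 7, 8, 9, 19}
    alkp = [(70.0 + i if i in alkp_low else 130.0 + i) for i in range(n)]
    # PSA: all 20 present; 10 low / 10 high, the count-missing patient high
    psa_low = {0, 1, 2, 3, 4, 5, 6, 7, 8, 9}
    psa = [(10.0 + i if i in psa_low else 80.0 + i) for i in range(n)]

    rng = np.random.default_rng(20210301)
    pfs = np.round(rng.uniform(60, 500, n), 0)
    os_ = pfs + np.round(rng.uniform(30, 450, n), 0)
    clinical = pd.DataFrame({
        "patient_id": pid,
        "age": age,
        "gleason": gleason,
        "castration_surgery": surgery,
        "prior_hormone_lines": prior,
        "visceral_metastasis": visceral,
        "ldh": ldh,
        "alkp": alkp,
        "psa": psa,
        "pfs_days": pfs,
        "pfs_event": True,
        "os_days": os_,
        "os_event": [bool(v) for v in rng.random(n) < 0.75],
    })
    counts_df = pd.DataFrame({
        "patient_id": pid,
        "visit": "V1",
        "ctc_count": [np.nan if c is None else c for c in counts],
    })
    return {"clinical": clinical, "cellsearch_counts": counts_df}
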