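"""Cohort-generator configuration.

The defaults describe a small but structurally complete pan-cancer PDX cohort:
each patient case contributes one human tumor, one human normal and a couple of
independently engrafted models carried over a few passages.  Purity, depth and
clone-structure defaults follow what is typical for whole-exome PDX data
(high PDX purity, moderate human-tumor purity, ~80x tumor coverage).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence


class ConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


#: Autosome model used by the generator: 22 chromosomes of 100 Mb each.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
CHROM_LENGTH: int = 100_000_000

#: TP53 placed at its familiar position on chr17 (coordinates are synthetic
#: but keep the gene on the right chromosome arm).
TP53_CHROM = "chr17"
TP53_START = 7_668_000
TP53_END = 7_688_000

CANCER_TYPES: tuple[str, ...] = (
    "BRCA", "LUAD", "LUSC", "COAD", "HNSC", "SARC", "SKCM", "PAAD", "BLCA",
)

#: Genes with fixed symbols; everything else is a numbered filler gene.
DRIVER_GENES: tuple[str, ...] = (
    "TP53", "PIK3CA", "BRAF", "KRAS", "EGFR", "ERBB2", "CDKN2A", "FGFR3",
    "TACC3", "MET", "CCND1", "CDK6", "FGFR1", "PTEN", "APC", "NTRK1", "ALK",
    "RET", "SS18", "SSX1",
)

KINASE_GENES: tuple[str, ...] = (
    "BRAF", "EGFR", "ERBB2", "FGFR1", "FGFR3", "MET", "CDK6", "NTRK1",
    "ALK", "RET",
)

#: Fusion annotation tags treated as evidence of a normal (non-tumor) fusion.
NORMAL_FUSION_TAGS: tuple[str, ...] = (
    "GTEx_recurrent", "BodyMap", "DGD_PARALOGS", "HGNC_GENEFAM",
    "Greger_Normal", "Babiceanu_Normal", "ConjoinG",
)


def _default_arm_spikes() -> list[dict]:
    # One spiked model per alteration class, modeled on well-known
    # basket-trial arms (PI3K inhibitor, BRAF/MEK, HER2, CDKN2A, FGFR).
    return [
        {"gene": "PIK3CA", "alteration_class": "non_silent_mutation",
         "hotspot": "E545K", "n_models": 2},
        {"gene": "BRAF", "alteration_class": "variant_whitelist",
         "hotspot": "V600E", "n_models": 2},
        {"gene": "ERBB2", "alteration_class": "amplification", "n_models": 2},
        {"gene": "CDKN2A", "alteration_class": "deletion", "n_models": 2},
        {"gene": "FGFR3", "alteration_class": "fusion", "partner": "TACC3",
         "n_models": 2},
    ]


@dataclass
class CohortConfig:
    """All knobs of the synthetic PDX cohort generator.

    Parameters with a biological meaning carry their unit in the name or the
    comment; probabilities are plain fractions in [0, 1].  ``seed`` is
    mandatory: the generator is fully deterministic given the config.
    """

    seed: int

    # --- cohort layout -----------------------------------------------------
    n_cases: int = 12
    models_per_case: int = 2
    passages_per_model: int = 3          # passage indices 0..n-1
    human_tumor_per_case: bool = True
    human_normal_per_case: bool = True

    # --- clonal architecture ----------------------------------------------
    n_clonal_mutations: int = 60
    subclone_ccfs: Sequence[float] = (0.5, 0.3)   # cancer-cell fractions
    n_subclone_mutations: int = 25                # private to each subclone
    n_model_private_mutations: int = 15           # acquired at engraftment
    n_passage_private_mutations: int = 3          # per passage, CCF below
    passage_private_ccf: float = 0.35
    bottleneck_survival_prob: float = 0.5         # P(subclone survives engraftment)
    indel_fraction: float = 0.15
    nonsilent_fraction: float = 0.75
    whitelist_prob: float = 0.25                  # known-somatic list membership

    # --- purity and sequencing ---------------------------------------------
    # Human tumors centre near 0.5, PDXs near 0.85 (mouse stroma replaces
    # human stroma, so engrafted tumors run purer).
    human_purity_beta: tuple[float, float] = (8.0, 8.0)
    pdx_purity_beta: tuple[float, float] = (17.0, 3.0)
    human_purity: float | None = None             # constant override
    pdx_purity: float | None = None               # constant override
    tumor_mean_depth: float = 80.0
    normal_mean_depth: float = 40.0
    sequencing_error_rate: float = 0.001

    # --- caller emulation ----------------------------------------------------
    caller_sensitivity: dict = field(default_factory=lambda: {
        "strelka": 0.95, "mutect": 0.95, "varscan": 0.90, "pindel": 0.90,
    })
    false_positives_per_sample: float = 4.0       # Poisson mean, 1-caller artifacts
    germline_leak_per_sample: float = 1.0         # Poisson mean, high n_VAF artifacts

    # --- germline SNP panel -------------------------------------------------
    snp_panel_size: int = 1500
    snp_af_range: tuple[float, float] = (0.1, 0.9)
    snp_mean_depth: float = 60.0
    snp_min_depth_missing: int = 4                # below this the VAF is NA

    # --- copy number / WGD / LOH ---------------------------------------------
    p_wgd: float = 0.5
    p_tp53_loh_given_wgd: float = 0.9
    p_tp53_loh_given_no_wgd: float = 0.2
    p_deletion_abundant_given_wgd: float = 0.9
    p_deletion_abundant_given_no_wgd: float = 0.2
    segments_per_chromosome: int = 2
    log2_noise_sd: float = 0.05
    subclonal_event_prob: float = 0.15            # P(CNA event is subclonal)
    baf_snps_in_tp53_window: int = 25
    baf_mean_depth: float = 80.0

    # --- expression -----------------------------------------------------------
    n_genes: int = 2000
    n_expression_groups: int = 4
    signature_genes_per_group: int = 40
    expression_effect_size: float = 2.0           # in units of noise SD
    expression_noise_sd: float = 1.0
    expression_baseline_mean: float = 6.0
    expression_baseline_sd: float = 1.0
    expression_na_fraction: float = 0.01
    cluster_shift_prob: float = 0.05              # P(sample drifts to another group)
    balanced_expression_groups: bool = False      # round-robin case -> group
    n_centers: int = 1
    center_effect_sd: float = 0.0

    # --- fusions --------------------------------------------------------------
    background_fusions_per_cohort: int = 6

    # --- arm matching spike-ins ------------------------------------------------
    arm_spikes: list = field(default_factory=_default_arm_spikes)

    # --- anomaly plan (applied by plant_anomalies) -----------------------------
    swap_plan: list = field(default_factory=list)           # [(sample_a, sample_b)]
    contamination_plan: list = field(default_factory=list)  # [(sample, by, fraction)]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name in ("n_cases", "models_per_case", "passages_per_model",
                     "snp_panel_size", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_clonal_mutations", "n_subclone_mutations",
                     "n_model_private_mutations", "n_passage_private_mutations"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        probs = {
            "bottleneck_survival_prob": self.bottleneck_survival_prob,
            "indel_fraction": self.indel_fraction,
            "nonsilent_fraction": self.nonsilent_fraction,
            "whitelist_prob": self.whitelist_prob,
            "p_wgd": self.p_wgd,
            "p_tp53_loh_given_wgd": self.p_tp53_loh_given_wgd,
            "p_tp53_loh_given_no_wgd": self.p_tp53_loh_given_no_wgd,
            "p_deletion_abundant_given_wgd": self.p_deletion_abundant_given_wgd,
            "p_deletion_abundant_given_no_wgd": self.p_deletion_abundant_given_no_wgd,
            "cluster_shift_prob": self.cluster_shift_prob,
            "sequencing_error_rate": self.sequencing_error_rate,
            "passage_private_ccf": self.passage_private_ccf,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        for ccf in self.subclone_ccfs:
            if not 0.0 < ccf <= 1.0:
                raise ConfigError(f"subclone CCF {ccf} outside (0, 1]")
        for name, value in self.caller_sensitivity.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"caller sensitivity {name}={value} outside [0, 1]")
        for a, b, frac in self.contamination_plan:
            if not 0.0 < frac < 1.0:
                raise ConfigError(f"contamination fraction {frac} outside (0, 1)")

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)
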