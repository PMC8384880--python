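"""Basket-trial treatment-arm matching and the S_arm passage-depth score.

An arm rule pairs a drug with genomic inclusion criteria (non-silent
mutations in target genes, exact protein changes from a variant whitelist,
gene-level amplification/deletion, or fusions involving a target gene) plus
disease exclusions and optional biomarker requirements.  A PDX model
matches an arm when at least one criterion is satisfied by its
(post-filter) alterations, its cancer type is not excluded, and all
biomarker requirements hold.

The passage-depth score S_arm measures how deep into the passage series an
arm's signal persists: PDX samples are binned by passage number (N_pb
bins); a bin is positive when at least one sample with that passage index
carries the matching alteration in its own data (per-sample re-detection,
not inheritance from the model); S_arm = positive bins / N_pb.  S_arm = 1
means every represented passage bin has a positive sample.

Arm rules are data, not code: JSON/YAML with the schema of
:func:`ArmRule.from_dict`.  The bundled default set mirrors well-known
basket-trial arms and pairs 1:1 with the synthetic generator's spike-in
table.  Kinase fusions are classified by which partner is a kinase (5',
3' or both) after dropping normal-panel-annotated fusions and those with
FFPM <= 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pdxkit.cna import gene_level_categories
from pdxkit.config import KINASE_GENES, NORMAL_FUSION_TAGS
from pdxkit.stats import rank_sum_test

ALTERATION_CLASSES = ("non_silent_mutation", "variant_whitelist",
                      "amplification", "deletion", "fusion")

FFPM_MIN_EXCLUSIVE = 0.1          # "FFPM <= 0.1" is dropped
ASSOC_P_CUTOFF = 0.05
ASSOC_LOG2FC_CUTOFF = 0.585


@dataclass
class ArmCriterion:
    genes: frozenset
    alteration_class: str
    variants: frozenset = frozenset()       # protein changes, e.g. "V600E"
    five_prime_only: bool = False           # fusion: require gene5 membership

    def __post_init__(self):
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValueError(f"unknown alteration class "
                             f"{self.alteration_class!r}")


@dataclass
class ArmRule:
    arm_id: str
    drug: str
    criteria: list
    exclusions: frozenset = frozenset()     # cancer_type codes
    biomarkers: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.criteria:
            raise ValueError(f"arm {self.arm_id} has no inclusion criteria")

    @classmethod
    def from_dict(cls, d: dict) -> "ArmRule":
        crits = [ArmCriterion(
            genes=frozenset(c["genes"]),
            alteration_class=c["alteration_class"],
            variants=frozenset(c.get("variants", [])),
            five_prime_only=bool(c.get("five_prime_only", False)))
            for c in d["criteria"]]
        return cls(arm_id=d["arm_id"], drug=d.get("drug", ""),
                   criteria=crits,
                   exclusions=frozenset(d.get("exclusions", [])),
                   biomarkers=dict(d.get("biomarkers", {})))

    def to_dict(self) -> dict:
        return {"arm_id": self.arm_id, "drug": self.drug,
                "criteria": [{"genes": sorted(c.genes),
                              "alteration_class": c.alteration_class,
                              "variants": sorted(c.variants),
                              "five_prime_only": c.five_prime_only}
                             for c in self.criteria],
                "exclusions": sorted(self.exclusions),
                "biomarkers": dict(self.biomarkers)}


def load_arm_rules(path: str | Path) -> list[ArmRule]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return [ArmRule.from_dict(d) for d in data]


def default_arm_rules() -> list[ArmRule]:
    """Illustrative rule set modeled on familiar basket-trial arms."""
    raw = [
        {"arm_id": "ARM-PIK3CA", "drug": "copanlisib",
         "criteria": [{"genes": ["PIK3CA"],
                       "alteration_class": "non_silent_mutation"}]},
        {"arm_id": "ARM-BRAF-V600", "drug": "dabrafenib+trametinib",
         "criteria": [{"genes": ["BRAF"],
                       "alteration_class": "variant_whitelist",
                       "variants": ["V600E", "V600K"]}]},
        {"arm_id": "ARM-ERBB2-AMP", "drug": "trastuzumab+pertuzumab",
         "criteria": [{"genes": ["ERBB2"],
                       "alteration_class": "amplification"}]},
        {"arm_id": "ARM-CDKN2A-DEL", "drug": "palbociclib",
         "criteria": [{"genes": ["CDKN2A"],
                       "alteration_class": "deletion"}]},
        {"arm_id": "ARM-FGFR", "drug": "erdafitinib",
         "criteria": [{"genes": ["FGFR1", "FGFR3"],
                       "alteration_class": "fusion"}]},
    ]
    return [ArmRule.from_dict(d) for d in raw]


# ---------------------------------------------------------------------------
# model alteration summaries
# ---------------------------------------------------------------------------

@dataclass
class SampleAlterations:
    """Normalized post-filter alterations of one sample."""
    sample_id: str
    nonsilent_genes: set = field(default_factory=set)
    protein_changes: set = field(default_factory=set)   # (gene, change)
    amplified_genes: set = field(default_factory=set)
    deleted_genes: set = field(default_factory=set)
    fusion_genes_5p: set = field(default_factory=set)
    fusion_genes_3p: set = field(default_factory=set)

    def matches(self, crit: ArmCriterion) -> list[str]:
        hits = []
        if crit.alteration_class == "non_silent_mutation":
            hits = sorted(self.nonsilent_genes & crit.genes)
        elif crit.alteration_class == "variant_whitelist":
            hits = sorted(f"{g}:{c}" for g, c in self.protein_changes
                          if g in crit.genes and c in crit.variants)
        elif crit.alteration_class == "amplification":
            hits = sorted(self.amplified_genes & crit.genes)
        elif crit.alteration_class == "deletion":
            hits = sorted(self.deleted_genes & crit.genes)
        elif crit.alteration_class == "fusion":
            pool = self.fusion_genes_5p if crit.five_prime_only \
                else self.fusion_genes_5p | self.fusion_genes_3p
            hits = sorted(pool & crit.genes)
        return hits


def build_sample_alterations(filtered_mutations: pd.DataFrame,
                             segments: pd.DataFrame,
                             fusions: pd.DataFrame,
                             gene_map: pd.DataFrame,
                             sample_ids=None) -> dict[str, SampleAlterations]:
    """Normalize filtered calls into per-sample alteration summaries.

    Fusions are pre-filtered with the normal-panel / FFPM rule; copy-number
    categories are gene-level from retained segments.
    """
    out: dict[str, SampleAlterations] = {}

    def get(sid):
        return out.setdefault(sid, SampleAlterations(sid))

    for _, m in filtered_mutations.iterrows():
        if m["effect"] == "non_silent":
            alt = get(m["sample_id"])
            alt.nonsilent_genes.add(m["gene"])
            if isinstance(m.get("hotspot"), str) and m["hotspot"]:
                alt.protein_changes.add((m["gene"], m["hotspot"]))
    if len(segments):
        cats = gene_level_categories(segments, gene_map)
        for _, row in cats.iterrows():
            if row["cn_category"] == "amplification":
                get(row["sample_id"]).amplified_genes.add(row["gene"])
            elif row["cn_category"] == "deletion":
                get(row["sample_id"]).deleted_genes.add(row["gene"])
    for _, f in fusions.iterrows():
        _, keep = kinase_fusion_classify(f, KINASE_GENES)
        if keep:
            get(f["sample_id"]).fusion_genes_5p.add(f["gene5"])
            get(f["sample_id"]).fusion_genes_3p.add(f["gene3"])
    if sample_ids is not None:
        for sid in sample_ids:
            get(sid)
    return out


@dataclass
class ArmMatch:
    model_id: str
    arm_id: str
    matching_alterations: list
    passage_positivity: dict          # passage_index -> bool


def match_model_to_arms(model_id: str,
                        sample_alterations: dict[str, SampleAlterations],
                        passages: dict[str, int],
                        cancer_type: str,
                        rules: list[ArmRule],
                        biomarkers: dict | None = None,
                        known_cancer_types=None) -> list[ArmMatch]:
    """Match one model's PDX samples against every arm rule.

    ``sample_alterations`` maps the model's PDX sample_ids to their
    alteration summaries; ``passages`` maps sample_id -> passage_index.
    Unknown cancer-type codes pass through with a warning (exclusions
    cannot fire on them).
    """
    import warnings as _w
    biomarkers = biomarkers or {}
    if known_cancer_types is not None and cancer_type not in known_cancer_types:
        _w.warn(f"unknown cancer type code {cancer_type!r}; disease "
                "exclusions cannot fire", stacklevel=2)
    matches = []
    for rule in rules:
        if cancer_type in rule.exclusions:
            continue
        if any(biomarkers.get(k) != v for k, v in rule.biomarkers.items()):
            continue
        hits = set()
        positivity: dict[int, bool] = {}
        for sid, alt in sample_alterations.items():
            sample_hits: list[str] = []
            for crit in rule.criteria:
                sample_hits += alt.matches(crit)
            pidx = passages[sid]
            positivity[pidx] = positivity.get(pidx, False) or bool(sample_hits)
            hits.update(sample_hits)
        if hits:
            matches.append(ArmMatch(model_id, rule.arm_id, sorted(hits),
                                    positivity))
    return matches


def classify_models(matches: list[ArmMatch],
                    all_model_ids=None) -> dict[str, set]:
    """Partition models into single-arm / multi-arm / unmatched sets."""
    arms_per_model: dict[str, set] = {}
    for m in matches:
        arms_per_model.setdefault(m.model_id, set()).add(m.arm_id)
    single = {m for m, a in arms_per_model.items() if len(a) == 1}
    multi = {m for m, a in arms_per_model.items() if len(a) >= 2}
    unmatched = set()
    if all_model_ids is not None:
        unmatched = set(all_model_ids) - single - multi
    return {"single_arm": single, "multi_arm": multi, "unmatched": unmatched}


@dataclass
class ArmScore:
    arm_id: str
    s_arm: float
    n_pb: int
    positive_bins: int


def s_arm_score(matches: list[ArmMatch], samples: pd.DataFrame,
                cohort_wide_bins: bool = False) -> dict[str, ArmScore]:
    """S_arm per arm: positive passage bins / N_pb.

    By default N_pb counts the distinct passage indices present among the
    PDX samples of the arm's matched models; ``cohort_wide_bins=True``
    switches to all passage indices present in the cohort.
    """
    pdx = samples[samples["sample_class"] == "pdx"]
    if not len(pdx):
        raise ValueError("no PDX samples; S_arm undefined")
    cohort_bins = set(pdx["passage_index"].astype(int))
    model_bins: dict[str, set] = {
        mid: set(grp.astype(int))
        for mid, grp in pdx.groupby("model_id")["passage_index"]}
    by_arm: dict[str, list[ArmMatch]] = {}
    for m in matches:
        by_arm.setdefault(m.arm_id, []).append(m)
    out = {}
    for arm_id, arm_matches in by_arm.items():
        if cohort_wide_bins:
            bins = cohort_bins
        else:
            bins = set()
            for m in arm_matches:
                bins |= model_bins.get(m.model_id, set())
        positive = set()
        for m in arm_matches:
            positive |= {p for p, pos in m.passage_positivity.items() if pos}
        positive &= bins
        out[arm_id] = ArmScore(arm_id, len(positive) / len(bins),
                               len(bins), len(positive))
    return out


def kinase_fusion_classify(fusion, kinase_genes=KINASE_GENES,
                           ffpm_min: float = FFPM_MIN_EXCLUSIVE) -> tuple[str, bool]:
    """(5'/3'/both/none kinase class, keep flag).

    A fusion is dropped when it carries any normal-fusion-panel annotation
    tag or its FFPM is <= 0.1 (abundance too low to trust).
    """
    kinases = set(kinase_genes)
    five = fusion["gene5"] in kinases
    three = fusion["gene3"] in kinases
    cls = ("both" if five and three else
           "five_prime" if five else "three_prime" if three else "none")
    tags = fusion.get("annotation_tags", "")
    tag_set = {t for t in str(tags).split(";") if t} if pd.notna(tags) else set()
    keep = not (tag_set & set(NORMAL_FUSION_TAGS)) and fusion["ffpm"] > ffpm_min
    return cls, keep


def alteration_expression_association(expression: pd.DataFrame,
                                      altered_samples, wildtype_samples,
                                      target_gene: str,
                                      p_cutoff: float = ASSOC_P_CUTOFF,
                                      log2fc_cutoff: float = ASSOC_LOG2FC_CUTOFF
                                      ) -> tuple[float, float, bool]:
    """(log2 fold change of group means, Wilcoxon p, pass flag).

    pass ⇔ p < 0.05 and |log2FC| > 0.585 (i.e. a 1.5-fold change).
    """
    alt = [s for s in altered_samples if s in expression.columns]
    wt = [s for s in wildtype_samples if s in expression.columns]
    if not alt or not wt:
        raise ValueError("both groups must be non-empty")
    x = expression.loc[target_gene, alt].to_numpy(dtype=float)
    y = expression.loc[target_gene, wt].to_numpy(dtype=float)
    mx, my = np.nanmean(x), np.nanmean(y)
    eps = 1e-9
    log2fc = float(np.log2((mx + eps) / (my + eps)))
    _, p = rank_sum_test(x, y)
    passed = bool(p < p_cutoff and abs(log2fc) > log2fc_cutoff)
    return log2fc, p, passed


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def run_arm_matching(cohort, rules: list[ArmRule] | None = None,
                     filtered_mutations: pd.DataFrame | None = None) -> dict:
    """Filter, normalize and match a whole cohort; returns matches,
    model classification and per-arm S_arm scores."""
    from pdxkit.filters import filter_cohort
    rules = rules if rules is not None else default_arm_rules()
    if filtered_mutations is None:
        filtered_mutations = filter_cohort(cohort)
    pdx = cohort.samples[cohort.samples["sample_class"] == "pdx"]
    alterations = build_sample_alterations(
        filtered_mutations[filtered_mutations["sample_id"].isin(set(pdx["sample_id"]))],
        cohort.segments[cohort.segments["sample_id"].isin(set(pdx["sample_id"]))],
        cohort.fusions[cohort.fusions["sample_id"].isin(set(pdx["sample_id"]))],
        cohort.gene_map, sample_ids=list(pdx["sample_id"]))
    matches: list[ArmMatch] = []
    for model_id, grp in pdx.groupby("model_id"):
        passages = {r["sample_id"]: int(r["passage_index"])
                    for _, r in grp.iterrows()}
        sample_alt = {sid: alterations[sid] for sid in passages}
        matches += match_model_to_arms(
            model_id, sample_alt, passages,
            grp["cancer_type"].iloc[0], rules)
    classification = classify_models(matches,
                                     all_model_ids=set(pdx["model_id"]))
    scores = s_arm_score(matches, cohort.samples) if matches else {}
    return {"matches": matches, "classification": classification,
            "scores": scores}
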