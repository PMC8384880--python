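"""Sample-identity QC from germline SNP VAF profiles.

Every sample of one patient shares a germline, so the VAFs of a fixed panel
of common SNPs are near-identical across that patient's samples (human
tumor, normal, and all xenograft passages) and uncorrelated with unrelated
patients.  Pearson correlation of the VAF profiles therefore separates
matched pairs (r near 1), unrelated pairs (r near 0) and mixtures
(intermediate r), which is what swap / mismatch / contamination triage
needs.  Cohort-level concordance centers each locus by its cohort-mean VAF
first, removing the allele-frequency-driven correlation that unrelated
profiles otherwise share (see ``concordance_matrix``).  Coverage gating and
a pedigree-consistency report complete the QC.

Default verdict thresholds: a pair is a *match* at r >= 0.92 and a
*mismatch* at r <= 0.40; in between it is *ambiguous*, the contamination
signature.  The match cutoff sits between clean-replicate concordance
(~0.96-0.98 at panel depth ~60x) and centered concordance of a profile
30 %-contaminated by an unrelated sample (~0.88-0.91); the mismatch cutoff
sits between unrelated (~0) and first-degree-relative-like (~0.5)
profiles, which are reported as ambiguous for manual review rather than
auto-failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MATCH_THRESHOLD = 0.92
MISMATCH_THRESHOLD = 0.40
MIN_LOCUS_DEPTH = 8
MIN_SHARED_LOCI = 200

WES_MIN_CODING_COVERAGE_X = 20.0
RNA_MIN_MAPPED_DEPTH_MB = 25.0


class InsufficientDataError(ValueError):
    """Too few co-covered panel loci for a concordance verdict."""


@dataclass
class GermlineSNPProfile:
    """Per-sample VAF + depth over the cohort-wide SNP panel."""
    sample_id: str
    vaf: pd.Series        # indexed by locus, NaN where missing
    depth: pd.Series


@dataclass
class ConcordanceRecord:
    sample_id_a: str
    sample_id_b: str
    n_shared_loci: int
    correlation: float
    verdict: str | None = None


@dataclass
class CoverageQC:
    sample_id: str
    assay: str                       # "wes" or "rna"
    coding_coverage_x: float | None = None
    mapped_depth_mb: float | None = None

    @property
    def passed(self) -> bool:
        if self.assay == "wes":
            return (self.coding_coverage_x is not None
                    and self.coding_coverage_x > WES_MIN_CODING_COVERAGE_X)
        if self.assay == "rna":
            return (self.mapped_depth_mb is not None
                    and self.mapped_depth_mb > RNA_MIN_MAPPED_DEPTH_MB)
        raise ValueError(f"unknown assay {self.assay!r}")


def profiles_from_cohort(cohort) -> dict[str, GermlineSNPProfile]:
    return {sid: GermlineSNPProfile(sid, cohort.snp_vaf[sid], cohort.snp_depth[sid])
            for sid in cohort.snp_vaf.columns}


def vaf_concordance(profile_a: GermlineSNPProfile,
                    profile_b: GermlineSNPProfile,
                    min_depth: int = MIN_LOCUS_DEPTH,
                    min_shared_loci: int = MIN_SHARED_LOCI) -> ConcordanceRecord:
    """Pearson correlation of VAFs over loci covered >= min_depth in both."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    mask = ((profile_a.depth >= min_depth) & (profile_b.depth >= min_depth)
            & profile_a.vaf.notna() & profile_b.vaf.notna())
    n = int(mask.sum())
    if n < min_shared_loci:
        raise InsufficientDataError(
            f"only {n} co-covered loci (< {min_shared_loci})")
    a = profile_a.vaf[mask].to_numpy()
    b = profile_b.vaf[mask].to_numpy()
    if a.std() == 0 or b.std() == 0:
        r = 1.0 if np.array_equal(a, b) else 0.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return ConcordanceRecord(profile_a.sample_id, profile_b.sample_id, n, r)


def classify_pair(record: ConcordanceRecord | float,
                  match_threshold: float = MATCH_THRESHOLD,
                  mismatch_threshold: float = MISMATCH_THRESHOLD) -> str:
    """match / mismatch / ambiguous verdict from a concordance value."""
    if mismatch_threshold >= match_threshold:
        raise ValueError("mismatch_threshold must be < match_threshold")
    r = record.correlation if isinstance(record, ConcordanceRecord) else float(record)
    if r >= match_threshold:
        verdict = "match"
    elif r <= mismatch_threshold:
        verdict = "mismatch"
    else:
        verdict = "ambiguous"
    if isinstance(record, ConcordanceRecord):
        record.verdict = verdict
    return verdict


def concordance_matrix(snp_vaf: pd.DataFrame, snp_depth: pd.DataFrame,
                       min_depth: int = MIN_LOCUS_DEPTH,
                       center_loci: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson correlation and shared-locus counts.

    Depth-gated VAFs are correlated with pairwise NaN exclusion, so each
    pair uses exactly the loci covered >= min_depth in both samples.

    With ``center_loci`` (default) each locus's cohort-mean VAF is
    subtracted first.  Panel loci differ in population allele frequency, so
    raw VAF profiles of two *unrelated* individuals share an AF-driven
    component that inflates their correlation well above 0; locus centering
    removes it, pinning unrelated pairs near 0 while leaving same-genotype
    pairs near 1.
    """
    gated = snp_vaf.where(snp_depth >= min_depth)
    if center_loci:
        gated = gated.sub(gated.mean(axis=1, skipna=True), axis=0)
    corr = gated.corr(method="pearson", min_periods=2)
    present = gated.notna().astype(int)
    shared = present.T @ present
    return corr, shared


def pedigree_check(snp_vaf: pd.DataFrame, snp_depth: pd.DataFrame,
                   lineage: pd.DataFrame,
                   min_depth: int = MIN_LOCUS_DEPTH,
                   min_shared_loci: int = MIN_SHARED_LOCI,
                   match_threshold: float = MATCH_THRESHOLD,
                   mismatch_threshold: float = MISMATCH_THRESHOLD) -> dict:
    """Cohort-wide identity report.

    Flags every sample whose best-matching profile belongs to a different
    case *and* which no longer matches its own case (the swap signature;
    the second condition keeps innocent case-mates of a swapped-in sample,
    which genuinely share its germline, from being flagged).  Within-case
    pairs classified mismatch are reported as ``mismatch_pairs`` and
    within-case ambiguous pairs as contamination candidates; attributing a
    bad *pair* to one of its two members needs the best-match evidence, so
    pairs are reported as pairs.  Singleton cases are reported as
    unverifiable, not failed.
    """
    corr, shared = concordance_matrix(snp_vaf, snp_depth, min_depth)
    case_of = dict(zip(lineage["sample_id"], lineage["case_id"]))
    sample_ids = [s for s in corr.columns if s in case_of]
    case_sizes = pd.Series([case_of[s] for s in sample_ids]).value_counts()

    flagged, unverifiable, mismatch_pairs, candidates = [], [], [], []
    for s in sample_ids:
        if case_sizes.get(case_of[s], 0) < 2:
            unverifiable.append(s)
            continue
        others = [t for t in sample_ids if t != s
                  and shared.loc[s, t] >= min_shared_loci]
        if not others:
            unverifiable.append(s)
            continue
        best = max(others, key=lambda t: corr.loc[s, t])
        all_mates = [t for t in others if case_of[t] == case_of[s]]
        own_case_matched = any(
            corr.loc[s, t] >= match_threshold for t in all_mates)
        if case_of[best] != case_of[s] and not own_case_matched:
            flagged.append({"sample_id": s, "reason": "best_match_other_case",
                            "best_match": best, "best_match_case": case_of[best],
                            "correlation": float(corr.loc[s, best])})
        mates = [t for t in all_mates if t > s]
        for t in mates:
            verdict = classify_pair(float(corr.loc[s, t]),
                                    match_threshold, mismatch_threshold)
            if verdict == "mismatch":
                mismatch_pairs.append({"sample_a": s, "sample_b": t,
                                       "correlation": float(corr.loc[s, t])})
            elif verdict == "ambiguous":
                candidates.append({"sample_a": s, "sample_b": t,
                                   "correlation": float(corr.loc[s, t])})
    return {"flagged": flagged, "unverifiable": unverifiable,
            "mismatch_pairs": mismatch_pairs,
            "contamination_candidates": candidates}
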