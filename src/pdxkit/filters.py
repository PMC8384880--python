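"""Variant-retention cascades.

Four somatic cascades plus the germline post-filter, each returning a
decision table (one row per call, aligned with the input) that records which
rules failed; a call is retained iff no rule failed.

Thresholds (module constants, overridable per call):

* tumor/normal consensus: >= 2 callers, tumor depth >= 14, normal depth >= 8,
  >= 4 alt reads, tumor VAF >= 0.05, normal VAF <= 0.01,
* tumor-only: depth >= 20, alt reads > 3, VAF >= 0.1,
* PDX false-positive removal: keep a call only if it is on the known-somatic
  whitelist or re-found in the matched human tumor,
* indel proximity: drop SNVs within 20 bp of a retained indel (same sample,
  same chromosome, symmetric window around the indel anchor position),
* germline post-filter: alt allelic depth >= 5, VAF >= 20 %, cohort
  MAF <= 1 %, population AF <= 0.05 %, gene in the predisposition list; in
  tumor-only cases additionally drop keys seen somatically or whitelisted.

VAFs are computed as alt/depth with 0/0 -> 0.  "Total reads" means site
depth (ref + alt) in the respective sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

# tumor/normal consensus thresholds
MIN_CALLERS = 2
MIN_T_DEPTH = 14
MIN_N_DEPTH = 8
MIN_T_ALT = 4
MIN_T_VAF = 0.05
MAX_N_VAF = 0.01

# tumor-only thresholds
TO_MIN_DEPTH = 20
TO_MIN_ALT_EXCLUSIVE = 3          # "> 3 reads"
TO_MIN_VAF = 0.1

INDEL_WINDOW_BP = 20

# germline post-filter thresholds
GL_MIN_AD = 5
GL_MIN_VAF = 0.20
GL_MAX_COHORT_MAF = 0.01
GL_MAX_POP_AF = 0.0005


class ModeError(ValueError):
    """Raised when a cascade is applied to calls of the wrong mode."""


def _vaf(alt, depth) -> np.ndarray:
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(depth > 0, alt / np.where(depth > 0, depth, 1), 0.0)
    return v


def _decisions(calls: pd.DataFrame, failed: list[list[str]]) -> pd.DataFrame:
    out = calls[["sample_id", "chrom", "pos", "ref", "alt"]].copy()
    out["retained"] = [not f for f in failed]
    out["failed_rules"] = [";".join(f) for f in failed]
    return out.reset_index(drop=True)


def apply_decisions(calls: pd.DataFrame, decisions: pd.DataFrame) -> pd.DataFrame:
    """Subset ``calls`` to the rows a decision table retains."""
    return calls.loc[decisions["retained"].to_numpy()].reset_index(drop=True)


def caller_count(callers: pd.Series) -> np.ndarray:
    return np.array([len([c for c in str(v).split(",") if c]) if pd.notna(v) else 0
                     for v in callers])


# ---------------------------------------------------------------------------

def consensus_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Tumor/normal consensus cascade."""
    if calls["n_depth"].isna().any():
        raise ModeError("normal read counts absent; use tumor_only_filter "
                        "for tumor-only calls")
    n_callers = caller_count(calls["callers"])
    t_vaf = _vaf(calls["t_alt"], calls["t_depth"])
    n_vaf = _vaf(calls["n_alt"], calls["n_depth"])
    failed = []
    for i in range(len(calls)):
        f = []
        if n_callers[i] < MIN_CALLERS:
            f.append("min_callers")
        if calls["t_depth"].iat[i] < MIN_T_DEPTH:
            f.append("min_t_depth")
        if calls["n_depth"].iat[i] < MIN_N_DEPTH:
            f.append("min_n_depth")
        if calls["t_alt"].iat[i] < MIN_T_ALT:
            f.append("min_t_alt")
        if t_vaf[i] < MIN_T_VAF:
            f.append("min_t_vaf")
        if n_vaf[i] > MAX_N_VAF:
            f.append("max_n_vaf")
        failed.append(f)
    return _decisions(calls, failed)


def tumor_only_filter(calls: pd.DataFrame) -> pd.DataFrame:
    """Tumor-only cascade (no matched normal)."""
    t_vaf = _vaf(calls["t_alt"], calls["t_depth"])
    failed = []
    for i in range(len(calls)):
        f = []
        if calls["t_depth"].iat[i] < TO_MIN_DEPTH:
            f.append("min_depth")
        if calls["t_alt"].iat[i] <= TO_MIN_ALT_EXCLUSIVE:
            f.append("min_alt_reads")
        if t_vaf[i] < TO_MIN_VAF:
            f.append("min_vaf")
        failed.append(f)
    return _decisions(calls, failed)


def pdx_fp_filter(pdx_calls: pd.DataFrame,
                  matched_human_calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """PDX-specific false-positive removal.

    Mouse-homologous reads inflate false positives in xenografts even after
    read disambiguation, so a PDX call is kept only when it is on the
    known-somatic whitelist or re-found (identical chrom/pos/ref/alt key) in
    the matched human tumor.  Without a matched human tumor the whitelist
    alone decides.
    """
    human_keys: set[tuple] = set()
    if matched_human_calls is not None and len(matched_human_calls):
        human_keys = set(zip(matched_human_calls["chrom"],
                             matched_human_calls["pos"].astype(int),
                             matched_human_calls["ref"],
                             matched_human_calls["alt"]))
    failed = []
    for _, row in pdx_calls.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        ok = bool(row["whitelist"]) or key in human_keys
        failed.append([] if ok else ["not_whitelisted_or_in_human"])
    return _decisions(pdx_calls, failed)


def indel_proximity_filter(calls: pd.DataFrame,
                           window: int = INDEL_WINDOW_BP) -> pd.DataFrame:
    """Drop SNVs within ``window`` bp of a retained indel (per sample/chrom)."""
    indels = calls[calls["variant_type"] == "indel"]
    indel_pos: dict[tuple, np.ndarray] = {
        key: np.sort(grp["pos"].to_numpy())
        for key, grp in indels.groupby(["sample_id", "chrom"])}
    failed = []
    for _, row in calls.iterrows():
        f = []
        if row["variant_type"] == "snv":
            pos_arr = indel_pos.get((row["sample_id"], row["chrom"]))
            if pos_arr is not None:
                i = np.searchsorted(pos_arr, row["pos"])
                near = []
                if i < len(pos_arr):
                    near.append(pos_arr[i])
                if i > 0:
                    near.append(pos_arr[i - 1])
                if any(abs(int(p) - int(row["pos"])) <= window for p in near):
                    f.append("near_indel")
        failed.append(f)
    return _decisions(calls, failed)


def germline_post_filter(calls: pd.DataFrame,
                         predisposition_genes,
                         n_cohort_samples: int | None = None,
                         tumor_only: bool = False,
                         somatic_keys: set | None = None,
                         whitelist_keys: set | None = None) -> pd.DataFrame:
    """Post-filters on called germline variants.

    ``calls`` must carry ``ad_alt``, ``depth``, ``gene`` and ``pop_af``
    columns (population allele frequency; missing values treated as 0 with a
    warning).  The cohort minor-allele frequency of each key is computed from
    ``calls`` itself over ``n_cohort_samples`` (default: number of distinct
    sample_ids present).
    """
    genes = set(predisposition_genes)
    if n_cohort_samples is None:
        n_cohort_samples = calls["sample_id"].nunique()
    keys = list(zip(calls["chrom"], calls["pos"].astype(int),
                    calls["ref"], calls["alt"]))
    carriers = (pd.DataFrame({"key": keys, "sample_id": calls["sample_id"]})
                .drop_duplicates().groupby("key")["sample_id"].size())
    pop_af = calls["pop_af"]
    if pop_af.isna().any():
        warnings.warn("missing population AF treated as 0", stacklevel=2)
        pop_af = pop_af.fillna(0.0)
    vaf = _vaf(calls["ad_alt"], calls["depth"])
    somatic_keys = somatic_keys or set()
    whitelist_keys = whitelist_keys or set()
    failed = []
    for i, (_, row) in enumerate(calls.iterrows()):
        f = []
        if row["ad_alt"] < GL_MIN_AD:
            f.append("min_ad")
        if vaf[i] < GL_MIN_VAF:
            f.append("min_vaf")
        if carriers[keys[i]] / max(n_cohort_samples, 1) > GL_MAX_COHORT_MAF:
            f.append("cohort_maf")
        if pop_af.iat[i] > GL_MAX_POP_AF:
            f.append("pop_af")
        if row["gene"] not in genes:
            f.append("gene_list")
        if tumor_only:
            if keys[i] in somatic_keys:
                f.append("somatic_overlap")
            if keys[i] in whitelist_keys:
                f.append("whitelist_overlap")
        failed.append(f)
    return _decisions(calls, failed)


# ---------------------------------------------------------------------------
# cohort-level convenience cascade
# ---------------------------------------------------------------------------

def filter_cohort(cohort) -> pd.DataFrame:
    """Run the full somatic cascade over every tumor sample of a cohort.

    Human tumors: consensus (or tumor-only) filter, then indel proximity.
    PDX samples: the same, plus the PDX false-positive filter against the
    matched human tumor of their case.  Returns the retained mutation table.
    """
    samples = cohort.samples.set_index("sample_id")
    tumor_only = cohort.mutations["n_depth"].isna().all()
    base = tumor_only_filter(cohort.mutations) if tumor_only \
        else consensus_filter(cohort.mutations)
    retained = apply_decisions(cohort.mutations, base)

    human_by_case: dict[str, pd.DataFrame] = {}
    for sid, row in samples.iterrows():
        if row["sample_class"] == "human_tumor":
            human_by_case[row["case_id"]] = retained[retained["sample_id"] == sid]

    pieces = []
    for sid, grp in retained.groupby("sample_id"):
        cls = samples.loc[sid, "sample_class"]
        if cls == "pdx":
            matched = human_by_case.get(samples.loc[sid, "case_id"])
            grp = apply_decisions(grp.reset_index(drop=True),
                                  pdx_fp_filter(grp, matched))
        grp = apply_decisions(grp.reset_index(drop=True),
                              indel_proximity_filter(grp))
        pieces.append(grp)
    if not pieces:
        return cohort.mutations.iloc[0:0]
    return pd.concat(pieces, ignore_index=True)
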