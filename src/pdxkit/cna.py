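"""Copy-number categorization, WGD and TP53-LOH calling, association tests.

Segment log2 ratios are binned with the four thresholds −1.3, −0.4, 0.3,
0.9 (upper bounds inclusive) into deletion / loss / neutral / gain /
amplification — the conventional ~0, 1, 2, 3+ and high-level copy states of
an impure diploid tumor.  Whole-genome duplication is proxied from
allele-specific copy numbers: a genome whose major allele carries >= 2
copies over more than half its length has doubled.  TP53 LOH is read from
the allelic imbalance of heterozygous SNPs in a 6 Mb window around the
gene.  Binary sample features (WGD, deletion abundance, TP53 LOH) are
associated with Pearson's chi-squared statistic on the 2x2 table, no
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdxkit.stats import pearson_chi2

CN_THRESHOLDS = (-1.3, -0.4, 0.3, 0.9)
CN_CATEGORIES = ("deletion", "loss", "neutral", "gain", "amplification")

MIN_SEGMENT_COVERAGE = 20.0
MIN_SEGMENT_PROBES = 10
MIN_SEGMENT_LENGTH_BP = 5_000

WGD_MAJOR_CN_FRACTION = 0.5
LOH_MIN_INFORMATIVE_SNPS = 10
LOH_IMBALANCE_THRESHOLD = 0.25
TP53_WINDOW_BP = 6_000_000

SUBCLONAL_CN_DEVIATION = 0.1
MIN_CLONE_PROPORTION = 0.1
RECIPROCAL_OVERLAP = 0.5


def call_cn_category(log2_ratio):
    """Map log2 ratio(s) to a copy-number category (total step function)."""
    arr = np.asarray(log2_ratio, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite log2 ratio")
    idx = np.searchsorted(CN_THRESHOLDS, arr, side="left")
    cats = np.take(CN_CATEGORIES, idx)
    if np.isscalar(log2_ratio) or arr.ndim == 0:
        return str(cats)
    return cats


def integer_cn(log2_ratio) -> np.ndarray:
    """round(2 * 2**log2): integer copy number implied by the log2 ratio,
    for pipelines that want a strict CN > 5 amplification definition."""
    return np.round(2.0 * np.power(2.0, np.asarray(log2_ratio, dtype=float))).astype(int)


def segment_quality_filter(segments: pd.DataFrame,
                           min_coverage: float = MIN_SEGMENT_COVERAGE,
                           min_probes: int = MIN_SEGMENT_PROBES,
                           min_length: int = MIN_SEGMENT_LENGTH_BP) -> pd.DataFrame:
    """Drop low-quality segments (coverage < 20, probes < 10, length < 5 kb)."""
    keep = ((segments["coverage"] >= min_coverage)
            & (segments["n_probes"] >= min_probes)
            & ((segments["end"] - segments["start"]) >= min_length))
    return segments[keep].reset_index(drop=True)


def genome_fractions(segments: pd.DataFrame,
                     covered_genome_bp: float | None = None,
                     count_loss: bool = True) -> tuple[float, float, bool]:
    """(frac_deleted, frac_amplified, deletion_abundant) of one sample.

    frac_deleted counts bp in {deletion, loss} (set ``count_loss=False`` to
    count homozygous deletions only); frac_amplified counts {gain,
    amplification}.  ``deletion_abundant`` is the strict inequality.
    """
    lengths = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    covered = float(lengths.sum()) if covered_genome_bp is None else float(covered_genome_bp)
    if covered <= 0:
        raise ValueError("zero covered genome")
    cats = call_cn_category(segments["log2"].to_numpy()) if len(segments) \
        else np.array([], dtype=object)
    del_cats = {"deletion", "loss"} if count_loss else {"deletion"}
    frac_del = float(lengths[np.isin(cats, list(del_cats))].sum() / covered)
    frac_amp = float(lengths[np.isin(cats, ["gain", "amplification"])].sum() / covered)
    return frac_del, frac_amp, frac_del > frac_amp


def call_wgd(segments: pd.DataFrame,
             fraction_threshold: float = WGD_MAJOR_CN_FRACTION) -> bool | None:
    """WGD iff the length-weighted fraction of the genome with major allele
    copy number >= 2 exceeds ``fraction_threshold``.  Returns None (not
    applicable) when allele-specific fields are missing — never silently
    False."""
    if "major_cn" not in segments or segments["major_cn"].isna().any() or not len(segments):
        return None
    lengths = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    frac = lengths[segments["major_cn"].to_numpy() >= 2].sum() / lengths.sum()
    return bool(frac > fraction_threshold)


def detect_tp53_loh(bafs, min_snps: int = LOH_MIN_INFORMATIVE_SNPS,
                    imbalance_threshold: float = LOH_IMBALANCE_THRESHOLD) -> bool | None:
    """LOH iff mean |BAF − 0.5| of the window's heterozygous SNPs exceeds
    the imbalance threshold; None when fewer than ``min_snps`` SNPs."""
    baf = np.asarray(bafs, dtype=float)
    baf = baf[~np.isnan(baf)]
    if len(baf) < min_snps:
        return None
    return bool(np.mean(np.abs(baf - 0.5)) > imbalance_threshold)


def flag_subclonality(segments: pd.DataFrame, samples: pd.DataFrame,
                      deviation: float = SUBCLONAL_CN_DEVIATION,
                      min_clone_proportion: float = MIN_CLONE_PROPORTION,
                      reciprocal_overlap: float = RECIPROCAL_OVERLAP) -> pd.DataFrame:
    """Per-sample subclonality flags.

    ``intra_subclonal``: some retained segment's fractional total copy
    number (``frac_cn`` column) deviates from the nearest integer by more
    than ``deviation``, honoring the minimum clone proportion (deviations
    explainable only by clones below it are ignored).

    ``inter_subclonal`` (per case, reported on each sample): some sample of
    the case carries a categorized non-neutral segment with no
    reciprocal-overlap >= 0.5 match of the same category in another sample
    of the case; single-sample cases get None (not applicable).
    """
    case_of = dict(zip(samples["sample_id"], samples["case_id"]))
    rows = []
    intra_flags = {}
    for sid, grp in segments.groupby("sample_id"):
        if "frac_cn" in grp and grp["frac_cn"].notna().any():
            fc = grp["frac_cn"].to_numpy(dtype=float)
            dev = np.abs(fc - np.round(fc))
            # a single-copy event deviating by > 0.1 implies a clone above
            # the 10% minimum proportion, so the deviation cutoff honors it
            intra = bool(np.any(dev > max(deviation, min_clone_proportion)))
        else:
            intra = False
        intra_flags[sid] = intra

    # inter: compare non-neutral segments across samples of one case
    seg_by_sample = {sid: grp for sid, grp in segments.groupby("sample_id")}
    inter_by_case: dict[str, bool | None] = {}
    by_case: dict[str, list[str]] = {}
    for sid in seg_by_sample:
        if sid in case_of:
            by_case.setdefault(case_of[sid], []).append(sid)
    for case_id, sids in by_case.items():
        if len(sids) < 2:
            inter_by_case[case_id] = None
            continue
        inter = False
        for a in sids:
            ga = seg_by_sample[a]
            cats_a = call_cn_category(ga["log2"].to_numpy())
            for b in sids:
                if a == b or inter:
                    continue
                gb = seg_by_sample[b]
                cats_b = call_cn_category(gb["log2"].to_numpy())
                for (_, seg), cat in zip(ga.iterrows(), cats_a):
                    if cat == "neutral":
                        continue
                    if not _has_reciprocal_match(seg, cat, gb, cats_b,
                                                 reciprocal_overlap):
                        inter = True
                        break
        inter_by_case[case_id] = inter
    for sid in seg_by_sample:
        rows.append({"sample_id": sid,
                     "intra_subclonal": intra_flags[sid],
                     "inter_subclonal": inter_by_case.get(case_of.get(sid), None)})
    return pd.DataFrame(rows)


def _has_reciprocal_match(seg, cat, other, other_cats, min_ro) -> bool:
    length = seg["end"] - seg["start"]
    for (_, o), ocat in zip(other.iterrows(), other_cats):
        if ocat != cat or o["chrom"] != seg["chrom"]:
            continue
        ov = min(seg["end"], o["end"]) - max(seg["start"], o["start"])
        if ov <= 0:
            continue
        if ov / length >= min_ro and ov / (o["end"] - o["start"]) >= min_ro:
            return True
    return False


def association_test(feature_a, feature_b) -> tuple[float, float, np.ndarray]:
    """Pearson chi-squared association of two paired boolean features.

    Returns (chi2, p, 2x2 table); rows index feature_a (False, True),
    columns feature_b.  Degenerate margins raise ValueError.
    """
    a = np.asarray(feature_a, dtype=bool)
    b = np.asarray(feature_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("features must be paired 1-D vectors")
    if len(a) < 4:
        raise ValueError("need at least 4 paired observations")
    table = np.array([[np.sum(~a & ~b), np.sum(~a & b)],
                      [np.sum(a & ~b), np.sum(a & b)]], dtype=float)
    chi2, p = pearson_chi2(table)
    return chi2, p, table


# ---------------------------------------------------------------------------
# cohort-level features
# ---------------------------------------------------------------------------

@dataclass
class SampleCNFeatures:
    sample_id: str
    frac_deleted: float
    frac_amplified: float
    deletion_abundant: bool
    wgd: bool | None
    tp53_loh: bool | None


def sample_cn_features(segments: pd.DataFrame, baf: pd.DataFrame,
                       count_loss: bool = True) -> pd.DataFrame:
    """Quality-filter segments and derive the per-sample binary CN features."""
    retained = segment_quality_filter(segments)
    rows = []
    baf_by_sample = dict(tuple(baf.groupby("sample_id"))) if len(baf) else {}
    for sid, grp in retained.groupby("sample_id"):
        fd, fa, da = genome_fractions(grp, count_loss=count_loss)
        sb = baf_by_sample.get(sid)
        loh = detect_tp53_loh(sb["baf"]) if sb is not None else None
        rows.append({"sample_id": sid, "frac_deleted": fd, "frac_amplified": fa,
                     "deletion_abundant": da, "wgd": call_wgd(grp),
                     "tp53_loh": loh})
    return pd.DataFrame(rows)


def gene_level_categories(segments: pd.DataFrame, gene_map: pd.DataFrame,
                          genes=None) -> pd.DataFrame:
    """Per-sample gene-level CN category (category of the max-overlap
    retained segment; genes with no overlapping segment are absent)."""
    retained = segment_quality_filter(segments)
    gm = gene_map if genes is None else gene_map[gene_map["gene"].isin(set(genes))]
    genes_by_chrom = {c: g.sort_values("start")
                      for c, g in gm.groupby("chrom")}
    rows = []
    for sid, grp in retained.groupby("sample_id"):
        for chrom, segs in grp.groupby("chrom"):
            gch = genes_by_chrom.get(chrom)
            if gch is None:
                continue
            segs = segs.sort_values("start")
            s_start = segs["start"].to_numpy()
            s_end = segs["end"].to_numpy()
            s_log2 = segs["log2"].to_numpy()
            cats = call_cn_category(s_log2)
            g_start = gch["start"].to_numpy()
            g_end = gch["end"].to_numpy()
            # candidate = last segment starting at or before the gene start;
            # a gene straddling a boundary may overlap the next one more
            idx = np.searchsorted(s_start, g_start, side="right") - 1
            for gi, gene in enumerate(gch["gene"]):
                best, best_ov = -1, 0
                for j in (idx[gi], idx[gi] + 1):
                    if 0 <= j < len(s_start):
                        ov = min(s_end[j], g_end[gi]) - max(s_start[j], g_start[gi])
                        if ov > best_ov:
                            best, best_ov = j, ov
                if best >= 0:
                    rows.append({"sample_id": sid, "gene": gene,
                                 "cn_category": cats[best],
                                 "integer_cn": int(integer_cn(s_log2[best]))})
    out = pd.DataFrame(rows, columns=["sample_id", "gene", "cn_category",
                                      "integer_cn"])
    return out.sort_values(["sample_id", "gene"], kind="stable").reset_index(drop=True)
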