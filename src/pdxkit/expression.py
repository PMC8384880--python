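"""Pan-cancer transcriptional grouping and mutation-expression testing.

The grouping pipeline mirrors the consensus-clustering recipe standard in
pan-cancer expression work: select the 1000 genes with the highest median
absolute deviation (excluding genes with >= 30 % missing values), z-scale
each gene across samples, repeatedly subsample 80 % of samples and
partition them, accumulate co-assignment frequencies into a per-k consensus
matrix, cut the consensus matrix into the final groups, and pick k at the
elbow of the consensus-CDF delta-area curve (manual override available).

The base partitioner is k-means on the scaled values (deterministic given
the seed and fast); hierarchical clustering of the subsample is available
as a switch for parity with tools whose default is hierarchical.

Downstream: one-vs-rest Wilcoxon DEGs per group with BH-FDR, the per-model
cluster-shift score (largest fraction of a model's samples landing in one
group; 1 = perfectly stable), cis/trans mutation-expression tests, and a
median-alignment stand-in for inter-center batch adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from pdxkit.stats import bh_fdr, rank_sum_test

TOP_N_GENES = 1000
MAX_NA_FRACTION = 0.30
CONSENSUS_ITERATIONS = 1000
SUBSAMPLE_FRACTION = 0.8
ELBOW_RELATIVE_DELTA = 0.1
DEG_FDR_CUTOFF = 0.05
DEG_FOLD_CHANGE_MIN = 1.0
CIS_TRANS_FDR_CUTOFF = 0.1
MIN_GROUP_SIZE = 3


def select_variable_genes(matrix: pd.DataFrame, top_n: int = TOP_N_GENES,
                          max_na_fraction: float = MAX_NA_FRACTION) -> list[str]:
    """Top-``top_n`` genes by NA-ignoring median absolute deviation.

    Genes with an NA fraction >= ``max_na_fraction`` are dropped first;
    ties are broken by gene identifier order.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    na_frac = matrix.isna().mean(axis=1)
    eligible = matrix[na_frac < max_na_fraction]
    med = eligible.median(axis=1, skipna=True)
    mad = (eligible.sub(med, axis=0)).abs().median(axis=1, skipna=True)
    ranked = mad.sort_index().sort_values(ascending=False, kind="stable")
    if len(ranked) < top_n:
        warnings.warn(f"only {len(ranked)} eligible genes (< {top_n}); "
                      "returning all", stacklevel=2)
    return list(ranked.index[:top_n])


def scale_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Zero-center, unit-spread each gene across samples (NA -> 0)."""
    mu = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, skipna=True).replace(0, 1.0)
    return matrix.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


@dataclass
class ConsensusClusteringResult:
    assignments: pd.DataFrame              # sample_id, group_label, confidence
    consensus: dict                        # k -> (n x n) consensus matrix
    chosen_k: int
    cdf_area: dict = field(default_factory=dict)
    relative_delta: dict = field(default_factory=dict)
    labels_by_k: dict = field(default_factory=dict)
    sample_ids: list = field(default_factory=list)


def consensus_cluster(matrix: pd.DataFrame, k_range,
                      iterations: int = CONSENSUS_ITERATIONS,
                      subsample_fraction: float = SUBSAMPLE_FRACTION,
                      seed: int = 0, base: str = "kmeans",
                      force_k: int | None = None) -> ConsensusClusteringResult:
    """Consensus clustering of samples (columns of ``matrix``).

    ``matrix`` should already be restricted to the variable genes; genes are
    scaled internally.  Deterministic given ``seed``.  ``force_k`` overrides
    the elbow choice without recomputation.
    """
    k_range = sorted(set(int(k) for k in k_range))
    sample_ids = list(matrix.columns)
    n = len(sample_ids)
    if any(k >= n for k in k_range) or any(k < 2 for k in k_range):
        raise ValueError("k_range must lie in [2, n_samples)")
    X = scale_genes(matrix).to_numpy().T        # samples x genes
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_fraction * n)))
    consensus, labels_by_k = {}, {}
    for k in k_range:
        co = np.zeros((n, n))
        together = np.zeros((n, n))
        for _ in range(iterations):
            idx = rng.choice(n, size=m, replace=False)
            labels = _base_partition(X[idx], k, rng, base)
            together[np.ix_(idx, idx)] += 1
            for lab in range(k):
                members = idx[labels == lab]
                co[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore"):
            cm = np.where(together > 0, co / np.maximum(together, 1), 0.0)
        np.fill_diagonal(cm, 1.0)
        cm = (cm + cm.T) / 2
        consensus[k] = cm
        dist = squareform(1.0 - cm, checks=False)
        labels_by_k[k] = fcluster(linkage(dist, method="average"),
                                  t=k, criterion="maxclust")
    cdf_area, rel_delta = _delta_area(consensus, k_range)
    chosen_k = force_k if force_k is not None else _elbow_k(k_range, rel_delta)
    labels = labels_by_k[chosen_k]
    cm = consensus[chosen_k]
    conf = np.array([cm[i, labels == labels[i]].mean() for i in range(n)])
    assignments = pd.DataFrame({"sample_id": sample_ids,
                                "group_label": labels.astype(int),
                                "confidence": conf})
    return ConsensusClusteringResult(
        assignments=assignments, consensus=consensus, chosen_k=int(chosen_k),
        cdf_area=cdf_area, relative_delta=rel_delta,
        labels_by_k=labels_by_k, sample_ids=sample_ids)


def _base_partition(X: np.ndarray, k: int, rng, base: str) -> np.ndarray:
    if base == "kmeans":
        km = KMeans(n_clusters=k, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)))
        return km.fit_predict(X)
    if base == "hierarchical":
        from scipy.spatial.distance import pdist
        return fcluster(linkage(pdist(X), method="average"),
                        t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown base partitioner {base!r}")


def _delta_area(consensus: dict, k_range) -> tuple[dict, dict]:
    """Area under the consensus CDF per k, and its relative increase."""
    area = {}
    for k in k_range:
        cm = consensus[k]
        iu = np.triu_indices_from(cm, k=1)
        vals = np.sort(cm[iu])
        # area under the empirical CDF over [0, 1] equals 1 - mean
        area[k] = float(1.0 - vals.mean()) if len(vals) else 0.0
    rel = {}
    for i, k in enumerate(k_range):
        if i == 0:
            rel[k] = area[k]
        else:
            prev = area[k_range[i - 1]]
            rel[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    return area, rel


def _elbow_k(k_range, rel_delta, threshold: float = ELBOW_RELATIVE_DELTA) -> int:
    """Elbow of the delta-area curve: the k after which the relative gain
    in consensus-CDF area collapses (largest fold-drop to the next k).
    Candidate ks must themselves clear a minimal relative gain, so pure
    noise decay cannot win over real structure."""
    if len(k_range) == 1:
        return k_range[0]
    eps = 1e-12
    best_k, best_drop = k_range[0], -np.inf
    for i, k in enumerate(k_range[:-1]):
        if rel_delta[k] < threshold:
            continue
        drop = rel_delta[k] / max(rel_delta[k_range[i + 1]], eps)
        if drop > best_drop:
            best_k, best_drop = k, drop
    return best_k


def group_degs(matrix: pd.DataFrame, assignments: pd.DataFrame,
               fdr_cutoff: float = DEG_FDR_CUTOFF,
               fold_change_min: float = DEG_FOLD_CHANGE_MIN) -> dict[int, pd.DataFrame]:
    """Per-group positive DEGs: one-vs-rest two-sided Wilcoxon rank-sum,
    BH-FDR across genes within each comparison, reported at FDR <
    ``fdr_cutoff`` with fold change (group mean / rest mean, on the scale in
    use) above ``fold_change_min``.  Groups smaller than 3 are skipped."""
    labels = dict(zip(assignments["sample_id"], assignments["group_label"]))
    groups = sorted(set(labels.values()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for g in groups:
        in_ids = [s for s in matrix.columns if labels.get(s) == g]
        out_ids = [s for s in matrix.columns if s in labels and labels[s] != g]
        if len(in_ids) < MIN_GROUP_SIZE:
            warnings.warn(f"group {g} has fewer than {MIN_GROUP_SIZE} samples; "
                          "skipped", stacklevel=2)
            continue
        pvals, fcs = [], []
        for gene in matrix.index:
            x = matrix.loc[gene, in_ids].to_numpy(dtype=float)
            y = matrix.loc[gene, out_ids].to_numpy(dtype=float)
            _, p = rank_sum_test(x, y)
            pvals.append(p)
            my = np.nanmean(y)
            fcs.append(np.nanmean(x) / my if my > 0 else np.inf)
        df = pd.DataFrame({"gene": matrix.index, "p": pvals,
                           "fold_change": fcs})
        df["fdr"] = bh_fdr(df["p"])
        df = df[(df["fdr"] < fdr_cutoff) & (df["fold_change"] > fold_change_min)]
        out[g] = df.sort_values("fdr", kind="stable").reset_index(drop=True)
    return out


@dataclass
class ClusterShiftRecord:
    model_id: str
    n_samples: int
    score: float


def cluster_shift_score(labels, model_id: str = "") -> ClusterShiftRecord:
    """Largest fraction of a model's samples co-assigned to one group."""
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one sample")
    counts = pd.Series(labels).value_counts()
    return ClusterShiftRecord(model_id, len(labels),
                              float(counts.iloc[0] / len(labels)))


def model_shift_scores(assignments: pd.DataFrame,
                       samples: pd.DataFrame) -> pd.DataFrame:
    labels = dict(zip(assignments["sample_id"], assignments["group_label"]))
    rows = []
    pdx = samples[samples["sample_class"] == "pdx"]
    for model_id, grp in pdx.groupby("model_id"):
        labs = [labels[s] for s in grp["sample_id"] if s in labels]
        if labs:
            rec = cluster_shift_score(labs, model_id)
            rows.append({"model_id": model_id, "n_samples": rec.n_samples,
                         "score": rec.score})
    return pd.DataFrame(rows)


def mutated_sample_set(mutations: pd.DataFrame, query_gene: str) -> set[str]:
    """Samples carrying a non-silent mutation in ``query_gene`` (silent
    mutations do not count — a sample whose only mutation in the gene is
    silent is wild-type)."""
    sel = mutations[(mutations["gene"] == query_gene)
                    & (mutations["effect"] == "non_silent")]
    return set(sel["sample_id"])


def cis_trans_test(expression: pd.DataFrame, mutated_samples: set,
                   query_gene: str, target_genes=None,
                   fdr_cutoff: float = CIS_TRANS_FDR_CUTOFF,
                   min_group_size: int = MIN_GROUP_SIZE) -> pd.DataFrame:
    """Mutated-vs-wild-type Wilcoxon per target gene with BH-FDR.

    cis = the target is the query gene itself; trans = any other target.
    Returns one row per testable target with direction ('up' when the
    mutated group's mean is higher) and a ``significant`` flag at
    FDR < ``fdr_cutoff``.
    """
    targets = list(expression.index if target_genes is None else target_genes)
    mut_ids = [s for s in expression.columns if s in mutated_samples]
    wt_ids = [s for s in expression.columns if s not in mutated_samples]
    if len(mut_ids) < min_group_size or len(wt_ids) < min_group_size:
        raise ValueError("mutated and wild-type groups must both have at "
                         f"least {min_group_size} samples")
    rows = []
    for gene in targets:
        x = expression.loc[gene, mut_ids].to_numpy(dtype=float)
        y = expression.loc[gene, wt_ids].to_numpy(dtype=float)
        if np.isnan(x).all() or np.isnan(y).all():
            continue
        _, p = rank_sum_test(x, y)
        rows.append({"gene": gene,
                     "relation": "cis" if gene == query_gene else "trans",
                     "direction": "up" if np.nanmean(x) > np.nanmean(y) else "down",
                     "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["p"])
        df["significant"] = df["fdr"] < fdr_cutoff
    return df


def center_adjust(matrix: pd.DataFrame, centers: dict | pd.Series) -> pd.DataFrame:
    """Batch-adjustment stand-in: per gene, subtract each center's median
    and restore the global gene median.  Centers of size 1 pass through
    unchanged (warned).  An externally adjusted matrix can be supplied to
    downstream steps instead."""
    centers = pd.Series(centers)
    missing = [s for s in matrix.columns if s not in centers.index]
    if missing:
        raise ValueError(f"unlabeled samples: {missing[:5]}")
    out = matrix.copy()
    global_median = matrix.median(axis=1, skipna=True)
    for center, sids in centers.groupby(centers).groups.items():
        sids = [s for s in sids if s in matrix.columns]
        if len(sids) < 2:
            warnings.warn(f"center {center!r} has a single sample; passed "
                          "through unchanged", stacklevel=2)
            continue
        cm = matrix[sids].median(axis=1, skipna=True)
        out[sids] = matrix[sids].sub(cm, axis=0).add(global_median, axis=0)
    return out
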