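"""Mutational similarity within and across PDX models.

Similarity between two samples is the fraction of overlapping mutations on
the canonical (chrom, pos, ref, alt) identity key.  The default denominator
is the union (Jaccard index, |A∩B| / |A∪B|); the overlap coefficient
(|A∩B| / min(|A|, |B|)) is available as an alternative and both are worth
reporting side by side when the sets are very unequal in size.  Two empty
sets score 1 (vacuous agreement, flagged with a warning) so that
driver-only comparisons on driver-free samples do not poison summaries;
exactly one empty set scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdxkit.cohort import mutation_keys

LOW_SIMILARITY_CUTOFF = 0.2


def mutational_similarity(set_a: set, set_b: set,
                          method: str = "jaccard") -> float:
    """Similarity of two mutation key sets in [0, 1]."""
    if not set_a and not set_b:
        warnings.warn("both mutation sets empty; similarity defined as 1",
                      stacklevel=2)
        return 1.0
    if not set_a or not set_b:
        return 0.0
    inter = len(set_a & set_b)
    if method == "jaccard":
        return inter / len(set_a | set_b)
    if method == "overlap":
        return inter / min(len(set_a), len(set_b))
    raise ValueError(f"unknown method {method!r}")


def sample_key_sets(mutations: pd.DataFrame, scope: str = "all_mutations",
                    sample_ids=None) -> dict[str, set]:
    """Per-sample mutation key sets; scope 'driver_only' keeps driver calls."""
    if scope == "driver_only":
        mutations = mutations[mutations["driver"].astype(bool)]
    elif scope != "all_mutations":
        raise ValueError(f"unknown scope {scope!r}")
    sets = {sid: mutation_keys(grp)
            for sid, grp in mutations.groupby("sample_id")}
    if sample_ids is not None:
        for sid in sample_ids:
            sets.setdefault(sid, set())
    return sets


@dataclass
class SimilarityMatrix:
    sample_ids: list
    values: pd.DataFrame          # symmetric, diagonal 1
    relation: pd.DataFrame        # intra_model / inter_model / human_vs_pdx / other
    scope: str


def similarity_matrix(mutations: pd.DataFrame, samples: pd.DataFrame,
                      scope: str = "all_mutations",
                      method: str = "jaccard") -> SimilarityMatrix:
    tumor = samples[samples["sample_class"] != "human_normal"]
    sids = list(tumor["sample_id"])
    sets = sample_key_sets(mutations, scope, sample_ids=sids)
    model = dict(zip(tumor["sample_id"], tumor["model_id"]))
    case = dict(zip(tumor["sample_id"], tumor["case_id"]))
    cls = dict(zip(tumor["sample_id"], tumor["sample_class"]))
    n = len(sids)
    vals = np.ones((n, n))
    rel = np.full((n, n), "", dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                a, b = sids[i], sids[j]
                vals[i, j] = vals[j, i] = mutational_similarity(
                    sets[a], sets[b], method)
                rel[i, j] = rel[j, i] = _relation(a, b, model, case, cls)
    return SimilarityMatrix(
        sids, pd.DataFrame(vals, index=sids, columns=sids),
        pd.DataFrame(rel, index=sids, columns=sids), scope)


def _relation(a, b, model, case, cls) -> str:
    if "pdx" in (cls[a], cls[b]) and "human_tumor" in (cls[a], cls[b]):
        return "human_vs_pdx"
    if cls[a] == cls[b] == "pdx" and case[a] == case[b]:
        return "intra_model" if model[a] == model[b] else "inter_model"
    return "other"


def case_similarity_summary(mutations: pd.DataFrame, samples: pd.DataFrame,
                            scope: str = "all_mutations",
                            method: str = "jaccard") -> pd.DataFrame:
    """Per-case mean intra-model and inter-model similarity.

    Intra pairs are two passages of the same model; inter pairs are samples
    of different models of the same case.  Cases without eligible pairs are
    absent from the respective column (NaN), never reported as zero.
    """
    sim = similarity_matrix(mutations, samples, scope, method)
    rows = []
    pdx = samples[samples["sample_class"] == "pdx"]
    for case_id, grp in pdx.groupby("case_id"):
        sids = [s for s in grp["sample_id"] if s in sim.values.index]
        intra, inter = [], []
        for i, a in enumerate(sids):
            for b in sids[i + 1:]:
                r = sim.relation.loc[a, b]
                if r == "intra_model":
                    intra.append(sim.values.loc[a, b])
                elif r == "inter_model":
                    inter.append(sim.values.loc[a, b])
        if not intra and not inter:
            continue
        rows.append({
            "case_id": case_id,
            "n_intra_pairs": len(intra), "n_inter_pairs": len(inter),
            "mean_intra": float(np.mean(intra)) if intra else np.nan,
            "mean_inter": float(np.mean(inter)) if inter else np.nan,
        })
    return pd.DataFrame(rows)


def human_pdx_similarity(mutations: pd.DataFrame, samples: pd.DataFrame,
                         scope: str = "all_mutations",
                         method: str = "jaccard",
                         low_cutoff: float = LOW_SIMILARITY_CUTOFF) -> pd.DataFrame:
    """Per-model similarity of each PDX passage to the matched human tumor.

    The model score is the median across its passages; models scoring below
    ``low_cutoff`` are flagged as low-similarity (poor representation of the
    originating tumor).  Models without a matched human tumor are absent.
    """
    sets = sample_key_sets(mutations, scope,
                           sample_ids=list(samples["sample_id"]))
    human = {row["case_id"]: row["sample_id"]
             for _, row in samples.iterrows()
             if row["sample_class"] == "human_tumor"}
    rows = []
    pdx = samples[samples["sample_class"] == "pdx"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model_id, grp in pdx.groupby("model_id"):
            case_id = grp["case_id"].iloc[0]
            ht = human.get(case_id)
            if ht is None or not sets.get(ht):
                continue
            scores = {row["sample_id"]: mutational_similarity(
                sets[ht], sets[row["sample_id"]], method)
                for _, row in grp.iterrows()}
            score = float(np.median(list(scores.values())))
            rows.append({"model_id": model_id, "case_id": case_id,
                         "human_tumor": ht, "score": score,
                         "low_similarity": score < low_cutoff,
                         "per_passage": scores})
    return pd.DataFrame(rows)
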