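"""Variable-gene selection, consensus grouping, DEGs, shift score,
cis/trans tests and the center-adjustment stand-in."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pdxkit.expression import (
    center_adjust,
    cis_trans_test,
    cluster_shift_score,
    consensus_cluster,
    group_degs,
    model_shift_scores,
    mutated_sample_set,
    select_variable_genes,
    scale_genes,
)
from pdxkit.stats import bh_fdr, rank_sum_test


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------

def test_top_mad_genes_match_bruteforce():
    m = pd.DataFrame({
        "s1": [0, 0, 0, 5, 5], "s2": [3, 2, 1, 5, 5],
        "s3": [6, 4, 2, 5, 5], "s4": [9, 6, 3, 5, 5]},
        index=["gA", "gB", "gC", "gD", "gE"], dtype=float)
    # brute-force MADs: gA 3, gB 2, gC 1, gD 0, gE 0
    brute = {g: np.median(np.abs(m.loc[g] - np.median(m.loc[g])))
             for g in m.index}
    assert brute == {"gA": 3, "gB": 2, "gC": 1, "gD": 0, "gE": 0}
    assert select_variable_genes(m, top_n=2) == ["gA", "gB"]


def test_high_na_gene_excluded_regardless_of_mad():
    m = pd.DataFrame({
        "s1": [0.0, 1], "s2": [100.0, 1.1], "s3": [np.nan, 0.9],
        "s4": [np.nan, 1.0], "s5": [200.0, 1.05]},
        index=["volatile", "flat"])
    # 40 % NA excludes the high-MAD gene
    assert select_variable_genes(m, top_n=1) == ["flat"]


def test_constant_gene_ranks_last_and_short_supply_warns():
    m = pd.DataFrame({"s1": [1.0, 5], "s2": [2.0, 5], "s3": [3.0, 5]},
                     index=["varies", "constant"])
    with pytest.warns(UserWarning):
        genes = select_variable_genes(m, top_n=5)
    assert genes == ["varies", "constant"]


def test_mad_ties_broken_by_gene_order():
    m = pd.DataFrame({"s1": [0.0, 0], "s2": [1.0, 1], "s3": [2.0, 2]},
                     index=["zB", "aA"])
    assert select_variable_genes(m, top_n=1) == ["aA"]


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

def _planted(rng, n_groups, per_group, n_genes=120, sig=15, shift=3.0):
    X = rng.normal(0, 1, size=(n_genes, n_groups * per_group))
    for g in range(n_groups):
        rows = slice(g * sig, (g + 1) * sig)
        cols = slice(g * per_group, (g + 1) * per_group)
        X[rows, cols] += shift
    cols = [f"s{i:02d}" for i in range(n_groups * per_group)]
    truth = np.repeat(np.arange(n_groups), per_group)
    return pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                        columns=cols), truth


def test_two_planted_groups_recovered_with_k_two():
    m, truth = _planted(np.random.default_rng(0), 2, 15)
    res = consensus_cluster(m, range(2, 7), iterations=60, seed=1)
    assert res.chosen_k == 2
    assert adjusted_rand_score(truth, res.assignments["group_label"]) == 1.0


def test_consensus_matrix_properties():
    m, _ = _planted(np.random.default_rng(1), 2, 10)
    res = consensus_cluster(m, [2, 3], iterations=40, seed=2)
    for cm in res.consensus.values():
        assert np.allclose(cm, cm.T)
        assert np.allclose(np.diag(cm), 1.0)
        assert cm.min() >= 0 and cm.max() <= 1


def test_always_coclustered_pair_has_consensus_one():
    m, _ = _planted(np.random.default_rng(2), 2, 10)
    res = consensus_cluster(m, [2], iterations=50, seed=3)
    i, j = 0, 1                     # same planted group, trivially separable
    assert res.consensus[2][i, j] == pytest.approx(1.0)


def test_duplicated_samples_coassign_with_originals():
    m, _ = _planted(np.random.default_rng(3), 2, 8)
    dup = m.copy()
    dup.columns = [f"dup_{c}" for c in m.columns]
    both = pd.concat([m, dup], axis=1)
    res = consensus_cluster(both, [2], iterations=50, seed=4)
    labels = dict(zip(res.assignments["sample_id"],
                      res.assignments["group_label"]))
    for c in m.columns:
        assert labels[c] == labels[f"dup_{c}"]


def test_determinism_given_seed():
    m, _ = _planted(np.random.default_rng(4), 3, 8)
    r1 = consensus_cluster(m, [2, 3, 4], iterations=30, seed=9)
    r2 = consensus_cluster(m, [2, 3, 4], iterations=30, seed=9)
    pd.testing.assert_frame_equal(r1.assignments, r2.assignments)
    assert r1.chosen_k == r2.chosen_k


def test_k_range_validation():
    m, _ = _planted(np.random.default_rng(5), 2, 4)
    with pytest.raises(ValueError):
        consensus_cluster(m, [2, 8], iterations=5, seed=0)


def test_force_k_override():
    m, _ = _planted(np.random.default_rng(6), 2, 10)
    res = consensus_cluster(m, [2, 3], iterations=30, seed=0, force_k=3)
    assert res.chosen_k == 3
    assert res.assignments["group_label"].nunique() == 3


# ---------------------------------------------------------------------------
# DEGs
# ---------------------------------------------------------------------------

def test_separated_gene_reported_with_small_p():
    rng = np.random.default_rng(7)
    n_in, n_out = 10, 30
    m = pd.DataFrame(
        rng.normal(0, 1, size=(5, n_in + n_out)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(n_in + n_out)])
    m.iloc[0, :n_in] += 10.0       # complete separation for g0
    assignments = pd.DataFrame({
        "sample_id": m.columns,
        "group_label": [1] * n_in + [2] * n_out})
    degs = group_degs(m + 10.0, assignments)    # shift positive for FC
    assert "g0" in set(degs[1]["gene"])
    assert degs[1].set_index("gene").loc["g0", "p"] < 1e-6


def test_identical_distributions_not_reported():
    rng = np.random.default_rng(8)
    m = pd.DataFrame(rng.normal(5, 1, size=(10, 30)),
                     index=[f"g{i}" for i in range(10)],
                     columns=[f"s{i}" for i in range(30)])
    assignments = pd.DataFrame({"sample_id": m.columns,
                                "group_label": [1] * 15 + [2] * 15})
    degs = group_degs(m, assignments)
    assert len(degs[1]) == 0 and len(degs[2]) == 0


def test_small_group_skipped_with_warning():
    rng = np.random.default_rng(9)
    m = pd.DataFrame(rng.normal(5, 1, size=(4, 10)),
                     columns=[f"s{i}" for i in range(10)])
    assignments = pd.DataFrame({"sample_id": m.columns,
                                "group_label": [1] * 2 + [2] * 8})
    with pytest.warns(UserWarning):
        degs = group_degs(m, assignments)
    assert 1 not in degs


def test_bh_stepup_hand_example():
    adjusted = bh_fdr([0.01, 0.02, 0.04])
    assert np.allclose(adjusted, [0.03, 0.03, 0.04])


# ---------------------------------------------------------------------------
# cluster shift score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("labels,score", [
    ((1, 1, 1), 1.0), ((1, 1, 2, 2), 0.5), ((1, 2, 3, 4), 0.25),
    ((2,), 1.0),
])
def test_shift_score_examples(labels, score):
    rec = cluster_shift_score(labels, "M")
    assert rec.score == score
    assert rec.n_samples == len(labels)


def test_shift_score_matches_bruteforce_over_random_vectors():
    rng = np.random.default_rng(10)
    for _ in range(500):
        labels = rng.integers(1, 5, size=rng.integers(1, 9)).tolist()
        got = cluster_shift_score(labels).score
        brute = max(labels.count(v) for v in set(labels)) / len(labels)
        assert got == brute
        assert (got == 1.0) == (len(set(labels)) == 1)


def test_model_shift_scores_table(default_cohort):
    assignments = pd.DataFrame({
        "sample_id": default_cohort.samples["sample_id"],
        "group_label": 1})
    scores = model_shift_scores(assignments, default_cohort.samples)
    assert (scores["score"] == 1.0).all()


# ---------------------------------------------------------------------------
# cis / trans
# ---------------------------------------------------------------------------

def test_planted_cis_downregulation_detected():
    rng = np.random.default_rng(11)
    n_mut, n_wt = 15, 30
    samples = [f"s{i}" for i in range(n_mut + n_wt)]
    m = pd.DataFrame(rng.normal(5, 1, size=(20, n_mut + n_wt)),
                     index=[f"g{i}" for i in range(19)] + ["QUERY"],
                     columns=samples)
    m.loc["QUERY", samples[:n_mut]] -= 2.0
    res = cis_trans_test(m, set(samples[:n_mut]), "QUERY")
    row = res.set_index("gene").loc["QUERY"]
    assert row["relation"] == "cis" and row["direction"] == "down"
    assert row["significant"]


def test_silent_only_sample_counts_as_wildtype():
    muts = pd.DataFrame([
        dict(sample_id="s1", gene="TP53", effect="silent"),
        dict(sample_id="s2", gene="TP53", effect="non_silent"),
        dict(sample_id="s3", gene="KRAS", effect="non_silent")])
    assert mutated_sample_set(muts, "TP53") == {"s2"}


def test_cis_trans_null_calibration_under_permuted_labels():
    # permuting the mutated/wild-type labels kills the signal: across
    # permutations the fraction of targets reported at FDR < 0.1 stays
    # essentially zero
    rng = np.random.default_rng(18)
    n = 40
    samples = [f"s{i}" for i in range(n)]
    m = pd.DataFrame(rng.normal(5, 1, size=(25, n)),
                     index=[f"g{i}" for i in range(25)], columns=samples)
    reported = total = 0
    for _ in range(50):
        perm = rng.permutation(samples)
        res = cis_trans_test(m, set(perm[:15]), "g0")
        reported += int(res["significant"].sum())
        total += len(res)
    assert reported / total < 0.01


def test_cis_trans_requires_minimum_groups():
    rng = np.random.default_rng(12)
    m = pd.DataFrame(rng.normal(5, 1, size=(3, 10)),
                     index=["a", "b", "c"],
                     columns=[f"s{i}" for i in range(10)])
    with pytest.raises(ValueError):
        cis_trans_test(m, {"s0"}, "a")


# ---------------------------------------------------------------------------
# center adjustment
# ---------------------------------------------------------------------------

def test_single_center_matrix_unchanged():
    rng = np.random.default_rng(13)
    m = pd.DataFrame(rng.normal(5, 1, size=(10, 8)),
                     columns=[f"s{i}" for i in range(8)])
    out = center_adjust(m, {c: "A" for c in m.columns})
    assert np.allclose(out.to_numpy(), m.to_numpy())


def test_constant_center_offset_removed():
    rng = np.random.default_rng(14)
    base = rng.normal(5, 1, size=(20, 10))
    m = pd.DataFrame(np.hstack([base[:, :5], base[:, 5:] + 3.0]),
                     columns=[f"s{i}" for i in range(10)])
    centers = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
    out = center_adjust(m, centers)
    # after alignment the two centers' per-gene medians coincide
    med_a = out[[f"s{i}" for i in range(5)]].median(axis=1)
    med_b = out[[f"s{i}" for i in range(5, 10)]].median(axis=1)
    assert np.max(np.abs(med_a - med_b)) < 1e-10


def test_center_adjustment_improves_group_recovery():
    rng = np.random.default_rng(15)
    n = 40
    truth = np.array([0, 1] * (n // 2))
    center = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    X = rng.normal(0, 1, size=(60, n))
    X[:10, truth == 1] += 2.0                    # group signal
    X[:, center == "B"] += 4.0                   # batch offset, orthogonal
    m = pd.DataFrame(X, columns=[f"s{i}" for i in range(n)])
    adj = center_adjust(m, dict(zip(m.columns, center)))
    from sklearn.cluster import KMeans
    def ari(mat):
        lab = KMeans(2, n_init=10, random_state=0).fit_predict(
            scale_genes(mat).to_numpy().T)
        return adjusted_rand_score(truth, lab)
    assert ari(adj) >= ari(m)


def test_singleton_center_passed_through_with_warning():
    rng = np.random.default_rng(16)
    m = pd.DataFrame(rng.normal(5, 1, size=(6, 3)),
                     columns=["a", "b", "c"])
    with pytest.warns(UserWarning):
        out = center_adjust(m, {"a": "X", "b": "X", "c": "lonely"})
    assert np.allclose(out["c"], m["c"])


# ---------------------------------------------------------------------------
# rank-sum exactness
# ---------------------------------------------------------------------------

def test_rank_sum_matches_exact_enumeration_small_samples():
    rng = np.random.default_rng(17)
    for nx, ny in [(3, 4), (5, 5), (4, 6)]:
        x = rng.normal(0, 1, nx)
        y = rng.normal(1, 1, ny)
        _, p = rank_sum_test(x, y)
        # enumerate all group assignments of the pooled sample
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:nx].sum()
        total = 0
        extreme = 0
        mu = nx * (nx + ny + 1) / 2
        for combo in itertools.combinations(range(nx + ny), nx):
            total += 1
            w = ranks[list(combo)].sum()
            if abs(w - mu) >= abs(obs - mu) - 1e-9:
                extreme += 1
        assert p == pytest.approx(extreme / total, rel=1e-9)
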