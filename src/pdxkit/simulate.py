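"""Synthetic PDX cohort generator with known ground truth.

The generator emulates the statistical structure a pan-cancer PDX study rests
on, without touching reads:

* a case → model → passage lineage forest (human tumor, human normal, and
  serially passaged xenografts),
* a clonal mutation architecture per case (one truncal clone plus subclones
  with fixed cancer-cell fractions) propagated through an engraftment
  bottleneck: each subclone independently survives engraftment of each model,
  and every model additionally fixes a private set of mutations,
* read counts drawn per variant as binomial draws with success probability
  purity x CCF x allele-dosage / total-copy-number (total CN 2, heterozygous
  dosage 1 for point mutations),
* caller provenance simulated by independently flagging each variant in each
  applicable caller, plus caller-specific false positives,
* a cohort-wide germline SNP panel with Hardy-Weinberg genotypes shared
  within a case (the backbone of identity QC),
* allele-specific copy-number segments with case-level WGD, TP53-LOH and
  deletion-abundance flags, and B-allele fractions around TP53,
* expression groups with signature genes, and spiked-in treatment-arm
  alterations whose target genes are kept free of incidental alterations so
  planted truth is exact.

Fix the seed and every emitted byte is fixed.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pdxkit.config import (
    CHROM_LENGTH,
    CHROMOSOMES,
    CANCER_TYPES,
    DRIVER_GENES,
    NORMAL_FUSION_TAGS,
    TP53_CHROM,
    TP53_END,
    TP53_START,
    CohortConfig,
    ConfigError,
)
from pdxkit.cohort import (
    BAF_COLUMNS,
    FUSION_COLUMNS,
    MUTATION_COLUMNS,
    SEGMENT_COLUMNS,
    Cohort,
)

_BASES = np.array(list("ACGT"))

#: half-width of the allelic-imbalance window around TP53 (3 Mb each side)
TP53_WINDOW_HALF = 3_000_000

#: spiked segments and the TP53 window are carved as forced segments; random
#: CNA events keep this margin away from reserved arm-target genes
_RESERVE_MARGIN = 1_000_000

_EXPRESSION_SPIKE_BOOST = 6.0   # log-like units added for up-regulating spikes
_EXPRESSION_SPIKE_DOWN = 4.0    # subtracted for deletion spikes



# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------

def build_gene_map(n_genes: int) -> pd.DataFrame:
    """Deterministic synthetic gene coordinates: named driver genes first,
    numbered filler genes after, spread round-robin over 22 autosomes.
    TP53 sits at its familiar chr17 position."""
    names = list(DRIVER_GENES) + [f"G{i:04d}" for i in range(n_genes - len(DRIVER_GENES))]
    if n_genes < len(DRIVER_GENES):
        names = names[:n_genes]
    n_chrom = len(CHROMOSOMES)
    per_chrom = -(-len(names) // n_chrom)
    rows = []
    for i, name in enumerate(names):
        chrom = CHROMOSOMES[i % n_chrom]
        slot = i // n_chrom
        start = int((slot + 1) * CHROM_LENGTH / (per_chrom + 1))
        end = start + 20_000
        if name == "TP53":
            chrom, start, end = TP53_CHROM, TP53_START, TP53_END
        rows.append({"gene": name, "chrom": chrom, "start": start, "end": end})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clone bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _Clone:
    clone_id: str
    ccf: float
    mutations: list = field(default_factory=list)   # list of mutation dicts


def _random_mutation(rng, gene_row, used_keys, config,
                     effect=None, hotspot="", driver=False,
                     whitelist=None, variant_type=None) -> dict:
    for _ in range(200):
        pos = int(rng.integers(gene_row["start"] + 1, gene_row["end"]))
        if variant_type is None:
            vt = "indel" if rng.random() < config.indel_fraction else "snv"
        else:
            vt = variant_type
        if vt == "snv":
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            ref, alt = str(ref), str(alt)
        else:
            if rng.random() < 0.5:  # insertion
                ref = str(rng.choice(_BASES))
                alt = ref + "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
            else:                   # deletion
                ref = "".join(rng.choice(_BASES, size=int(rng.integers(2, 5))))
                alt = ref[0]
        key = (gene_row["chrom"], pos, ref, alt)
        if key not in used_keys:
            used_keys.add(key)
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a unique mutation key")
    if effect is None:
        effect = "non_silent" if rng.random() < config.nonsilent_fraction else "silent"
    if whitelist is None:
        whitelist = bool(rng.random() < config.whitelist_prob)
    return {
        "chrom": gene_row["chrom"], "pos": pos, "ref": ref, "alt": alt,
        "variant_type": vt, "gene": gene_row["gene"], "effect": effect,
        "hotspot": hotspot, "driver": driver, "whitelist": whitelist,
    }


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (deterministic for a fixed seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_map = build_gene_map(config.n_genes)
    gene_by_name = {r["gene"]: r for r in gene_map.to_dict("records")}

    spikes = [dict(s) for s in config.arm_spikes]
    reserved_mut_genes = {s["gene"] for s in spikes
                          if s["alteration_class"] in
                          ("non_silent_mutation", "variant_whitelist")}
    reserved_cn_genes = {s["gene"] for s in spikes
                         if s["alteration_class"] in ("amplification", "deletion")}
    reserved_fusion_genes = {s["gene"] for s in spikes
                             if s["alteration_class"] == "fusion"}
    reserved_intervals = [
        (gene_by_name[g]["chrom"],
         gene_by_name[g]["start"] - _RESERVE_MARGIN,
         gene_by_name[g]["end"] + _RESERVE_MARGIN)
        for g in sorted(reserved_cn_genes) if g in gene_by_name
    ]
    mutable_genes = gene_map[~gene_map["gene"].isin(reserved_mut_genes)]
    mutable_rows = mutable_genes.to_dict("records")

    # ---- SNP panel ---------------------------------------------------------
    panel = _snp_panel(rng, config)

    # ---- cohort layout -----------------------------------------------------
    samples: list[dict] = []
    used_keys: set = set()
    case_data: dict[str, dict] = {}
    model_ids: list[str] = []

    for ci in range(config.n_cases):
        case_id = f"C{ci + 1:03d}"
        cancer_type = str(rng.choice(CANCER_TYPES))
        wgd = bool(rng.random() < config.p_wgd)
        p_loh = (config.p_tp53_loh_given_wgd if wgd
                 else config.p_tp53_loh_given_no_wgd)
        loh = bool(rng.random() < p_loh)
        p_da = (config.p_deletion_abundant_given_wgd if wgd
                else config.p_deletion_abundant_given_no_wgd)
        del_abund = bool(rng.random() < p_da)
        group = (ci % config.n_expression_groups + 1
                 if config.balanced_expression_groups
                 else int(rng.integers(config.n_expression_groups)) + 1)
        genotype = _case_genotype(rng, panel)

        # clonal architecture
        clonal = _Clone(f"{case_id}.clonal", 1.0)
        for _ in range(config.n_clonal_mutations):
            gene_row = mutable_rows[int(rng.integers(len(mutable_rows)))]
            clonal.mutations.append(
                _random_mutation(rng, gene_row, used_keys, config))
        # one clonal driver per case
        driver_pool = [g for g in DRIVER_GENES
                       if g not in reserved_mut_genes and g != "TP53"]
        dg = gene_by_name[str(rng.choice(driver_pool))]
        clonal.mutations.append(_random_mutation(
            rng, dg, used_keys, config, effect="non_silent",
            hotspot=f"{dg['gene'][0]}{int(rng.integers(100, 999))}X",
            driver=True, whitelist=True, variant_type="snv"))
        subclones = []
        for si, ccf in enumerate(config.subclone_ccfs):
            sc = _Clone(f"{case_id}.sub{si + 1}", float(ccf))
            for _ in range(config.n_subclone_mutations):
                gene_row = mutable_rows[int(rng.integers(len(mutable_rows)))]
                sc.mutations.append(
                    _random_mutation(rng, gene_row, used_keys, config))
            subclones.append(sc)

        case_data[case_id] = {
            "cancer_type": cancer_type, "wgd": wgd, "loh": loh,
            "del_abund": del_abund, "group": group, "genotype": genotype,
            "clonal": clonal, "subclones": subclones, "models": {},
        }

        normal_id = f"{case_id}-N" if config.human_normal_per_case else None
        if normal_id:
            samples.append({
                "sample_id": normal_id, "case_id": case_id, "model_id": None,
                "sample_class": "human_normal", "passage_index": np.nan,
                "parent_sample_id": None, "cancer_type": cancer_type,
                "purity": np.nan})
        ht_id = f"{case_id}-HT" if config.human_tumor_per_case else None
        if ht_id:
            samples.append({
                "sample_id": ht_id, "case_id": case_id, "model_id": None,
                "sample_class": "human_tumor", "passage_index": np.nan,
                "parent_sample_id": None, "cancer_type": cancer_type,
                "purity": _purity(rng, config, "human")})

        for mi in range(config.models_per_case):
            model_id = f"{case_id}-M{mi + 1}"
            model_ids.append(model_id)
            survived = [sc for sc in subclones
                        if rng.random() < config.bottleneck_survival_prob]
            total_orig = sum(sc.ccf for sc in subclones)
            total_surv = sum(sc.ccf for sc in survived)
            model_subclones = []
            for sc in survived:
                new_ccf = (min(1.0, sc.ccf * total_orig / total_surv)
                           if total_surv > 0 else sc.ccf)
                model_subclones.append(_Clone(sc.clone_id, new_ccf, sc.mutations))
            private = _Clone(f"{model_id}.private", 1.0)
            for _ in range(config.n_model_private_mutations):
                gene_row = mutable_rows[int(rng.integers(len(mutable_rows)))]
                private.mutations.append(
                    _random_mutation(rng, gene_row, used_keys, config))
            passage_privates = []
            parent = ht_id
            for pi in range(config.passages_per_model):
                sid = f"{model_id}-P{pi}"
                samples.append({
                    "sample_id": sid, "case_id": case_id, "model_id": model_id,
                    "sample_class": "pdx", "passage_index": pi,
                    "parent_sample_id": parent, "cancer_type": cancer_type,
                    "purity": _purity(rng, config, "pdx")})
                parent = sid
                pp = _Clone(f"{model_id}.p{pi}", config.passage_private_ccf)
                for _ in range(config.n_passage_private_mutations):
                    gene_row = mutable_rows[int(rng.integers(len(mutable_rows)))]
                    pp.mutations.append(
                        _random_mutation(rng, gene_row, used_keys, config))
                passage_privates.append(pp)
            case_data[case_id]["models"][model_id] = {
                "subclones": model_subclones, "private": private,
                "passage_privates": passage_privates, "spikes": [],
            }

    samples_df = pd.DataFrame(samples)

    # ---- arm spike assignment ---------------------------------------------
    spike_truth = _assign_spikes(rng, spikes, model_ids, case_data,
                                 gene_by_name, used_keys, config)

    # ---- mutation calls ----------------------------------------------------
    mutations = _emit_mutations(rng, samples_df, case_data, config,
                                reserved_genes=(reserved_mut_genes
                                                | reserved_cn_genes
                                                | reserved_fusion_genes),
                                gene_map=gene_map, used_keys=used_keys)

    # ---- SNP profiles -------------------------------------------------------
    snp_vaf, snp_depth = _emit_snp_profiles(rng, samples_df, case_data,
                                            panel, config)

    # ---- copy number, BAF ---------------------------------------------------
    segments, baf = _emit_cn(rng, samples_df, case_data, config,
                             reserved_intervals, gene_by_name)

    # ---- expression ---------------------------------------------------------
    expression, centers, group_truth = _emit_expression(
        rng, samples_df, case_data, config, gene_map)
    samples_df["center"] = samples_df["sample_id"].map(centers).fillna("")

    # ---- fusions -------------------------------------------------------------
    fusions = _emit_fusions(rng, samples_df, case_data, config, gene_map,
                            reserved_fusion_genes)

    # ---- truth ---------------------------------------------------------------
    truth = _build_truth(samples_df, case_data, group_truth, spike_truth)

    cohort = Cohort(
        samples=samples_df, mutations=mutations, snp_vaf=snp_vaf,
        snp_depth=snp_depth, segments=segments,
        expression=expression, baf=baf, fusions=fusions,
        gene_map=gene_map, truth=truth)

    plan = {"swaps": [list(p) for p in config.swap_plan],
            "contaminations": [list(p) for p in config.contamination_plan]}
    if plan["swaps"] or plan["contaminations"]:
        cohort = plant_anomalies(cohort, plan)
    return cohort


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _purity(rng, config: CohortConfig, kind: str) -> float:
    override = (config.human_purity if kind == "human" else config.pdx_purity) \
        if hasattr(config, f"{kind}_purity") else None
    if override is not None:
        return float(override)
    a, b = (config.human_purity_beta if kind == "human"
            else config.pdx_purity_beta)
    return float(rng.beta(a, b))


def _snp_panel(rng, config: CohortConfig) -> pd.DataFrame:
    n = config.snp_panel_size
    chroms = [CHROMOSOMES[i % len(CHROMOSOMES)] for i in range(n)]
    pos = rng.integers(1, CHROM_LENGTH, size=n)
    lo, hi = config.snp_af_range
    af = rng.uniform(lo, hi, size=n)
    df = pd.DataFrame({"chrom": chroms, "pos": pos, "af": af})
    df["locus"] = df["chrom"] + ":" + df["pos"].astype(str)
    return df.drop_duplicates("locus").reset_index(drop=True)


def _case_genotype(rng, panel: pd.DataFrame) -> np.ndarray:
    """Hardy-Weinberg germline dosage (0, 0.5, 1) at each panel locus."""
    af = panel["af"].to_numpy()
    u = rng.random(len(af))
    hom_ref = (1 - af) ** 2
    het = 2 * af * (1 - af)
    g = np.where(u < hom_ref, 0.0, np.where(u < hom_ref + het, 0.5, 1.0))
    return g


def _sample_clones(case, model_info, passage_index) -> list[_Clone]:
    """Clone set carried by one sample."""
    clones = [case["clonal"]]
    if model_info is None:           # human tumor
        clones += case["subclones"]
    else:
        clones += model_info["subclones"]
        clones.append(model_info["private"])
        clones += model_info["passage_privates"][: passage_index + 1]
        clones += model_info["spikes"]
    return clones


def _emit_mutations(rng, samples_df, case_data, config, reserved_genes,
                    gene_map, used_keys) -> pd.DataFrame:
    snv_callers = ["strelka", "mutect", "varscan"]
    indel_callers = ["strelka", "varscan", "pindel"]
    fp_genes = gene_map[~gene_map["gene"].isin(reserved_genes)].to_dict("records")
    rows = []
    for _, s in samples_df.iterrows():
        if s["sample_class"] == "human_normal":
            continue
        case = case_data[s["case_id"]]
        model_info = (case["models"][s["model_id"]]
                      if s["model_id"] else None)
        has_normal = config.human_normal_per_case
        purity = s["purity"]
        pidx = int(s["passage_index"]) if model_info is not None else None
        for clone in _sample_clones(case, model_info, pidx):
            vaf_true = purity * clone.ccf / 2.0
            for mut in clone.mutations:
                row = _read_counts_row(rng, s["sample_id"], mut, vaf_true,
                                       config, has_normal,
                                       snv_callers, indel_callers)
                if row is not None:
                    rows.append(row)
        # caller-specific artifacts (single caller, low VAF)
        n_fp = rng.poisson(config.false_positives_per_sample)
        for _ in range(n_fp):
            gene_row = fp_genes[int(rng.integers(len(fp_genes)))]
            mut = _random_mutation(rng, gene_row, used_keys, config,
                                   whitelist=False)
            depth = max(1, int(rng.poisson(config.tumor_mean_depth)))
            alt = max(1, int(rng.binomial(depth, rng.uniform(0.03, 0.15))))
            caller_pool = snv_callers if mut["variant_type"] == "snv" else indel_callers
            row = _mutation_row(s["sample_id"], mut, depth, min(alt, depth),
                                [str(rng.choice(caller_pool))])
            if has_normal:
                nd = max(1, int(rng.poisson(config.normal_mean_depth)))
                row["n_depth"], row["n_alt"] = nd, int(
                    rng.binomial(nd, config.sequencing_error_rate))
            rows.append(row)
        # germline leak-through (called by 2 callers but high normal VAF)
        n_leak = rng.poisson(config.germline_leak_per_sample)
        for _ in range(n_leak):
            gene_row = fp_genes[int(rng.integers(len(fp_genes)))]
            mut = _random_mutation(rng, gene_row, used_keys, config,
                                   whitelist=False)
            depth = max(1, int(rng.poisson(config.tumor_mean_depth)))
            alt = int(rng.binomial(depth, 0.5))
            caller_pool = snv_callers if mut["variant_type"] == "snv" else indel_callers
            callers = sorted(rng.choice(caller_pool, size=2, replace=False))
            row = _mutation_row(s["sample_id"], mut, depth, alt,
                                [str(c) for c in callers])
            if has_normal:
                nd = max(1, int(rng.poisson(config.normal_mean_depth)))
                row["n_depth"], row["n_alt"] = nd, int(rng.binomial(nd, 0.5))
            rows.append(row)
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    return df.sort_values(["sample_id", "chrom", "pos", "ref", "alt"],
                          kind="stable").reset_index(drop=True)


def _read_counts_row(rng, sample_id, mut, vaf_true, config, has_normal,
                     snv_callers, indel_callers):
    depth = int(rng.poisson(config.tumor_mean_depth))
    if depth == 0:
        return None
    p = min(1.0, vaf_true + config.sequencing_error_rate)
    alt = int(rng.binomial(depth, p))
    if alt == 0:
        return None
    pool = snv_callers if mut["variant_type"] == "snv" else indel_callers
    callers = [c for c in pool
               if rng.random() < config.caller_sensitivity.get(c, 0.0)]
    if not callers:
        return None
    row = _mutation_row(sample_id, mut, depth, alt, callers)
    if has_normal:
        nd = max(1, int(rng.poisson(config.normal_mean_depth)))
        row["n_depth"] = nd
        row["n_alt"] = int(rng.binomial(nd, config.sequencing_error_rate))
    return row


def _mutation_row(sample_id, mut, t_depth, t_alt, callers) -> dict:
    return {
        "sample_id": sample_id, "chrom": mut["chrom"], "pos": mut["pos"],
        "ref": mut["ref"], "alt": mut["alt"],
        "variant_type": mut["variant_type"], "gene": mut["gene"],
        "effect": mut["effect"], "hotspot": mut["hotspot"],
        "driver": bool(mut["driver"]), "callers": ",".join(sorted(callers)),
        "t_depth": t_depth, "t_alt": t_alt,
        "n_depth": np.nan, "n_alt": np.nan,
        "whitelist": bool(mut["whitelist"]),
    }


def _emit_snp_profiles(rng, samples_df, case_data, panel, config):
    error = config.sequencing_error_rate
    vaf_cols, depth_cols = {}, {}
    for _, s in samples_df.iterrows():
        g = case_data[s["case_id"]]["genotype"]
        p = np.clip(g, error, 1 - error)
        depth = rng.poisson(config.snp_mean_depth, size=len(g))
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(depth > 0, rng.binomial(depth, p) / np.maximum(depth, 1),
                           np.nan)
        vaf = np.where(depth < config.snp_min_depth_missing, np.nan, vaf)
        vaf_cols[s["sample_id"]] = vaf
        depth_cols[s["sample_id"]] = depth
    index = pd.Index(panel["locus"], name="locus")
    return (pd.DataFrame(vaf_cols, index=index),
            pd.DataFrame(depth_cols, index=index))


def _overlaps_reserved(chrom, start, end, reserved) -> bool:
    return any(c == chrom and start < e and s < end for c, s, e in reserved)


def _event_state(rng, kind: str, wgd: bool) -> tuple[int, int]:
    """(major, minor) allele copy numbers for a CNA event."""
    if kind == "loss":
        if rng.random() < 0.15:
            return (0, 0)                       # homozygous deletion
        return (2, 0) if wgd else (1, 0)        # single/copy-balanced loss
    if rng.random() < 0.3:
        return (6, 2) if wgd else (4, 1)        # amplification
    return (4, 2) if wgd else (2, 1)            # gain


def _emit_cn(rng, samples_df, case_data, config, reserved, gene_by_name):
    seg_rows, baf_rows = [], []
    win_lo = (TP53_START + TP53_END) // 2 - TP53_WINDOW_HALF
    win_hi = win_lo + 2 * TP53_WINDOW_HALF
    for _, s in samples_df.iterrows():
        if s["sample_class"] == "human_normal":
            continue
        case = case_data[s["case_id"]]
        wgd, loh = case["wgd"], case["loh"]
        purity = s["purity"]
        bg = (2, 2) if wgd else (1, 1)
        median_cn = sum(bg)
        if case["del_abund"]:
            fd, fa = rng.uniform(0.2, 0.3), rng.uniform(0.03, 0.07)
        else:
            fd, fa = rng.uniform(0.03, 0.07), rng.uniform(0.2, 0.3)
        # forced segments: TP53 window plus any spiked amp/del regions
        forced: dict[str, list] = {}
        if loh:
            tp53_state = (2, 0) if wgd else (1, 0)
        else:
            tp53_state = bg
        forced.setdefault(TP53_CHROM, []).append(
            (win_lo, win_hi, tp53_state, 1.0))
        model_info = case["models"].get(s["model_id"]) if s["model_id"] else None
        spike_list = []
        if s["model_id"]:
            spike_list = [sp for sp in case.get("cn_spikes", [])
                          if sp["model_id"] == s["model_id"]]
        for sp in spike_list:
            g = gene_by_name[sp["gene"]]
            state = ((10, 2) if wgd else (8, 1)) \
                if sp["alteration_class"] == "amplification" else (0, 0)
            forced.setdefault(g["chrom"], []).append(
                (max(0, g["start"] - 500_000), min(CHROM_LENGTH, g["end"] + 500_000),
                 state, 1.0))
        for chrom in CHROMOSOMES:
            fseg = sorted(forced.get(chrom, []))
            bounds = [0]
            for lo, hi, _, _ in fseg:
                bounds += [lo, hi]
            bounds.append(CHROM_LENGTH)
            piece = CHROM_LENGTH // config.segments_per_chromosome
            for gi in range(0, len(bounds) - 1):
                lo, hi = bounds[gi], bounds[gi + 1]
                is_forced = any(lo == f[0] and hi == f[1] for f in fseg)
                if hi <= lo:
                    continue
                if is_forced:
                    state, cp = next((f[2], f[3]) for f in fseg if f[0] == lo)
                    seg_rows.append(_segment_row(
                        rng, s, chrom, lo, hi, state, bg, purity,
                        median_cn, config, clone_prop=cp))
                    continue
                n_cuts = max(1, round((hi - lo) / piece))
                cuts = np.sort(rng.integers(lo + 1, hi, size=n_cuts - 1)) \
                    if n_cuts > 1 else np.array([], dtype=int)
                edges = [lo] + [int(c) for c in cuts] + [hi]
                for a, b in zip(edges[:-1], edges[1:]):
                    u = rng.random()
                    if u < fd and not _overlaps_reserved(chrom, a, b, reserved):
                        state = _event_state(rng, "loss", wgd)
                    elif u < fd + fa and not _overlaps_reserved(chrom, a, b, reserved):
                        state = _event_state(rng, "gain", wgd)
                    else:
                        state = bg
                    cp = 1.0
                    if state != bg and rng.random() < config.subclonal_event_prob:
                        cp = float(rng.uniform(0.2, 0.8))
                    seg_rows.append(_segment_row(
                        rng, s, chrom, a, b, state, bg, purity,
                        median_cn, config, clone_prop=cp))
        # B-allele fractions in the TP53 window
        n_snp = config.baf_snps_in_tp53_window
        positions = np.sort(rng.integers(win_lo + 1, win_hi, size=n_snp))
        cn_t, cn_b_major = sum(tp53_state), tp53_state[0]
        for pos in positions:
            if loh:
                cn_b = cn_b_major if rng.random() < 0.5 else tp53_state[1]
            else:
                cn_b = cn_t // 2
            denom = purity * cn_t + (1 - purity) * 2
            baf_true = (purity * cn_b + (1 - purity) * 1) / denom if denom else 0.5
            depth = max(1, int(rng.poisson(config.baf_mean_depth)))
            baf_obs = rng.binomial(depth, min(1.0, max(0.0, baf_true))) / depth
            baf_rows.append({"sample_id": s["sample_id"], "chrom": TP53_CHROM,
                             "pos": int(pos), "baf": baf_obs, "depth": depth})
    segments = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS + ["frac_cn"])
    baf = pd.DataFrame(baf_rows, columns=BAF_COLUMNS)
    return segments, baf


def _segment_row(rng, s, chrom, start, end, state, bg, purity,
                 median_cn, config, clone_prop=1.0):
    major, minor = state
    total = major + minor
    frac_cn = clone_prop * total + (1 - clone_prop) * sum(bg)
    tumor_cn = purity * frac_cn + (1 - purity) * 2
    ref_cn = purity * median_cn + (1 - purity) * 2
    log2 = np.log2(max(tumor_cn, 0.05) / ref_cn) + rng.normal(0, config.log2_noise_sd)
    length = end - start
    n_probes = max(1, int(round(length / 3000 * rng.uniform(0.7, 1.3))))
    coverage = max(1.0, rng.normal(config.tumor_mean_depth, 8.0))
    return {
        "sample_id": s["sample_id"], "chrom": chrom, "start": int(start),
        "end": int(end), "log2": float(log2), "n_probes": n_probes,
        "coverage": float(coverage), "major_cn": int(major),
        "minor_cn": int(minor), "frac_cn": float(frac_cn),
    }


def _emit_expression(rng, samples_df, case_data, config, gene_map):
    genes = list(gene_map["gene"])
    filler = [g for g in genes if g.startswith("G")]
    sig_sets = {}
    k = config.signature_genes_per_group
    for g in range(config.n_expression_groups):
        sig_sets[g + 1] = set(filler[g * k:(g + 1) * k])
    baseline = pd.Series(
        rng.normal(config.expression_baseline_mean,
                   config.expression_baseline_sd, size=len(genes)),
        index=genes)
    tumor_samples = samples_df[samples_df["sample_class"] != "human_normal"]
    centers, cols, group_truth = {}, {}, {}
    center_names = [f"CTR{i + 1}" for i in range(config.n_centers)]
    center_offsets = {
        c: rng.normal(0, config.center_effect_sd, size=len(genes))
        for c in center_names}
    effect = config.expression_effect_size * config.expression_noise_sd
    for _, s in tumor_samples.iterrows():
        case = case_data[s["case_id"]]
        group = case["group"]
        if rng.random() < config.cluster_shift_prob:
            group = int(rng.integers(config.n_expression_groups)) + 1
        group_truth[s["sample_id"]] = group
        center = center_names[int(rng.integers(config.n_centers))]
        centers[s["sample_id"]] = center
        vals = baseline.to_numpy() + rng.normal(
            0, config.expression_noise_sd, size=len(genes))
        vals = vals + center_offsets[center]
        sig_mask = np.array([g in sig_sets[group] for g in genes])
        vals = vals + effect * sig_mask
        cols[s["sample_id"]] = vals
    expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    # spiked arm alterations shift the target gene's expression
    for case in case_data.values():
        for sp in case.get("all_spikes", []):
            target = sp["gene"]
            shift = (-_EXPRESSION_SPIKE_DOWN
                     if sp["alteration_class"] == "deletion"
                     else _EXPRESSION_SPIKE_BOOST)
            for sid in sp["sample_ids"]:
                if sid in expr.columns:
                    expr.loc[target, sid] += shift
    expr = expr.clip(lower=0.0)
    if config.expression_na_fraction > 0:
        mask = rng.random(expr.shape) < config.expression_na_fraction
        expr = expr.mask(mask)
    return expr, centers, group_truth


def _emit_fusions(rng, samples_df, case_data, config, gene_map,
                  reserved_fusion_genes):
    rows = []
    pdx = samples_df[samples_df["sample_class"] != "human_normal"]
    # spiked fusions: every sample of the spiked model carries the event
    for case in case_data.values():
        for sp in case.get("all_spikes", []):
            if sp["alteration_class"] != "fusion":
                continue
            for sid in sp["sample_ids"]:
                rows.append({
                    "sample_id": sid, "gene5": sp["gene"],
                    "gene3": sp.get("partner", "G0000"), "in_frame": True,
                    "ffpm": float(rng.uniform(0.5, 3.0)), "annotation_tags": ""})
    # background fusions, some failing the normal-panel / FFPM filters
    pool = [g for g in gene_map["gene"] if g not in reserved_fusion_genes]
    sids = list(pdx["sample_id"])
    for _ in range(config.background_fusions_per_cohort):
        sid = str(rng.choice(sids))
        g5, g3 = rng.choice(pool, size=2, replace=False)
        u = rng.random()
        tags, ffpm = "", float(rng.uniform(0.2, 2.0))
        if u < 0.4:
            tags = str(rng.choice(NORMAL_FUSION_TAGS))
        elif u < 0.7:
            ffpm = float(rng.uniform(0.0, 0.1))
        rows.append({"sample_id": sid, "gene5": str(g5), "gene3": str(g3),
                     "in_frame": bool(rng.random() < 0.6), "ffpm": ffpm,
                     "annotation_tags": tags})
    df = pd.DataFrame(rows, columns=FUSION_COLUMNS)
    return df.sort_values(["sample_id", "gene5", "gene3"],
                          kind="stable").reset_index(drop=True)


def _assign_spikes(rng, spikes, model_ids, case_data, gene_by_name,
                   used_keys, config) -> list[dict]:
    """Attach planted arm alterations to distinct models; returns truth."""
    wanted = []
    for sp in spikes:
        for _ in range(int(sp.get("n_models", 1))):
            wanted.append(dict(sp))
    if not wanted:
        return []
    replace = len(wanted) > len(model_ids)
    chosen = rng.choice(model_ids, size=len(wanted), replace=replace)
    truth = []
    for sp, model_id in zip(wanted, chosen):
        model_id = str(model_id)
        case_id = model_id.split("-")[0]
        case = case_data[case_id]
        model_info = case["models"][model_id]
        sample_ids = [f"{model_id}-P{pi}"
                      for pi in range(config.passages_per_model)]
        rec = {"model_id": model_id, "case_id": case_id,
               "gene": sp["gene"], "alteration_class": sp["alteration_class"],
               "hotspot": sp.get("hotspot", ""),
               "partner": sp.get("partner", ""),
               "sample_ids": sample_ids}
        cls = sp["alteration_class"]
        if cls in ("non_silent_mutation", "variant_whitelist"):
            clone = _Clone(f"{model_id}.spike.{sp['gene']}", 1.0)
            clone.mutations.append(_random_mutation(
                rng, gene_by_name[sp["gene"]], used_keys, config,
                effect="non_silent", hotspot=sp.get("hotspot", ""),
                driver=True, whitelist=True, variant_type="snv"))
            model_info["spikes"].append(clone)
        elif cls in ("amplification", "deletion"):
            case.setdefault("cn_spikes", []).append(rec)
        case.setdefault("all_spikes", []).append(rec)
        truth.append(rec)
    return truth


def _build_truth(samples_df, case_data, group_truth, spike_truth) -> dict:
    flags = {}
    for _, s in samples_df.iterrows():
        case = case_data[s["case_id"]]
        is_normal = s["sample_class"] == "human_normal"
        flags[s["sample_id"]] = {
            "wgd": None if is_normal else case["wgd"],
            "tp53_loh": None if is_normal else case["loh"],
            "deletion_abundant": None if is_normal else case["del_abund"],
            "expression_group": group_truth.get(s["sample_id"]),
            "purity": None if is_normal else round(float(s["purity"]), 6),
        }
    clones = {}
    for case_id, case in case_data.items():
        entry = {"clonal": len(case["clonal"].mutations),
                 "subclones": {sc.clone_id: {"ccf": sc.ccf,
                                             "n_mutations": len(sc.mutations)}
                               for sc in case["subclones"]},
                 "models": {}}
        for model_id, mi in case["models"].items():
            entry["models"][model_id] = {
                "surviving_subclones": [sc.clone_id for sc in mi["subclones"]],
                "subclone_ccfs": {sc.clone_id: sc.ccf for sc in mi["subclones"]},
                "n_private": len(mi["private"].mutations),
            }
        clones[case_id] = entry
    spikes = [{k: v for k, v in rec.items()} for rec in spike_truth]
    return {"sample_flags": flags, "clones": clones, "arm_spikes": spikes,
            "anomalies": {"swaps": [], "contaminations": []}}


# ---------------------------------------------------------------------------
# anomaly planting
# ---------------------------------------------------------------------------

def plant_anomalies(cohort: Cohort, plan: dict) -> Cohort:
    """Apply sample swaps and contaminations; records them in the truth table.

    ``plan`` is ``{"swaps": [[a, b], ...],
    "contaminations": [[sample, by, fraction], ...]}``.  A swap exchanges the
    two samples' germline SNP profiles and variant tables; a contamination
    replaces the profile's VAFs by the convex mixture
    ``(1 - f) * vaf_sample + f * vaf_by``.
    """
    plan = {"swaps": plan.get("swaps", []),
            "contaminations": plan.get("contaminations", [])}
    known = set(cohort.samples["sample_id"])
    for a, b in plan["swaps"]:
        for sid in (a, b):
            if sid not in known:
                raise KeyError(f"unknown sample_id {sid!r} in swap plan")
    for a, b, frac in plan["contaminations"]:
        for sid in (a, b):
            if sid not in known:
                raise KeyError(f"unknown sample_id {sid!r} in contamination plan")
        if not 0.0 < frac < 1.0:
            raise ConfigError(f"contamination fraction {frac} outside (0, 1)")

    out = Cohort(
        samples=cohort.samples.copy(), mutations=cohort.mutations.copy(),
        snp_vaf=cohort.snp_vaf.copy(), snp_depth=cohort.snp_depth.copy(),
        segments=cohort.segments.copy(), expression=cohort.expression.copy(),
        baf=cohort.baf.copy(), fusions=cohort.fusions.copy(),
        gene_map=cohort.gene_map.copy(), truth=_copy.deepcopy(cohort.truth))
    truth_anom = out.truth.setdefault("anomalies",
                                      {"swaps": [], "contaminations": []})
    for a, b in plan["swaps"]:
        out.snp_vaf[[a, b]] = out.snp_vaf[[b, a]].to_numpy()
        out.snp_depth[[a, b]] = out.snp_depth[[b, a]].to_numpy()
        sid = out.mutations["sample_id"]
        out.mutations.loc[sid == a, "sample_id"] = "__tmp__"
        out.mutations.loc[sid == b, "sample_id"] = a
        out.mutations.loc[out.mutations["sample_id"] == "__tmp__", "sample_id"] = b
        truth_anom["swaps"].append([a, b])
    for a, b, frac in plan["contaminations"]:
        out.snp_vaf[a] = (1 - frac) * out.snp_vaf[a] + frac * out.snp_vaf[b]
        truth_anom["contaminations"].append([a, b, frac])
    return out
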