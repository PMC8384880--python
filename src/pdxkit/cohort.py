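"""Cohort container and plain-text serialization.

A :class:`Cohort` bundles the tables every analysis module consumes:

* ``samples`` — one row per sequenced specimen, positioned in the
  case → model → passage lineage forest,
* ``mutations`` — MAF-like long table of small-variant calls (1-based
  positions, VCF convention),
* ``snp_vaf`` / ``snp_depth`` — germline SNP panel, loci × samples,
* ``segments`` — SEG-like copy-number table (0-based half-open intervals,
  BED convention),
* ``expression`` — genes × samples,
* ``baf`` — heterozygous-SNP B-allele fractions around TP53,
* ``fusions`` — RNA fusion records,
* ``gene_map`` — synthetic gene coordinates,
* ``truth`` — planted ground truth (dict of plain records).

Everything serializes to uncompressed TSV/JSON plus one VCF 4.2 per tumor
sample, and round-trips losslessly through :func:`read_cohort`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MUTATION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "variant_type", "gene",
    "effect", "hotspot", "driver", "callers", "t_depth", "t_alt",
    "n_depth", "n_alt", "whitelist",
]

SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start", "end", "log2", "n_probes", "coverage",
    "major_cn", "minor_cn",
]

FUSION_COLUMNS = ["sample_id", "gene5", "gene3", "in_frame", "ffpm", "annotation_tags"]

BAF_COLUMNS = ["sample_id", "chrom", "pos", "baf", "depth"]

_FLOAT_FMT = "%.6g"


def mutation_keys(df: pd.DataFrame) -> set[tuple]:
    """Canonical (chrom, pos, ref, alt) identity keys of a mutation table."""
    return set(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))


def vcf_to_bed_interval(pos: int, ref: str) -> tuple[int, int]:
    """1-based VCF position + ref allele -> 0-based half-open interval."""
    return pos - 1, pos - 1 + len(ref)


def bed_to_vcf_pos(start: int) -> int:
    """0-based interval start -> 1-based position of its first base."""
    return start + 1


@dataclass
class Cohort:
    samples: pd.DataFrame
    mutations: pd.DataFrame
    snp_vaf: pd.DataFrame
    snp_depth: pd.DataFrame
    segments: pd.DataFrame
    expression: pd.DataFrame
    baf: pd.DataFrame
    fusions: pd.DataFrame
    gene_map: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def lineage_children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, row in self.samples.iterrows():
            parent = row["parent_sample_id"]
            if isinstance(parent, str) and parent:
                out.setdefault(parent, []).append(row["sample_id"])
        return out

    def mutations_of(self, sample_id: str) -> pd.DataFrame:
        return self.mutations[self.mutations["sample_id"] == sample_id]

    def equals(self, other: "Cohort") -> bool:
        try:
            assert_cohorts_equal(self, other)
        except AssertionError:
            return False
        return True


def assert_cohorts_equal(a: Cohort, b: Cohort, atol: float = 1e-9) -> None:
    pd.testing.assert_frame_equal(
        a.samples.reset_index(drop=True), b.samples.reset_index(drop=True),
        check_dtype=False, atol=atol)
    for name in ("mutations", "segments", "baf", "fusions", "gene_map"):
        pd.testing.assert_frame_equal(
            getattr(a, name).reset_index(drop=True),
            getattr(b, name).reset_index(drop=True),
            check_dtype=False, atol=atol)
    for name in ("snp_vaf", "snp_depth", "expression"):
        pd.testing.assert_frame_equal(
            getattr(a, name), getattr(b, name), check_dtype=False, atol=atol)
    assert json.dumps(a.truth, sort_keys=True) == json.dumps(b.truth, sort_keys=True)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pdxkit
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFF,Number=1,Type=String,Description="silent or non_silent">
##INFO=<ID=VT,Number=1,Type=String,Description="snv or indel">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">
##INFO=<ID=WL,Number=0,Type=Flag,Description="Known-somatic whitelist member">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=2,Type=Integer,Description="Ref and alt read counts">
"""


def _write_vcf(path: Path, muts: pd.DataFrame, sample_id: str,
               contigs: list[str]) -> None:
    has_normal = muts["n_depth"].notna().any() if len(muts) else False
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                "FORMAT", "TUMOR"] + (["NORMAL"] if has_normal else [])
        fh.write("\t".join(cols) + "\n")
        for _, m in muts.iterrows():
            info = (f"GENE={m['gene']};EFF={m['effect']};VT={m['variant_type']};"
                    f"CALLERS={m['callers'].replace(',', '|') if m['callers'] else '.'}")
            if m["whitelist"]:
                info += ";WL"
            t_ref = int(m["t_depth"]) - int(m["t_alt"])
            row = [m["chrom"], str(int(m["pos"])), ".", m["ref"], m["alt"], ".",
                   "PASS", info, "DP:AD", f"{int(m['t_depth'])}:{t_ref},{int(m['t_alt'])}"]
            if has_normal:
                nd, na = int(m["n_depth"]), int(m["n_alt"])
                row.append(f"{nd}:{nd - na},{na}")
            fh.write("\t".join(row) + "\n")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    """Write a cohort as TSV/JSON/VCF under ``out_dir``; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _tsv(df: pd.DataFrame, name: str, index: bool) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT,
                  na_rep="NA")
        written.append(path)

    _tsv(cohort.samples, "lineage.tsv", index=False)
    with open(out / "lineage.json", "w") as fh:
        json.dump(_samples_records(cohort.samples), fh, indent=1, sort_keys=True)
    written.append(out / "lineage.json")

    _tsv(cohort.mutations, "mutations.tsv", index=False)
    _tsv(cohort.segments, "segments.tsv", index=False)
    _tsv(cohort.snp_vaf, "snp_vaf.tsv", index=True)
    _tsv(cohort.snp_depth, "snp_depth.tsv", index=True)
    _tsv(cohort.expression, "expression.tsv", index=True)
    _tsv(cohort.baf, "baf.tsv", index=False)
    _tsv(cohort.fusions, "fusions.tsv", index=False)
    _tsv(cohort.gene_map, "gene_map.tsv", index=False)

    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    written.append(out / "truth.json")

    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contigs = sorted(set(cohort.mutations["chrom"]) | set(cohort.segments["chrom"]))
    for sid in sorted(set(cohort.mutations["sample_id"])):
        path = vcf_dir / f"{sid}.vcf"
        _write_vcf(path, cohort.mutations_of(sid), sid, contigs)
        written.append(path)
    return written


def _samples_records(samples: pd.DataFrame) -> list[dict]:
    recs = []
    for _, row in samples.iterrows():
        rec = {}
        for key, val in row.items():
            if isinstance(val, float) and np.isnan(val):
                rec[key] = None
            elif isinstance(val, (np.integer,)):
                rec[key] = int(val)
            elif isinstance(val, (np.floating,)):
                rec[key] = float(val)
            else:
                rec[key] = val
        recs.append(rec)
    return recs


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_lineage(path: str | Path) -> pd.DataFrame:
    """Read a lineage table from JSON (records) or TSV."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("model_id", "parent_sample_id"):
        if col in df:
            df[col] = df[col].where(df[col].notna(), None)
    return df


def read_cohort(in_dir: str | Path) -> Cohort:
    d = Path(in_dir)

    def _tsv(name: str, index_col=None) -> pd.DataFrame:
        return pd.read_csv(d / name, sep="\t", index_col=index_col,
                           na_values=["NA"], keep_default_na=False)

    samples = _tsv("lineage.tsv")
    for col in ("model_id", "parent_sample_id"):
        samples[col] = samples[col].where(samples[col].notna(), None)
    mutations = _tsv("mutations.tsv")
    mutations["callers"] = mutations["callers"].fillna("")
    fusions = _tsv("fusions.tsv")
    if len(fusions):
        fusions["annotation_tags"] = fusions["annotation_tags"].fillna("")
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    return Cohort(
        samples=samples,
        mutations=mutations,
        snp_vaf=_tsv("snp_vaf.tsv", index_col=0),
        snp_depth=_tsv("snp_depth.tsv", index_col=0),
        segments=_tsv("segments.tsv"),
        expression=_tsv("expression.tsv", index_col=0),
        baf=_tsv("baf.tsv"),
        fusions=fusions,
        gene_map=_tsv("gene_map.tsv"),
        truth=truth,
    )
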