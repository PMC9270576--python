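"""Readers, writers, run configuration and the pipeline driver.

Formats
-------
VCF 4.2 (via pysam): one alternate allele per record (multi-allelic sites
are rejected with the offending position named), FORMAT ``GT:DP:AD:GQ``,
INFO keys ``GENE, CSQ, AAPOS, AF_POP, CADD, SIFT, PP2``.  The VAF of a
call is derived from AD as alt / (ref + alt).  Float INFO fields are
normalised to six significant digits on read, matching the precision of
VCF's 32-bit floats, so tables written and re-read compare equal.

Flat TSV dialect: ``variants.tsv`` and ``genotypes.tsv`` with columns
mirroring the variant and genotype records; coordinates are 1-based
inclusive (stated in the header comment).  Sample labels travel in a
two-column TSV (sample_id, label).

The pipeline driver runs filter -> collapse -> exact test -> FDR ->
tiers (and the expression stages independently when configured), writes
every output table plus a JSON manifest with the config, seed and input
digests, and is deterministic for fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .burden import AssocConfig, run_burden_scan
from .filters import (
    GENOTYPE_COLUMNS,
    LOF_CLASSES,
    VARIANT_COLUMNS,
    FilterConfig,
    candidate_risk_mask,
    filter_log,
    genotype_qc_mask,
)
from .hotspot import RegionSpec, region_enrichment
from .rescue import GridConfig, compute_lfc, overlap_sets, select_down_up
from .tiers import DEFAULT_RULES, EvidenceProfile, assign_tier, tier_summary

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_config",
    "read_variants",
    "read_vcf",
    "write_vcf",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_expression_tsv",
    "read_gene_list",
    "run_pipeline",
]

_INFO_KEYS = ("GENE", "CSQ", "AAPOS", "AF_POP", "CADD", "SIFT", "PP2")


class SchemaError(ValueError):
    """Input does not match the documented schema."""


def _f6(x: float) -> float:
    return float(f"{x:.6g}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(variants: pd.DataFrame, genotypes: pd.DataFrame, samples, path) -> None:
    """Write an annotated single-alt-per-record VCF 4.2.

    ``samples`` fixes the column order; samples without a call at a site
    are written as homozygous reference with missing DP/AD/GQ.
    """
    header = pysam.VariantHeader()
    for contig in pd.unique(variants["chrom"]):
        header.contigs.add(str(contig), length=300_000_000)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Consequence class")
    header.info.add("AAPOS", 1, "Integer", "1-based protein residue")
    header.info.add("AF_POP", 1, "Float", "Highest population allele frequency")
    header.info.add("CADD", 1, "Float", "CADD Phred score")
    header.info.add("SIFT", 1, "String", "SIFT label")
    header.info.add("PP2", 1, "String", "PolyPhen2 label")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    samples = [str(s) for s in samples]
    for s in samples:
        header.add_sample(s)

    by_variant = {k: g for k, g in genotypes.groupby("variant_key")}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        ordered = variants.sort_values(["chrom", "pos"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info["GENE"] = str(row.gene)
            rec.info["CSQ"] = str(row.csq)
            if pd.notna(row.aa_pos):
                rec.info["AAPOS"] = int(row.aa_pos)
            if pd.notna(row.af_pop):
                rec.info["AF_POP"] = float(row.af_pop)
            if pd.notna(row.cadd):
                rec.info["CADD"] = float(row.cadd)
            if isinstance(row.sift, str) and row.sift:
                rec.info["SIFT"] = row.sift
            if isinstance(row.pp2, str) and row.pp2:
                rec.info["PP2"] = row.pp2
            calls = by_variant.get(row.variant_key)
            called = {}
            if calls is not None:
                for c in calls.itertuples(index=False):
                    called[c.sample_id] = c
            for s in samples:
                st = rec.samples[s]
                if s in called:
                    c = called[s]
                    ac = int(c.allele_count)
                    st["GT"] = (0, 1) if ac == 1 else (1, 1)
                    depth = int(c.depth)
                    ad_alt = int(round(float(c.vaf) * depth))
                    st["DP"] = depth
                    st["AD"] = (depth - ad_alt, ad_alt)
                    st["GQ"] = int(c.gq)
                else:
                    st["GT"] = (0, 0)
            out.write(rec)


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (variant table, genotype table).

    Only calls with at least one alternate allele enter the genotype
    table; VAF is derived from AD.  Multi-allelic records are rejected.
    """
    var_rows, gt_rows = [], []
    with pysam.VariantFile(str(path)) as vf:
        missing = [k for k in _INFO_KEYS if k not in vf.header.info]
        if missing:
            raise SchemaError(f"VCF header lacks required INFO keys: {missing}")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise SchemaError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; split alternates first"
                )
            alt = rec.alts[0]
            info = rec.info
            key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            var_rows.append(
                {
                    "variant_key": key,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "gene": info.get("GENE", ""),
                    "csq": info.get("CSQ", ""),
                    "aa_pos": info.get("AAPOS", np.nan),
                    "af_pop": _f6(info["AF_POP"]) if "AF_POP" in info else np.nan,
                    "cadd": _f6(info["CADD"]) if "CADD" in info else np.nan,
                    "sift": info.get("SIFT", ""),
                    "pp2": info.get("PP2", ""),
                }
            )
            for s, st in rec.samples.items():
                gt = st.get("GT")
                if gt is None or all(g in (None, 0) for g in gt):
                    continue
                ac = sum(1 for g in gt if g == 1)
                ad = st.get("AD")
                depth = st.get("DP")
                if ad is not None and ad[0] is not None:
                    tot = (ad[0] or 0) + (ad[1] or 0)
                    vaf = (ad[1] or 0) / tot if tot > 0 else np.nan
                else:
                    vaf = np.nan
                gt_rows.append(
                    {
                        "sample_id": s,
                        "variant_key": key,
                        "allele_count": ac,
                        "depth": depth if depth is not None else np.nan,
                        "vaf": vaf,
                        "gq": st.get("GQ") if st.get("GQ") is not None else np.nan,
                    }
                )
    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS)
    genotypes = pd.DataFrame(gt_rows, columns=GENOTYPE_COLUMNS)
    if not genotypes.empty:
        genotypes = genotypes.sort_values(["sample_id", "variant_key"], ignore_index=True)
        genotypes["allele_count"] = genotypes["allele_count"].astype(int)
        genotypes["depth"] = genotypes["depth"].astype(int)
        genotypes["gq"] = genotypes["gq"].astype(int)
    return variants, genotypes


# ---------------------------------------------------------------------------
# flat TSV dialect
# ---------------------------------------------------------------------------

_TSV_HEADER = "# carrierscan flat TSV; coordinates 1-based inclusive\n"


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        variants.to_csv(fh, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"variant TSV lacks columns: {missing}")
    return df[VARIANT_COLUMNS]


def write_genotypes_tsv(genotypes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        genotypes.to_csv(fh, sep="\t", index=False)


def read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"genotype TSV lacks columns: {missing}")
    return df[GENOTYPE_COLUMNS]


def write_labels_tsv(labels: pd.Series, path) -> None:
    labels.rename("label").rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if not {"sample_id", "label"} <= set(df.columns):
        raise SchemaError("label TSV needs columns sample_id and label")
    bad = set(df["label"]) - {"case", "control"}
    if bad:
        raise SchemaError(f"labels must be 'case'/'control', got {sorted(bad)}")
    return df.set_index("sample_id")["label"]


def read_variants(path, genotypes_path=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read variant + genotype tables from VCF or the TSV dialect."""
    p = Path(path)
    if p.suffix in (".vcf", ".bcf") or str(p).endswith(".vcf.gz"):
        return read_vcf(p)
    if genotypes_path is None:
        raise SchemaError("TSV input needs both a variant and a genotype table path")
    return read_variants_tsv(p), read_genotypes_tsv(genotypes_path)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in ("gene", "CON", "KD", "RE") if c not in df.columns]
    if missing:
        raise SchemaError(f"expression TSV lacks columns: {missing}")
    return df


def read_gene_list(path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-compatible mapping)."""

    out_dir: str
    variants: str | None = None
    genotypes: str | None = None
    labels: str | None = None
    expression: str | None = None
    gene_lists: dict = field(default_factory=dict)
    functional_evidence: str | None = None  # file of variant keys
    region_gene: str | None = None
    protein_length: int | None = None
    split_after: int | None = None
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    tier_rules: dict = field(default_factory=lambda: DEFAULT_RULES)

    def __post_init__(self) -> None:
        if self.variants is None and self.expression is None:
            raise SchemaError("config needs a variant input, an expression input or both")
        if self.variants is not None and self.labels is None:
            raise SchemaError("variant analysis needs a sample label table")
        if (self.region_gene is None) != (self.protein_length is None):
            raise SchemaError("region analysis needs both region_gene and protein_length")
        if self.protein_length is not None and self.split_after is None:
            raise SchemaError("region analysis needs split_after")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError("config must be a mapping")
    for sub, cls in (("filter", FilterConfig), ("assoc", AssocConfig), ("grid", GridConfig)):
        if sub in raw and isinstance(raw[sub], dict):
            try:
                if sub == "filter" and "coding_classes" in raw[sub]:
                    raw[sub]["coding_classes"] = frozenset(raw[sub]["coding_classes"])
                raw[sub] = cls(**raw[sub])
            except (TypeError, ValueError) as e:
                raise SchemaError(f"invalid {sub} config: {e}") from e
    try:
        return RunConfig(**raw)
    except TypeError as e:
        raise SchemaError(f"invalid config: {e}") from e


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (FilterConfig, AssocConfig, GridConfig)):
        d = asdict(obj)
        return {k: sorted(v) if isinstance(v, frozenset) else _jsonable(v) for k, v in d.items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _derive_tiers(variants, genotypes, labels, cfg: RunConfig) -> pd.DataFrame:
    """Evidence profiles and tiers for qualifying variants with case calls."""
    functional = set()
    if cfg.functional_evidence:
        functional = set(read_gene_list(cfg.functional_evidence))
    risk = variants.loc[candidate_risk_mask(variants, cfg.filter)].copy()
    ok = genotype_qc_mask(genotypes, cfg.filter) & (genotypes["allele_count"] >= 1)
    calls = genotypes.loc[ok].assign(label=lambda d: d["sample_id"].map(labels))
    case_counts = (
        calls[calls["label"] == "case"].groupby("variant_key")["sample_id"].nunique()
    )
    risk = risk[risk["variant_key"].isin(case_counts.index)]
    rows = []
    for v in risk.itertuples(index=False):
        profile = EvidenceProfile(
            is_lof=v.csq in LOF_CLASSES,
            absent_all_databases=bool(pd.isna(v.af_pop)),
            in_silico_damaging=bool(
                pd.notna(v.cadd)
                and v.cadd > cfg.filter.cadd_min
                and (v.sift == "deleterious" or v.pp2 in ("probably_damaging", "possibly_damaging"))
            ),
            functional_evidence=v.variant_key in functional,
            recurrent_in_cases=bool(case_counts.get(v.variant_key, 0) >= 2),
        )
        rows.append(
            {
                "variant_key": v.variant_key,
                "gene": v.gene,
                **{f: getattr(profile, f) for f in profile.__dataclass_fields__},
                "tier": assign_tier(profile, cfg.tier_rules),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages and write outputs + manifest.

    Returns the output directory.  Any stage failure raises with the
    stage name prefixed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "carrierscan",
        "version": __version__,
        "seed": cfg.seed,
        "config": _jsonable(
            {
                k: getattr(cfg, k)
                for k in (
                    "variants", "genotypes", "labels", "expression", "gene_lists",
                    "functional_evidence", "region_gene", "protein_length",
                    "split_after", "filter", "assoc", "grid", "tier_rules",
                )
            }
        ),
        "inputs": {},
        "stages": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for name in ("variants", "genotypes", "labels", "expression", "functional_evidence"):
        p = getattr(cfg, name)
        if p:
            manifest["inputs"][name] = _sha256(p)
    for name, p in cfg.gene_lists.items():
        manifest["inputs"][f"gene_list:{name}"] = _sha256(p)

    def stage(name):
        manifest["stages"].append(name)

    if cfg.variants:
        try:
            stage("read")
            variants, genotypes = read_variants(cfg.variants, cfg.genotypes)
            labels = read_labels_tsv(cfg.labels)
            stage("filter")
            log = filter_log(variants, genotypes, cfg.filter)
            log.to_csv(out / "filter_log.tsv", sep="\t", index=False)
            stage("burden")
            gene_table = run_burden_scan(variants, genotypes, labels, cfg.assoc, cfg.filter)
            gene_table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
            stage("tiers")
            tier_table = _derive_tiers(variants, genotypes, labels, cfg)
            tier_table.to_csv(out / "tier_table.tsv", sep="\t", index=False)
            if len(tier_table):
                summary = tier_summary(tier_table["tier"])
                (out / "tier_summary.json").write_text(json.dumps(summary, indent=2))
            if cfg.region_gene:
                stage("hotspot")
                spec = RegionSpec(protein_length=cfg.protein_length, split_after=cfg.split_after)
                risk = variants.loc[
                    candidate_risk_mask(variants, cfg.filter)
                    & (variants["gene"] == cfg.region_gene)
                    & variants["aa_pos"].notna()
                ]
                enr = region_enrichment(risk["aa_pos"].astype(int), spec)
                (out / "hotspot.json").write_text(
                    json.dumps(
                        {
                            "gene": cfg.region_gene,
                            "n_region1": enr.n_region1,
                            "n_region2": enr.n_region2,
                            "p": enr.result.p_two_sided,
                            "or_hat": enr.result.or_hat,
                            "ci_low": enr.result.ci_low,
                            "ci_high": enr.result.ci_high,
                        },
                        indent=2,
                    )
                )
        except SchemaError:
            raise
        except Exception as e:
            raise RuntimeError(f"stage {manifest['stages'][-1]!r} failed: {e}") from e

    if cfg.expression:
        try:
            stage("expression")
            counts = read_expression_tsv(cfg.expression)
            grid = compute_lfc(counts, cfg.grid)
            grid.to_csv(out / "grid_table.tsv", sep="\t", index=False)
            down, up = select_down_up(grid)
            lists = {"DOWN": sorted(down), "UP": sorted(up)}
            for name, p in cfg.gene_lists.items():
                lists[name] = read_gene_list(p)
            if len(lists) >= 2:
                stage("overlap")
                (out / "overlaps.json").write_text(
                    json.dumps(overlap_sets(lists), indent=2)
                )
        except SchemaError:
            raise
        except Exception as e:
            raise RuntimeError(f"stage {manifest['stages'][-1]!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
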