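"""Qualifying-variant filtering for annotated case-control calls.

The exclusion cascade mirrors a standard WES rare-variant design:

genotype QC   - drop calls with read depth < 20, alternate-allele
                fraction < 30% or genotype quality < 20 (thresholds are
                inclusive on the pass side; missing fields fail closed);
annotation    - drop non-coding and synonymous consequences, variants at
                or above 0.1% population frequency, and variants without
                strong in-silico support (CADD Phred > 20 and not called
                benign/tolerated by both SIFT and PolyPhen2).

Predicted loss-of-function consequences (nonsense, frameshift, splice)
pass the in-silico leg regardless of missing missense predictors, since
those scores are routinely unavailable for truncating alleles.  A
variant absent from every population database counts as rare.

Scalar predicates (`pass_genotype_qc`, `is_candidate_risk`) define the
semantics; the vectorised masks apply the same rules to whole tables and
are what the pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONSEQUENCE_CLASSES",
    "LOF_CLASSES",
    "DEFAULT_CODING_CLASSES",
    "FilterConfig",
    "VariantRecord",
    "GenotypeCall",
    "pass_genotype_qc",
    "is_candidate_risk",
    "genotype_qc_mask",
    "candidate_risk_mask",
    "first_failing_rule",
    "filter_log",
    "qualifying_variants",
]

CONSEQUENCE_CLASSES = frozenset(
    {
        "missense", "nonsense", "splice", "nonframeshift_deletion",
        "frameshift", "synonymous", "intronic", "utr", "upstream", "downstream",
    }
)
#: consequences treated as predicted loss of function
LOF_CLASSES = frozenset({"nonsense", "frameshift", "splice"})
#: non-silent consequences eligible as candidate risk variants
DEFAULT_CODING_CLASSES = frozenset(
    {"missense", "nonsense", "splice", "nonframeshift_deletion", "frameshift"}
)

VARIANT_COLUMNS = [
    "variant_key", "chrom", "pos", "ref", "alt", "gene", "csq",
    "aa_pos", "af_pop", "cadd", "sift", "pp2",
]
GENOTYPE_COLUMNS = ["sample_id", "variant_key", "allele_count", "depth", "vaf", "gq"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the exclusion cascade.

    Pass conditions are depth >= depth_min, vaf >= vaf_min, gq >= gq_min
    (exclusions are phrased strictly below threshold), af_pop < af_max
    and cadd > cadd_min (strict, "top 1% deleterious").

    predictor_rule:
        "either"  keep unless both SIFT and PolyPhen2 call the variant
                  tolerated/benign (default);
        "both"    require SIFT deleterious and PolyPhen2 damaging.
    """

    depth_min: float = 20.0
    vaf_min: float = 0.30
    gq_min: float = 20.0
    af_max: float = 0.001
    cadd_min: float = 20.0
    coding_classes: frozenset = field(default=DEFAULT_CODING_CLASSES)
    predictor_rule: str = "either"

    def __post_init__(self) -> None:
        for name in ("depth_min", "vaf_min", "gq_min", "af_max", "cadd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.af_max <= 1.0):
            raise ValueError("af_max must lie in [0, 1]")
        if self.predictor_rule not in ("either", "both"):
            raise ValueError("predictor_rule must be 'either' or 'both'")
        unknown = set(self.coding_classes) - CONSEQUENCE_CLASSES
        if unknown:
            raise ValueError(f"unknown consequence classes: {sorted(unknown)}")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele at a site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    csq: str
    aa_pos: int | None = None
    af_pop: float | None = None
    cadd_phred: float | None = None
    sift: str | None = None
    pp2: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.csq not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.csq!r}")
        if self.af_pop is not None and not (0.0 <= self.af_pop <= 1.0):
            raise ValueError("af_pop must lie in [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one variant."""

    sample_id: str
    variant_key: str
    allele_count: int
    depth: float | None
    vaf: float | None
    gq: float | None

    def __post_init__(self) -> None:
        if self.allele_count not in (0, 1, 2):
            raise ValueError("allele_count must be 0, 1 or 2")
        if self.vaf is not None and not np.isnan(self.vaf) and not (0.0 <= self.vaf <= 1.0):
            raise ValueError("vaf must lie in [0, 1]")
        if self.depth is not None and not np.isnan(self.depth) and self.depth < 0:
            raise ValueError("depth must be >= 0")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def pass_genotype_qc(call: GenotypeCall, cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff depth, VAF and GQ all reach their thresholds (fail closed)."""
    if _missing(call.depth) or _missing(call.vaf) or _missing(call.gq):
        return False
    return (
        call.depth >= cfg.depth_min
        and call.vaf >= cfg.vaf_min
        and call.gq >= cfg.gq_min
    )


def is_candidate_risk(v: VariantRecord, cfg: FilterConfig = FilterConfig()) -> bool:
    """True iff the variant survives the annotation exclusions."""
    if v.csq not in cfg.coding_classes:
        return False
    if not _missing(v.af_pop) and v.af_pop >= cfg.af_max:
        return False
    if v.csq in LOF_CLASSES:
        return True
    if _missing(v.cadd_phred) or v.cadd_phred <= cfg.cadd_min:
        return False
    if cfg.predictor_rule == "either":
        return not (v.sift == "tolerated" and v.pp2 == "benign")
    sift_damaging = v.sift == "deleterious"
    pp2_damaging = v.pp2 in ("probably_damaging", "possibly_damaging")
    return sift_damaging and pp2_damaging


# ---------------------------------------------------------------------------
# vectorised application to whole tables
# ---------------------------------------------------------------------------

def genotype_qc_mask(genotypes: pd.DataFrame, cfg: FilterConfig = FilterConfig()) -> pd.Series:
    depth = pd.to_numeric(genotypes["depth"], errors="coerce")
    vaf = pd.to_numeric(genotypes["vaf"], errors="coerce")
    gq = pd.to_numeric(genotypes["gq"], errors="coerce")
    return (depth >= cfg.depth_min) & (vaf >= cfg.vaf_min) & (gq >= cfg.gq_min)


def candidate_risk_mask(variants: pd.DataFrame, cfg: FilterConfig = FilterConfig()) -> pd.Series:
    csq = variants["csq"]
    coding = csq.isin(cfg.coding_classes)
    af = pd.to_numeric(variants["af_pop"], errors="coerce")
    rare = af.isna() | (af < cfg.af_max)
    lof = csq.isin(LOF_CLASSES)
    cadd = pd.to_numeric(variants["cadd"], errors="coerce")
    cadd_ok = cadd > cfg.cadd_min  # NaN compares False: missing scores fail
    if cfg.predictor_rule == "either":
        pred_ok = ~((variants["sift"] == "tolerated") & (variants["pp2"] == "benign"))
    else:
        pred_ok = (variants["sift"] == "deleterious") & (
            variants["pp2"].isin(["probably_damaging", "possibly_damaging"])
        )
    return coding & rare & (lof | (cadd_ok & pred_ok))


_QC_RULES = ("low_depth", "low_vaf", "low_gq")
_VARIANT_RULES = ("noncoding_or_silent", "common", "low_cadd", "benign_predictors")
FILTER_RULES = _QC_RULES + _VARIANT_RULES


def _variant_rule_frame(variants: pd.DataFrame, cfg: FilterConfig) -> pd.Series:
    """First failing annotation rule per variant ('' when retained)."""
    csq = variants["csq"]
    af = pd.to_numeric(variants["af_pop"], errors="coerce")
    cadd = pd.to_numeric(variants["cadd"], errors="coerce")
    lof = csq.isin(LOF_CLASSES)
    if cfg.predictor_rule == "either":
        pred_ok = ~((variants["sift"] == "tolerated") & (variants["pp2"] == "benign"))
    else:
        pred_ok = (variants["sift"] == "deleterious") & (
            variants["pp2"].isin(["probably_damaging", "possibly_damaging"])
        )
    rule = pd.Series("", index=variants.index, dtype=object)
    fail_pred = ~lof & ~pred_ok
    rule[fail_pred] = "benign_predictors"
    fail_cadd = ~lof & ~(cadd > cfg.cadd_min)
    rule[fail_cadd] = "low_cadd"
    fail_common = af.notna() & (af >= cfg.af_max)
    rule[fail_common] = "common"
    fail_csq = ~csq.isin(cfg.coding_classes)
    rule[fail_csq] = "noncoding_or_silent"
    return rule


def first_failing_rule(
    variants: pd.DataFrame, genotypes: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.Series:
    """First failing rule per genotype call, '' for retained calls.

    Rule order follows the cascade: depth, VAF, GQ, then the annotation
    exclusions of the underlying variant.  Every call is either retained
    or attributed to exactly one rule.
    """
    depth = pd.to_numeric(genotypes["depth"], errors="coerce")
    vaf = pd.to_numeric(genotypes["vaf"], errors="coerce")
    gq = pd.to_numeric(genotypes["gq"], errors="coerce")
    vrule = _variant_rule_frame(variants, cfg)
    per_call = genotypes["variant_key"].map(
        dict(zip(variants["variant_key"], vrule))
    ).fillna("")
    rule = per_call.copy()
    rule[~(gq >= cfg.gq_min)] = "low_gq"
    rule[~(vaf >= cfg.vaf_min)] = "low_vaf"
    rule[~(depth >= cfg.depth_min)] = "low_depth"
    return rule


def filter_log(
    variants: pd.DataFrame, genotypes: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Audit table: one row per genotype call with its first failing rule."""
    rule = first_failing_rule(variants, genotypes, cfg)
    return pd.DataFrame(
        {
            "variant_key": genotypes["variant_key"].to_numpy(),
            "sample_id": genotypes["sample_id"].to_numpy(),
            "first_failing_rule": rule.to_numpy(),
        }
    )


def qualifying_variants(
    variants: pd.DataFrame, genotypes: pd.DataFrame, cfg: FilterConfig = FilterConfig()
) -> pd.DataFrame:
    """Per-sample, per-gene qualifying-variant carrier table.

    A sample carries gene g iff it has at least one call with allele
    count >= 1 passing genotype QC on a candidate-risk variant of g.
    Returns columns (sample_id, gene, n_qualifying_variants), one row
    per carrier-gene pair.
    """
    unknown = set(genotypes["variant_key"]) - set(variants["variant_key"])
    if unknown:
        some = sorted(unknown)[:5]
        raise ValueError(f"genotype table references unknown variants: {some}")
    risk_keys = set(variants.loc[candidate_risk_mask(variants, cfg), "variant_key"])
    ok = (
        genotype_qc_mask(genotypes, cfg)
        & (genotypes["allele_count"] >= 1)
        & genotypes["variant_key"].isin(risk_keys)
    )
    kept = genotypes.loc[ok, ["sample_id", "variant_key"]].merge(
        variants[["variant_key", "gene"]], on="variant_key", how="left"
    )
    if kept.empty:
        return pd.DataFrame(columns=["sample_id", "gene", "n_qualifying_variants"])
    out = (
        kept.groupby(["sample_id", "gene"], as_index=False)
        .size()
        .rename(columns={"size": "n_qualifying_variants"})
    )
    return out.sort_values(["gene", "sample_id"], ignore_index=True)
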