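"""Synthetic cohorts and knockdown/rescue expression tables.

Generators with known ground truth for every downstream stage.

``simulate_cohort`` emulates the statistical structure of an annotated
rare-variant case-control cohort under a dominant carrier model: per
gene, carrier status is an independent Bernoulli draw per sample
(separate case/control probabilities for planted genes, one background
probability elsewhere), and each carrier receives exactly one
heterozygous qualifying variant in the gene.  Annotation fields of
non-qualifying variants are drawn from mixtures that place mass on both
sides of every filter threshold, with a configurable fraction exactly on
the boundaries (DP=20, VAF=0.30, GQ=20, AF=0.001, CADD=20), so the
filter cascade is exercised at its edges.  A configurable fraction of
genotype calls is seeded with a failing DP/VAF/GQ field; the ground
truth sidecar records the realized post-QC carrier counts, so filter
output can always be compared to truth exactly.

``simulate_rescue_counts`` emulates a three-condition (CON/KD/RE)
expression experiment with a single library per condition:
negative-binomial counts around log-normal baseline abundances, with
planted genes shifted down (or up) in KD by a configured log2 effect and
restored in RE.  Dispersion 0 means deterministic expected counts.

All randomness flows from one integer seed; sub-streams are derived from
it by fixed offsets, so output tables are byte-identical for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import (
    CONSEQUENCE_CLASSES,
    FilterConfig,
    GENOTYPE_COLUMNS,
    VARIANT_COLUMNS,
)

__all__ = [
    "CohortSimParams",
    "ExprSimParams",
    "SimulatedCohort",
    "SimulatedExpression",
    "simulate_cohort",
    "simulate_rescue_counts",
]

_NOISE_CSQ = sorted(CONSEQUENCE_CLASSES)
_NOISE_CSQ_W = np.array(
    [3.0 if c == "missense" else 2.0 if c == "synonymous" else 1.0 for c in _NOISE_CSQ]
)


@dataclass(frozen=True)
class CohortSimParams:
    """Study design of a synthetic annotated cohort.

    Defaults mirror a small discovery design: 37 cases vs 208 controls
    with one planted risk gene carried by ~4/37 cases and ~1/208
    controls over a polygenic null background.
    """

    n_cases: int = 37
    n_controls: int = 208
    n_genes: int = 500
    variants_per_gene: int = 3
    planted_gene_ids: tuple = ("GENE0001",)
    case_carrier_prob: float = 4.0 / 37.0
    control_carrier_prob: float = 1.0 / 208.0
    background_carrier_prob: float = 0.007
    qc_fail_fraction: float = 0.05
    annotation_boundary_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "variants_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in (
            "case_carrier_prob", "control_carrier_prob",
            "background_carrier_prob", "qc_fail_fraction",
            "annotation_boundary_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        object.__setattr__(self, "planted_gene_ids", tuple(self.planted_gene_ids))
        genes = {f"GENE{i + 1:04d}" for i in range(self.n_genes)}
        unknown = set(self.planted_gene_ids) - genes
        if unknown:
            raise ValueError(f"planted genes outside generated gene set: {sorted(unknown)}")


@dataclass(frozen=True)
class SimulatedCohort:
    variants: pd.DataFrame
    genotypes: pd.DataFrame
    labels: pd.Series  # sample_id -> 'case' / 'control'
    truth: pd.DataFrame  # per-gene planted flags and realized carrier counts
    params: CohortSimParams


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def _noise_annotations(rng: np.random.Generator, n: int, cfg: FilterConfig, boundary_frac: float):
    """Annotation draws spanning both sides of every threshold."""
    csq = rng.choice(_NOISE_CSQ, size=n, p=_NOISE_CSQ_W / _NOISE_CSQ_W.sum())
    af = np.where(
        rng.random(n) < 0.4,
        np.nan,  # absent from all databases counts as rare
        np.where(
            rng.random(n) < 0.5,
            rng.uniform(0.0, cfg.af_max, size=n),
            rng.uniform(cfg.af_max, 0.05, size=n),
        ),
    )
    cadd = np.where(
        rng.random(n) < 0.5,
        rng.uniform(0.0, cfg.cadd_min, size=n),
        rng.uniform(cfg.cadd_min, 45.0, size=n),
    )
    cadd = np.where(rng.random(n) < 0.1, np.nan, cadd)
    sift = rng.choice(["deleterious", "tolerated", ""], size=n, p=[0.4, 0.4, 0.2])
    pp2 = rng.choice(
        ["probably_damaging", "possibly_damaging", "benign", ""],
        size=n, p=[0.3, 0.2, 0.3, 0.2],
    )
    # boundary placement: exactly on the rarity / deleteriousness edges
    on_edge = rng.random(n) < boundary_frac
    which = rng.integers(0, 2, size=n)
    af = np.where(on_edge & (which == 0), cfg.af_max, af)
    cadd = np.where(on_edge & (which == 1), cfg.cadd_min, cadd)
    return csq, af, cadd, sift, pp2


def simulate_cohort(params: CohortSimParams) -> SimulatedCohort:
    """Generate an annotated synthetic cohort with ground truth."""
    cfg = FilterConfig()
    rng_var = np.random.default_rng([params.seed, 1])
    rng_carrier = np.random.default_rng([params.seed, 2])
    rng_geno = np.random.default_rng([params.seed, 3])
    rng_qc = np.random.default_rng([params.seed, 4])

    genes = _gene_names(params.n_genes)
    vpg = params.variants_per_gene
    n_var = params.n_genes * vpg
    gene_col = np.repeat(genes, vpg)
    slot = np.tile(np.arange(vpg), params.n_genes)
    chrom = np.array([f"chr{(i % 22) + 1}" for i in range(params.n_genes)])
    chrom_col = np.repeat(chrom, vpg)
    pos = (np.repeat(np.arange(params.n_genes), vpg) % 1000) * 100_000 + slot * 50 + 1_000
    bases = np.array(list("ACGT"))
    ref = bases[rng_var.integers(0, 4, size=n_var)]
    alt = bases[(np.searchsorted(bases, ref) + rng_var.integers(1, 4, size=n_var)) % 4]
    aa_pos = rng_var.integers(1, 701, size=n_var)

    csq, af, cadd, sift, pp2 = _noise_annotations(
        rng_var, n_var, cfg, params.annotation_boundary_fraction
    )
    # slot 0 of every gene is a guaranteed qualifying variant
    anchor = slot == 0
    n_anchor = int(anchor.sum())
    csq = np.where(anchor, rng_var.choice(["missense", "nonsense"], size=n_var, p=[0.85, 0.15]), csq)
    af[anchor] = np.where(rng_var.random(n_anchor) < 0.5, np.nan, rng_var.uniform(0.0, cfg.af_max * 0.5, size=n_anchor))
    cadd[anchor] = rng_var.uniform(cfg.cadd_min + 1.0, 45.0, size=n_anchor)
    sift = np.asarray(sift, dtype=object)
    pp2 = np.asarray(pp2, dtype=object)
    sift[anchor] = "deleterious"
    pp2[anchor] = "probably_damaging"

    # six significant digits: survives the float32 INFO fields of VCF
    af = np.array([float(f"{x:.6g}") if np.isfinite(x) else np.nan for x in af])
    cadd = np.array([float(f"{x:.6g}") if np.isfinite(x) else np.nan for x in cadd])

    variants = pd.DataFrame(
        {
            "variant_key": [
                f"{c}:{p}:{r}:{al}" for c, p, r, al in zip(chrom_col, pos, ref, alt)
            ],
            "chrom": chrom_col,
            "pos": pos.astype(int),
            "ref": ref,
            "alt": alt,
            "gene": gene_col,
            "csq": csq,
            "aa_pos": aa_pos.astype(int),
            "af_pop": af,
            "cadd": cadd,
            "sift": sift,
            "pp2": pp2,
        },
        columns=VARIANT_COLUMNS,
    )

    samples = [f"CASE{i + 1:04d}" for i in range(params.n_cases)] + [
        f"CTRL{i + 1:04d}" for i in range(params.n_controls)
    ]
    labels = pd.Series(
        ["case"] * params.n_cases + ["control"] * params.n_controls,
        index=pd.Index(samples, name="sample_id"),
        name="label",
    )
    n_samples = len(samples)

    planted = np.isin(genes, params.planted_gene_ids)
    prob = np.full((params.n_genes, n_samples), params.background_carrier_prob)
    prob[planted, : params.n_cases] = params.case_carrier_prob
    prob[planted, params.n_cases:] = params.control_carrier_prob
    carrier = rng_carrier.random((params.n_genes, n_samples)) < prob
    g_idx, s_idx = np.nonzero(carrier)
    n_calls = g_idx.size

    # each carrier receives one heterozygous call on the gene's anchor variant
    var_idx = g_idx * vpg  # slot 0
    depth = 30 + rng_geno.poisson(40.0, size=n_calls)
    ad_alt = rng_geno.binomial(depth, 0.5)
    gq = rng_geno.integers(40, 100, size=n_calls)

    # seed failing QC fields on a configured fraction of calls
    fail = rng_qc.random(n_calls) < params.qc_fail_fraction
    fail_kind = rng_qc.integers(0, 3, size=n_calls)
    low_depth = rng_qc.integers(5, int(cfg.depth_min), size=n_calls)
    sel = fail & (fail_kind == 0)
    depth = np.where(sel, low_depth, depth)
    ad_alt = np.where(sel, np.minimum(ad_alt, depth), ad_alt)
    sel = fail & (fail_kind == 1)
    ad_alt = np.where(sel, np.floor(depth * cfg.vaf_min * rng_qc.random(n_calls)), ad_alt)
    sel = fail & (fail_kind == 2)
    gq = np.where(sel, rng_qc.integers(0, int(cfg.gq_min), size=n_calls), gq)

    depth = depth.astype(int)
    ad_alt = ad_alt.astype(int)
    vaf = np.where(depth > 0, ad_alt / np.maximum(depth, 1), 0.0)
    genotypes = pd.DataFrame(
        {
            "sample_id": np.asarray(samples, dtype=object)[s_idx],
            "variant_key": variants["variant_key"].to_numpy()[var_idx],
            "allele_count": np.ones(n_calls, dtype=int),
            "depth": depth,
            "vaf": vaf,
            "gq": gq.astype(int),
        },
        columns=GENOTYPE_COLUMNS,
    ).sort_values(["sample_id", "variant_key"], ignore_index=True)

    passed = (depth >= cfg.depth_min) & (vaf >= cfg.vaf_min) & (gq >= cfg.gq_min)
    realized = np.zeros((params.n_genes, 2), dtype=int)
    is_case_call = s_idx < params.n_cases
    np.add.at(realized[:, 0], g_idx[passed & is_case_call], 1)
    np.add.at(realized[:, 1], g_idx[passed & ~is_case_call], 1)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "planted": planted,
            "case_carrier_prob": np.where(planted, params.case_carrier_prob, params.background_carrier_prob),
            "control_carrier_prob": np.where(planted, params.control_carrier_prob, params.background_carrier_prob),
            "case_carriers": realized[:, 0],
            "control_carriers": realized[:, 1],
        }
    )
    return SimulatedCohort(variants=variants, genotypes=genotypes, labels=labels, truth=truth, params=params)


# ---------------------------------------------------------------------------
# knockdown / rescue expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExprSimParams:
    """Design of a synthetic CON/KD/RE counts experiment.

    ``effect_log2fc`` is the planted knockdown magnitude; planted "down"
    genes have KD means shifted by -effect relative to both CON and RE
    (restored in rescue), "up" genes by +effect.  ``dispersion`` is the
    negative-binomial dispersion (variance = m + dispersion * m^2); zero
    means deterministic expected counts.
    """

    n_genes: int = 2000
    n_down_planted: int = 50
    n_up_planted: int = 50
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    library_sizes: tuple = (1e7, 1e7, 1e7)  # CON, KD, RE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_down_planted < 0 or self.n_up_planted < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_down_planted + self.n_up_planted > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.library_sizes) != 3 or any(s <= 0 for s in self.library_sizes):
            raise ValueError("library_sizes needs three positive totals")


@dataclass(frozen=True)
class SimulatedExpression:
    counts: pd.DataFrame  # gene, CON, KD, RE
    truth: pd.DataFrame  # gene, planted ('down' / 'up' / '')
    params: ExprSimParams


def simulate_rescue_counts(params: ExprSimParams) -> SimulatedExpression:
    """Generate a CON/KD/RE count table with planted rescue-design genes."""
    rng = np.random.default_rng([params.seed, 11])
    genes = [f"EXPR{i + 1:05d}" for i in range(params.n_genes)]
    status = np.array([""] * params.n_genes, dtype=object)
    status[: params.n_down_planted] = "down"
    status[params.n_down_planted: params.n_down_planted + params.n_up_planted] = "up"
    rng.shuffle(status)

    base_cpm = np.exp(rng.normal(np.log(100.0), 1.0, size=params.n_genes))
    fold = np.ones(params.n_genes)
    fold[status == "down"] = 2.0 ** (-params.effect_log2fc)
    fold[status == "up"] = 2.0 ** params.effect_log2fc
    means = {
        "CON": base_cpm * params.library_sizes[0] / 1e6,
        "KD": base_cpm * fold * params.library_sizes[1] / 1e6,
        "RE": base_cpm * params.library_sizes[2] / 1e6,
    }
    counts = {}
    for cond, m in means.items():
        if params.dispersion == 0.0:
            counts[cond] = np.round(m).astype(np.int64)
        else:
            lam = rng.gamma(1.0 / params.dispersion, m * params.dispersion)
            counts[cond] = rng.poisson(lam).astype(np.int64)
    table = pd.DataFrame({"gene": genes, **counts})
    truth = pd.DataFrame({"gene": genes, "planted": status})
    return SimulatedExpression(counts=table, truth=truth, params=params)
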