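"""Gene-level carrier collapsing and exact burden association.

Collapses each gene's qualifying variants to a binary carrier indicator
per sample (dominant model), tests case vs control carrier counts with
the exact machinery of :mod:`carrierscan.exact`, and controls the FDR by
Benjamini-Hochberg over all genes entering the scan.

A gene enters the scan when it has at least one qualifying variant call
in a case.  Significance is declared at the nominal p threshold; the
FDR-level claim is annotated only for genes with more than two
qualifying case variants, mirroring the discovery design the scan
reimplements.  An allele-count collapsing mode (two alleles from a
homozygous carrier) is available behind ``unit="alleles"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exact import ContingencyTable2x2, bh_fdr, exact_table_test
from .filters import FilterConfig, qualifying_variants

__all__ = ["AssocConfig", "collapse_gene", "run_burden_scan", "carrier_share"]

GENE_TABLE_COLUMNS = [
    "gene", "a", "b", "c", "d", "n_case_carriers", "n_control_carriers",
    "n_qualifying_case_variants", "p", "or_hat", "or_sample",
    "ci_low", "ci_high", "q", "significant", "fdr_claim",
]


@dataclass(frozen=True)
class AssocConfig:
    """Significance conventions of the burden scan."""

    nominal_p: float = 0.005
    fdr_level: float = 0.10
    min_case_variants_for_fdr_claim: int = 3
    alpha_ci: float = 0.05
    unit: str = "carriers"  # or "alleles"
    or_method: str = "precise"  # or "r-compat"

    def __post_init__(self) -> None:
        for name in ("nominal_p", "fdr_level", "alpha_ci"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_case_variants_for_fdr_claim < 1:
            raise ValueError("min_case_variants_for_fdr_claim must be >= 1")
        if self.unit not in ("carriers", "alleles"):
            raise ValueError("unit must be 'carriers' or 'alleles'")


def _check_labels(labels: pd.Series) -> pd.Series:
    labels = pd.Series(labels)
    bad = set(labels.unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"labels must be 'case'/'control', got {sorted(bad)}")
    return labels


def collapse_gene(carriers: pd.DataFrame, gene: str, labels: pd.Series) -> ContingencyTable2x2:
    """Carrier 2x2 table for one gene.

    ``carriers`` is the (sample_id, gene, n_qualifying_variants) table of
    :func:`carrierscan.filters.qualifying_variants`; ``labels`` maps every
    sample id to 'case' or 'control'.  Each sample counts at most once.
    """
    labels = _check_labels(labels)
    in_gene = carriers.loc[carriers["gene"] == gene, "sample_id"]
    unlabeled = set(in_gene) - set(labels.index)
    if unlabeled:
        raise ValueError(f"samples without case/control label: {sorted(unlabeled)[:5]}")
    carrier_labels = labels.loc[in_gene.unique()]
    a = int((carrier_labels == "case").sum())
    c = int((carrier_labels == "control").sum())
    n_cases = int((labels == "case").sum())
    n_controls = int((labels == "control").sum())
    return ContingencyTable2x2(a, n_cases - a, c, n_controls - c)


def run_burden_scan(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    labels: pd.Series,
    cfg: AssocConfig = AssocConfig(),
    filter_cfg: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Filter, collapse and exactly test every gene with case signal.

    Returns one row per gene with >= 1 qualifying case variant, ranked by
    ascending p, then descending odds ratio, then gene name; q-values are
    BH over exactly this gene set.
    """
    labels = _check_labels(labels)
    missing = set(genotypes["sample_id"].unique()) - set(labels.index)
    if missing:
        raise ValueError(f"samples without case/control label: {sorted(missing)[:5]}")
    carriers = qualifying_variants(variants, genotypes, filter_cfg)
    n_cases = int((labels == "case").sum())
    n_controls = int((labels == "control").sum())
    if carriers.empty:
        warnings.warn("no qualifying variants; empty burden scan", stacklevel=2)
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)

    carriers = carriers.assign(label=carriers["sample_id"].map(labels))
    is_case = carriers["label"] == "case"
    per_gene = carriers.groupby("gene").agg(
        n_case_carriers=("label", lambda s: int((s == "case").sum())),
        n_control_carriers=("label", lambda s: int((s == "control").sum())),
    )
    case_var_counts = (
        carriers.loc[is_case].groupby("gene")["n_qualifying_variants"].sum()
    )
    per_gene["n_qualifying_case_variants"] = (
        case_var_counts.reindex(per_gene.index).fillna(0).astype(int)
    )
    if cfg.unit == "alleles":
        from .filters import candidate_risk_mask, genotype_qc_mask

        risk_keys = set(variants.loc[candidate_risk_mask(variants, filter_cfg), "variant_key"])
        ok = (
            genotype_qc_mask(genotypes, filter_cfg)
            & (genotypes["allele_count"] >= 1)
            & genotypes["variant_key"].isin(risk_keys)
        )
        qual_calls = (
            genotypes.loc[ok]
            .merge(variants[["variant_key", "gene"]], on="variant_key")
            .assign(label=lambda d: d["sample_id"].map(labels))
        )
        allele_totals = qual_calls.pivot_table(
            index="gene", columns="label", values="allele_count",
            aggfunc="sum", fill_value=0,
        )

    rows = []
    scanned = per_gene[per_gene["n_qualifying_case_variants"] >= 1]
    if scanned.empty:
        warnings.warn("no gene with a qualifying case variant", stacklevel=2)
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    for gene, row in scanned.iterrows():
        a, c = int(row["n_case_carriers"]), int(row["n_control_carriers"])
        if cfg.unit == "alleles":
            a = int(allele_totals.at[gene, "case"]) if "case" in allele_totals else 0
            c = (
                int(allele_totals.at[gene, "control"])
                if "control" in allele_totals and gene in allele_totals.index
                else 0
            )
            table = ContingencyTable2x2(a, 2 * n_cases - a, c, 2 * n_controls - c)
        else:
            table = ContingencyTable2x2(a, n_cases - a, c, n_controls - c)
        res = exact_table_test(table, cfg.alpha_ci, method=cfg.or_method)
        rows.append(
            {
                "gene": gene,
                "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                "n_case_carriers": int(row["n_case_carriers"]),
                "n_control_carriers": int(row["n_control_carriers"]),
                "n_qualifying_case_variants": int(row["n_qualifying_case_variants"]),
                "p": res.p_two_sided,
                "or_hat": res.or_hat,
                "or_sample": res.or_sample,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p"] < cfg.nominal_p
    out["fdr_claim"] = (
        out["significant"]
        & (out["q"] < cfg.fdr_level)
        & (out["n_qualifying_case_variants"] >= cfg.min_case_variants_for_fdr_claim)
    )
    out = out.sort_values(
        ["p", "or_hat", "gene"], ascending=[True, False, True], ignore_index=True
    )
    return out[GENE_TABLE_COLUMNS]


def carrier_share(n_carriers: int, n_total: int) -> int:
    """Carrier share of a patient group as a whole percent (half-up)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_carriers <= n_total):
        raise ValueError("n_carriers must lie in [0, n_total]")
    return int(np.floor(100.0 * n_carriers / n_total + 0.5))
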