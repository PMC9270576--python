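"""Protein-region clustering test for coding variants.

Splits a protein into an N-terminal and a C-terminal region and asks
whether variant residues concentrate in one of them.  The 2x2 table
contrasts variant counts against non-variant residue counts per region
(residues minus variants), which is then handed to the exact 2x2
machinery.  Recurrent variants at one residue each count once per
variant; positions are not deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exact import ContingencyTable2x2, ExactTestResult, exact_table_test

__all__ = ["RegionSpec", "RegionEnrichment", "region_enrichment"]


@dataclass(frozen=True)
class RegionSpec:
    """Region 1 = residues 1..split_after; region 2 = the remainder."""

    protein_length: int
    split_after: int

    def __post_init__(self) -> None:
        if not (1 <= self.split_after < self.protein_length):
            raise ValueError("require 1 <= split_after < protein_length")

    @property
    def len_region1(self) -> int:
        return self.split_after

    @property
    def len_region2(self) -> int:
        return self.protein_length - self.split_after


@dataclass(frozen=True)
class RegionEnrichment:
    n_region1: int
    n_region2: int
    table: ContingencyTable2x2
    result: ExactTestResult


def region_enrichment(
    aa_positions,
    spec: RegionSpec,
    alpha: float = 0.05,
    *,
    method: str = "precise",
) -> RegionEnrichment:
    """Exact enrichment of variant positions in region 1 vs region 2.

    ``aa_positions`` are 1-based protein residues, one entry per variant.
    Raises on positions outside [1, protein_length], naming the value.
    """
    positions = [int(p) for p in aa_positions]
    for p in positions:
        if not (1 <= p <= spec.protein_length):
            raise ValueError(
                f"amino-acid position {p} outside [1, {spec.protein_length}]"
            )
    n1 = sum(p <= spec.split_after for p in positions)
    n2 = len(positions) - n1
    if n1 > spec.len_region1 or n2 > spec.len_region2:
        raise ValueError("more variants than residues in a region")
    table = ContingencyTable2x2(
        n1, spec.len_region1 - n1, n2, spec.len_region2 - n2
    )
    return RegionEnrichment(
        n_region1=n1,
        n_region2=n2,
        table=table,
        result=exact_table_test(table, alpha, method=method),
    )
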