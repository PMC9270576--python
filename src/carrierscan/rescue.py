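"""Knockdown/rescue expression grid analysis.

Given one expression library per condition — control (CON), knockdown
(KD) and rescue (RE, knockdown with re-expression) — each gene gets two
log2 fold-changes, KD/CON and KD/RE, after counts-per-million
normalisation with a pseudocount.  Thresholding both axes at +-cutoff
partitions genes into a 3x3 grid labelled A..I in row-major order
(y = KD/RE bin from high to low, x = KD/CON bin from low to high):

        x low   x mid   x high
 y high   A       B       C
 y mid    D       E       F
 y low    G       H       I

Group G (down in KD on both comparisons) is the DOWN group: genes
knocked down with the target and restored by rescue.  Group C is the UP
group.  Values exactly at +-cutoff belong to the outer bins.  With a
single library per condition no dispersion-based testing is attempted;
the grid is a descriptive classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "GridConfig",
    "CONDITIONS",
    "GROUPS",
    "compute_lfc",
    "assign_grid_group",
    "select_down_up",
    "overlap_sets",
]

CONDITIONS = ("CON", "KD", "RE")
GROUPS = tuple("ABCDEFGHI")
DOWN_GROUP = "G"
UP_GROUP = "C"


@dataclass(frozen=True)
class GridConfig:
    lfc_cutoff: float = 1.5
    pseudocount: float = 1.0
    library_sizes: dict | None = None  # override per-condition totals

    def __post_init__(self) -> None:
        if self.lfc_cutoff <= 0:
            raise ValueError("lfc_cutoff must be > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def _bin(x: float, cutoff: float) -> int:
    """-1 (<= -cutoff), 0 (interior), +1 (>= +cutoff); outer bins closed."""
    if x <= -cutoff:
        return -1
    if x >= cutoff:
        return 1
    return 0


_GRID = {
    (-1, 1): "A", (0, 1): "B", (1, 1): "C",
    (-1, 0): "D", (0, 0): "E", (1, 0): "F",
    (-1, -1): "G", (0, -1): "H", (1, -1): "I",
}


def assign_grid_group(lfc_kd_con: float, lfc_kd_re: float, cfg: GridConfig = GridConfig()) -> str:
    """Grid letter for one gene; raises on non-finite fold-changes."""
    if not (np.isfinite(lfc_kd_con) and np.isfinite(lfc_kd_re)):
        raise ValueError("fold-changes must be finite for grid assignment")
    return _GRID[(_bin(lfc_kd_con, cfg.lfc_cutoff), _bin(lfc_kd_re, cfg.lfc_cutoff))]


def compute_lfc(counts: pd.DataFrame, cfg: GridConfig = GridConfig()) -> pd.DataFrame:
    """Per-gene CPM, log2 fold-changes and grid group.

    ``counts`` needs columns gene, CON, KD, RE with non-negative counts.
    Normalisation is counts-per-million per library (library size = the
    column total unless overridden in the config), then
    lfc = log2((cpm_KD + pseudocount) / (cpm_ref + pseudocount)).
    """
    for col in ("gene",) + CONDITIONS:
        if col not in counts.columns:
            raise ValueError(f"missing column {col!r}")
    vals = counts[list(CONDITIONS)].astype(float)
    if (vals < 0).any().any():
        raise ValueError("expression counts must be non-negative")
    libsizes = {}
    for cond in CONDITIONS:
        if cfg.library_sizes and cond in cfg.library_sizes:
            libsizes[cond] = float(cfg.library_sizes[cond])
        else:
            libsizes[cond] = float(vals[cond].sum())
        if libsizes[cond] <= 0:
            raise ValueError(f"library size for {cond} must be positive")
    cpm = {c: vals[c] / libsizes[c] * 1e6 for c in CONDITIONS}
    pc = cfg.pseudocount
    lfc_kd_con = np.log2((cpm["KD"] + pc) / (cpm["CON"] + pc))
    lfc_kd_re = np.log2((cpm["KD"] + pc) / (cpm["RE"] + pc))
    out = pd.DataFrame(
        {
            "gene": counts["gene"].to_numpy(),
            "expr_con": cpm["CON"].to_numpy(),
            "expr_kd": cpm["KD"].to_numpy(),
            "expr_re": cpm["RE"].to_numpy(),
            "lfc_kd_con": lfc_kd_con.to_numpy(),
            "lfc_kd_re": lfc_kd_re.to_numpy(),
        }
    )
    out["group"] = [
        assign_grid_group(x, y, cfg)
        for x, y in zip(out["lfc_kd_con"], out["lfc_kd_re"])
    ]
    return out


def select_down_up(records: pd.DataFrame) -> tuple[set, set]:
    """(DOWN, UP) gene sets = grid groups G and C; always disjoint."""
    down = set(records.loc[records["group"] == DOWN_GROUP, "gene"])
    up = set(records.loc[records["group"] == UP_GROUP, "gene"])
    return down, up


def overlap_sets(named_lists: dict, *, casefold: bool = False) -> dict:
    """Exclusive region counts of the Venn partition of named gene lists.

    Keys of the result are '&'-joined sorted list names; a key contains
    the genes present in exactly those lists.  Symbols are deduplicated
    within each list (case-sensitively unless ``casefold``).
    """
    if len(named_lists) < 2:
        raise ValueError("need at least two lists to overlap")
    if any(not str(name) for name in named_lists):
        raise ValueError("list names must be non-empty")
    sets = {
        name: {str(g).casefold() if casefold else str(g) for g in genes}
        for name, genes in named_lists.items()
    }
    names = sorted(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            members = set.intersection(*(sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    members = members - sets[n]
            regions["&".join(inside)] = len(members)
    return regions
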