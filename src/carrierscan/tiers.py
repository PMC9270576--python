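"""Evidence-based risk tiers for qualifying variants.

A deliberately small, configurable stand-in for guideline-style
(ACMG-AMP-like) evidence combination over five boolean evidence flags.
Because sporadic-cohort variants lack segregation data, the tiers are
named "established risk" / "likely risk" / "uncertain risk" rather than
pathogenic / likely pathogenic.  The rule table is data, not code: the
default rules below are one monotone choice, and alternative tables can
be supplied (e.g. from YAML) and are validated on load.  This module is
a framework for reproducible tiering, not a re-implementation of any
specific curation panel's per-variant judgments.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "EVIDENCE_FLAGS",
    "TIERS",
    "EvidenceProfile",
    "DEFAULT_RULES",
    "assign_tier",
    "tier_summary",
]

EVIDENCE_FLAGS = (
    "is_lof",
    "absent_all_databases",
    "in_silico_damaging",
    "functional_evidence",
    "recurrent_in_cases",
)
TIERS = ("established_risk", "likely_risk", "uncertain_risk")


@dataclass(frozen=True)
class EvidenceProfile:
    """Boolean evidence for one variant.

    is_lof: nonsense / frameshift / splice consequence.
    absent_all_databases: not seen in any population database.
    in_silico_damaging: CADD > 20 and at least one damaging predictor.
    functional_evidence: failed a functional (e.g. rescue) assay.
    recurrent_in_cases: observed in >= 2 unrelated patients.
    """

    is_lof: bool = False
    absent_all_databases: bool = False
    in_silico_damaging: bool = False
    functional_evidence: bool = False
    recurrent_in_cases: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (bool, np.bool_)):
                raise ValueError(f"{f.name} must be boolean, got {v!r}")


#: default rule table: established requires functional proof plus either a
#: truncating consequence or a novel, damaging, recurrent missense; likely
#: requires any two of the four primary evidence lines.
DEFAULT_RULES = {
    "established": {
        "all_of": ["functional_evidence"],
        "any_of": [
            ["is_lof"],
            ["absent_all_databases", "in_silico_damaging", "recurrent_in_cases"],
        ],
    },
    "likely": {
        "min_count": 2,
        "among": [
            "is_lof",
            "absent_all_databases",
            "in_silico_damaging",
            "functional_evidence",
        ],
    },
}


def _validate_rules(rules: dict) -> None:
    if not isinstance(rules, dict) or set(rules) != {"established", "likely"}:
        raise ValueError("rule table needs exactly the keys 'established' and 'likely'")
    est, lik = rules["established"], rules["likely"]
    if not isinstance(est, dict) or set(est) != {"all_of", "any_of"}:
        raise ValueError("'established' needs 'all_of' and 'any_of'")
    flags = set(EVIDENCE_FLAGS)
    if not set(est["all_of"]) <= flags:
        raise ValueError(f"unknown flags in all_of: {est['all_of']}")
    for grp in est["any_of"]:
        if not set(grp) <= flags:
            raise ValueError(f"unknown flags in any_of group: {grp}")
    if not isinstance(lik, dict) or set(lik) != {"min_count", "among"}:
        raise ValueError("'likely' needs 'min_count' and 'among'")
    if not set(lik["among"]) <= flags:
        raise ValueError(f"unknown flags in among: {lik['among']}")
    if not (isinstance(lik["min_count"], int) and lik["min_count"] >= 1):
        raise ValueError("min_count must be a positive integer")


def assign_tier(e: EvidenceProfile, rules: dict = DEFAULT_RULES) -> str:
    """Deterministically map an evidence profile to exactly one tier."""
    _validate_rules(rules)
    est = rules["established"]
    established = all(getattr(e, f) for f in est["all_of"]) and any(
        all(getattr(e, f) for f in grp) for grp in est["any_of"]
    )
    if established:
        return "established_risk"
    lik = rules["likely"]
    if sum(bool(getattr(e, f)) for f in lik["among"]) >= lik["min_count"]:
        return "likely_risk"
    return "uncertain_risk"


def tier_summary(tiers) -> dict:
    """Counts and whole percentages (rounded half-up) per tier.

    Also reports the combined high-risk share (established + likely).
    """
    tiers = list(tiers)
    if not tiers:
        raise ValueError("need at least one tiered variant")
    bad = set(tiers) - set(TIERS)
    if bad:
        raise ValueError(f"unknown tiers: {sorted(bad)}")
    total = len(tiers)

    def pct(k: int) -> int:
        return int(np.floor(100.0 * k / total + 0.5))

    counts = {t: tiers.count(t) for t in TIERS}
    high = counts["established_risk"] + counts["likely_risk"]
    return {
        "total": total,
        "counts": counts,
        "percent": {t: pct(counts[t]) for t in TIERS},
        "high_risk_count": high,
        "high_risk_percent": pct(high),
    }
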