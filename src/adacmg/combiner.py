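"""Combine an evidence profile into the five-tier ACMG-AMP classification.

The combining rules operate on *strength-class counts* only — how many
very-strong (PVS), strong (PS), moderate (PM) and supporting (PP) pathogenic
codes, and how many stand-alone (BA), strong (BS) and supporting (BP) benign
codes are active — never on individual codes. The 2015 categorical rule
table is the default and can be overridden from config.

A strict contradiction rule applies first: any co-occurrence of
pathogenic-side and benign-side evidence yields a variant of uncertain
significance (VUS), with no strength-weighted arbitration. Profiles that
satisfy no rule are likewise VUS ("insufficient"). When both a Pathogenic
and a Likely-pathogenic rule fire, Pathogenic wins (and Benign over
Likely-benign).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .model import (
    BENIGN_CLASSES,
    PATHOGENIC_CLASSES,
    STRENGTH_CLASSES,
    EvidenceProfile,
    Tier,
    strength_class,
)

__all__ = ["RuleTable", "DEFAULT_RULE_TABLE", "strength_counts", "classify", "explain", "Explanation"]

#: A rule is a minimum-count requirement over strength classes.
Rule = dict[str, int]


def _describe(rule: Rule) -> str:
    return " + ".join(f"{n} {cls}" for cls, n in rule.items())


@dataclass(frozen=True)
class RuleTable:
    """Minimum-count rules for each non-VUS tier, evaluated by precedence."""

    pathogenic: tuple[Rule, ...] = (
        {"PVS": 1, "PS": 1},
        {"PVS": 1, "PM": 2},
        {"PVS": 1, "PM": 1, "PP": 1},
        {"PVS": 1, "PP": 2},
        {"PS": 2},
        {"PS": 1, "PM": 3},
        {"PS": 1, "PM": 2, "PP": 2},
        {"PS": 1, "PM": 1, "PP": 4},
    )
    likely_pathogenic: tuple[Rule, ...] = (
        {"PVS": 1, "PM": 1},
        {"PS": 1, "PM": 1},
        {"PS": 1, "PP": 2},
        {"PM": 3},
        {"PM": 2, "PP": 2},
        {"PM": 1, "PP": 4},
    )
    benign: tuple[Rule, ...] = (
        {"BA": 1},
        {"BS": 2},
    )
    likely_benign: tuple[Rule, ...] = (
        {"BS": 1, "BP": 1},
        {"BP": 2},
    )

    def __post_init__(self):
        for rules in (self.pathogenic, self.likely_pathogenic, self.benign, self.likely_benign):
            for rule in rules:
                unknown = set(rule) - set(STRENGTH_CLASSES)
                if unknown:
                    raise ValueError(f"rule references unknown strength classes: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RuleTable":
        kwargs = {}
        for tier_name in ("pathogenic", "likely_pathogenic", "benign", "likely_benign"):
            if tier_name in d:
                kwargs[tier_name] = tuple({str(k): int(v) for k, v in rule.items()} for rule in d[tier_name])
        return cls(**kwargs)


DEFAULT_RULE_TABLE = RuleTable()


def strength_counts(p: EvidenceProfile) -> dict[str, int]:
    """Count active codes per strength class; all seven classes are present."""
    counts = Counter(strength_class(code) for code in p)
    return {cls: counts.get(cls, 0) for cls in STRENGTH_CLASSES}


def _fired(rules: tuple[Rule, ...], counts: dict[str, int]) -> list[Rule]:
    return [r for r in rules if all(counts[cls] >= n for cls, n in r.items())]


@dataclass(frozen=True)
class Explanation:
    """Classification outcome with the rules that produced it."""

    tier: Tier
    reason: str  # "rule", "contradictory" or "insufficient"
    fired_rules: tuple[str, ...] = ()

    def __str__(self) -> str:
        if self.reason == "rule":
            return f"{self.tier.label}: {'; '.join(self.fired_rules)}"
        return f"{self.tier.label}: {self.reason}"


def explain(p: EvidenceProfile, table: RuleTable | None = None) -> Explanation:
    """Classify a profile and report which rules fired (or why none did)."""
    table = table or DEFAULT_RULE_TABLE
    counts = strength_counts(p)
    p_side = sum(counts[c] for c in PATHOGENIC_CLASSES)
    b_side = sum(counts[c] for c in BENIGN_CLASSES)
    if p_side > 0 and b_side > 0:
        return Explanation(Tier.VUS, "contradictory")
    for tier, rules in (
        (Tier.PATHOGENIC, table.pathogenic),
        (Tier.LIKELY_PATHOGENIC, table.likely_pathogenic),
        (Tier.BENIGN, table.benign),
        (Tier.LIKELY_BENIGN, table.likely_benign),
    ):
        fired = _fired(rules, counts)
        if fired:
            return Explanation(tier, "rule", tuple(_describe(r) for r in fired))
    return Explanation(Tier.VUS, "insufficient")


def classify(p: EvidenceProfile, table: RuleTable | None = None) -> Tier:
    """Map an evidence profile to its five-tier classification (total function)."""
    return explain(p, table).tier
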