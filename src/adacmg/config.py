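"""Run configuration: thresholds, applicability, rule table, TM ranges.

Config files are YAML or JSON with any of the keys::

    thresholds: {ba1_min: 0.05, bs1_min: 0.001}
    applicability_excluded: {PM3: "reason", ...}   # full override
    rule_table: {pathogenic: [{PVS: 1, PS: 1}, ...], ...}
    tm_ranges: {PSEN1: [[83, 103], ...], ...}
    seed: 0

Defaults reproduce the dominant-AD settings: the PM3/PP4/BS2/BP1/BP2
exclusion profile and the 2015 categorical combining table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .combiner import RuleTable
from .evidence import ApplicabilityProfile, FrequencyThresholds

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    thresholds: FrequencyThresholds = field(default_factory=FrequencyThresholds)
    applicability: ApplicabilityProfile = field(default_factory=ApplicabilityProfile)
    rule_table: RuleTable = field(default_factory=RuleTable)
    tm_ranges: dict[str, list[tuple[int, int]]] | None = None
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config file; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = data or {}
    cfg = RunConfig()
    if "thresholds" in data:
        cfg.thresholds = FrequencyThresholds(**data["thresholds"])
    if "applicability_excluded" in data:
        cfg.applicability = ApplicabilityProfile(dict(data["applicability_excluded"]))
    if "rule_table" in data:
        cfg.rule_table = RuleTable.from_dict(data["rule_table"])
    if "tm_ranges" in data:
        cfg.tm_ranges = {
            gene: [(int(lo), int(hi)) for lo, hi in ranges]
            for gene, ranges in data["tm_ranges"].items()
        }
    if "seed" in data:
        cfg.seed = int(data["seed"])
    return cfg
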