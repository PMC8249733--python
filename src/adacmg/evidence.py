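"""Evidence engine: derive ACMG-AMP criterion codes from variant annotations.

Four criteria are computed here, the rest are curator-supplied input:

* **PM2** — absence from ESP6500, 1000 Genomes and ExAC. The three genes act
  in an autosomal-dominant mode, so absence from large general-population
  cohorts is moderate pathogenic evidence.
* **BA1 / BS1** — stand-alone / strong benign evidence from a high allele
  frequency. BA1 uses the standard 5% stand-alone cutoff; BS1 has no
  universally agreed cutoff for these genes and defaults to 0.1%.
* **PP3 / BP4** — in-silico consensus. PP3 requires *every* available tool to
  call the variant damaging; any disagreement withholds the code. BP4 mirrors
  this with unanimous benign calls. Missense variants use the ten
  protein-level tools, splicing variants the two splice-site tools.
* **PS3 / BS3** — functional evidence on amyloid-beta readouts. PS3 requires
  at least one study showing an increased Aβ42/Aβ40 ratio or increased total
  Aβ and none showing no effect; BS3 requires all studies to show no effect;
  conflicting studies yield neither.

An applicability profile removes criteria that make no sense for
autosomal-dominant, incompletely penetrant Alzheimer's disease (PM3, PP4,
BS2, BP1, BP2 by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model import (
    ALL_CODES,
    MISSENSE_TOOLS,
    SPLICE_TOOLS,
    AnnotatedVariant,
    Domain,
    EvidenceProfile,
    FunctionalResult,
    InSilicoPredictions,
    PopulationFrequencies,
    Effect,
    Variant,
    VariantType,
    Verdict,
)

__all__ = [
    "ApplicabilityProfile",
    "FrequencyThresholds",
    "InsufficientPredictionsError",
    "filter_applicable",
    "assess_pm2",
    "assess_frequency_benign",
    "assess_insilico",
    "assess_functional",
    "flag_candidate_null",
    "derive_domain",
    "build_profile",
]

logger = logging.getLogger(__name__)

#: Criteria excluded for autosomal-dominant AD, with one-line rationales.
DEFAULT_EXCLUSIONS: dict[str, str] = {
    "PM3": "in-trans with a pathogenic variant applies to recessive disorders; AD is dominant",
    "PP4": "a family history of AD is not a highly specific clinical phenotype",
    "BS2": "penetrance is incomplete at early ages, so healthy carriers are uninformative",
    "BP1": "missense is the primary disease mechanism in these genes, not truncation",
    "BP2": "observation in cis/trans in healthy carriers fails for the same penetrance reason as BS2",
}


@dataclass(frozen=True)
class ApplicabilityProfile:
    """Partition of the 28 criterion codes into allowed and excluded sets."""

    excluded: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_EXCLUSIONS))

    def __post_init__(self):
        unknown = set(self.excluded) - ALL_CODES
        if unknown:
            raise ValueError(f"unknown codes in applicability profile: {sorted(unknown)}")

    @property
    def allowed(self) -> frozenset[str]:
        return ALL_CODES - set(self.excluded)


@dataclass(frozen=True)
class FrequencyThresholds:
    """Allele-frequency cutoffs for benign evidence.

    ``ba1_min`` is the stand-alone cutoff (default 5%); ``bs1_min`` the
    strong cutoff (default 0.1%, configurable — no published cutoff exists
    for these genes).
    """

    ba1_min: float = 0.05
    bs1_min: float = 0.001

    def __post_init__(self):
        if not (0.0 < self.bs1_min < self.ba1_min <= 1.0):
            raise ValueError(
                f"require 0 < bs1_min < ba1_min <= 1, got bs1_min={self.bs1_min}, ba1_min={self.ba1_min}"
            )


class InsufficientPredictionsError(ValueError):
    """No in-silico tool is available for a variant that requires one."""


def filter_applicable(
    codes: Iterable[str], profile: ApplicabilityProfile | None = None
) -> frozenset[str]:
    """Drop criterion codes that are not applicable to dominant AD.

    Logs one line per removed code with the profile's rationale.
    """
    profile = profile or ApplicabilityProfile()
    codes = frozenset(codes)
    unknown = codes - ALL_CODES
    if unknown:
        raise ValueError(f"unknown criterion codes: {sorted(unknown)}")
    removed = codes & set(profile.excluded)
    for code in sorted(removed):
        logger.info("dropping %s: %s", code, profile.excluded[code])
    return codes - removed


def assess_pm2(freqs: PopulationFrequencies) -> bool:
    """PM2: true iff the variant is absent from all three population sources."""
    return freqs.absent_everywhere()


def assess_frequency_benign(
    freqs: PopulationFrequencies, thresholds: FrequencyThresholds | None = None
) -> frozenset[str]:
    """Benign frequency evidence: {BA1}, {BS1} or the empty set, never both."""
    thresholds = thresholds or FrequencyThresholds()
    mx = freqs.max_present()
    if mx is None:
        return frozenset()
    if mx >= thresholds.ba1_min:
        return frozenset({"BA1"})
    if mx >= thresholds.bs1_min:
        return frozenset({"BS1"})
    return frozenset()


def assess_insilico(
    preds: InSilicoPredictions, variant_type: VariantType
) -> str | None:
    """In-silico consensus: 'PP3', 'BP4' or None.

    Unanimous damaging verdicts across the available tools give PP3,
    unanimous benign verdicts give BP4, any disagreement gives None.
    Tools reporting ``unavailable`` are excluded from the consensus.
    Only missense and splicing variants are assessable.

    Raises
    ------
    InsufficientPredictionsError
        If the variant type is assessable but no tool has a verdict.
    """
    if variant_type is VariantType.MISSENSE:
        tools = MISSENSE_TOOLS
    elif variant_type is VariantType.SPLICING:
        tools = SPLICE_TOOLS
    else:
        return None
    available = preds.available(tools)
    if not available:
        raise InsufficientPredictionsError(
            f"no in-silico tool available for a {variant_type.value} variant"
        )
    verdicts = set(available.values())
    if verdicts == {Verdict.DAMAGING}:
        return "PP3"
    if verdicts == {Verdict.BENIGN}:
        return "BP4"
    return None


def assess_functional(results: Iterable[FunctionalResult]) -> str | None:
    """Functional evidence on Aβ readouts: 'PS3', 'BS3' or None.

    PS3 when at least one study shows increased Aβ42/Aβ40 ratio or increased
    total Aβ and no study shows no effect; BS3 when all (≥1) studies show no
    effect; None for an empty list or conflicting studies.
    """
    results = list(results)
    if not results:
        return None
    pathogenic = any(
        r.effect in (Effect.INCREASED_AB42_40_RATIO, Effect.INCREASED_TOTAL_AB)
        for r in results
    )
    null = any(r.effect is Effect.NO_EFFECT for r in results)
    if pathogenic and not null:
        return "PS3"
    if null and not pathogenic:
        if all(r.effect is Effect.NO_EFFECT for r in results):
            return "BS3"
        return None
    if pathogenic and null:
        return None  # conflicting evidence across studies
    return None  # only 'other' effects


def flag_candidate_null(variant: Variant) -> bool:
    """True for variant types that could abolish the protein product.

    Used only to warn when such a variant lacks a curated PVS1; PVS1 itself
    is never auto-assigned (loss of function is not an established AD
    mechanism for APP).
    """
    return variant.variant_type in (
        VariantType.FRAMESHIFT,
        VariantType.SPLICING,
        VariantType.CNV,
    )


_RESIDUE_RE = re.compile(r"(?:p\.)?[A-Za-z*]{1,3}?(\d+)")


def derive_domain(
    variant: Variant, tm_ranges: Mapping[str, Iterable[tuple[int, int]]] | None
) -> Domain:
    """Resolve the transmembrane-domain column, optionally from residue ranges.

    The input column wins whenever it is TM/nonTM. If it is NA, the variant
    is missense, a residue-range table is supplied for the gene, and the
    protein-change label carries a parseable residue number, the domain is
    filled from the ranges (1-based inclusive).
    """
    if variant.domain is not Domain.NA or tm_ranges is None:
        return variant.domain
    if variant.variant_type is not VariantType.MISSENSE:
        return variant.domain
    ranges = tm_ranges.get(variant.gene.value)
    if not ranges:
        return variant.domain
    m = _RESIDUE_RE.match(variant.protein_change.strip())
    if not m:
        return variant.domain
    residue = int(m.group(1))
    for lo, hi in ranges:
        if lo <= residue <= hi:
            return Domain.TM
    return Domain.NON_TM


def build_profile(
    av: AnnotatedVariant,
    profile: ApplicabilityProfile | None = None,
    thresholds: FrequencyThresholds | None = None,
) -> EvidenceProfile:
    """Merge curated and computed criterion codes into one evidence profile.

    Computed codes (PM2, BA1/BS1, PP3/BP4, PS3/BS3) are unioned with the
    curated codes, then the applicability filter removes codes that do not
    apply to dominant AD. Mutual-exclusion invariants hold by construction:
    the frequency rules emit at most one of PM2/BA1/BS1, the consensus rule
    one of PP3/BP4, the functional rule one of PS3/BS3. A curated BS1 is
    dropped (with a warning) when the variant is absent from every frequency
    source, since absence and elevated frequency contradict each other.
    """
    profile = profile or ApplicabilityProfile()
    thresholds = thresholds or FrequencyThresholds()

    computed: set[str] = set()
    if assess_pm2(av.frequencies):
        computed.add("PM2")
    computed |= assess_frequency_benign(av.frequencies, thresholds)
    try:
        code = assess_insilico(av.predictions, av.variant.variant_type)
    except InsufficientPredictionsError:
        code = None  # not assessable without any tool verdict
    if code:
        computed.add(code)
    code = assess_functional(av.functional)
    if code:
        computed.add(code)

    curated = set(av.curated_codes)
    if "PM2" in computed and "BS1" in curated:
        logger.warning(
            "dropping curated BS1 for %s %s: variant is absent from all frequency sources (PM2)",
            av.variant.gene.value,
            av.variant.protein_change,
        )
        curated.discard("BS1")

    if flag_candidate_null(av.variant) and "PVS1" not in curated:
        logger.info(
            "candidate null variant %s %s (%s) has no curated PVS1",
            av.variant.gene.value,
            av.variant.protein_change,
            av.variant.variant_type.value,
        )

    return EvidenceProfile(filter_applicable(curated | computed, profile))
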