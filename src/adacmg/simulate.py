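"""Synthetic cohorts with evidence profiles that classify to chosen tiers.

Two generators are provided:

* :func:`generate_cohort` builds a randomized cohort from per-cell target
  counts over (gene, variant type, domain, tier). Evidence is sampled
  *rule-directed*: a combining rule satisfying the target tier is picked,
  its codes instantiated, and optional redundant codes added only when they
  cannot change the tier — there is no rejection sampling. Annotations
  (frequencies, predictor verdicts, functional studies, curated codes) are
  then materialized so that running the evidence engine and combiner on the
  variant reproduces the target tier exactly.

* :func:`reference_cohort` is a deterministic 452-variant benchmark cohort
  of APP/PSEN1/PSEN2 variants mirroring the published re-evaluation
  spectrum for these genes, including prior-classification labels chosen so
  the per-gene concordance fractions (279/287, 30/31, 8/16) hold, and the
  PSEN2 T122R example variant with evidence {PM2, PM5, PP3}. Cells where
  the published cross-tabulation and the per-gene narrative totals disagree
  follow the narrative totals; the reallocations are listed in
  :func:`reference_metadata`.

Synthetic evidence profiles are representative, not historical: the true
per-variant curated evidence behind the published spectrum is unpublished.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .combiner import classify
from .evidence import FrequencyThresholds, build_profile
from .model import (
    AnnotatedVariant,
    Domain,
    Effect,
    EvidenceProfile,
    FunctionalResult,
    Gene,
    InSilicoPredictions,
    MISSENSE_TOOLS,
    PopulationFrequencies,
    PriorLabel,
    SPLICE_TOOLS,
    Tier,
    Variant,
    VariantType,
    Verdict,
)

__all__ = [
    "CohortSpec",
    "CellError",
    "sample_evidence_for_tier",
    "generate_cohort",
    "reference_cohort",
    "reference_metadata",
    "REFERENCE_CELLS",
]

Cell = tuple[Gene, VariantType, Domain, Tier]

#: Codes whose annotations the evidence engine derives; everything else is curated.
_MATERIALIZED = frozenset({"PM2", "BA1", "BS1", "PP3", "BP4", "PS3", "BS3"})

_NULL_TYPES = (VariantType.FRAMESHIFT, VariantType.SPLICING, VariantType.CNV)
_PREDICTABLE = (VariantType.MISSENSE, VariantType.SPLICING)


def _compatible(codes: frozenset[str], vtype: VariantType) -> bool:
    """Whether a code template can be materialized for a variant type."""
    if "PVS1" in codes and vtype not in _NULL_TYPES:
        return False
    if codes & {"PP3", "BP4"} and vtype not in _PREDICTABLE:
        return False
    if codes & {"PM1", "PM5"} and vtype is not VariantType.MISSENSE:
        return False
    if codes & {"PM4", "BP3"} and vtype is not VariantType.INDEL:
        return False
    if "BP7" in codes:  # synonymous-variant code; no synonymous type exists here
        return False
    return True


#: Rule-directed code templates per target tier.
TIER_TEMPLATES: dict[Tier, tuple[frozenset[str], ...]] = {
    Tier.PATHOGENIC: (
        frozenset({"PS3", "PM1", "PM2", "PM5"}),          # PS + 3 PM (missense)
        frozenset({"PS3", "PM2", "PM6", "PP2", "PP3"}),   # PS + 2 PM + 2 PP (missense)
        frozenset({"PVS1", "PS3", "PM2"}),                # PVS + PS (null variants)
        frozenset({"PS3", "PM2", "PM4", "PM6"}),          # PS + 3 PM (indel)
        frozenset({"PS3", "PS4", "PM2"}),                 # 2 PS (any type)
    ),
    Tier.LIKELY_PATHOGENIC: (
        frozenset({"PS3", "PM2"}),                        # PS + PM (any type)
        frozenset({"PM1", "PM2", "PM5"}),                 # 3 PM (missense)
        frozenset({"PVS1", "PM2"}),                       # PVS + PM (null variants)
        frozenset({"PM2", "PM5", "PP1", "PP3"}),          # 2 PM + 2 PP (missense)
    ),
    Tier.VUS: (
        frozenset({"PM2", "PP3"}),                        # insufficient (missense/splicing)
        frozenset({"PM2", "PM5"}),                        # insufficient; conflicting in-silico
        frozenset({"PM2", "PP1"}),                        # insufficient (any type)
        frozenset({"PM2", "PM6", "BS3"}),                 # contradictory: benign functional data
    ),
    Tier.LIKELY_BENIGN: (
        frozenset({"BS1", "BP4"}),                        # BS + BP (missense)
        frozenset({"BS1", "BP5"}),                        # BS + BP (any type)
        frozenset({"BP4", "BP5"}),                        # 2 BP (missense)
    ),
    Tier.BENIGN: (
        frozenset({"BA1"}),                               # stand-alone frequency
        frozenset({"BS1", "BS3"}),                        # 2 BS (any type)
    ),
}

#: Curated codes safe to add as redundant noise, by evidence side.
_NOISE_P = ("PP1", "PP2", "PP5", "PM6", "PS2")
_NOISE_B = ("BS4", "BP5", "BP6")


class CellError(ValueError):
    """A cohort cell cannot be generated; names the offending cell."""


def _templates_for(tier: Tier, vtype: VariantType,
                   overrides: Mapping[Tier, Sequence[frozenset[str]]] | None = None
                   ) -> list[frozenset[str]]:
    pool = (overrides or {}).get(tier, TIER_TEMPLATES[tier])
    return [t for t in map(frozenset, pool) if _compatible(t, vtype)]


def sample_evidence_for_tier(
    tier: Tier,
    rng: np.random.Generator,
    variant_type: VariantType = VariantType.MISSENSE,
    noise: float = 0.0,
    template_index: int | None = None,
    template_overrides: Mapping[Tier, Sequence[frozenset[str]]] | None = None,
) -> EvidenceProfile:
    """Draw an evidence profile that classifies exactly to ``tier``.

    Construction is rule-directed: a satisfying template is chosen
    (uniformly, or by ``template_index`` modulo the compatible templates),
    then with probability ``noise`` redundant same-side curated codes are
    added, each kept only if the classification is unchanged.
    """
    templates = _templates_for(tier, variant_type, template_overrides)
    if not templates:
        raise CellError(f"no evidence template yields {tier.label} for a {variant_type.value} variant")
    if template_index is not None:
        codes = set(templates[template_index % len(templates)])
    else:
        codes = set(templates[int(rng.integers(len(templates)))])
    if noise > 0:
        pool = _NOISE_P if tier > Tier.VUS else _NOISE_B if tier < Tier.VUS else ()
        for extra in pool:
            if extra in codes or rng.random() >= noise:
                continue
            trial = EvidenceProfile(frozenset(codes | {extra}))
            if classify(trial) is tier:
                codes.add(extra)
    profile = EvidenceProfile(frozenset(codes))
    assert classify(profile) is tier
    return profile


def _materialize(
    variant: Variant,
    profile: EvidenceProfile,
    rng: np.random.Generator,
    thresholds: FrequencyThresholds,
) -> AnnotatedVariant:
    """Build annotations so the evidence engine re-derives ``profile``."""
    codes = set(profile)
    # population frequencies
    if "PM2" in codes:
        freqs = PopulationFrequencies()
    elif "BA1" in codes:
        freqs = PopulationFrequencies(exac=round(thresholds.ba1_min + 0.01 + 0.04 * rng.random(), 6))
    elif "BS1" in codes:
        mid = thresholds.bs1_min + 0.3 * (thresholds.ba1_min - thresholds.bs1_min)
        freqs = PopulationFrequencies(exac=round(mid, 6))
    else:
        freqs = PopulationFrequencies(exac=round(thresholds.bs1_min / 50, 9))
    # in-silico verdicts
    verdicts: dict[str, Verdict] = {}
    tools = (
        MISSENSE_TOOLS
        if variant.variant_type is VariantType.MISSENSE
        else SPLICE_TOOLS
        if variant.variant_type is VariantType.SPLICING
        else ()
    )
    if tools:
        if "PP3" in codes:
            verdicts = {t: Verdict.DAMAGING for t in tools}
        elif "BP4" in codes:
            verdicts = {t: Verdict.BENIGN for t in tools}
        else:  # conflicting verdicts: consensus rule withholds both codes
            verdicts = {tools[0]: Verdict.DAMAGING, tools[1]: Verdict.BENIGN}
    # functional studies
    if "PS3" in codes:
        effect = Effect.INCREASED_AB42_40_RATIO if rng.random() < 0.5 else Effect.INCREASED_TOTAL_AB
        functional = (FunctionalResult("synthetic_assay_1", effect),)
    elif "BS3" in codes:
        functional = (FunctionalResult("synthetic_assay_1", Effect.NO_EFFECT),)
    else:
        functional = ()
    curated = frozenset(codes - _MATERIALIZED)
    return AnnotatedVariant(
        variant=variant,
        frequencies=freqs,
        predictions=InSilicoPredictions(verdicts),
        functional=functional,
        curated_codes=curated,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Target cell counts plus generation settings for a synthetic cohort."""

    cells: Mapping[Cell, int]
    seed: int = 0
    noise: float = 0.0
    template_overrides: Mapping[Tier, Sequence[frozenset[str]]] | None = None

    def __post_init__(self):
        for cell, count in self.cells.items():
            if count < 0:
                raise CellError(f"negative count {count} for cell {_cell_name(cell)}")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError(f"noise probability {self.noise} outside [0, 1]")


def _cell_name(cell: Cell) -> str:
    g, vt, dom, tier = cell
    return f"({g.value}, {vt.value}, {dom.value}, {tier.label})"


def _sorted_cells(cells: Mapping[Cell, int]) -> list[tuple[Cell, int]]:
    return sorted(
        cells.items(),
        key=lambda kv: (kv[0][0].value, kv[0][1].value, kv[0][2].value, kv[0][3].rank),
    )


def generate_cohort(
    spec: CohortSpec,
    thresholds: FrequencyThresholds | None = None,
) -> list[AnnotatedVariant]:
    """Generate a cohort with exactly the requested counts per cell.

    Deterministic under a fixed seed; every generated variant's closed-loop
    classification (evidence engine + combiner) equals its cell's tier.

    Raises
    ------
    CellError
        For a negative count or a cell whose tier cannot be realized for
        its variant type (e.g. a template requiring PVS1 on a missense).
    """
    thresholds = thresholds or FrequencyThresholds()
    rng = np.random.default_rng(spec.seed)
    out: list[AnnotatedVariant] = []
    serial = 0
    for cell, count in _sorted_cells(spec.cells):
        gene, vtype, domain, tier = cell
        for _ in range(count):
            serial += 1
            try:
                profile = sample_evidence_for_tier(
                    tier,
                    rng,
                    variant_type=vtype,
                    noise=spec.noise,
                    template_overrides=spec.template_overrides,
                )
            except CellError as e:
                raise CellError(f"cell {_cell_name(cell)}: {e}") from None
            variant = Variant(
                gene=gene,
                protein_change=f"p.SIM{serial:04d}",
                variant_type=vtype,
                domain=domain,
                exon_label="",
                prior_label=PriorLabel.UNKNOWN,
            )
            av = _materialize(variant, profile, rng, thresholds)
            _check_closed_loop(av, profile, tier, cell, thresholds)
            out.append(av)
    return out


def _check_closed_loop(av, profile, tier, cell, thresholds):
    rebuilt = build_profile(av, thresholds=thresholds)
    if rebuilt.codes != profile.codes or classify(rebuilt) is not tier:
        raise CellError(
            f"cell {_cell_name(cell)}: materialized annotations re-derive "
            f"{sorted(rebuilt.codes)} -> {classify(rebuilt).label}, expected "
            f"{sorted(profile.codes)} -> {tier.label}"
        )


# ---------------------------------------------------------------------------
# Deterministic benchmark cohort (452 APP/PSEN1/PSEN2 variants)

_P, _LP, _VUS, _LB, _B = (
    Tier.PATHOGENIC,
    Tier.LIKELY_PATHOGENIC,
    Tier.VUS,
    Tier.LIKELY_BENIGN,
    Tier.BENIGN,
)
_MIS, _IND, _FS, _SPL, _CNV, _UTR = (
    VariantType.MISSENSE,
    VariantType.INDEL,
    VariantType.FRAMESHIFT,
    VariantType.SPLICING,
    VariantType.CNV,
    VariantType.UTR,
)
_TM, _NTM, _NA = Domain.TM, Domain.NON_TM, Domain.NA

#: Benchmark histogram: (gene, variant_type, domain, tier) -> count.
REFERENCE_CELLS: tuple[tuple[Cell, int], ...] = (
    ((Gene.APP, _MIS, _TM, _P), 11),
    ((Gene.APP, _MIS, _TM, _LP), 6),
    ((Gene.APP, _MIS, _TM, _VUS), 3),
    ((Gene.APP, _MIS, _TM, _LB), 1),
    ((Gene.APP, _MIS, _NTM, _P), 5),
    ((Gene.APP, _MIS, _NTM, _LP), 8),
    ((Gene.APP, _MIS, _NTM, _VUS), 27),
    ((Gene.APP, _IND, _NTM, _LP), 1),
    ((Gene.APP, _IND, _NA, _VUS), 2),
    ((Gene.APP, _UTR, _NA, _VUS), 2),
    ((Gene.PSEN1, _MIS, _TM, _P), 85),
    ((Gene.PSEN1, _MIS, _TM, _LP), 95),
    ((Gene.PSEN1, _MIS, _TM, _VUS), 7),
    ((Gene.PSEN1, _MIS, _NTM, _P), 37),
    ((Gene.PSEN1, _MIS, _NTM, _LP), 46),
    ((Gene.PSEN1, _MIS, _NTM, _VUS), 25),
    ((Gene.PSEN1, _IND, _TM, _P), 6),
    ((Gene.PSEN1, _IND, _TM, _LP), 5),
    ((Gene.PSEN1, _IND, _NTM, _P), 3),
    ((Gene.PSEN1, _IND, _NTM, _LP), 2),
    ((Gene.PSEN1, _IND, _NTM, _VUS), 3),
    ((Gene.PSEN1, _FS, _NTM, _P), 1),
    ((Gene.PSEN1, _CNV, _NA, _P), 6),
    ((Gene.PSEN1, _SPL, _NA, _LP), 2),
    ((Gene.PSEN2, _MIS, _TM, _P), 3),
    ((Gene.PSEN2, _MIS, _TM, _LP), 3),
    ((Gene.PSEN2, _MIS, _TM, _VUS), 24),
    ((Gene.PSEN2, _MIS, _TM, _B), 1),
    ((Gene.PSEN2, _MIS, _NTM, _LP), 1),
    ((Gene.PSEN2, _MIS, _NTM, _VUS), 21),
    ((Gene.PSEN2, _MIS, _NTM, _B), 3),
    ((Gene.PSEN2, _SPL, _NA, _LP), 1),
    ((Gene.PSEN2, _FS, _NA, _P), 2),
    ((Gene.PSEN2, _FS, _NTM, _P), 2),
    ((Gene.PSEN2, _FS, _NTM, _LP), 1),
    ((Gene.PSEN2, _FS, _NTM, _VUS), 1),
)

#: Previously-pathogenic counts to embed: gene -> (among P/LP, among VUS).
_PRIOR_PATHOGENIC = {
    Gene.PSEN1: (279, 8),   # 279/287 re-classified P/LP
    Gene.APP: (30, 1),      # 30/31
    Gene.PSEN2: (8, 8),     # 8/16
}

#: Per-gene exon-label pools (label, count), special pools consumed first.
_EXON_POOLS: dict[Gene, dict[str, list[tuple[str, int]]]] = {
    Gene.PSEN1: {
        "CNV": [("intron 8, exon 9", 6)],
        "splicing": [("intron 8/11", 2)],
        "general": [
            ("exon 7", 72), ("exon 5", 61), ("exon 8", 42), ("exon 4", 35),
            ("exon 6", 34), ("exon 11", 30), ("exon 12", 23), ("exon 10", 10),
            ("exon 9", 5), ("exons 9-10, introns 8-10", 1), ("exon 3", 1),
            ("intron 4", 1),
        ],
    },
    Gene.PSEN2: {
        "splicing": [("intron 11/12", 1)],
        "general": [
            ("exon 5", 18), ("exon 7", 15), ("exon 4", 9), ("exon 12", 4),
            ("exon 3", 3), ("exon 6", 3), ("exon 10", 3), ("exon 11", 3),
            ("exon 8", 1), ("exon 9", 1), ("intron 11/12", 1), ("intron 9/12", 1),
        ],
    },
    Gene.APP: {
        "UTR": [("3'UTR", 3)],
        "general": [
            ("exon 17", 30), ("exon 16", 12), ("exon 14", 5), ("exon 6", 3),
            ("exon 7", 3), ("exon 11", 3), ("exon 12", 2), ("exon 13", 2),
            ("exon 5", 1), ("exon 9", 1), ("intron 17", 1),
        ],
    },
}


class _LabelPool:
    def __init__(self, pools: dict[str, list[tuple[str, int]]]):
        self._pools = {k: [lab for lab, n in v for _ in range(n)] for k, v in pools.items()}

    def draw(self, vtype: VariantType) -> str:
        key = vtype.value if vtype.value in self._pools else "general"
        for k in (key, "general", *self._pools):
            pool = self._pools.get(k)
            if pool:
                return pool.pop(0)
        return ""


def reference_cohort(seed: int = 2015) -> list[AnnotatedVariant]:
    """Deterministic 452-variant benchmark cohort.

    The (gene, type, domain, tier) histogram equals :data:`REFERENCE_CELLS`;
    prior-classification labels reproduce the per-gene concordance counts;
    PSEN2 T122R appears verbatim with evidence {PM2, PM5, PP3}. The seed
    varies annotation details only, never the histogram or closed-loop
    classifications.
    """
    thresholds = FrequencyThresholds()
    rng = np.random.default_rng(seed)

    # expand cells to per-variant plans, in fixed cell order
    plans: list[dict] = []
    for cell, count in REFERENCE_CELLS:
        for i in range(count):
            plans.append({"cell": cell, "index": i})

    # T122R: first variant of the PSEN2 missense non-TM VUS cell
    for plan in plans:
        g, vt, dom, tier = plan["cell"]
        if (g, vt, dom, tier) == (Gene.PSEN2, _MIS, _NTM, _VUS) and plan["index"] == 0:
            plan["t122r"] = True
            break

    # prior labels: first k P/LP and first k VUS per gene (T122R always counted)
    for gene, (k_plp, k_vus) in _PRIOR_PATHOGENIC.items():
        plp = [p for p in plans if p["cell"][0] is gene and p["cell"][3] in (_P, _LP)]
        for p in plp[:k_plp]:
            p["prior"] = PriorLabel.PATHOGENIC
        vus = [p for p in plans if p["cell"][0] is gene and p["cell"][3] is _VUS]
        vus.sort(key=lambda p: (not p.get("t122r", False),))
        for p in vus[:k_vus]:
            p["prior"] = PriorLabel.PATHOGENIC
    for p in plans:
        if "prior" not in p:
            tier = p["cell"][3]
            p["prior"] = (
                PriorLabel.NON_PATHOGENIC if tier in (_B, _LB) else PriorLabel.UNKNOWN
            )

    pools = {g: _LabelPool(_EXON_POOLS[g]) for g in Gene}
    out: list[AnnotatedVariant] = []
    serial = 0
    for plan in plans:
        gene, vtype, domain, tier = plan["cell"]
        serial += 1
        if plan.get("t122r"):
            label, profile = "T122R", EvidenceProfile(frozenset({"PM2", "PM5", "PP3"}))
        else:
            label = f"p.SIM{serial:04d}"
            # rotate templates within each cell so VUS mechanisms (conflicting
            # in-silico, benign functional data, insufficient criteria) all occur
            profile = sample_evidence_for_tier(
                tier, rng, variant_type=vtype, template_index=plan["index"]
            )
        variant = Variant(
            gene=gene,
            protein_change=label,
            variant_type=vtype,
            domain=domain,
            exon_label=pools[gene].draw(vtype),
            prior_label=plan["prior"],
        )
        av = _materialize(variant, profile, rng, thresholds)
        _check_closed_loop(av, profile, tier, plan["cell"], thresholds)
        out.append(av)
    return out


def reference_metadata() -> dict:
    """Provenance notes for the benchmark cohort, including reconciled cells.

    Where the published cross-tabulation and per-gene narrative totals
    disagree, the narrative totals win; the affected cells are listed here
    rather than silently reconciled.
    """
    return {
        "n_variants": sum(n for _, n in REFERENCE_CELLS),
        "gene_totals": {"APP": 66, "PSEN1": 323, "PSEN2": 63},
        "prior_pathogenic": {
            g.value: {"plp": k[0], "vus": k[1], "total": k[0] + k[1]}
            for g, k in _PRIOR_PATHOGENIC.items()
        },
        "adjusted_cells": [
            {
                "cell": "APP missense TM benign",
                "source_count": 2,
                "action": "reallocated to 1 VUS + 1 likely_benign (narrative: 34 VUS, 1 likely benign, 0 benign)",
            },
            {
                "cell": "APP missense nonTM benign",
                "source_count": 1,
                "action": "reallocated to likely_pathogenic (narrative: 15 likely pathogenic, 14 P/LP in non-TM)",
            },
            {
                "cell": "PSEN2 missense TM likely_benign",
                "source_count": 1,
                "action": "reallocated to VUS (narrative: 46 VUS, 4 benign)",
            },
            {
                "cell": "PSEN2 missense TM benign",
                "source_count": 2,
                "action": "1 kept benign, 1 reallocated to VUS (narrative: 46 VUS, 4 benign)",
            },
            {
                "cell": "APP missense NA VUS",
                "source_count": 2,
                "action": "encoded as variant_type=UTR (narrative type totals: 61 missense, 3 indel, 2 UTR)",
            },
            {
                "cell": "PSEN1 'missense,CNV' NA pathogenic",
                "source_count": 6,
                "action": "encoded as variant_type=CNV (narrative type totals: 295 missense, 6 CNV)",
            },
        ],
        "notes": [
            "Evidence profiles are representative synthetic reconstructions, not the historical per-variant evidence.",
            "PSEN2 T122R is included verbatim with evidence {PM2, PM5, PP3} and a previously-pathogenic prior label.",
        ],
    }
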