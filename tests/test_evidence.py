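"""Evidence-engine rules: applicability, frequency, in-silico, functional."""

import pytest
from hypothesis import given, settings, strategies as st

from adacmg import (
    AnnotatedVariant,
    ApplicabilityProfile,
    Domain,
    Effect,
    FrequencyThresholds,
    FunctionalResult,
    Gene,
    InSilicoPredictions,
    PopulationFrequencies,
    Variant,
    VariantType,
    Verdict,
    assess_frequency_benign,
    assess_functional,
    assess_insilico,
    assess_pm2,
    build_profile,
    filter_applicable,
    flag_candidate_null,
)
from adacmg.evidence import InsufficientPredictionsError, derive_domain
from adacmg.model import ALL_CODES, MISSENSE_TOOLS, SPLICE_TOOLS

pytestmark = []


def _variant(vtype=VariantType.MISSENSE, gene=Gene.PSEN2, domain=Domain.TM, change="T122R"):
    return Variant(gene=gene, protein_change=change, variant_type=vtype, domain=domain)


# ---------------------------------------------------------------------------
# applicability


def test_filter_drops_inapplicable_codes():
    assert filter_applicable({"PM2", "PM3", "PP3"}) == {"PM2", "PP3"}


def test_filter_of_all_codes_leaves_23():
    allowed = filter_applicable(ALL_CODES)
    assert len(allowed) == 23
    assert allowed & {"PM3", "PP4", "BS2", "BP1", "BP2"} == set()
    assert filter_applicable(set()) == set()


def test_filter_rejects_unknown_code():
    with pytest.raises(ValueError, match="PQ1"):
        filter_applicable({"PQ1"})


def test_applicability_profile_partitions_all_codes():
    profile = ApplicabilityProfile()
    assert profile.allowed | set(profile.excluded) == ALL_CODES
    assert profile.allowed & set(profile.excluded) == set()


@settings(derandomize=True, max_examples=200)
@given(st.sets(st.sampled_from(sorted(ALL_CODES))))
def test_filter_applicable_idempotent(codes):
    once = filter_applicable(codes)
    assert filter_applicable(once) == once


# ---------------------------------------------------------------------------
# frequency rules


@pytest.mark.parametrize(
    "freqs, expected",
    [
        (PopulationFrequencies(), True),
        (PopulationFrequencies(exac=0.01), False),
        (PopulationFrequencies(g1000=0.0005), False),
    ],
)
def test_pm2_requires_absence_everywhere(freqs, expected):
    assert assess_pm2(freqs) is expected


@pytest.mark.parametrize(
    "freqs, expected",
    [
        (PopulationFrequencies(exac=0.06), {"BA1"}),
        (PopulationFrequencies(), set()),
        (PopulationFrequencies(g1000=0.002), {"BS1"}),
        (PopulationFrequencies(exac=0.0005), set()),
        (PopulationFrequencies(esp6500=0.002, exac=0.07), {"BA1"}),
    ],
)
def test_frequency_benign_thresholds(freqs, expected):
    assert assess_frequency_benign(freqs, FrequencyThresholds(ba1_min=0.05, bs1_min=0.001)) == expected


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        FrequencyThresholds(ba1_min=0.001, bs1_min=0.05)


@settings(derandomize=True, max_examples=300)
@given(
    st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
    st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
    st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
)
def test_pm2_and_benign_frequency_never_both_fire(e, g, x):
    freqs = PopulationFrequencies(esp6500=e, g1000=g, exac=x)
    benign = assess_frequency_benign(freqs)
    assert not (assess_pm2(freqs) and benign)
    assert benign in ({"BA1"}, {"BS1"}, set())


# ---------------------------------------------------------------------------
# in-silico consensus


def _preds(damaging=(), benign=(), unavailable=()):
    v = {t: Verdict.DAMAGING for t in damaging}
    v.update({t: Verdict.BENIGN for t in benign})
    v.update({t: Verdict.UNAVAILABLE for t in unavailable})
    return InSilicoPredictions(v)


def test_unanimous_damaging_gives_pp3():
    assert assess_insilico(_preds(damaging=MISSENSE_TOOLS), VariantType.MISSENSE) == "PP3"


def test_conflicting_verdicts_withhold_code():
    preds = _preds(damaging=MISSENSE_TOOLS[:9], benign=MISSENSE_TOOLS[9:])
    assert assess_insilico(preds, VariantType.MISSENSE) is None


def test_unanimous_benign_gives_bp4():
    assert assess_insilico(_preds(benign=MISSENSE_TOOLS), VariantType.MISSENSE) == "BP4"


def test_unavailable_tools_excluded_from_consensus():
    preds = _preds(damaging=MISSENSE_TOOLS[:3], unavailable=MISSENSE_TOOLS[3:])
    assert assess_insilico(preds, VariantType.MISSENSE) == "PP3"


def test_splicing_uses_splice_tools_only():
    preds = _preds(damaging=SPLICE_TOOLS, benign=MISSENSE_TOOLS)
    assert assess_insilico(preds, VariantType.SPLICING) == "PP3"


def test_no_tool_available_raises():
    with pytest.raises(InsufficientPredictionsError):
        assess_insilico(InSilicoPredictions({}), VariantType.MISSENSE)
    with pytest.raises(InsufficientPredictionsError):
        assess_insilico(_preds(unavailable=MISSENSE_TOOLS), VariantType.MISSENSE)


def test_non_predictable_types_not_assessed():
    assert assess_insilico(InSilicoPredictions({}), VariantType.CNV) is None


@settings(derandomize=True, max_examples=100)
@given(st.permutations(list(MISSENSE_TOOLS)))
def test_consensus_order_independent(order):
    preds = InSilicoPredictions(
        {t: (Verdict.DAMAGING if i % 2 else Verdict.BENIGN) for i, t in enumerate(order)}
    )
    assert assess_insilico(preds, VariantType.MISSENSE) is None
    unanimous = InSilicoPredictions({t: Verdict.DAMAGING for t in order})
    assert assess_insilico(unanimous, VariantType.MISSENSE) == "PP3"


# ---------------------------------------------------------------------------
# functional evidence


@pytest.mark.parametrize(
    "effects, expected",
    [
        ([Effect.INCREASED_AB42_40_RATIO], "PS3"),
        ([Effect.INCREASED_TOTAL_AB, Effect.INCREASED_AB42_40_RATIO], "PS3"),
        ([Effect.NO_EFFECT, Effect.NO_EFFECT], "BS3"),
        ([Effect.INCREASED_TOTAL_AB, Effect.NO_EFFECT], None),  # conflicting studies
        ([], None),
        ([Effect.OTHER], None),
        ([Effect.NO_EFFECT, Effect.OTHER], None),
    ],
)
def test_functional_evidence_rule(effects, expected):
    results = [FunctionalResult(f"s{i}", e) for i, e in enumerate(effects)]
    assert assess_functional(results) == expected


@pytest.mark.parametrize(
    "vtype, expected",
    [
        (VariantType.FRAMESHIFT, True),
        (VariantType.SPLICING, True),
        (VariantType.CNV, True),
        (VariantType.MISSENSE, False),
        (VariantType.INDEL, False),
        (VariantType.UTR, False),
    ],
)
def test_candidate_null_flag(vtype, expected):
    assert flag_candidate_null(_variant(vtype=vtype)) is expected


# ---------------------------------------------------------------------------
# profile assembly


def test_build_profile_t122r_example():
    """Absent from all sources + curated PM5 + unanimous damaging -> {PM2, PM5, PP3}."""
    av = AnnotatedVariant(
        variant=_variant(),
        frequencies=PopulationFrequencies(),
        predictions=_preds(damaging=MISSENSE_TOOLS),
        curated_codes=frozenset({"PM5"}),
    )
    assert build_profile(av).codes == {"PM2", "PM5", "PP3"}


def test_build_profile_no_annotations_is_empty():
    av = AnnotatedVariant(
        variant=_variant(vtype=VariantType.CNV, domain=Domain.NA),
        frequencies=PopulationFrequencies(exac=0.0001),
    )
    assert build_profile(av).codes == set()


def test_build_profile_filters_inapplicable_curated_code():
    av = AnnotatedVariant(variant=_variant(), curated_codes=frozenset({"PM3"}))
    assert build_profile(av).codes == {"PM2"}  # PM3 dropped, absence gives PM2


def test_build_profile_drops_curated_bs1_under_pm2():
    av = AnnotatedVariant(variant=_variant(), curated_codes=frozenset({"BS1"}))
    assert build_profile(av).codes == {"PM2"}


_curated_pool = sorted(ALL_CODES - {"PM2", "PP3", "BP4", "PS3", "BS3", "BA1"})


@settings(derandomize=True, max_examples=300, deadline=None)
@given(
    freq=st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
    verdict_seed=st.lists(st.sampled_from(list(Verdict)), min_size=0, max_size=10),
    effects=st.lists(st.sampled_from(list(Effect)), max_size=3),
    curated=st.sets(st.sampled_from(_curated_pool), max_size=6),
    vtype=st.sampled_from(list(VariantType)),
)
def test_build_profile_always_satisfies_invariants(freq, verdict_seed, effects, curated, vtype):
    """Randomized annotations always yield a valid, applicable evidence profile."""
    av = AnnotatedVariant(
        variant=_variant(vtype=vtype),
        frequencies=PopulationFrequencies(exac=freq),
        predictions=InSilicoPredictions(dict(zip(MISSENSE_TOOLS, verdict_seed))),
        functional=tuple(FunctionalResult(f"s{i}", e) for i, e in enumerate(effects)),
        curated_codes=frozenset(curated),
    )
    profile = build_profile(av)  # EvidenceProfile validates exclusion pairs itself
    assert profile.codes <= ALL_CODES
    assert profile.codes & {"PM3", "PP4", "BS2", "BP1", "BP2"} == set()


# ---------------------------------------------------------------------------
# optional domain derivation

_TM_RANGES = {"PSEN2": [(88, 108), (139, 159)]}


@pytest.mark.parametrize(
    "change, domain_in, expected",
    [
        ("T122R", Domain.NA, Domain.NON_TM),
        ("p.V148I", Domain.NA, Domain.TM),
        ("T122R", Domain.TM, Domain.TM),  # explicit input column wins
        ("delX", Domain.NA, Domain.NA),  # unparseable residue stays NA
    ],
)
def test_domain_derivation_from_residue_ranges(change, domain_in, expected):
    v = _variant(change=change, domain=domain_in)
    assert derive_domain(v, _TM_RANGES) is expected
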