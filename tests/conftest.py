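import pytest

from adacmg import ACMGClassifier, EvidenceAssigner, reference_cohort, tabulate


@pytest.fixture(scope="session")
def benchmark_cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def classified(benchmark_cohort):
    """(AnnotatedVariant, Tier) pairs from running the full pipeline."""
    assigner = EvidenceAssigner().fit(None)
    classifier = ACMGClassifier().fit()
    pairs = assigner.transform(benchmark_cohort)
    return list(zip(benchmark_cohort, classifier.predict_tiers(pairs)))


@pytest.fixture(scope="session")
def cohort_table(classified):
    return tabulate(classified)
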