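"""Contingency tests against closed forms and enumeration; cohort tabulation."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from adacmg import (
    Gene,
    Tier,
    chi2_2x2,
    chi2_rx2,
    concordance_with_prior,
    fisher_two_sided,
    fraction_plp,
    tabulate,
)
from adacmg.model import PriorLabel
from adacmg.stats import PLP_TIERS, run_paper_panel


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2) or c1 in (0, n):
        return 1.0
    denom = comb(n, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    tot = sum(
        w
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (w := comb(r1, x) * comb(r2, c1 - x)) <= obs
    )
    return tot / denom


# ---------------------------------------------------------------------------
# chi-square


def test_chi2_yates_reproduces_tm_comparison():
    res = chi2_2x2([[191, 8], [89, 28]])
    assert f"{res.p_value:.2e}" == "2.04e-07"
    assert res.df == 1 and res.method.value == "chi2_yates"


def test_chi2_yates_gene_pair():
    assert f"{chi2_2x2([[31, 35], [13, 50]]).p_value:.2e}" == "3.00e-03"


def test_chi2_perfect_fit_gives_p_one():
    res = chi2_2x2([[10, 20], [10, 20]])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi2_2x2([[0, 0], [5, 8]])


def test_chi2_floors_overcorrected_statistic():
    # |ad - bc| < N/2: Yates would overshoot past zero without the floor
    a = [[3, 4], [4, 5]]
    res = chi2_2x2(a)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_chi2_rx2_three_genes():
    res = chi2_rx2([[288, 35], [31, 35], [13, 50]])
    assert res.p_value < 2.2e-16
    assert res.df == 2 and res.method.value == "chi2_plain"


def test_chi2_rx2_identical_rows_p_one():
    assert chi2_rx2([[7, 13], [7, 13]]).p_value == 1.0


def test_chi2_rx2_on_2x2_applies_yates():
    res = chi2_rx2([[288, 35], [31, 35]])
    assert f"{res.p_value:.2e}" == "1.78e-15"
    assert res.method.value == "chi2_yates"


_margin_tables = st.tuples(
    st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60)
)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(_margin_tables)
def test_chi2_matches_scipy_where_correction_is_regular(cells):
    """Statistic equals scipy's Yates chi-square when the floor is inactive."""
    a, b, c, d = cells
    n = a + b + c + d
    if abs(a * d - b * c) < n / 2:
        stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        res = chi2_2x2([[a, b], [c, d]], correction=False)
    else:
        stat, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=True)
        res = chi2_2x2([[a, b], [c, d]])
    assert res.statistic == pytest.approx(stat, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-10)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(5, 40), st.integers(5, 40))
def test_chi2_p_decreases_with_imbalance(r, c):
    """With margins fixed, moving mass off the diagonal lowers the p-value."""
    base = [[r, r], [c, c]]
    shifted = [[r + min(r, c) - 1, r - min(r, c) + 1], [c - min(r, c) + 1, c + min(r, c) - 1]]
    assert chi2_2x2(shifted).p_value <= chi2_2x2(base).p_value


# ---------------------------------------------------------------------------
# Fisher


@pytest.mark.parametrize(
    "table, expected",
    [
        ([[15, 273], [1, 29]], 1.0),
        ([[2, 284], [1, 12]], 0.13),
        ([[5, 0], [0, 5]], 2 / comb(10, 5)),
    ],
)
def test_fisher_examples(table, expected):
    assert round(fisher_two_sided(table).p_value, 2) == round(expected, 2)


def test_fisher_negative_entry_rejected():
    with pytest.raises(ValueError):
        fisher_two_sided([[-1, 2], [3, 4]])


def test_fisher_equals_enumeration_small_tables():
    for n in range(1, 26):
        rng = np.random.default_rng(n)
        for _ in range(20):
            cut = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cut[0], cut[1] - cut[0], cut[2] - cut[1]
            d = n - a - b - c
            p = fisher_two_sided([[a, b], [c, d]]).p_value
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_fisher_symmetries(a, b, c, d):
    """Invariant under transposition and simultaneous row/column swap."""
    p = fisher_two_sided([[a, b], [c, d]]).p_value
    assert fisher_two_sided([[a, c], [b, d]]).p_value == pytest.approx(p, rel=1e-12)
    assert fisher_two_sided([[d, c], [b, a]]).p_value == pytest.approx(p, rel=1e-12)


# ---------------------------------------------------------------------------
# cohort table


def test_tabulate_matches_direct_scan(classified, cohort_table):
    assert cohort_table.total == len(classified) == 452
    direct = sum(
        1
        for av, tier in classified
        if av.variant.gene is Gene.PSEN1 and tier is Tier.PATHOGENIC
    )
    assert cohort_table.marginal(gene=Gene.PSEN1, tier=Tier.PATHOGENIC) == direct == 138
    assert cohort_table.marginal(gene=Gene.PSEN1) == 323
    assert cohort_table.marginal(gene=Gene.APP) == 66
    assert cohort_table.marginal(gene=Gene.PSEN2) == 63
    assert cohort_table.marginal(gene=Gene.PSEN1, domain="TM", tier=PLP_TIERS) == 191


def test_tabulate_empty_cohort():
    table = tabulate([])
    assert table.total == 0
    assert table.marginal(gene=Gene.APP) == 0


def test_fraction_plp(cohort_table):
    assert fraction_plp(cohort_table, Gene.PSEN1) == (89.16, 288, 323)
    assert fraction_plp(cohort_table, Gene.APP) == (46.97, 31, 66)
    with pytest.raises(ValueError):
        fraction_plp(tabulate([]), Gene.APP)


def test_concordance_with_prior(classified):
    assert concordance_with_prior(classified) == (94.91, 317, 334)


def test_concordance_edge_cases(benchmark_cohort):
    prior_path = [
        (av, t)
        for av, t in zip(benchmark_cohort, [Tier.PATHOGENIC] * len(benchmark_cohort))
        if av.variant.prior_label is PriorLabel.PATHOGENIC
    ]
    assert concordance_with_prior(prior_path)[0] == 100.0
    all_vus = [(av, Tier.VUS) for av, _ in prior_path]
    assert concordance_with_prior(all_vus)[0] == 0.0
    with pytest.raises(ValueError):
        concordance_with_prior([])


def test_panel_requires_all_three_genes(classified):
    one_gene = [(av, t) for av, t in classified if av.variant.gene is Gene.PSEN1]
    with pytest.raises(ValueError, match="APP|PSEN2"):
        run_paper_panel(tabulate(one_gene))


def test_panel_labels_and_validity(cohort_table):
    results = run_paper_panel(cohort_table)
    labels = [r.label for r in results]
    assert "plp_genes_3x2" in labels
    assert "plp_frameshift_PSEN1_vs_PSEN2" in labels
    assert all(0 < r.p_value <= 1 for r in results)
    frameshift = next(r for r in results if r.label == "plp_frameshift_PSEN1_vs_PSEN2")
    assert frameshift.table == ((1, 287), (5, 8))
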