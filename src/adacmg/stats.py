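"""Cohort cross-tabulation and contingency tests.

The classified cohort is summarised as counts over
(gene, variant type, transmembrane domain, tier), from which the module
derives per-gene pathogenic/likely-pathogenic (P/LP) fractions, concordance
with the previously reported classification, and a panel of contingency
tests contrasting genes, variant types and domain location:

* gene-spectrum comparisons use the Pearson chi-square (Yates continuity
  correction on 2x2 tables, df = r-1 without correction for r > 2);
* variant-type comparisons among P/LP variants use the two-sided Fisher
  exact test (sum of hypergeometric probabilities no larger than the
  observed table's);
* transmembrane vs non-transmembrane comparisons (domain=NA excluded) are
  reported under Yates, plain chi-square and Fisher, since small cells make
  the choice consequential.

The 2x2 Yates statistic is computed by the closed form
``N * (max(0, |ad-bc| - N/2))^2 / (r1*r2*c1*c2)`` so that the corrected
|O-E| is floored at zero; r x 2 tables and Fisher tests delegate to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Domain, Gene, Tier

__all__ = [
    "CohortTable",
    "ContingencyResult",
    "TestMethod",
    "tabulate",
    "fraction_plp",
    "concordance_with_prior",
    "chi2_2x2",
    "chi2_rx2",
    "fisher_two_sided",
    "run_paper_panel",
    "panel_frame",
    "write_panel",
    "write_report",
]

PLP_TIERS = (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC)

AXES = ("gene", "variant_type", "domain", "tier")


class TestMethod(str, Enum):
    CHI2_YATES = "chi2_yates"
    CHI2_PLAIN = "chi2_plain"
    FISHER_TWO_SIDED = "fisher_two_sided"


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of one contingency test."""

    label: str
    table: tuple[tuple[int, ...], ...]
    method: TestMethod
    p_value: float
    statistic: float | None = None  # absent for Fisher
    df: int | None = None

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _as_int_array(table, allow_rx2: bool = False) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[1] != 2 or (not allow_rx2 and arr.shape[0] != 2):
        shape = "r x 2" if allow_rx2 else "2 x 2"
        raise ValueError(f"expected a {shape} table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("table entries must be nonnegative")
    if not np.all(arr == np.floor(arr)):
        raise ValueError("table entries must be integers")
    return arr.astype(np.int64)


def chi2_2x2(table, label: str = "", correction: bool = True) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table (Yates-corrected by default, df=1)."""
    arr = _as_int_array(table)
    n = int(arr.sum())
    r1, r2 = arr.sum(axis=1)
    c1, c2 = arr.sum(axis=0)
    if 0 in (r1, r2, c1, c2):
        raise ValueError("2x2 table has a zero margin")
    (a, b), (c, d) = arr
    cross = abs(int(a) * int(d) - int(b) * int(c))
    if correction:
        cross = max(0, cross - n / 2)
        method = TestMethod.CHI2_YATES
    else:
        method = TestMethod.CHI2_PLAIN
    stat = n * cross**2 / (int(r1) * int(r2) * int(c1) * int(c2))
    p = float(sps.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return ContingencyResult(label, _tup(arr), method, p, statistic=float(stat), df=1)


def chi2_rx2(table, label: str = "") -> ContingencyResult:
    """Pearson chi-square on an r x 2 table.

    2x2 input gets the Yates correction; r > 2 is uncorrected with df = r-1.
    """
    arr = _as_int_array(table, allow_rx2=True)
    if arr.shape[0] == 2:
        res = chi2_2x2(arr, label=label)
        return res
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return ContingencyResult(
        label, _tup(arr), TestMethod.CHI2_PLAIN, float(p), statistic=float(stat), df=int(dof)
    )


def fisher_two_sided(table, label: str = "") -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, that do not exceed the observed table's probability.
    """
    arr = _as_int_array(table)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return ContingencyResult(label, _tup(arr), TestMethod.FISHER_TWO_SIDED, float(min(p, 1.0)))


def _tup(arr: np.ndarray) -> tuple[tuple[int, ...], ...]:
    return tuple(tuple(int(x) for x in row) for row in arr)


# ---------------------------------------------------------------------------
# Cohort table


@dataclass(frozen=True)
class CohortTable:
    """Counts of classified variants over (gene, variant_type, domain, tier)."""

    counts: pd.DataFrame  # columns: gene, variant_type, domain, tier, count

    def __post_init__(self):
        df = self.counts
        missing = [c for c in (*AXES, "count") if c not in df.columns]
        if missing:
            raise ValueError(f"counts frame missing columns: {missing}")
        if (df["count"] < 0).any():
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return int(self.counts["count"].sum())

    def marginal(self, **conditions) -> int:
        """Count of variants matching the given axis values.

        Values may be single enum/str values or collections; e.g.
        ``marginal(gene=Gene.PSEN1, tier=PLP_TIERS)``.
        """
        df = self.counts
        mask = pd.Series(True, index=df.index)
        for axis, value in conditions.items():
            if axis not in AXES:
                raise ValueError(f"unknown axis {axis!r}")
            if isinstance(value, (list, tuple, set, frozenset)):
                labels = {_axis_label(v) for v in value}
            else:
                labels = {_axis_label(value)}
            mask &= df[axis].isin(labels)
        return int(df.loc[mask, "count"].sum())

    def histogram(self) -> dict[tuple[str, str, str, str], int]:
        """Nonzero cells as a plain dict keyed by (gene, type, domain, tier)."""
        out: dict[tuple[str, str, str, str], int] = {}
        for rec in self.counts.itertuples(index=False):
            if rec.count:
                key = (rec.gene, rec.variant_type, rec.domain, rec.tier)
                out[key] = out.get(key, 0) + int(rec.count)
        return out


def _axis_label(value) -> str:
    if isinstance(value, Tier):
        return value.label
    if isinstance(value, Enum):
        return value.value
    return str(value)


def tabulate(classified: Iterable[tuple]) -> CohortTable:
    """Cross-tabulate (AnnotatedVariant, Tier) pairs into a CohortTable."""
    rows = []
    for av, tier in classified:
        v = av.variant
        rows.append(
            {
                "gene": v.gene.value,
                "variant_type": v.variant_type.value,
                "domain": v.domain.value,
                "tier": tier.label,
            }
        )
    if not rows:
        df = pd.DataFrame(columns=[*AXES, "count"])
        return CohortTable(df)
    df = pd.DataFrame(rows).value_counts().rename("count").reset_index()
    df = df.sort_values(list(AXES)).reset_index(drop=True)
    return CohortTable(df)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    factor = 10**ndigits
    return math.floor(x * factor + 0.5) / factor


def fraction_plp(table: CohortTable, gene: Gene | str) -> tuple[float, int, int]:
    """P/LP fraction for a gene: (percent to 2 decimals, numerator, denominator)."""
    total = table.marginal(gene=gene)
    if total == 0:
        raise ValueError(f"no variants for gene {_axis_label(gene)}")
    plp = table.marginal(gene=gene, tier=PLP_TIERS)
    return _round_half_up(100.0 * plp / total), plp, total


def concordance_with_prior(classified: Iterable[tuple]) -> tuple[float, int, int]:
    """Fraction of previously-pathogenic variants re-classified P/LP.

    Returns (percent to 2 decimals, numerator, denominator); raises if no
    variant carries a previously-pathogenic label.
    """
    from .model import PriorLabel

    num = den = 0
    for av, tier in classified:
        if av.variant.prior_label is PriorLabel.PATHOGENIC:
            den += 1
            if tier in PLP_TIERS:
                num += 1
    if den == 0:
        raise ValueError("no previously-pathogenic variants in cohort")
    return _round_half_up(100.0 * num / den), num, den


# ---------------------------------------------------------------------------
# The published comparison panel

_TYPE_TESTS = (
    ("missense", Gene.PSEN1, Gene.PSEN2),
    ("missense", Gene.PSEN1, Gene.APP),
    ("frameshift", Gene.PSEN1, Gene.PSEN2),
    ("splicing", Gene.PSEN1, Gene.PSEN2),
    ("indel", Gene.PSEN1, Gene.APP),
)


def _gene_plp_rows(table: CohortTable, genes: Sequence[Gene]) -> list[list[int]]:
    rows = []
    for g in genes:
        plp = table.marginal(gene=g, tier=PLP_TIERS)
        rows.append([plp, table.marginal(gene=g) - plp])
    return rows


def run_paper_panel(table: CohortTable) -> list[ContingencyResult]:
    """Run the full comparison panel on a three-gene cohort.

    Emits, labeled: the 3-gene P/LP chi-square; the three pairwise gene
    chi-squares (Yates); Fisher tests per variant type among P/LP variants;
    and TM vs non-TM 2x2 tests per gene (NA excluded) under Yates, plain
    and Fisher, contrasting P/LP against all other tiers and additionally
    against VUS only.
    """
    genes = (Gene.PSEN1, Gene.APP, Gene.PSEN2)
    for g in genes:
        if table.marginal(gene=g) == 0:
            raise ValueError(f"cohort has no {g.value} variants; all three genes required")

    results: list[ContingencyResult] = []
    results.append(chi2_rx2(_gene_plp_rows(table, genes), label="plp_genes_3x2"))
    for g1, g2 in ((Gene.PSEN1, Gene.APP), (Gene.PSEN1, Gene.PSEN2), (Gene.APP, Gene.PSEN2)):
        results.append(
            chi2_2x2(_gene_plp_rows(table, (g1, g2)), label=f"plp_{g1.value}_vs_{g2.value}")
        )

    for vtype, g1, g2 in _TYPE_TESTS:
        rows = []
        for g in (g1, g2):
            plp_total = table.marginal(gene=g, tier=PLP_TIERS)
            of_type = table.marginal(gene=g, tier=PLP_TIERS, variant_type=vtype)
            rows.append([of_type, plp_total - of_type])
        results.append(
            fisher_two_sided(rows, label=f"plp_{vtype}_{g1.value}_vs_{g2.value}")
        )

    other_tiers = [t for t in Tier if t not in PLP_TIERS]
    for g in genes:
        for contrast_name, contrast in (("all", other_tiers), ("vus", [Tier.VUS])):
            rows = []
            for dom in (Domain.TM, Domain.NON_TM):
                rows.append(
                    [
                        table.marginal(gene=g, domain=dom, tier=PLP_TIERS),
                        table.marginal(gene=g, domain=dom, tier=contrast),
                    ]
                )
            base = f"tm_{g.value}_plp_vs_{contrast_name}"
            for fn, suffix in (
                (chi2_2x2, "chi2_yates"),
                (lambda t, label: chi2_2x2(t, label, correction=False), "chi2_plain"),
                (fisher_two_sided, "fisher"),
            ):
                try:
                    results.append(fn(rows, label=f"{base}_{suffix}"))
                except ValueError:
                    continue  # zero margin in a sparse synthetic cohort
    return results


def panel_frame(results: Sequence[ContingencyResult]) -> pd.DataFrame:
    """Flatten panel results into one row per test."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "table": ";".join(",".join(str(x) for x in row) for row in r.table),
                "method": r.method.value,
                "statistic": "" if r.statistic is None else f"{r.statistic:.6g}",
                "df": "" if r.df is None else r.df,
                "p_value": f"{r.p_value:.3g}",
                "p_value_raw": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def write_panel(results: Sequence[ContingencyResult], path: str | Path) -> None:
    panel_frame(results).drop(columns="p_value_raw").to_csv(path, sep="\t", index=False)


def write_report(
    table: CohortTable,
    results: Sequence[ContingencyResult],
    fractions: dict[str, tuple[float, int, int]],
    concordance: tuple[float, int, int] | None,
    path: str | Path,
) -> None:
    """Write a human-readable markdown summary of the cohort statistics."""
    lines = ["# Cohort re-evaluation summary", ""]
    lines.append(f"Total classified variants: {table.total}")
    lines.append("")
    lines.append("## Classification spectrum by gene")
    lines.append("")
    lines.append("| gene | total | " + " | ".join(t.label for t in reversed(list(Tier))) + " | P/LP % |")
    lines.append("|" + "---|" * (len(list(Tier)) + 3))
    for gene in (Gene.PSEN1, Gene.APP, Gene.PSEN2):
        total = table.marginal(gene=gene)
        if total == 0:
            continue
        cells = [str(table.marginal(gene=gene, tier=t)) for t in reversed(list(Tier))]
        pct = fractions.get(gene.value)
        pct_s = f"{pct[0]:.2f} ({pct[1]}/{pct[2]})" if pct else ""
        lines.append(f"| {gene.value} | {total} | " + " | ".join(cells) + f" | {pct_s} |")
    lines.append("")
    if concordance is not None:
        pct, num, den = concordance
        lines.append(
            f"Concordance with prior pathogenic reports: {pct:.2f}% ({num}/{den}) re-classified P/LP."
        )
        lines.append("")
    lines.append("## Contingency tests")
    lines.append("")
    lines.append("| label | table | method | p |")
    lines.append("|---|---|---|---|")
    for r in results:
        tbl = "; ".join(",".join(str(x) for x in row) for row in r.table)
        lines.append(f"| {r.label} | {tbl} | {r.method.value} | {r.p_value:.3g} |")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
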