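"""Scikit-learn estimator interface to the evidence engine and combiner.

Both estimators operate on the flat variant-table DataFrame (the TSV
schema) and compose in a :class:`~sklearn.pipeline.Pipeline`::

    pipe = Pipeline([
        ("evidence", EvidenceAssigner()),
        ("acmg", ACMGClassifier()),
    ])
    tiers = pipe.fit(table).predict(table)

Neither step learns from data — ``fit`` validates input and freezes the
configuration (thresholds, applicability profile, rule table) into fitted
attributes, which keeps the deterministic rule engine usable inside
sklearn model-selection and pipeline machinery.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .combiner import RuleTable, explain
from .evidence import ApplicabilityProfile, FrequencyThresholds, build_profile, derive_domain
from .model import (
    AnnotatedVariant,
    EvidenceProfile,
    Tier,
    Variant,
    validate_table,
)

__all__ = ["EvidenceAssigner", "ACMGClassifier"]


def _coerce_variants(X) -> list[AnnotatedVariant]:
    if isinstance(X, pd.DataFrame):
        return validate_table(X.to_dict(orient="records"))
    X = list(X)
    if all(isinstance(v, AnnotatedVariant) for v in X):
        return X
    return validate_table(X)


class EvidenceAssigner(TransformerMixin, BaseEstimator):
    """Derive ACMG-AMP evidence codes for each variant row.

    Parameters
    ----------
    ba1_min, bs1_min : float
        Allele-frequency cutoffs for the stand-alone (BA1) and strong (BS1)
        benign criteria.
    excluded : mapping of code to rationale, optional
        Applicability-profile override; defaults to the dominant-AD profile
        (PM3, PP4, BS2, BP1, BP2 excluded).
    tm_ranges : mapping gene -> [(start, end), ...], optional
        1-based inclusive transmembrane residue ranges used to fill a
        missing domain column from the protein-change label.
    """

    def __init__(
        self,
        ba1_min: float = 0.05,
        bs1_min: float = 0.001,
        excluded: Mapping[str, str] | None = None,
        tm_ranges: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    ):
        self.ba1_min = ba1_min
        self.bs1_min = bs1_min
        self.excluded = excluded
        self.tm_ranges = tm_ranges

    def fit(self, X, y=None):
        self.thresholds_ = FrequencyThresholds(ba1_min=self.ba1_min, bs1_min=self.bs1_min)
        self.profile_ = (
            ApplicabilityProfile(dict(self.excluded))
            if self.excluded is not None
            else ApplicabilityProfile()
        )
        self.n_features_in_ = 1
        return self

    def _apply_tm_ranges(self, av: AnnotatedVariant) -> AnnotatedVariant:
        if self.tm_ranges is None:
            return av
        domain = derive_domain(av.variant, self.tm_ranges)
        if domain is av.variant.domain:
            return av
        variant = Variant(
            gene=av.variant.gene,
            protein_change=av.variant.protein_change,
            variant_type=av.variant.variant_type,
            domain=domain,
            exon_label=av.variant.exon_label,
            prior_label=av.variant.prior_label,
        )
        return AnnotatedVariant(
            variant=variant,
            frequencies=av.frequencies,
            predictions=av.predictions,
            functional=av.functional,
            curated_codes=av.curated_codes,
        )

    def transform(self, X) -> list[tuple[AnnotatedVariant, EvidenceProfile]]:
        """Return (validated variant, evidence profile) pairs, row order kept."""
        check_is_fitted(self, "thresholds_")
        out = []
        for av in _coerce_variants(X):
            av = self._apply_tm_ranges(av)
            out.append((av, build_profile(av, self.profile_, self.thresholds_)))
        return out

    def transform_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Transform a table and append an ``evidence_codes`` column."""
        pairs = self.transform(X)
        out = X.copy()
        out["evidence_codes"] = [",".join(sorted(p.codes)) for _, p in pairs]
        return out


class ACMGClassifier(ClassifierMixin, BaseEstimator):
    """Five-tier ACMG-AMP classifier over evidence profiles.

    Accepts either the output of :class:`EvidenceAssigner` (pairs of
    variant and profile), bare :class:`EvidenceProfile` objects / code
    sets, or a DataFrame with an ``evidence_codes`` column.

    Parameters
    ----------
    rule_table : RuleTable, optional
        Combining-rule override; defaults to the 2015 categorical table.
    """

    def __init__(self, rule_table: RuleTable | None = None):
        self.rule_table = rule_table

    def fit(self, X=None, y=None):
        self.rule_table_ = self.rule_table or RuleTable()
        self.classes_ = np.array([t.label for t in Tier])
        return self

    @staticmethod
    def _coerce_profiles(X) -> list[EvidenceProfile]:
        if isinstance(X, pd.DataFrame):
            if "evidence_codes" not in X.columns:
                raise ValueError("DataFrame input requires an 'evidence_codes' column")
            return [
                EvidenceProfile(frozenset(c for c in str(cell).split(",") if c))
                if str(cell).strip()
                else EvidenceProfile(frozenset())
                for cell in X["evidence_codes"]
            ]
        profiles = []
        for item in X:
            if isinstance(item, EvidenceProfile):
                profiles.append(item)
            elif isinstance(item, tuple) and len(item) == 2 and isinstance(item[1], EvidenceProfile):
                profiles.append(item[1])
            else:
                profiles.append(EvidenceProfile(frozenset(item)))
        return profiles

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "rule_table_")
        return np.array(
            [explain(p, self.rule_table_).tier.label for p in self._coerce_profiles(X)]
        )

    def predict_tiers(self, X) -> list[Tier]:
        check_is_fitted(self, "rule_table_")
        return [explain(p, self.rule_table_).tier for p in self._coerce_profiles(X)]

    def explain(self, X):
        """Per-row explanation records (tier, reason, fired rules)."""
        check_is_fitted(self, "rule_table_")
        return [explain(p, self.rule_table_) for p in self._coerce_profiles(X)]
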