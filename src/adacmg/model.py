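"""Domain types for the APP/PSEN1/PSEN2 ACMG-AMP re-evaluation pipeline.

The unit of work is one literature-curated variant in one of the three
autosomal-dominant Alzheimer's disease genes, carrying

* identity: gene, protein-level label, variant type, transmembrane-domain
  location, exon label, and the classification reported by the source
  literature before re-evaluation;
* population allele frequencies from ESP6500, 1000 Genomes and ExAC;
* in-silico predictor verdicts (ten missense tools, two splice tools);
* functional-study outcomes on amyloid-beta readouts;
* curated ACMG-AMP criterion codes that cannot be derived from the above.

Protein-change strings are opaque labels; nothing here parses HGVS or
genomic coordinates.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Gene",
    "VariantType",
    "Domain",
    "PriorLabel",
    "Tier",
    "Verdict",
    "Effect",
    "Variant",
    "PopulationFrequencies",
    "InSilicoPredictions",
    "FunctionalResult",
    "EvidenceProfile",
    "AnnotatedVariant",
    "ValidationError",
    "ALL_CODES",
    "STRENGTH_CLASSES",
    "PATHOGENIC_CLASSES",
    "BENIGN_CLASSES",
    "COMPUTED_CODES",
    "MISSENSE_TOOLS",
    "SPLICE_TOOLS",
    "TABLE_COLUMNS",
    "strength_class",
    "validate_table",
    "read_table",
    "write_table",
    "to_frame",
]


class Gene(str, Enum):
    APP = "APP"
    PSEN1 = "PSEN1"
    PSEN2 = "PSEN2"


class VariantType(str, Enum):
    MISSENSE = "missense"
    INDEL = "indel"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    CNV = "CNV"
    UTR = "UTR"


class Domain(str, Enum):
    TM = "TM"
    NON_TM = "nonTM"
    NA = "NA"


class PriorLabel(str, Enum):
    PATHOGENIC = "pathogenic"
    NON_PATHOGENIC = "non_pathogenic"
    UNKNOWN = "unknown"


class Tier(Enum):
    """Five-tier classification, totally ordered from benign to pathogenic."""

    BENIGN = ("benign", 0)
    LIKELY_BENIGN = ("likely_benign", 1)
    VUS = ("VUS", 2)
    LIKELY_PATHOGENIC = ("likely_pathogenic", 3)
    PATHOGENIC = ("pathogenic", 4)

    def __init__(self, label: str, rank: int):
        self.label = label
        self.rank = rank

    def __lt__(self, other: "Tier") -> bool:
        return self.rank < other.rank

    def __le__(self, other: "Tier") -> bool:
        return self.rank <= other.rank

    def __gt__(self, other: "Tier") -> bool:
        return self.rank > other.rank

    def __ge__(self, other: "Tier") -> bool:
        return self.rank >= other.rank

    @classmethod
    def from_label(cls, label: str) -> "Tier":
        for t in cls:
            if t.label == label:
                return t
        raise ValueError(f"unknown tier label: {label!r}")


class Verdict(str, Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    UNAVAILABLE = "unavailable"


class Effect(str, Enum):
    INCREASED_AB42_40_RATIO = "increased_ab42_40_ratio"
    INCREASED_TOTAL_AB = "increased_total_ab"
    NO_EFFECT = "no_effect"
    OTHER = "other"


# The 28 ACMG-AMP criterion codes.
ALL_CODES: frozenset[str] = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

STRENGTH_CLASSES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")
PATHOGENIC_CLASSES = ("PVS", "PS", "PM", "PP")
BENIGN_CLASSES = ("BA", "BS", "BP")

#: Codes derived by the evidence engine; they may never appear as curated input.
COMPUTED_CODES: frozenset[str] = frozenset({"PM2", "PP3", "BP4", "PS3", "BS3", "BA1"})

#: Pairs of codes that can never co-occur in a valid profile.
EXCLUSION_PAIRS: tuple[frozenset[str], ...] = (
    frozenset({"PS3", "BS3"}),
    frozenset({"PM2", "BA1"}),
    frozenset({"PM2", "BS1"}),
    frozenset({"PP3", "BP4"}),
)

MISSENSE_TOOLS = (
    "sift",
    "polyphen2",
    "lrt",
    "mutationtaster",
    "mutationassessor",
    "fathmm",
    "provean",
    "cadd",
    "revel",
    "reve",
)
SPLICE_TOOLS = ("genesplicer", "hsf")

FREQ_SOURCES = ("esp6500", "1000g", "exac")

_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)$")


def strength_class(code: str) -> str:
    """Return the strength class (PVS/PS/PM/PP/BA/BS/BP) of a criterion code."""
    m = _CODE_RE.match(code)
    if not m or code not in ALL_CODES:
        raise ValueError(f"unknown ACMG criterion code: {code!r}")
    return m.group(1)


class ValidationError(ValueError):
    """Raised when an input record violates the table schema.

    Carries the 1-based data row number and offending field where known.
    """

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


@dataclass(frozen=True)
class Variant:
    gene: Gene
    protein_change: str
    variant_type: VariantType
    domain: Domain
    exon_label: str = ""
    prior_label: PriorLabel = PriorLabel.UNKNOWN


@dataclass(frozen=True)
class PopulationFrequencies:
    """Allele frequency per source; ``None`` means absent from that source."""

    esp6500: float | None = None
    g1000: float | None = None
    exac: float | None = None

    def __post_init__(self):
        for name in ("esp6500", "g1000", "exac"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"frequency {v} outside [0, 1]", field=name)

    def present(self) -> dict[str, float]:
        return {
            n: v
            for n, v in (("esp6500", self.esp6500), ("g1000", self.g1000), ("exac", self.exac))
            if v is not None
        }

    def absent_everywhere(self) -> bool:
        return not self.present()

    def max_present(self) -> float | None:
        vals = self.present().values()
        return max(vals) if vals else None


@dataclass(frozen=True)
class InSilicoPredictions:
    """Per-tool verdicts; missing tools default to ``unavailable``."""

    verdicts: Mapping[str, Verdict] = field(default_factory=dict)

    def __post_init__(self):
        known = set(MISSENSE_TOOLS) | set(SPLICE_TOOLS)
        for tool, v in self.verdicts.items():
            if tool not in known:
                raise ValidationError(f"unknown prediction tool {tool!r}", field=f"pred_{tool}")
            if not isinstance(v, Verdict):
                raise ValidationError(f"bad verdict {v!r}", field=f"pred_{tool}")

    def available(self, tools: Sequence[str]) -> dict[str, Verdict]:
        return {
            t: self.verdicts[t]
            for t in tools
            if self.verdicts.get(t, Verdict.UNAVAILABLE) is not Verdict.UNAVAILABLE
        }


@dataclass(frozen=True)
class FunctionalResult:
    study_id: str
    effect: Effect


@dataclass(frozen=True)
class EvidenceProfile:
    """An immutable set of active ACMG-AMP criterion codes."""

    codes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "codes", frozenset(self.codes))
        unknown = self.codes - ALL_CODES
        if unknown:
            raise ValidationError(f"unknown criterion codes: {sorted(unknown)}")
        for pair in EXCLUSION_PAIRS:
            if pair <= self.codes:
                raise ValidationError(
                    f"mutually exclusive codes co-occur: {sorted(pair)}"
                )

    def __iter__(self):
        return iter(self.codes)

    def __len__(self):
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Variant
    frequencies: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    predictions: InSilicoPredictions = field(default_factory=InSilicoPredictions)
    functional: tuple[FunctionalResult, ...] = ()
    curated_codes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "functional", tuple(self.functional))
        object.__setattr__(self, "curated_codes", frozenset(self.curated_codes))
        unknown = self.curated_codes - ALL_CODES
        if unknown:
            raise ValidationError(
                f"unknown curated codes: {sorted(unknown)}", field="curated_codes"
            )
        computed = self.curated_codes & COMPUTED_CODES
        if computed:
            raise ValidationError(
                f"curated_codes may not contain computed codes: {sorted(computed)}",
                field="curated_codes",
            )


# ---------------------------------------------------------------------------
# TSV schema

TABLE_COLUMNS: tuple[str, ...] = (
    "gene",
    "protein_change",
    "variant_type",
    "domain",
    "exon_label",
    "prior_label",
    "freq_esp6500",
    "freq_1000g",
    "freq_exac",
    *(f"pred_{t}" for t in MISSENSE_TOOLS),
    *(f"pred_{t}" for t in SPLICE_TOOLS),
    "functional",
    "curated_codes",
)


def _parse_enum(enum_cls, raw, row: int, fieldname: str):
    try:
        return enum_cls(raw)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"invalid value {raw!r} (expected one of: {valid})", row=row, field=fieldname
        ) from None


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == ""


def _parse_freq(raw, row: int, fieldname: str) -> float | None:
    if _is_blank(raw):
        return None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"not a number: {raw!r}", row=row, field=fieldname) from None
    if not (0.0 <= v <= 1.0):
        raise ValidationError(f"frequency {v} outside [0, 1]", row=row, field=fieldname)
    return v


def _parse_functional(raw, row: int) -> tuple[FunctionalResult, ...]:
    if _is_blank(raw):
        return ()
    out = []
    for item in str(raw).split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise ValidationError(
                f"expected 'study:effect', got {item!r}", row=row, field="functional"
            )
        study, effect_raw = item.rsplit(":", 1)
        effect = _parse_enum(Effect, effect_raw.strip(), row, "functional")
        out.append(FunctionalResult(study_id=study.strip(), effect=effect))
    return tuple(out)


def _record_to_variant(rec: Mapping, row: int) -> AnnotatedVariant:
    gene = _parse_enum(Gene, str(rec.get("gene", "")).strip(), row, "gene")
    vtype = _parse_enum(VariantType, str(rec.get("variant_type", "")).strip(), row, "variant_type")
    dom_raw = rec.get("domain", "")
    domain = Domain.NA if _is_blank(dom_raw) else _parse_enum(Domain, str(dom_raw).strip(), row, "domain")
    prior_raw = rec.get("prior_label", "")
    prior = (
        PriorLabel.UNKNOWN
        if _is_blank(prior_raw)
        else _parse_enum(PriorLabel, str(prior_raw).strip(), row, "prior_label")
    )
    variant = Variant(
        gene=gene,
        protein_change="" if _is_blank(rec.get("protein_change")) else str(rec["protein_change"]).strip(),
        variant_type=vtype,
        domain=domain,
        exon_label="" if _is_blank(rec.get("exon_label")) else str(rec["exon_label"]).strip(),
        prior_label=prior,
    )
    freqs = PopulationFrequencies(
        esp6500=_parse_freq(rec.get("freq_esp6500"), row, "freq_esp6500"),
        g1000=_parse_freq(rec.get("freq_1000g"), row, "freq_1000g"),
        exac=_parse_freq(rec.get("freq_exac"), row, "freq_exac"),
    )
    verdicts: dict[str, Verdict] = {}
    for tool in (*MISSENSE_TOOLS, *SPLICE_TOOLS):
        raw = rec.get(f"pred_{tool}")
        if _is_blank(raw):
            continue
        verdicts[tool] = _parse_enum(Verdict, str(raw).strip(), row, f"pred_{tool}")
    functional = _parse_functional(rec.get("functional"), row)
    codes_raw = rec.get("curated_codes")
    curated: frozenset[str] = frozenset()
    if not _is_blank(codes_raw):
        curated = frozenset(c.strip() for c in str(codes_raw).split(",") if c.strip())
    try:
        return AnnotatedVariant(
            variant=variant,
            frequencies=freqs,
            predictions=InSilicoPredictions(verdicts),
            functional=functional,
            curated_codes=curated,
        )
    except ValidationError as e:
        raise ValidationError(str(e), row=row) from None


def validate_table(rows: Iterable[Mapping]) -> list[AnnotatedVariant]:
    """Validate raw records against the table schema.

    Parameters
    ----------
    rows
        Mappings keyed by the TSV column names (see ``TABLE_COLUMNS``).

    Returns
    -------
    list of AnnotatedVariant, in input order.

    Raises
    ------
    ValidationError
        On the first malformed record, naming the 1-based data row and field.
    """
    return [_record_to_variant(rec, row) for row, rec in enumerate(rows, start=1)]


def read_table(path: str | Path | io.TextIOBase) -> list[AnnotatedVariant]:
    """Read and validate a variant table TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene", "variant_type") if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    return validate_table(df.to_dict(orient="records"))


def _variant_to_record(av: AnnotatedVariant) -> dict[str, str]:
    v = av.variant
    rec = {
        "gene": v.gene.value,
        "protein_change": v.protein_change,
        "variant_type": v.variant_type.value,
        "domain": v.domain.value,
        "exon_label": v.exon_label,
        "prior_label": v.prior_label.value,
        "freq_esp6500": "" if av.frequencies.esp6500 is None else repr(av.frequencies.esp6500),
        "freq_1000g": "" if av.frequencies.g1000 is None else repr(av.frequencies.g1000),
        "freq_exac": "" if av.frequencies.exac is None else repr(av.frequencies.exac),
    }
    for tool in (*MISSENSE_TOOLS, *SPLICE_TOOLS):
        verdict = av.predictions.verdicts.get(tool)
        rec[f"pred_{tool}"] = verdict.value if verdict is not None else ""
    rec["functional"] = ";".join(f"{f.study_id}:{f.effect.value}" for f in av.functional)
    rec["curated_codes"] = ",".join(sorted(av.curated_codes))
    return rec


def to_frame(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Render validated variants back into the flat table schema."""
    return pd.DataFrame(
        [_variant_to_record(av) for av in variants], columns=list(TABLE_COLUMNS)
    )


def write_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    to_frame(variants).to_csv(path, sep="\t", index=False)
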