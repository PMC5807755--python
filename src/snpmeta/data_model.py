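"""Study records, genetic-model contrasts and the genotype count-table CSV.

The atomic input of the pipeline is one case-control study's genotype
counts for a biallelic SNP, split into the three genotype classes
(homozygous reference, heterozygous, homozygous effect-allele) per arm,
plus the subgroup attributes used for stratified meta-analysis
(ethnicity, disease type, source of controls, gender).

Each of the five classical genetic models maps a record onto a 2x2
exposed/unexposed x case/control table.  "Exposed" always means the
category carrying the effect allele:

========================  =====================  =====================
model                     exposed                unexposed
========================  =====================  =====================
allele                    2*hom_alt + het        2*hom_ref + het
homozygote                hom_alt                hom_ref
heterozygote              het                    hom_ref
dominant                  het + hom_alt          hom_ref
recessive                 hom_alt                hom_ref + het
========================  =====================  =====================

The allele model counts alleles, so its table total is twice the number
of subjects; the homozygote and heterozygote models drop the excluded
genotype's subjects from the table entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd


class ValidationError(ValueError):
    """Raised when an input record or file fails validation."""


class Ethnicity(str, enum.Enum):
    ASIAN = "Asian"
    CAUCASIAN = "Caucasian"
    OTHER = "other"


class Disease(str, enum.Enum):
    HYPERTENSION = "hypertension"
    CAD = "CAD"
    IS = "IS"
    CI = "CI"
    MI = "MI"
    OTHER = "other"


class ControlSource(str, enum.Enum):
    POPULATION = "population"
    HOSPITAL = "hospital"


class Gender(str, enum.Enum):
    MIXED = "mixed"
    MALE = "male"
    FEMALE = "female"


class GeneticModel(str, enum.Enum):
    """The five 2x2 contrasts derivable from genotype counts."""

    ALLELE = "allele"
    HOMOZYGOTE = "homozygote"
    HETEROZYGOTE = "heterozygote"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


#: Exact header of the count-table CSV, in column order.
CSV_COLUMNS = [
    "study_id", "snp_id", "effect_allele", "ref_allele",
    "ethnicity", "disease", "control_source", "gender",
    "case_hom_ref", "case_het", "case_hom_alt",
    "ctrl_hom_ref", "ctrl_het", "ctrl_hom_alt",
]

_COUNT_COLUMNS = CSV_COLUMNS[8:]


def _coerce_enum(cls, value, field: str):
    if isinstance(value, cls):
        return value
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"invalid {field} {value!r}; expected one of: {allowed}"
        ) from None


def _coerce_count(value, field: str) -> int:
    try:
        as_float = float(value)
        as_int = int(as_float)
    except (TypeError, ValueError):
        raise ValidationError(f"{field} must be an integer, got {value!r}") from None
    if as_float != as_int:
        raise ValidationError(f"{field} must be an integer, got {value!r}")
    if as_int < 0:
        raise ValidationError(f"{field} must be non-negative, got {as_int}")
    return as_int


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposed/unexposed x case/control counts under one genetic model.

    ``a`` = exposed cases, ``b`` = unexposed cases, ``c`` = exposed
    controls, ``d`` = unexposed controls.  Entries are non-negative;
    they may be non-integral after a continuity correction.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValidationError(f"table cell {name} is negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class GenotypeCountRecord:
    """One study's case/control genotype counts and subgroup attributes."""

    study_id: str
    snp_id: str
    effect_allele: str
    ref_allele: str
    ethnicity: Ethnicity
    disease: Disease
    control_source: ControlSource
    gender: Gender
    case_hom_ref: int
    case_het: int
    case_hom_alt: int
    ctrl_hom_ref: int
    ctrl_het: int
    ctrl_hom_alt: int

    def __post_init__(self):
        object.__setattr__(self, "ethnicity",
                           _coerce_enum(Ethnicity, self.ethnicity, "ethnicity"))
        object.__setattr__(self, "disease",
                           _coerce_enum(Disease, self.disease, "disease"))
        object.__setattr__(self, "control_source",
                           _coerce_enum(ControlSource, self.control_source,
                                        "control_source"))
        object.__setattr__(self, "gender",
                           _coerce_enum(Gender, self.gender, "gender"))
        for field in _COUNT_COLUMNS:
            object.__setattr__(self, field,
                               _coerce_count(getattr(self, field), field))
        for allele_field in ("effect_allele", "ref_allele"):
            allele = getattr(self, allele_field)
            if not isinstance(allele, str) or len(allele) != 1:
                raise ValidationError(
                    f"{allele_field} must be a single character, got {allele!r}")
        if self.effect_allele == self.ref_allele:
            raise ValidationError("effect_allele must differ from ref_allele")
        if self.n_case == 0:
            raise ValidationError(f"study {self.study_id!r}: case arm is empty")
        if self.n_ctrl == 0:
            raise ValidationError(f"study {self.study_id!r}: control arm is empty")

    @property
    def n_case(self) -> int:
        """Number of case subjects (all genotypes)."""
        return self.case_hom_ref + self.case_het + self.case_hom_alt

    @property
    def n_ctrl(self) -> int:
        """Number of control subjects (all genotypes)."""
        return self.ctrl_hom_ref + self.ctrl_het + self.ctrl_hom_alt


def build_contrast(record: GenotypeCountRecord,
                   model: Union[GeneticModel, str]) -> TwoByTwoTable:
    """Collapse a record's genotype counts into the model's 2x2 table."""
    model = _coerce_enum(GeneticModel, model, "genetic model")
    cr, ch, ca = record.case_hom_ref, record.case_het, record.case_hom_alt
    kr, kh, ka = record.ctrl_hom_ref, record.ctrl_het, record.ctrl_hom_alt
    if model is GeneticModel.ALLELE:
        return TwoByTwoTable(2 * ca + ch, 2 * cr + ch, 2 * ka + kh, 2 * kr + kh)
    if model is GeneticModel.HOMOZYGOTE:
        return TwoByTwoTable(ca, cr, ka, kr)
    if model is GeneticModel.HETEROZYGOTE:
        return TwoByTwoTable(ch, cr, kh, kr)
    if model is GeneticModel.DOMINANT:
        return TwoByTwoTable(ch + ca, cr, kh + ka, kr)
    # recessive
    return TwoByTwoTable(ca, cr + ch, ka, kr + kh)


def read_counts_csv(path: Union[str, Path]) -> list[GenotypeCountRecord]:
    """Read a genotype count table (see :data:`CSV_COLUMNS` for the schema).

    Raises :class:`ValidationError` naming the missing column or the
    offending data row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        values = dict(zip(frame.columns, row))
        try:
            records.append(GenotypeCountRecord(
                **{col: values[col] for col in CSV_COLUMNS}))
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
    return records


def write_counts_csv(records: Iterable[GenotypeCountRecord],
                     path: Union[str, Path]) -> None:
    """Write records to CSV with the canonical column order."""
    rows = []
    for rec in records:
        row = asdict(rec)
        for key, value in row.items():
            if isinstance(value, enum.Enum):
                row[key] = value.value
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def filter_by_snp(records: Sequence[GenotypeCountRecord],
                  snp_id: str) -> list[GenotypeCountRecord]:
    """Subset records to one SNP."""
    return [r for r in records if r.snp_id == snp_id]
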