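"""Stage 1: partition the registry table and harvest variant submissions.

The registry arrives as one CSV row per subject.  Rows are first split by
disorder category and disease (quarantining, never silently dropping,
anything with an unknown disease code), then each subject's raw variant
fields are parsed.  Free-text tokens meaning "no variant" are filtered and
counted, and a subject counts as genotyped only when at least one field
parses to an actual variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .variant_parsing import (
    DEFAULT_INVALID_TOKENS,
    MappingStatus,
    NormalizedVariant,
    parse_variant_string,
)

__all__ = [
    "SUBJECT_COLUMNS",
    "VARIANT_COLUMNS",
    "SubjectRecord",
    "Observation",
    "PartitionResult",
    "HarvestResult",
    "partition_by_disease",
    "harvest_variants",
    "read_subjects",
]

logger = logging.getLogger(__name__)

#: Schema of the subject-level registry CSV (documented in docs/subject_schema.md).
SUBJECT_COLUMNS = [
    "subject_id",
    "disease",
    "category",
    "gene",
    "transcript",
    "confirmed_dx",
    "variant_1",
    "variant_2",
    "fh_affected_carrier_variant",
    "fh_de_novo_variant",
    "fh_parents_confirmed",
    "phase_tested",
    "in_trans",
]

VARIANT_COLUMNS = ["variant_1", "variant_2"]


def _as_bool(value: object) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes"}
    return bool(value) and value == value  # NaN -> False


def _as_text(value: object) -> str:
    if value is None or value != value:
        return ""
    return str(value).strip()


@dataclass(frozen=True)
class SubjectRecord:
    """One enrollee's evidence-bearing fields."""

    subject_id: str
    disease: str
    category: str
    gene: str
    transcript: str
    confirmed_dx: bool
    raw_variants: tuple[str, ...]
    fh_affected_carrier_variant: str = ""
    fh_de_novo_variant: str = ""
    fh_parents_confirmed: bool = False
    phase_tested: bool = False
    in_trans: bool = False

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        raw = tuple(
            _as_text(row.get(col)) for col in VARIANT_COLUMNS if _as_text(row.get(col))
        )
        return cls(
            subject_id=str(row["subject_id"]),
            disease=str(row["disease"]),
            category=_as_text(row.get("category")),
            gene=_as_text(row.get("gene")),
            transcript=_as_text(row.get("transcript")),
            confirmed_dx=_as_bool(row.get("confirmed_dx", True)),
            raw_variants=raw,
            fh_affected_carrier_variant=_as_text(row.get("fh_affected_carrier_variant")),
            fh_de_novo_variant=_as_text(row.get("fh_de_novo_variant")),
            fh_parents_confirmed=_as_bool(row.get("fh_parents_confirmed")),
            phase_tested=_as_bool(row.get("phase_tested")),
            in_trans=_as_bool(row.get("in_trans")),
        )


@dataclass(frozen=True)
class Observation:
    """One non-invalid raw variant string from one subject."""

    subject_id: str
    disease: str
    gene: str
    raw: str
    variant: NormalizedVariant


@dataclass
class PartitionResult:
    tables: dict[str, pd.DataFrame]
    counts: dict[str, int]
    quarantined: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return sum(self.counts.values())

    def category_counts(self) -> dict[str, int]:
        """Number of distinct diseases per disorder category."""
        cats: dict[str, set[str]] = {}
        for disease, table in self.tables.items():
            if len(table):
                cats.setdefault(str(table["category"].iloc[0]), set()).add(disease)
        return {cat: len(dis) for cat, dis in sorted(cats.items())}


def partition_by_disease(
    subjects: pd.DataFrame,
    known_diseases: Optional[Iterable[str]] = None,
) -> PartitionResult:
    """Split the registry table into disease-keyed tables.

    Every row lands in exactly one disease table; rows whose disease code is
    not in ``known_diseases`` (when given) are quarantined and logged rather
    than dropped.
    """
    if "disease" not in subjects.columns or "subject_id" not in subjects.columns:
        raise ValueError("subject table must have 'subject_id' and 'disease' columns")
    known = set(known_diseases) if known_diseases is not None else None
    if known is not None:
        bad_mask = ~subjects["disease"].astype(str).isin(known)
        quarantined = subjects.loc[bad_mask].copy()
        kept = subjects.loc[~bad_mask]
        if len(quarantined):
            logger.warning(
                "quarantined %d rows with unknown disease codes: %s",
                len(quarantined),
                sorted(set(quarantined["disease"].astype(str))),
            )
    else:
        quarantined = subjects.iloc[0:0].copy()
        kept = subjects
    tables = {
        str(disease): group.reset_index(drop=True)
        for disease, group in kept.groupby("disease", sort=True)
    }
    counts = {disease: len(table) for disease, table in tables.items()}
    return PartitionResult(tables=tables, counts=counts, quarantined=quarantined)


@dataclass
class HarvestResult:
    """Variant observations harvested from one (or more) disease tables."""

    observations: list[Observation] = field(default_factory=list)
    filtered_tokens: list[tuple[str, str]] = field(default_factory=list)
    n_fields: int = 0
    n_empty: int = 0
    genotyped_ids: set[str] = field(default_factory=set)
    subject_ids: set[str] = field(default_factory=set)

    @property
    def n_genotyped(self) -> int:
        return len(self.genotyped_ids)

    @property
    def valid_observations(self) -> list[Observation]:
        return [
            o
            for o in self.observations
            if o.variant.mapping_status is MappingStatus.MAPPED
        ]

    def conserved(self) -> bool:
        """Filtered tokens + observations + empty fields = total fields."""
        return (
            len(self.filtered_tokens) + len(self.observations) + self.n_empty
            == self.n_fields
        )

    def merge(self, other: "HarvestResult") -> "HarvestResult":
        return HarvestResult(
            observations=self.observations + other.observations,
            filtered_tokens=self.filtered_tokens + other.filtered_tokens,
            n_fields=self.n_fields + other.n_fields,
            n_empty=self.n_empty + other.n_empty,
            genotyped_ids=self.genotyped_ids | other.genotyped_ids,
            subject_ids=self.subject_ids | other.subject_ids,
        )


def harvest_variants(
    disease_table: pd.DataFrame,
    invalid_tokens: Iterable[str] = DEFAULT_INVALID_TOKENS,
) -> HarvestResult:
    """Harvest each subject's raw variant fields into observations.

    Empty fields are tallied separately from filtered invalid tokens so the
    conservation identity (tokens + observations + empties = fields) holds.
    """
    tokens = {t.lower() for t in invalid_tokens} - {""}
    result = HarvestResult()
    for _, row in disease_table.iterrows():
        subject_id = str(row["subject_id"])
        disease = str(row["disease"])
        gene = _as_text(row.get("gene")) or None
        result.subject_ids.add(subject_id)
        for col in VARIANT_COLUMNS:
            if col not in disease_table.columns:
                continue
            result.n_fields += 1
            text = _as_text(row.get(col))
            if not text:
                result.n_empty += 1
                continue
            if text.lower() in tokens:
                result.filtered_tokens.append((subject_id, text))
                continue
            variant = parse_variant_string(text, gene, invalid_tokens=tokens)
            result.observations.append(
                Observation(
                    subject_id=subject_id,
                    disease=disease,
                    gene=gene or "",
                    raw=text,
                    variant=variant,
                )
            )
            if variant.mapping_status is MappingStatus.MAPPED:
                result.genotyped_ids.add(subject_id)
    return result


def read_subjects(path) -> pd.DataFrame:
    """Read a subject registry CSV (UTF-8, header row required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"subject_id", "disease"} - set(df.columns)
    if missing:
        raise ValueError(f"subject CSV missing required columns: {sorted(missing)}")
    return df
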