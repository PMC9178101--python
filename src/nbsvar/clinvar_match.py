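"""Stages 2-3: convert ClinVar-style extracts, match, and deduplicate.

A gene extract row names a variant in HGVS form
(``NM_000155.4(GALT):c.601C>T (p.Arg201Cys)``).  The protein segment is
converted to single-letter form so that registry submissions reported as
``R201C`` compare directly.  Matching is c.-anchored: when a registry
variant carries coding-DNA notation it must match on gene + c. string;
otherwise it matches on gene + protein change.  No cross-level inference is
attempted (a protein-only submission never matches a c.-only extract row),
and transcript accession versions are ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .case_data import Observation
from .variant_parsing import (
    MappingStatus,
    NormalizedVariant,
    parse_variant_string,
)

__all__ = [
    "SIGNIFICANCE_TERMS",
    "REVIEW_STATUS_STARS",
    "ClinVarEntry",
    "DistinctVariant",
    "ExtractConversion",
    "ExtractIndex",
    "convert_extract",
    "match_variant",
    "deduplicate",
    "read_extract",
]

logger = logging.getLogger(__name__)

#: The five ACMG/AMP standard significance terms plus ClinVar's conflict bin.
SIGNIFICANCE_TERMS = (
    "Benign",
    "Likely Benign",
    "Uncertain Significance",
    "Likely Pathogenic",
    "Pathogenic",
    "Conflicting Interpretations of Pathogenicity",
)

_SIGNIFICANCE_ALIASES = {
    "benign": "Benign",
    "likely benign": "Likely Benign",
    "uncertain significance": "Uncertain Significance",
    "of uncertain significance": "Uncertain Significance",
    "variant of uncertain significance": "Uncertain Significance",
    "vus": "Uncertain Significance",
    "likely pathogenic": "Likely Pathogenic",
    "pathogenic": "Pathogenic",
    "pathogenic/likely pathogenic": "Likely Pathogenic",
    "conflicting interpretations of pathogenicity": (
        "Conflicting Interpretations of Pathogenicity"
    ),
}

#: ClinVar review-status phrases -> star count.
REVIEW_STATUS_STARS = {
    "no assertion criteria provided": 0,
    "no assertion provided": 0,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting interpretations": 1,
    "criteria provided, multiple submitters, no conflicts": 2,
    "reviewed by expert panel": 3,
    "practice guideline": 4,
}


def canonical_significance(text: object) -> Optional[str]:
    if text is None or text != text:
        return None
    cleaned = str(text).split("(")[0].strip().lower()
    return _SIGNIFICANCE_ALIASES.get(cleaned)


def parse_review_stars(value: object) -> int:
    """Accept either a star count or a ClinVar review-status phrase."""
    if value is None or value != value:
        return 0
    text = str(value).strip()
    if text.isdigit():
        return min(int(text), 4)
    return REVIEW_STATUS_STARS.get(text.lower(), 0)


@dataclass(frozen=True)
class ClinVarEntry:
    """One converted extract row."""

    gene: str
    name: str
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    significance: str = "Uncertain Significance"
    review_stars: int = 0
    snapshot_date: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("ClinVar entry requires a gene symbol")
        if self.significance not in SIGNIFICANCE_TERMS:
            raise ValueError(f"unknown significance term: {self.significance!r}")

    @property
    def key(self) -> Optional[str]:
        gene = self.gene.upper()
        if self.cdna_change:
            return f"{gene}|c:{self.cdna_change}"
        if self.protein_change:
            return f"{gene}|p:{self.protein_change}"
        return None

    @property
    def protein_key(self) -> Optional[str]:
        if self.protein_change:
            return f"{self.gene.upper()}|p:{self.protein_change}"
        return None


@dataclass
class ExtractConversion:
    entries: list[ClinVarEntry]
    n_skipped: int = 0


def convert_extract(
    extract: pd.DataFrame, snapshot_date: Optional[str] = None
) -> ExtractConversion:
    """Convert raw extract rows into matchable :class:`ClinVarEntry` objects.

    The HGVS protein segment of each Name is converted to single-letter
    form.  Malformed rows are logged and skipped, with a count returned.
    """
    gene_col = next(
        (c for c in ("Gene", "Gene(s)", "gene") if c in extract.columns), None
    )
    sig_col = next(
        (c for c in extract.columns if c.lower().startswith("clinical significance")),
        None,
    )
    status_col = next(
        (c for c in extract.columns if c.lower().startswith("review status")), None
    )
    protein_col = next(
        (c for c in extract.columns if c.lower().startswith("protein change")), None
    )
    if "Name" not in extract.columns:
        raise ValueError("extract is missing the 'Name' column")

    entries: list[ClinVarEntry] = []
    n_skipped = 0
    for _, row in extract.iterrows():
        name = str(row["Name"]).strip()
        gene = str(row[gene_col]).strip() if gene_col else ""
        parsed = parse_variant_string(name, gene or None)
        if parsed.mapping_status is not MappingStatus.MAPPED:
            # Fall back to the dedicated protein-change column.
            fallback = str(row[protein_col]).strip() if protein_col else ""
            parsed = parse_variant_string(fallback, gene or None)
        if parsed.mapping_status is not MappingStatus.MAPPED or not (
            parsed.gene or gene
        ):
            n_skipped += 1
            logger.warning("skipping malformed extract row: %r", name)
            continue
        significance = canonical_significance(row[sig_col]) if sig_col else None
        entries.append(
            ClinVarEntry(
                gene=(parsed.gene or gene).upper(),
                name=name,
                cdna_change=parsed.cdna_change,
                protein_change=parsed.protein_change,
                significance=significance or "Uncertain Significance",
                review_stars=parse_review_stars(row[status_col]) if status_col else 0,
                snapshot_date=snapshot_date,
            )
        )
    return ExtractConversion(entries=entries, n_skipped=n_skipped)


_PROT_POS = re.compile(r"^([A-Z])(\d+)([A-Z*]|fs)$")


class ExtractIndex:
    """Lookup structure over converted extract entries.

    Indexed three ways: by c.-anchored key, by protein-level key, and by
    (gene, residue position) for same-residue neighbour queries (PM5).
    The first entry wins on key collisions, so lookups are deterministic
    under row reordering only if entries are sorted first — `from_entries`
    sorts by name for exactly that reason.
    """

    def __init__(self, entries: Iterable[ClinVarEntry]):
        self._by_key: dict[str, ClinVarEntry] = {}
        self._by_protein: dict[str, ClinVarEntry] = {}
        self._by_residue: dict[tuple[str, int], list[ClinVarEntry]] = {}
        self.entries = list(entries)
        for entry in self.entries:
            if entry.key and entry.key not in self._by_key:
                self._by_key[entry.key] = entry
            pk = entry.protein_key
            if pk and pk not in self._by_protein:
                self._by_protein[pk] = entry
            if entry.protein_change:
                m = _PROT_POS.match(entry.protein_change)
                if m:
                    self._by_residue.setdefault(
                        (entry.gene.upper(), int(m.group(2))), []
                    ).append(entry)

    @classmethod
    def from_entries(cls, entries: Iterable[ClinVarEntry]) -> "ExtractIndex":
        return cls(sorted(entries, key=lambda e: (e.gene, e.name)))

    @classmethod
    def from_frame(
        cls, extract: pd.DataFrame, snapshot_date: Optional[str] = None
    ) -> "ExtractIndex":
        return cls.from_entries(convert_extract(extract, snapshot_date).entries)

    def lookup(self, v: NormalizedVariant) -> Optional[ClinVarEntry]:
        """c.-anchored when the query has c. notation, else protein-level."""
        if v.gene is None:
            return None
        gene = v.gene.upper()
        if v.cdna_change:
            return self._by_key.get(f"{gene}|c:{v.cdna_change}")
        if v.protein_change:
            return self._by_protein.get(f"{gene}|p:{v.protein_change}")
        return None

    def same_residue_entries(self, gene: str, position: int) -> list[ClinVarEntry]:
        return self._by_residue.get((gene.upper(), position), [])


def match_variant(v: NormalizedVariant, extract: ExtractIndex) -> bool:
    """``True`` when the registry variant is published in the extract."""
    return extract.lookup(v) is not None


@dataclass
class DistinctVariant:
    """A deduplicated variant with its supporting subjects."""

    variant: NormalizedVariant
    subject_ids: tuple[str, ...]
    diseases: tuple[str, ...]
    allele_count: int
    published: bool = False
    clinvar_entry: Optional[ClinVarEntry] = None


def deduplicate(
    observations: Iterable[Observation],
    extract: Optional[ExtractIndex] = None,
) -> list[DistinctVariant]:
    """Collapse observations with identical (gene, canonical key).

    Supporting subjects accumulate per distinct variant; a homozygous
    subject reporting the same string twice contributes one supporter but
    two alleles.  When an extract index is supplied the published flag and
    matched entry are filled in.  Output order is sorted by key, so the
    result is independent of observation order.
    """
    groups: dict[str, list[Observation]] = {}
    for obs in observations:
        key = obs.variant.key
        if key is None:
            continue  # invalid tokens / unparseable never reach matching
        groups.setdefault(key, []).append(obs)

    distinct: list[DistinctVariant] = []
    for key in sorted(groups):
        obs_list = groups[key]
        subjects = tuple(sorted({o.subject_id for o in obs_list}))
        diseases = tuple(sorted({o.disease for o in obs_list}))
        variant = obs_list[0].variant
        entry = extract.lookup(variant) if extract is not None else None
        distinct.append(
            DistinctVariant(
                variant=variant,
                subject_ids=subjects,
                diseases=diseases,
                allele_count=len(obs_list),
                published=entry is not None,
                clinvar_entry=entry,
            )
        )
    return distinct


def read_extract(path) -> pd.DataFrame:
    """Read a ClinVar-style gene extract CSV."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)
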