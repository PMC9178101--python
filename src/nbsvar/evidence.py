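"""Stage 4: map longitudinal clinical data to ACMG/AMP evidence criteria.

Every mapped unpublished variant in this cohort receives PS3 (all subjects
were diagnosed through functional blood metabolite or enzyme assays via the
newborn screen plus confirmatory testing) and PP4 (the screened disorders
are well-characterised single-gene diseases with a distinctive early-onset
phenotype).  The remaining criteria are data-driven:

* PVS1 — predicted null variant (nonsense, frameshift, canonical +-1/2
  splice, start loss), from notation alone.
* PM3 — for autosomal recessive disease, a supporting subject's other
  allele is published Pathogenic/Likely Pathogenic (reported variants are
  assumed in trans).
* PM5 — novel missense at a residue where a different missense change is
  published Pathogenic/Likely Pathogenic.
* PM6 — de novo indication in the family history without confirmed
  parentage.
* PP1 — an affected relative carries the same variant.
* PP3 / BP4 — all available in-silico predictor calls deleterious /
  neutral (at least one call; discordant calls yield neither).
* PP5 — reported Pathogenic/Likely Pathogenic in a secondary database.
* BP7 — synonymous change with no deleterious predictor call.

Population-data criteria (PM2, BA1, BS1, ...) are representable by the
engine but never auto-assigned here, because the registry generates no
population data; they can be injected through the manual-override file.
Unmapped variants (wrong reference residue) receive no criteria at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .acmg_engine import ALL_CRITERIA, CRITERION_STRENGTH, Strength
from .case_data import SubjectRecord
from .clinvar_match import DistinctVariant, ExtractIndex, _PROT_POS
from .variant_parsing import (
    Consequence,
    MappingStatus,
    NormalizedVariant,
    parse_variant_string,
)

__all__ = [
    "EvidenceCriterion",
    "CriteriaProfile",
    "PredictionTable",
    "SecondaryDatabase",
    "assign_global_criteria",
    "assess_pvs1",
    "assess_pm3",
    "assess_pm5",
    "assess_family",
    "assess_computational",
    "assess_pp5",
    "assess_bp7",
    "build_profile",
    "apply_overrides",
]

logger = logging.getLogger(__name__)

_PLP = {"Pathogenic", "Likely Pathogenic"}
AUTOSOMAL_RECESSIVE = "autosomal_recessive"


@dataclass(frozen=True)
class EvidenceCriterion:
    """One ACMG/AMP evidence code with its fixed strength."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in ALL_CRITERIA:
            raise ValueError(f"unknown ACMG/AMP criterion code: {self.code!r}")

    @property
    def strength(self) -> Strength:
        return CRITERION_STRENGTH[self.code]

    @property
    def benign_axis(self) -> bool:
        return self.code.startswith("B")


@dataclass
class CriteriaProfile:
    """The evidence codes attached to one distinct variant, with provenance."""

    variant: DistinctVariant
    criteria: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, code: str, why: str) -> None:
        EvidenceCriterion(code)  # validates
        self.criteria.add(code)
        self.provenance[code] = why

    def remove(self, code: str, why: str) -> None:
        self.criteria.discard(code)
        self.provenance[code] = f"removed: {why}"


class PredictionTable:
    """In-silico predictor calls, keyed by c.- or protein-level variant key.

    Expected columns: ``gene``, ``tool``, ``call`` plus at least one of
    ``cdna_change`` / ``protein_change``.  Calls are ``deleterious`` or
    ``neutral``.
    """

    def __init__(self, frame: Optional[pd.DataFrame] = None):
        self._calls: dict[str, list[tuple[str, str]]] = {}
        if frame is not None:
            for _, row in frame.iterrows():
                gene = str(row["gene"]).upper()
                call = str(row["call"]).strip().lower()
                tool = str(row.get("tool", ""))
                for level, col in (("c", "cdna_change"), ("p", "protein_change")):
                    value = row.get(col)
                    if value is not None and value == value and str(value).strip():
                        key = f"{gene}|{level}:{str(value).strip()}"
                        self._calls.setdefault(key, []).append((tool, call))

    def lookup(self, v: NormalizedVariant) -> list[tuple[str, str]]:
        if v.gene is None:
            return []
        gene = v.gene.upper()
        if v.cdna_change:
            calls = self._calls.get(f"{gene}|c:{v.cdna_change}")
            if calls:
                return calls
        if v.protein_change:
            return self._calls.get(f"{gene}|p:{v.protein_change}", [])
        return []


class SecondaryDatabase:
    """A secondary source of published variants (ClinVitae-style extract)."""

    def __init__(self, frame: Optional[pd.DataFrame] = None):
        self._sig: dict[str, str] = {}
        if frame is not None:
            for _, row in frame.iterrows():
                gene = str(row["gene"]).upper()
                sig = str(row["significance"]).strip()
                for level, col in (("c", "cdna_change"), ("p", "protein_change")):
                    value = row.get(col)
                    if value is not None and value == value and str(value).strip():
                        self._sig.setdefault(f"{gene}|{level}:{str(value).strip()}", sig)

    def lookup(self, v: NormalizedVariant) -> Optional[str]:
        if v.gene is None:
            return None
        gene = v.gene.upper()
        if v.cdna_change:
            sig = self._sig.get(f"{gene}|c:{v.cdna_change}")
            if sig:
                return sig
        if v.protein_change:
            return self._sig.get(f"{gene}|p:{v.protein_change}")
        return None


# ---------------------------------------------------------------------------
# Individual assessments
# ---------------------------------------------------------------------------


def assign_global_criteria(
    dv: DistinctVariant, subjects: Mapping[str, SubjectRecord]
) -> set[str]:
    """PS3 + PP4 for mapped variants whose supporters all have a confirmed
    diagnosis; unmapped variants receive nothing."""
    if dv.variant.mapping_status is not MappingStatus.MAPPED:
        return set()
    unconfirmed = [
        sid for sid in dv.subject_ids if not subjects[sid].confirmed_dx
    ]
    if unconfirmed:
        logger.warning(
            "PS3/PP4 withheld for %s: supporters without confirmed diagnosis: %s",
            dv.variant.key,
            unconfirmed,
        )
        return set()
    return {"PS3", "PP4"}


def assess_pvs1(v: NormalizedVariant) -> bool:
    """PVS1 iff the variant is a predicted null."""
    return v.is_null


def assess_pm3(
    dv: DistinctVariant,
    alleles_by_subject: Mapping[str, list[NormalizedVariant]],
    extract: ExtractIndex,
    inheritance: str = AUTOSOMAL_RECESSIVE,
) -> Optional[str]:
    """PM3 when, in a recessive disease, some supporter's other allele is a
    published Pathogenic/Likely Pathogenic variant.

    Returns the supporting subject id, or ``None``.  The partner allele
    must itself be published at that strength: an unpublished or VUS
    partner does not qualify.
    """
    if inheritance != AUTOSOMAL_RECESSIVE:
        return None
    for sid in dv.subject_ids:
        for partner in alleles_by_subject.get(sid, []):
            if partner.key is None or partner.key == dv.variant.key:
                continue
            entry = extract.lookup(partner)
            if entry is not None and entry.significance in _PLP:
                return sid
    return None


def assess_pm5(v: NormalizedVariant, extract: ExtractIndex) -> Optional[str]:
    """PM5 for a novel missense at a residue carrying a published
    Pathogenic/Likely Pathogenic missense with a different alternate.

    Returns the neighbouring entry's name, or ``None``.
    """
    if v.consequence is not Consequence.MISSENSE or not v.protein_change:
        return None
    m = _PROT_POS.match(v.protein_change)
    if m is None or v.gene is None:
        return None
    position = int(m.group(2))
    for entry in extract.same_residue_entries(v.gene, position):
        if entry.protein_change == v.protein_change:
            continue
        nm = _PROT_POS.match(entry.protein_change or "")
        if nm is None or nm.group(3) in {"*", "fs"}:
            continue  # neighbour must itself be missense
        if nm.group(3) == nm.group(1):
            continue
        if entry.significance in _PLP:
            return entry.name
    return None


def assess_family(
    dv: DistinctVariant, subjects: Mapping[str, SubjectRecord]
) -> dict[str, str]:
    """Segregation and de novo evidence from family-history fields.

    PP1 when an affected relative carries the same variant; PM6 when a de
    novo indication exists without confirmed parentage.  Returns a mapping
    of code -> provenance note (empty when neither applies).
    """
    found: dict[str, str] = {}
    for sid in dv.subject_ids:
        record = subjects[sid]
        if "PP1" not in found and record.fh_affected_carrier_variant:
            carried = parse_variant_string(
                record.fh_affected_carrier_variant, record.gene or dv.variant.gene
            )
            if carried.key == dv.variant.key:
                found["PP1"] = f"affected relative of subject {sid} carries the variant"
        if "PM6" not in found and record.fh_de_novo_variant:
            denovo = parse_variant_string(
                record.fh_de_novo_variant, record.gene or dv.variant.gene
            )
            if denovo.key == dv.variant.key and not record.fh_parents_confirmed:
                found["PM6"] = f"de novo indication for subject {sid}, parentage unconfirmed"
    return found


def assess_computational(
    v: NormalizedVariant, predictions: PredictionTable
) -> Optional[str]:
    """PP3 when every available predictor call is deleterious, BP4 when
    every call is neutral (at least one call either way); discordant or
    absent calls yield neither."""
    calls = [call for _, call in predictions.lookup(v)]
    if not calls:
        return None
    if all(c == "deleterious" for c in calls):
        return "PP3"
    if all(c == "neutral" for c in calls):
        return "BP4"
    return None


def assess_pp5(v: NormalizedVariant, secondary: SecondaryDatabase) -> Optional[str]:
    """PP5 when a reputable secondary database reports the variant
    Pathogenic/Likely Pathogenic."""
    sig = secondary.lookup(v)
    if sig in _PLP:
        return sig
    return None


def assess_bp7(v: NormalizedVariant, predictions: PredictionTable) -> bool:
    """BP7 for a synonymous change that no predictor calls deleterious."""
    if v.consequence is not Consequence.SYNONYMOUS:
        return False
    calls = [call for _, call in predictions.lookup(v)]
    return not any(c == "deleterious" for c in calls)


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------


def build_profile(
    dv: DistinctVariant,
    subjects: Mapping[str, SubjectRecord],
    alleles_by_subject: Mapping[str, list[NormalizedVariant]],
    extract: ExtractIndex,
    predictions: Optional[PredictionTable] = None,
    secondary: Optional[SecondaryDatabase] = None,
    inheritance: str = AUTOSOMAL_RECESSIVE,
) -> CriteriaProfile:
    """Assemble the full criteria profile for one distinct variant.

    Order-independent over subjects; unmapped variants always come back
    with an empty profile.
    """
    profile = CriteriaProfile(variant=dv)
    if dv.variant.mapping_status is not MappingStatus.MAPPED:
        return profile
    predictions = predictions or PredictionTable()
    secondary = secondary or SecondaryDatabase()

    for code in sorted(assign_global_criteria(dv, subjects)):
        why = (
            "functional confirmation by newborn screen + diagnostic assay"
            if code == "PS3"
            else "well-characterised single-gene disorder phenotype"
        )
        profile.add(code, why)
    if assess_pvs1(dv.variant):
        profile.add("PVS1", f"predicted null ({dv.variant.consequence.value})")
    pm3_sid = assess_pm3(dv, alleles_by_subject, extract, inheritance)
    if pm3_sid is not None:
        profile.add("PM3", f"in-trans published P/LP allele in subject {pm3_sid}")
    pm5_name = assess_pm5(dv.variant, extract)
    if pm5_name is not None:
        profile.add("PM5", f"published P/LP missense at same residue: {pm5_name}")
    for code, why in assess_family(dv, subjects).items():
        profile.add(code, why)
    comp = assess_computational(dv.variant, predictions)
    if comp is not None:
        profile.add(comp, "concordant in-silico predictor calls")
    pp5_sig = assess_pp5(dv.variant, secondary)
    if pp5_sig is not None:
        profile.add("PP5", f"secondary database reports {pp5_sig}")
    if assess_bp7(dv.variant, predictions):
        profile.add("BP7", "synonymous, no deleterious predictor call")
    return profile


def apply_overrides(
    profiles: Mapping[str, CriteriaProfile], overrides: pd.DataFrame
) -> int:
    """Apply a curator override CSV of (variant_key, criterion, action).

    ``action`` is ``add`` or ``remove``; every application is logged into
    the profile's provenance.  Returns the number of overrides applied.
    """
    applied = 0
    for _, row in overrides.iterrows():
        key = str(row["variant_key"])
        code = str(row["criterion"]).upper()
        action = str(row["action"]).strip().lower()
        profile = profiles.get(key)
        if profile is None:
            logger.warning("override for unknown variant key %r ignored", key)
            continue
        if profile.variant.variant.mapping_status is not MappingStatus.MAPPED:
            logger.warning("override for unmapped variant %r ignored", key)
            continue
        if action == "add":
            profile.add(code, "manual override")
        elif action == "remove":
            profile.remove(code, "manual override")
        else:
            raise ValueError(f"override action must be add/remove, got {action!r}")
        applied += 1
    return applied
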