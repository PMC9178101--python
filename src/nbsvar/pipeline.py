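"""End-to-end orchestration of the classification pipeline.

Stage order mirrors the analysis: partition the registry by disease,
harvest variant submissions, convert the database extract, match and
deduplicate, validate reference residues for the unpublished set, assign
evidence criteria, and classify with the combining-rule engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .acmg_engine import ClassificationResult, classify_profile
from .case_data import (
    HarvestResult,
    SubjectRecord,
    harvest_variants,
    partition_by_disease,
    PartitionResult,
)
from .clinvar_match import DistinctVariant, ExtractIndex, deduplicate
from .evidence import (
    AUTOSOMAL_RECESSIVE,
    CriteriaProfile,
    PredictionTable,
    SecondaryDatabase,
    apply_overrides,
    build_profile,
)
from .variant_parsing import (
    MappingStatus,
    NormalizedVariant,
    ReferenceSet,
    validate_reference,
)

__all__ = ["PipelineRun", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineRun:
    """All intermediate and final products of one pipeline execution."""

    partition: PartitionResult
    harvest: HarvestResult
    harvest_by_disease: dict[str, HarvestResult]
    subjects: dict[str, SubjectRecord]
    extract_index: ExtractIndex
    distinct: list[DistinctVariant]
    profiles: dict[str, CriteriaProfile]
    classifications: dict[str, ClassificationResult]
    strict_lp3: bool = False

    @property
    def published(self) -> list[DistinctVariant]:
        return [dv for dv in self.distinct if dv.published]

    @property
    def unpublished(self) -> list[DistinctVariant]:
        return [dv for dv in self.distinct if not dv.published]

    @property
    def unmapped(self) -> list[DistinctVariant]:
        return [
            dv
            for dv in self.unpublished
            if dv.variant.mapping_status
            is MappingStatus.UNMAPPED_REFERENCE_MISMATCH
        ]

    def classified_pairs(
        self, include_unmapped: bool = False
    ) -> list[tuple[DistinctVariant, ClassificationResult]]:
        """(variant, classification) for the classified unpublished variants.

        Unmapped variants were never assigned a classification and are
        excluded unless ``include_unmapped`` is set.
        """
        return [
            (dv, self.classifications[dv.variant.key])
            for dv in self.unpublished
            if include_unmapped
            or dv.variant.mapping_status is MappingStatus.MAPPED
        ]


def run_pipeline(
    subjects: pd.DataFrame,
    extract: pd.DataFrame,
    references: Optional[ReferenceSet] = None,
    predictions: Optional[pd.DataFrame] = None,
    secondary: Optional[pd.DataFrame] = None,
    overrides: Optional[pd.DataFrame] = None,
    inheritance: Optional[Mapping[str, str]] = None,
    known_diseases=None,
    strict_lp3: bool = False,
) -> PipelineRun:
    """Run the full classification pipeline on in-memory tables."""
    partition = partition_by_disease(subjects, known_diseases)
    harvest_by_disease = {
        disease: harvest_variants(table)
        for disease, table in partition.tables.items()
    }
    harvest = HarvestResult()
    for disease in sorted(harvest_by_disease):
        harvest = harvest.merge(harvest_by_disease[disease])

    subject_records = {
        str(row["subject_id"]): SubjectRecord.from_row(row)
        for _, row in subjects.iterrows()
    }
    alleles_by_subject: dict[str, list[NormalizedVariant]] = {}
    for obs in harvest.valid_observations:
        alleles_by_subject.setdefault(obs.subject_id, []).append(obs.variant)

    extract_index = ExtractIndex.from_frame(extract)
    distinct = deduplicate(harvest.valid_observations, extract_index)

    # Reference-residue validation for unpublished variants that carry a
    # protein change; wrong-reference submissions become unmapped and are
    # excluded from criteria assignment.
    if references is not None:
        for dv in distinct:
            if dv.published or not dv.variant.protein_change:
                continue
            ref = references.for_variant(dv.variant)
            if ref is None:
                logger.warning(
                    "no reference sequence for %s; skipping validation",
                    dv.variant.key,
                )
                continue
            dv.variant = validate_reference(dv.variant, ref)

    prediction_table = PredictionTable(predictions)
    secondary_db = SecondaryDatabase(secondary)
    inheritance = inheritance or {}

    profiles: dict[str, CriteriaProfile] = {}
    classifications: dict[str, ClassificationResult] = {}
    for dv in distinct:
        if dv.published:
            continue
        mode = inheritance.get(dv.diseases[0], AUTOSOMAL_RECESSIVE)
        profiles[dv.variant.key] = build_profile(
            dv,
            subject_records,
            alleles_by_subject,
            extract_index,
            prediction_table,
            secondary_db,
            inheritance=mode,
        )
    if overrides is not None and len(overrides):
        apply_overrides(profiles, overrides)
    for key, profile in profiles.items():
        classifications[key] = classify_profile(profile, strict_lp3=strict_lp3)

    return PipelineRun(
        partition=partition,
        harvest=harvest,
        harvest_by_disease=harvest_by_disease,
        subjects=subject_records,
        extract_index=extract_index,
        distinct=distinct,
        profiles=profiles,
        classifications=classifications,
        strict_lp3=strict_lp3,
    )
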