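"""Stage 5: per-disease text reports and summary tables.

Percentages are computed as 100*count/denominator and rounded half-up to
one decimal (``percentage``); the denominator for criteria and
classification tables is the number of distinct unpublished variants.
With a zero denominator percentages are reported as undefined (``None``),
never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd

from .acmg_engine import Classification
from .pipeline import PipelineRun
from .variant_parsing import MappingStatus

__all__ = [
    "CRITERIA_ORDER",
    "percentage",
    "RunSummary",
    "summarize",
    "write_disease_report",
    "write_reports",
    "classifications_frame",
]

#: Presentation order for criteria tables.
CRITERIA_ORDER = [
    "PVS1",
    "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
    "BA1", "BS1", "BS2", "BS3", "BS4",
    "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
]

_CLASSIFICATION_ORDER = [
    Classification.PATHOGENIC.value,
    Classification.LIKELY_PATHOGENIC.value,
    Classification.VUS.value,
    Classification.LIKELY_BENIGN.value,
    Classification.BENIGN.value,
    Classification.EXCLUDED_UNMAPPED.value,
]


def percentage(count: int, denominator: int, ndigits: int = 1) -> Optional[float]:
    """100*count/denominator rounded half-up; ``None`` when undefined."""
    if denominator == 0:
        return None
    quantum = Decimal(1).scaleb(-ndigits)
    value = (Decimal(count) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class RunSummary:
    """Cohort-level counts, criteria table, and classification breakdown."""

    n_subjects: int
    n_genotyped: int
    n_distinct: int
    n_published: int
    n_unpublished: int
    n_unmapped: int
    n_invalid_tokens: int
    n_unparseable: int
    per_disease: list[dict]
    criteria_counts: dict[str, int]
    classification_counts: dict[str, int]
    rule_counts: dict[str, int]
    metadata: dict = field(default_factory=dict)

    @property
    def genotyped_pct(self) -> Optional[float]:
        return percentage(self.n_genotyped, self.n_subjects)

    @property
    def unpublished_pct(self) -> Optional[float]:
        return percentage(self.n_unpublished, self.n_distinct)

    @property
    def plp_count(self) -> int:
        return self.classification_counts.get(
            Classification.PATHOGENIC.value, 0
        ) + self.classification_counts.get(Classification.LIKELY_PATHOGENIC.value, 0)

    @property
    def plp_pct(self) -> Optional[float]:
        return percentage(self.plp_count, self.n_unpublished)

    def criteria_frame(self) -> pd.DataFrame:
        rows = [
            {
                "criterion": code,
                "n_variants": self.criteria_counts.get(code, 0),
                "pct_of_unpublished": percentage(
                    self.criteria_counts.get(code, 0), self.n_unpublished
                ),
            }
            for code in CRITERIA_ORDER
            if self.criteria_counts.get(code, 0)
        ]
        return pd.DataFrame(
            rows, columns=["criterion", "n_variants", "pct_of_unpublished"]
        )

    def classification_frame(self) -> pd.DataFrame:
        rows = [
            {
                "classification": category,
                "n_variants": self.classification_counts.get(category, 0),
                "pct_of_unpublished": percentage(
                    self.classification_counts.get(category, 0), self.n_unpublished
                ),
            }
            for category in _CLASSIFICATION_ORDER
        ]
        return pd.DataFrame(
            rows, columns=["classification", "n_variants", "pct_of_unpublished"]
        )

    def per_disease_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_disease)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_genotyped": self.n_genotyped,
            "genotyped_pct": self.genotyped_pct,
            "n_distinct": self.n_distinct,
            "n_published": self.n_published,
            "n_unpublished": self.n_unpublished,
            "unpublished_pct": self.unpublished_pct,
            "n_unmapped": self.n_unmapped,
            "n_invalid_tokens": self.n_invalid_tokens,
            "n_unparseable": self.n_unparseable,
            "pathogenic_or_likely_pathogenic": self.plp_count,
            "pathogenic_or_likely_pathogenic_pct": self.plp_pct,
            "criteria_counts": self.criteria_counts,
            "classification_counts": self.classification_counts,
            "rule_counts": self.rule_counts,
            "per_disease": self.per_disease,
            "metadata": self.metadata,
        }


def summarize(run: PipelineRun, **metadata) -> RunSummary:
    """Build the run summary (criteria and classification tables)."""
    unpublished = run.unpublished
    n_unpublished = len(unpublished)

    criteria_counts: dict[str, int] = {}
    for profile in run.profiles.values():
        for code in profile.criteria:
            criteria_counts[code] = criteria_counts.get(code, 0) + 1
    criteria_counts = {
        code: criteria_counts[code]
        for code in CRITERIA_ORDER
        if code in criteria_counts
    }

    classification_counts = {category: 0 for category in _CLASSIFICATION_ORDER}
    rule_counts: dict[str, int] = {}
    for dv in unpublished:
        result = run.classifications[dv.variant.key]
        classification_counts[result.category.value] += 1
        rule_counts[result.rule_label] = rule_counts.get(result.rule_label, 0) + 1
    rule_counts = dict(sorted(rule_counts.items()))

    published_keys = {dv.variant.key for dv in run.published}
    per_disease = []
    for disease in sorted(run.partition.tables):
        table = run.partition.tables[disease]
        harvest = run.harvest_by_disease[disease]
        disease_distinct = [dv for dv in run.distinct if disease in dv.diseases]
        per_disease.append(
            {
                "disease": disease,
                "category": str(table["category"].iloc[0]) if len(table) else "",
                "n_subjects": len(table),
                "n_genotyped": harvest.n_genotyped,
                "n_published": sum(
                    dv.variant.key in published_keys for dv in disease_distinct
                ),
                "n_unpublished": sum(
                    dv.variant.key not in published_keys for dv in disease_distinct
                ),
            }
        )

    n_unparseable = sum(
        1
        for obs in run.harvest.observations
        if obs.variant.mapping_status is MappingStatus.UNPARSEABLE
    )
    return RunSummary(
        n_subjects=len(run.harvest.subject_ids),
        n_genotyped=run.harvest.n_genotyped,
        n_distinct=len(run.distinct),
        n_published=len(run.published),
        n_unpublished=n_unpublished,
        n_unmapped=len(run.unmapped),
        n_invalid_tokens=len(run.harvest.filtered_tokens),
        n_unparseable=n_unparseable,
        per_disease=per_disease,
        criteria_counts=criteria_counts,
        classification_counts=classification_counts,
        rule_counts=rule_counts,
        metadata=dict(metadata),
    )


def write_disease_report(path: str | Path, disease: str, run: PipelineRun) -> None:
    """Write the plain-text per-disease report.

    Contains the subject total, the published and unpublished variant
    lists, per-variant criteria provenance, and an exclusions section for
    unmapped variants and filtered invalid tokens.  Output is
    deterministically ordered, so regeneration is byte-identical.
    """
    table = run.partition.tables[disease]
    harvest = run.harvest_by_disease[disease]
    distinct = sorted(
        (dv for dv in run.distinct if disease in dv.diseases),
        key=lambda dv: dv.variant.key,
    )
    published = [dv for dv in distinct if dv.published]
    unpublished = [
        dv
        for dv in distinct
        if not dv.published
        and dv.variant.mapping_status is MappingStatus.MAPPED
    ]
    unmapped = [
        dv
        for dv in distinct
        if not dv.published
        and dv.variant.mapping_status is not MappingStatus.MAPPED
    ]

    lines = [
        f"Disease: {disease}"
        + (f" ({table['category'].iloc[0]})" if len(table) else ""),
        f"Total subjects: {len(table)}",
        f"Genotyped subjects: {harvest.n_genotyped}",
        "",
        f"Published variants ({len(published)}):",
    ]
    for dv in published:
        entry = dv.clinvar_entry
        sig = f"  [{entry.significance}, {entry.review_stars} star]" if entry else ""
        lines.append(
            f"  {dv.variant.key}{sig}  subjects: {', '.join(dv.subject_ids)}"
        )
    if not published:
        lines.append("  (none)")
    lines += ["", f"Unpublished variants ({len(unpublished)}):"]
    for dv in unpublished:
        profile = run.profiles[dv.variant.key]
        result = run.classifications[dv.variant.key]
        lines.append(
            f"  {dv.variant.key}  classification: {result.category.value}"
            f" ({result.rule_label})"
        )
        lines.append(f"    subjects: {', '.join(dv.subject_ids)}")
        for code in sorted(profile.criteria):
            lines.append(f"    {code}: {profile.provenance.get(code, '')}")
    if not unpublished:
        lines.append("  (none)")
    lines += ["", "Exclusions:"]
    for dv in unmapped:
        lines.append(
            f"  unmapped (wrong reference residue): {dv.variant.key} — {dv.variant.note}"
        )
    for subject_id, token in sorted(harvest.filtered_tokens):
        lines.append(f"  invalid token: subject {subject_id}: {token!r}")
    if not unmapped and not harvest.filtered_tokens:
        lines.append("  (none)")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def classifications_frame(run: PipelineRun) -> pd.DataFrame:
    """Machine-readable classification table for the unpublished variants."""
    rows = []
    for dv in sorted(run.unpublished, key=lambda d: d.variant.key):
        result = run.classifications[dv.variant.key]
        profile = run.profiles[dv.variant.key]
        rows.append(
            {
                "variant_key": dv.variant.key,
                "gene": dv.variant.gene,
                "diseases": ";".join(dv.diseases),
                "cdna_change": dv.variant.cdna_change or "",
                "protein_change": dv.variant.protein_change or "",
                "consequence": dv.variant.consequence.value,
                "mapping_status": dv.variant.mapping_status.value,
                "n_subjects": len(dv.subject_ids),
                "allele_count": dv.allele_count,
                "criteria": ";".join(sorted(profile.criteria)),
                "classification": result.category.value,
                "rule_label": result.rule_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_key", "gene", "diseases", "cdna_change", "protein_change",
            "consequence", "mapping_status", "n_subjects", "allele_count",
            "criteria", "classification", "rule_label",
        ],
    )


def write_reports(outdir: str | Path, run: PipelineRun, **metadata) -> RunSummary:
    """Write per-disease text reports, summary CSVs and the run JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports_dir = outdir / "diseases"
    reports_dir.mkdir(exist_ok=True)
    for disease in sorted(run.partition.tables):
        write_disease_report(reports_dir / f"{disease}.txt", disease, run)
    summary = summarize(run, **metadata)
    summary.criteria_frame().to_csv(outdir / "criteria_summary.csv", index=False)
    summary.classification_frame().to_csv(
        outdir / "classification_summary.csv", index=False
    )
    summary.per_disease_frame().to_csv(outdir / "per_disease_summary.csv", index=False)
    classifications_frame(run).to_csv(outdir / "classifications.csv", index=False)
    (outdir / "run_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=1, sort_keys=True)
    )
    return summary
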