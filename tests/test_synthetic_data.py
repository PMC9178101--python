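"""Synthetic cohort generator: determinism, rates, manifest consistency."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from conftest import SMALL_CONFIG
from nbsvar.clinvar_match import SIGNIFICANCE_TERMS, convert_extract
from nbsvar.evidence import PredictionTable, assess_computational
from nbsvar.synthetic_data import (
    CohortConfig,
    generate_clinvar_extract,
    generate_cohort,
    generate_predictions,
    generate_study,
    generate_updated_extract,
)
from nbsvar.variant_parsing import MappingStatus, parse_variant_string


def test_seed_determinism_byte_identical():
    cfg = dict(SMALL_CONFIG, seed=7)
    a = generate_study(CohortConfig(**cfg))
    b = generate_study(CohortConfig(**cfg))
    assert a.subjects.to_csv(index=False) == b.subjects.to_csv(index=False)
    assert a.extract.to_csv(index=False) == b.extract.to_csv(index=False)
    assert a.updated_extract.to_csv(index=False) == b.updated_extract.to_csv(index=False)
    assert a.manifest.to_dict() == b.manifest.to_dict()


def test_zero_genotyping_rate_yields_no_variants():
    cfg = CohortConfig(**dict(SMALL_CONFIG, genotyping_rate=0.0, invalid_token_rate=0.0))
    subjects, manifest = generate_cohort(cfg)
    assert (subjects["variant_1"] == "").all()
    assert (subjects["variant_2"] == "").all()
    assert manifest.variants == []


def test_disease_and_subject_counts():
    cfg = CohortConfig(
        n_diseases_per_category={
            "amino_acid": 8,
            "fatty_acid_oxidation": 8,
            "organic_acid": 8,
            "other": 8,
        },
        subjects_per_disease=20,
        seed=3,
    )
    subjects, _ = generate_cohort(cfg)
    assert len(subjects) == 640
    counts = subjects.groupby("disease").size()
    assert len(counts) == 32
    assert (counts == 20).all()
    # each subject belongs to exactly one disease row-wise by construction
    assert subjects["subject_id"].is_unique


def test_total_subjects_distribution():
    subjects, _ = generate_cohort(CohortConfig(seed=5))
    assert len(subjects) == 1904
    sizes = subjects.groupby("disease").size()
    assert len(sizes) == 32
    assert sizes.max() - sizes.min() <= 1


@pytest.mark.parametrize(
    "overrides, field",
    [
        ({"genotyping_rate": 1.5}, "genotyping_rate"),
        ({"unpublished_rate": -0.1}, "unpublished_rate"),
        ({"subjects_per_disease": 0}, "subjects_per_disease"),
        ({"dialect_mix": {"single_letter": 0.5, "hgvs_c": 0.2}}, "dialect_mix"),
        ({"evidence_rates": {"PM3": 2.0}}, "evidence_rates"),
        (
            {"n_diseases_per_category": {"amino_acid": 1}},
            "n_diseases_per_category",
        ),
        (
            {"subjects_per_disease": 10, "total_subjects": 100},
            "subjects_per_disease",
        ),
    ],
)
def test_invalid_config_rejected_with_named_field(overrides, field):
    with pytest.raises(ValueError, match=field):
        CohortConfig(**overrides)


def test_clinvar_extract_shape_and_vocabulary():
    extract = generate_clinvar_extract(["GCDH"], 5, seed=2)
    assert len(extract) == 5
    assert (extract["Gene"] == "GCDH").all()
    assert set(extract["Clinical significance"]) <= set(SIGNIFICANCE_TERMS)
    conversion = convert_extract(extract)
    assert conversion.n_skipped == 0
    for entry in conversion.entries:
        assert entry.cdna_change and entry.protein_change


def test_clinvar_extract_requires_genes():
    with pytest.raises(ValueError):
        generate_clinvar_extract([], 5, seed=1)


def _overlap_rows():
    rows = []
    for i in range(8):
        protein = f"K{900 + i}R"
        rows.append(
            {
                "Name": f"NM_700001.1(G1):c.{2700 + 3 * i}A>G (p.Lys{900 + i}Arg)",
                "Gene": "G1",
                "Protein change": protein,
                "Clinical significance": "Likely Pathogenic",
                "Review status": "criteria provided, single submitter",
            }
        )
    return rows


def test_updated_extract_set_arithmetic():
    baseline = generate_clinvar_extract(["G1", "G2"], 50, seed=4)
    overlap = _overlap_rows()
    updated = generate_updated_extract(baseline, 50, overlap, seed=9)
    assert len(updated) == 150
    updated_keys = {e.key for e in convert_extract(updated).entries}
    baseline_keys = {e.key for e in convert_extract(baseline).entries}
    overlap_keys = {e.key for e in convert_extract(pd.DataFrame(overlap)).entries}
    assert overlap_keys <= updated_keys - baseline_keys
    assert len(overlap_keys) == 8


def test_updated_extract_identity_when_nothing_added():
    baseline = generate_clinvar_extract(["G1"], 10, seed=4)
    updated = generate_updated_extract(baseline, 0, [], seed=9)
    assert updated.equals(baseline)


def test_updated_extract_rejects_overlap_already_in_baseline():
    baseline = generate_clinvar_extract(["G1"], 10, seed=4)
    dup = baseline.iloc[[0]].to_dict("records")
    with pytest.raises(ValueError, match="already in baseline"):
        generate_updated_extract(baseline, 5, dup, seed=9)


def test_generate_predictions_contract():
    missense = parse_variant_string("R100W", "G1")
    synonymous = parse_variant_string("F50F", "G1")
    frame = generate_predictions([missense, synonymous], seed=1, concordance=1.0)
    assert set(frame["protein_change"]) == {"R100W"}  # synonymous gets no rows
    assert len(frame) == 2
    assert (frame["call"] == "deleterious").all()
    # A planted discordant pair yields neither PP3 nor BP4 downstream.
    discordant = generate_predictions([missense], seed=1, concordance=0.0)
    assert sorted(discordant["call"]) == ["deleterious", "neutral"]
    assert assess_computational(missense, PredictionTable(discordant)) is None


def test_rate_realization_large_cohort():
    """Empirical genotyping/unpublished rates within 3 SE of configured."""
    cfg = CohortConfig(
        n_diseases_per_category={
            "amino_acid": 1,
            "fatty_acid_oxidation": 1,
            "organic_acid": 1,
            "other": 1,
        },
        subjects_per_disease=500,
        seed=19,
    )
    subjects, manifest = generate_cohort(cfg)
    n = len(subjects)
    genotyped = sum(
        any(key != "<invalid>" for key in keys)
        for keys in manifest.subject_alleles.values()
        if keys
    )
    se = math.sqrt(cfg.genotyping_rate * (1 - cfg.genotyping_rate) * n)
    assert abs(genotyped - cfg.genotyping_rate * n) <= 3 * se

    n_distinct = len(manifest.variants)
    n_unpub = len(manifest.unpublished())
    se_u = math.sqrt(cfg.unpublished_rate * (1 - cfg.unpublished_rate) * n_distinct)
    assert abs(n_unpub - cfg.unpublished_rate * n_distinct) <= 3 * se_u


def test_manifest_consistency(small_study):
    """Every rendered subject string decodes to its manifest entry."""
    manifest = small_study.manifest
    planted_keys = {v.key for v in manifest.variants}
    gene_by_disease = {d["disease"]: d["gene"] for d in manifest.diseases}
    genotyped_with_alleles = 0
    for _, row in small_study.subjects.iterrows():
        gene = gene_by_disease[row["disease"]]
        for col in ("variant_1", "variant_2"):
            raw = row[col]
            if not raw:
                continue
            v = parse_variant_string(raw, gene)
            if v.mapping_status is MappingStatus.INVALID_TOKEN:
                continue
            assert v.mapping_status is MappingStatus.MAPPED, raw
            assert v.key in planted_keys, raw
        keys = manifest.subject_alleles.get(row["subject_id"], [])
        if any(k != "<invalid>" for k in keys):
            genotyped_with_alleles += 1
    assert genotyped_with_alleles > 0
    # every genotyped subject appears in the manifest allele map
    for v in manifest.variants:
        for sid in v.supporting_subjects:
            assert v.key in manifest.subject_alleles[sid]


def test_extract_rows_are_reference_consistent(small_study):
    """Planted extract c./p. pairs agree with the reference proteins."""
    for entry in convert_extract(small_study.extract).entries:
        if not entry.protein_change or entry.protein_change.endswith("fs"):
            continue
        ref = small_study.references.by_gene[entry.gene]
        position = int("".join(ch for ch in entry.protein_change if ch.isdigit()))
        assert ref.protein[position - 1] == entry.protein_change[0], entry.name
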