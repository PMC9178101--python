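"""Criteria assignment from clinical, computational and database evidence."""

from __future__ import annotations

from itertools import product

import pandas as pd
import pytest

from nbsvar.case_data import SubjectRecord
from nbsvar.clinvar_match import ClinVarEntry, DistinctVariant, ExtractIndex
from nbsvar.evidence import (
    PredictionTable,
    SecondaryDatabase,
    apply_overrides,
    assess_bp7,
    assess_computational,
    assess_family,
    assess_pm3,
    assess_pm5,
    assess_pp5,
    assess_pvs1,
    assign_global_criteria,
    build_profile,
)
from nbsvar.variant_parsing import MappingStatus, parse_variant_string


def _subject(sid="S1", confirmed=True, **kwargs):
    return SubjectRecord(
        subject_id=sid,
        disease="D1",
        category="amino_acid",
        gene="G1",
        transcript="NM_1.1",
        confirmed_dx=confirmed,
        raw_variants=(),
        **kwargs,
    )


def _dv(raw, sids=("S1",), gene="G1"):
    v = parse_variant_string(raw, gene)
    return DistinctVariant(
        variant=v, subject_ids=tuple(sids), diseases=("D1",), allele_count=len(sids)
    )


def _entry(gene, cdna, protein, sig):
    return ClinVarEntry(
        gene=gene,
        name=f"NM_1.1({gene}):{cdna}" + (f" (p.{protein})" if protein else ""),
        cdna_change=cdna,
        protein_change=protein,
        significance=sig,
        review_stars=1,
    )


EMPTY_INDEX = ExtractIndex([])


def test_global_criteria_for_confirmed_subjects():
    subjects = {"S1": _subject()}
    assert assign_global_criteria(_dv("F256L"), subjects) == {"PS3", "PP4"}


def test_global_criteria_withheld_without_confirmed_dx(caplog):
    subjects = {"S1": _subject(confirmed=False)}
    with caplog.at_level("WARNING"):
        assert assign_global_criteria(_dv("F256L"), subjects) == set()
    assert "withheld" in caplog.text


@pytest.mark.parametrize(
    "raw, expected",
    [("W123X", True), ("F256L", False), ("c.244+1G>A", True), ("K12fs", True)],
)
def test_pvs1_null_predicate(raw, expected):
    assert assess_pvs1(parse_variant_string(raw, "G1")) is expected


def test_pm3_requires_published_plp_partner():
    index = ExtractIndex([_entry("G1", "c.10A>G", "K4R", "Pathogenic")])
    dv = _dv("F256L")
    partner_pub = parse_variant_string("K4R", "G1")
    partner_unpub = parse_variant_string("Q9H", "G1")
    assert assess_pm3(dv, {"S1": [dv.variant, partner_pub]}, index) == "S1"
    assert assess_pm3(dv, {"S1": [dv.variant, partner_unpub]}, index) is None
    # single reported allele -> no PM3
    assert assess_pm3(dv, {"S1": [dv.variant]}, index) is None
    # homozygous for the unpublished variant itself -> no PM3
    assert assess_pm3(dv, {"S1": [dv.variant, dv.variant]}, index) is None
    # dominant disease -> never PM3
    assert (
        assess_pm3(
            dv,
            {"S1": [dv.variant, partner_pub]},
            index,
            inheritance="autosomal_dominant",
        )
        is None
    )


def test_pm3_vus_partner_does_not_qualify():
    index = ExtractIndex([_entry("G1", "c.10A>G", "K4R", "Uncertain Significance")])
    dv = _dv("F256L")
    partner = parse_variant_string("K4R", "G1")
    assert assess_pm3(dv, {"S1": [dv.variant, partner]}, index) is None


def test_pm5_same_residue_different_missense():
    index = ExtractIndex([_entry("GCDH", "c.880C>T", "R294W", "Pathogenic")])
    assert assess_pm5(parse_variant_string("R294Q", "GCDH"), index) is not None
    # identical change is a published match upstream, not PM5
    assert assess_pm5(parse_variant_string("R294W", "GCDH"), index) is None
    # different residue -> nothing
    assert assess_pm5(parse_variant_string("R300Q", "GCDH"), index) is None
    # benign neighbour does not count
    benign = ExtractIndex([_entry("GCDH", "c.880C>T", "R294W", "Benign")])
    assert assess_pm5(parse_variant_string("R294Q", "GCDH"), benign) is None


def test_family_segregation_and_de_novo():
    dv = _dv("F256L")
    carrier = {"S1": _subject(fh_affected_carrier_variant="p.Phe256Leu")}
    assert set(assess_family(dv, carrier)) == {"PP1"}
    denovo = {"S1": _subject(fh_de_novo_variant="F256L")}
    assert set(assess_family(dv, denovo)) == {"PM6"}
    confirmed = {
        "S1": _subject(fh_de_novo_variant="F256L", fh_parents_confirmed=True)
    }
    assert assess_family(dv, confirmed) == {}
    empty = {"S1": _subject()}
    assert assess_family(dv, empty) == {}
    # family history naming a different variant does not count
    other = {"S1": _subject(fh_affected_carrier_variant="R100W")}
    assert assess_family(dv, other) == {}


@pytest.mark.parametrize(
    "calls, expected",
    [
        (["deleterious", "deleterious"], "PP3"),
        (["neutral", "neutral"], "BP4"),
        (["deleterious", "neutral"], None),
        (["neutral", "deleterious"], None),
        (["deleterious"], "PP3"),
        (["neutral"], "BP4"),
        ([], None),
    ],
)
def test_computational_decision_rule_exhaustive(calls, expected):
    v = parse_variant_string("F256L", "G1")
    frame = pd.DataFrame(
        [
            {
                "gene": "G1",
                "cdna_change": "",
                "protein_change": "F256L",
                "tool": f"T{i}",
                "call": call,
            }
            for i, call in enumerate(calls)
        ],
        columns=["gene", "cdna_change", "protein_change", "tool", "call"],
    )
    assert assess_computational(v, PredictionTable(frame)) == expected


def test_pp5_secondary_database():
    frame = pd.DataFrame(
        [
            {"gene": "G1", "cdna_change": "", "protein_change": "F256L",
             "significance": "Pathogenic"},
            {"gene": "G1", "cdna_change": "", "protein_change": "R100W",
             "significance": "Uncertain Significance"},
        ]
    )
    db = SecondaryDatabase(frame)
    assert assess_pp5(parse_variant_string("F256L", "G1"), db) == "Pathogenic"
    assert assess_pp5(parse_variant_string("R100W", "G1"), db) is None
    assert assess_pp5(parse_variant_string("Q9H", "G1"), db) is None


def test_bp7_synonymous_without_deleterious_call():
    syn = parse_variant_string("F256F", "G1")
    assert assess_bp7(syn, PredictionTable())
    frame = pd.DataFrame(
        [{"gene": "G1", "cdna_change": "", "protein_change": "F256F",
          "tool": "T", "call": "deleterious"}]
    )
    assert not assess_bp7(syn, PredictionTable(frame))
    assert not assess_bp7(parse_variant_string("F256L", "G1"), PredictionTable())


def test_unmapped_variant_gets_empty_profile():
    from nbsvar.variant_parsing import ReferenceSequence, validate_reference

    dv = _dv("A2L")
    ref = ReferenceSequence(transcript="NM_1.1", protein="MFKL", gene="G1")
    dv.variant = validate_reference(dv.variant, ref)
    assert dv.variant.mapping_status is MappingStatus.UNMAPPED_REFERENCE_MISMATCH
    profile = build_profile(dv, {"S1": _subject()}, {}, EMPTY_INDEX)
    assert profile.criteria == set()


def test_profile_order_independent_over_subjects():
    subjects = {
        "S1": _subject("S1"),
        "S2": _subject("S2", fh_affected_carrier_variant="F256L"),
    }
    index = ExtractIndex([_entry("G1", "c.10A>G", "K4R", "Pathogenic")])
    alleles = {
        "S1": [parse_variant_string("F256L", "G1"), parse_variant_string("K4R", "G1")],
        "S2": [parse_variant_string("F256L", "G1")],
    }
    forward = build_profile(_dv("F256L", ("S1", "S2")), subjects, alleles, index)
    backward = build_profile(_dv("F256L", ("S2", "S1")), subjects, alleles, index)
    assert forward.criteria == backward.criteria == {"PS3", "PP4", "PM3", "PP1"}


def test_pp3_bp4_never_cooccur_and_bp7_implies_synonymous(small_run):
    from nbsvar.variant_parsing import Consequence

    for profile in small_run.profiles.values():
        assert not ({"PP3", "BP4"} <= profile.criteria)
        if "BP7" in profile.criteria:
            assert profile.variant.variant.consequence is Consequence.SYNONYMOUS


def test_manual_overrides_add_and_remove():
    dv = _dv("F256L")
    profile = build_profile(dv, {"S1": _subject()}, {}, EMPTY_INDEX)
    key = dv.variant.key
    overrides = pd.DataFrame(
        [
            {"variant_key": key, "criterion": "PM2", "action": "add"},
            {"variant_key": key, "criterion": "PP4", "action": "remove"},
            {"variant_key": "G1|p:Z9Z", "criterion": "PM2", "action": "add"},
        ]
    )
    applied = apply_overrides({key: profile}, overrides)
    assert applied == 2
    assert "PM2" in profile.criteria
    assert "PP4" not in profile.criteria
    assert profile.provenance["PM2"] == "manual override"
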