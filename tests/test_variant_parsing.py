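"""Parsing, reference validation, and consequence classification."""

from __future__ import annotations

import re

import pytest
from hypothesis import given, settings, strategies as st

from nbsvar.variant_parsing import (
    AA_1TO3,
    AA_3TO1,
    AA_LETTERS,
    Consequence,
    MappingStatus,
    NormalizedVariant,
    ReferenceSequence,
    classify_consequence,
    parse_variant_string,
    protein_three_letter,
    validate_reference,
)


@pytest.mark.parametrize(
    "raw, cdna, protein, consequence",
    [
        ("F256L", None, "F256L", Consequence.MISSENSE),
        ("c.549A > C", "c.549A>C", None, Consequence.UNKNOWN),
        ("c.549A>C", "c.549A>C", None, Consequence.UNKNOWN),
        ("p. Phe256Leu", None, "F256L", Consequence.MISSENSE),
        ("p.Arg31His", None, "R31H", Consequence.MISSENSE),
        ("p.Arg201Cys", None, "R201C", Consequence.MISSENSE),
        ("W123X", None, "W123*", Consequence.NONSENSE),
        ("p.Trp123Ter", None, "W123*", Consequence.NONSENSE),
        ("Trp123*", None, "W123*", Consequence.NONSENSE),
        ("c.244+1G>A", "c.244+1G>A", None, Consequence.CANONICAL_SPLICE),
        ("c.244-2A>G", "c.244-2A>G", None, Consequence.CANONICAL_SPLICE),
        ("F256F", None, "F256F", Consequence.SYNONYMOUS),
        ("p.Phe256=", None, "F256F", Consequence.SYNONYMOUS),
        ("K123fs", None, "K123fs", Consequence.FRAMESHIFT),
        ("p.Arg123GlyfsTer5", None, "R123fs", Consequence.FRAMESHIFT),
        ("c.123delA", "c.123delA", None, Consequence.FRAMESHIFT),
        ("c.100_102del", "c.100_102del", None, Consequence.OTHER),
        ("c.123dupA", "c.123dupA", None, Consequence.FRAMESHIFT),
        ("M1L", None, "M1L", Consequence.START_LOSS),
    ],
)
def test_parse_dialects(raw, cdna, protein, consequence):
    v = parse_variant_string(raw, "GENE1")
    assert v.mapping_status is MappingStatus.MAPPED
    assert v.cdna_change == cdna
    assert v.protein_change == protein
    assert v.consequence is consequence


def test_parse_full_clinvar_name():
    v = parse_variant_string("NM_000159.4 (GCDH):c.776C > T (p.Ser259Leu)")
    assert v.gene == "GCDH"
    assert v.transcript == "NM_000159.4"
    assert v.cdna_change == "c.776C>T"
    assert v.protein_change == "S259L"
    assert v.consequence is Consequence.MISSENSE


@pytest.mark.parametrize("raw", ["none", "NONE", "negative", " Negative ", ""])
def test_invalid_tokens(raw):
    v = parse_variant_string(raw, "GENE1")
    assert v.mapping_status is MappingStatus.INVALID_TOKEN
    assert v.key is None


@pytest.mark.parametrize("raw", ["not a variant", "X123Y", "???", "p.Xyz9Abc", "12345"])
def test_unparseable(raw):
    v = parse_variant_string(raw, "GENE1")
    assert v.mapping_status is MappingStatus.UNPARSEABLE
    assert v.key is None


def test_validate_reference_match_and_mismatch():
    ref = ReferenceSequence(transcript="NM_1.1", protein="MFAKLW", gene="G")
    ok = validate_reference(parse_variant_string("F2L", "G"), ref)
    assert ok.mapping_status is MappingStatus.MAPPED
    bad = validate_reference(parse_variant_string("A2L", "G"), ref)
    assert bad.mapping_status is MappingStatus.UNMAPPED_REFERENCE_MISMATCH
    assert "reference has F" in bad.note
    out = validate_reference(parse_variant_string("F99L", "G"), ref)
    assert out.mapping_status is MappingStatus.UNMAPPED_REFERENCE_MISMATCH
    assert "beyond" in out.note


def test_splice_detection_against_regex_oracle():
    """Offset grammar vs an independent regular-expression oracle."""
    oracle = re.compile(r"^c\.\d+[+-][12][ACGT]>[ACGT]$")
    for pos in (1, 88, 244, 9999):
        for off in range(-5, 6):
            if off == 0:
                continue
            raw = f"c.{pos}{off:+d}G>A"
            v = parse_variant_string(raw, "G")
            expected = bool(oracle.match(raw))
            assert (v.consequence is Consequence.CANONICAL_SPLICE) == expected, raw
            assert v.is_null == expected


def test_three_letter_table_is_bijection():
    # 20 residues plus stop, invertible in both directions.
    assert len(AA_3TO1) == 21
    assert len(AA_1TO3) == 21
    for three, one in AA_3TO1.items():
        assert AA_1TO3[one] == three


@given(
    ref=st.sampled_from(sorted(AA_LETTERS)),
    pos=st.integers(1, 9999),
    alt=st.sampled_from(sorted(AA_LETTERS) + ["*", "fs"]),
)
@settings(derandomize=True, max_examples=200)
def test_protein_parse_roundtrip(ref, pos, alt):
    """Canonical single-letter and three-letter renderings re-parse identically."""
    canonical = f"{ref}{pos}{alt}"
    v1 = parse_variant_string(canonical, "G")
    assert v1.protein_change == canonical
    v2 = parse_variant_string(f"p.{protein_three_letter(canonical)}", "G")
    assert v2 == v1
    # Idempotence: re-parsing the canonical form is a fixed point.
    assert parse_variant_string(v1.protein_change, "G") == v1


@given(st.text(max_size=40))
@settings(derandomize=True, max_examples=300)
def test_parser_never_raises(text):
    v = parse_variant_string(text, "G")
    assert isinstance(v.mapping_status, MappingStatus)


def test_cdna_idempotence():
    for raw in ("c.549A>C", "c.244+1G>A", "c.123delA", "c.10_12dup", "c.9_10insTT"):
        v1 = parse_variant_string(raw, "G")
        v2 = parse_variant_string(v1.cdna_change, "G")
        assert v1 == v2


def test_classify_consequence_of_unparsed_is_unknown():
    assert classify_consequence(NormalizedVariant(gene="G")) is Consequence.UNKNOWN
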