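"""Extract conversion, matching and deduplication."""

from __future__ import annotations

from itertools import product

import pandas as pd
import pytest

from nbsvar.case_data import Observation
from nbsvar.clinvar_match import (
    ClinVarEntry,
    ExtractIndex,
    convert_extract,
    deduplicate,
    match_variant,
)
from nbsvar.variant_parsing import parse_variant_string

EXTRACT_COLUMNS = [
    "Name",
    "Gene",
    "Protein change",
    "Clinical significance",
    "Review status",
]


def _frame(rows):
    return pd.DataFrame(rows, columns=EXTRACT_COLUMNS)


def test_convert_galt_row():
    frame = _frame(
        [
            (
                "NM_000155.4 (GALT):c.601C > T (p.Arg201Cys)",
                "GALT",
                "R201C",
                "Pathogenic",
                "criteria provided, multiple submitters, no conflicts",
            )
        ]
    )
    conversion = convert_extract(frame)
    assert conversion.n_skipped == 0
    entry = conversion.entries[0]
    assert entry.gene == "GALT"
    assert entry.cdna_change == "c.601C>T"
    assert entry.protein_change == "R201C"
    assert entry.significance == "Pathogenic"
    assert entry.review_stars == 2


def test_convert_row_without_protein_segment():
    frame = _frame(
        [("NM_1.1(G1):c.244+1G>A", "G1", "", "Likely Pathogenic", "1")]
    )
    entry = convert_extract(frame).entries[0]
    assert entry.cdna_change == "c.244+1G>A"
    assert entry.protein_change is None


def test_convert_empty_extract():
    assert convert_extract(_frame([])).entries == []


def test_convert_skips_malformed_rows_with_count():
    frame = _frame(
        [
            ("garbage text", "G1", "", "Pathogenic", "1"),
            ("NM_1.1(G1):c.10A>G", "G1", "", "Pathogenic", "1"),
        ]
    )
    conversion = convert_extract(frame)
    assert conversion.n_skipped == 1
    assert len(conversion.entries) == 1


def test_match_published_and_unpublished():
    index = ExtractIndex.from_frame(
        _frame(
            [
                (
                    "NM_000155.4(GALT):c.601C>T (p.Arg201Cys)",
                    "GALT",
                    "R201C",
                    "Pathogenic",
                    "2",
                )
            ]
        )
    )
    assert match_variant(parse_variant_string("R201C", "GALT"), index)
    assert match_variant(parse_variant_string("c.601C > T", "GALT"), index)
    assert not match_variant(parse_variant_string("F256L", "GALT"), index)
    # gene comparison is case-insensitive
    assert match_variant(parse_variant_string("R201C", "galt"), index)


def test_no_cross_level_matching():
    """Protein-only query never matches a c.-only extract row."""
    index = ExtractIndex.from_frame(
        _frame([("NM_1.1(G1):c.601C>T", "G1", "", "Pathogenic", "1")])
    )
    assert not match_variant(parse_variant_string("R201C", "G1"), index)


def test_transcript_version_ignored_in_matching():
    index = ExtractIndex.from_frame(
        _frame([("NM_000159.3(GCDH):c.776C>T (p.Ser259Leu)", "GCDH", "S259L", "Pathogenic", "1")])
    )
    query = parse_variant_string("NM_000159.4(GCDH):c.776C>T")
    assert match_variant(query, index)


@pytest.mark.parametrize(
    "extract_spelling, query_spelling",
    list(product(["Ter", "*"], ["X", "*", "Ter"])),
)
def test_stop_synonyms_unify_before_comparison(extract_spelling, query_spelling):
    """Exhaustive enumeration of stop spellings on both sides."""
    index = ExtractIndex.from_frame(
        _frame(
            [
                (
                    f"NM_1.1(G1):c.368G>A (p.Trp123{extract_spelling})",
                    "G1",
                    "",
                    "Pathogenic",
                    "1",
                )
            ]
        )
    )
    query = parse_variant_string(
        f"W123{query_spelling}" if query_spelling in "X*" else f"Trp123{query_spelling}",
        "G1",
    )
    assert query.protein_change == "W123*"
    assert match_variant(query, index)


def _obs(sid, raw, gene="G1", disease="D1"):
    return Observation(
        subject_id=sid,
        disease=disease,
        gene=gene,
        raw=raw,
        variant=parse_variant_string(raw, gene),
    )


def test_deduplicate_accumulates_supporters():
    observations = [_obs("S1", "R201C"), _obs("S2", "p.Arg201Cys")]
    distinct = deduplicate(observations)
    assert len(distinct) == 1
    assert distinct[0].subject_ids == ("S1", "S2")
    assert distinct[0].allele_count == 2


def test_deduplicate_homozygous_subject():
    observations = [_obs("S1", "R201C"), _obs("S1", "R201C")]
    distinct = deduplicate(observations)
    assert len(distinct) == 1
    assert distinct[0].subject_ids == ("S1",)
    assert distinct[0].allele_count == 2


def test_deduplicate_order_independent():
    observations = [_obs("S1", "R201C"), _obs("S2", "F10L"), _obs("S3", "R201C")]
    a = deduplicate(observations)
    b = deduplicate(list(reversed(observations)))
    assert [(d.variant.key, d.subject_ids) for d in a] == [
        (d.variant.key, d.subject_ids) for d in b
    ]


def test_published_plus_unpublished_equals_distinct(small_run):
    assert len(small_run.published) + len(small_run.unpublished) == len(
        small_run.distinct
    )


def test_match_stable_under_reparse(small_run):
    """match(parse(render(v))) == match(v) for every distinct variant."""
    for dv in small_run.distinct:
        v = dv.variant
        rendered = v.cdna_change or v.protein_change
        reparsed = parse_variant_string(rendered, v.gene)
        assert match_variant(reparsed, small_run.extract_index) == dv.published
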