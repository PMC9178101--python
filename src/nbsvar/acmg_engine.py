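"""ACMG/AMP combining-rule engine.

Evidence criteria carry fixed strengths (PVS1 very strong; PS1-PS4 strong;
PM1-PM6 moderate; PP1-PP5 supporting on the pathogenic axis; BA1
stand-alone, BS1-BS4 strong, BP1-BP7 supporting on the benign axis).  The
combining rules tally criteria by strength and map the tallies to one of
five significance categories; when both a pathogenic and a benign rule are
satisfied the result is Uncertain Significance with a conflict flag, and
when no rule fires the default is Uncertain Significance.

Rule labels ("Pathogenic 1a", "Likely Pathogenic 3", ...) identify the
first satisfied rule in canonical order — Pathogenic rules before Likely
Pathogenic, Benign before Likely Benign — giving deterministic provenance;
the category itself does not depend on that order.

The ``strict_lp3`` flag raises the Likely Pathogenic 3 requirement from
">=2 supporting" (the published standard, the default here) to "more than
two supporting", an alternative reading some studies have applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

__all__ = [
    "Classification",
    "Strength",
    "CRITERION_STRENGTH",
    "ALL_CRITERIA",
    "CriterionCounts",
    "Rule",
    "ClassificationResult",
    "rule_table",
    "classify",
    "classify_profile",
]


class Classification(str, Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely Pathogenic"
    VUS = "Uncertain Significance"
    LIKELY_BENIGN = "Likely Benign"
    BENIGN = "Benign"
    EXCLUDED_UNMAPPED = "Excluded-Unmapped"


class Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE = "stand_alone"
    BENIGN_STRONG = "benign_strong"
    BENIGN_SUPPORTING = "benign_supporting"


def _axis(codes: Sequence[str], strength: Strength) -> dict[str, Strength]:
    return {code: strength for code in codes}


#: Fixed code -> strength mapping per the ACMG/AMP standard.
CRITERION_STRENGTH: dict[str, Strength] = {
    "PVS1": Strength.VERY_STRONG,
    **_axis(["PS1", "PS2", "PS3", "PS4"], Strength.STRONG),
    **_axis(["PM1", "PM2", "PM3", "PM4", "PM5", "PM6"], Strength.MODERATE),
    **_axis(["PP1", "PP2", "PP3", "PP4", "PP5"], Strength.SUPPORTING),
    "BA1": Strength.STAND_ALONE,
    **_axis(["BS1", "BS2", "BS3", "BS4"], Strength.BENIGN_STRONG),
    **_axis(
        ["BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"],
        Strength.BENIGN_SUPPORTING,
    ),
}

ALL_CRITERIA = frozenset(CRITERION_STRENGTH)


@dataclass(frozen=True)
class CriterionCounts:
    """Tallies of criteria by strength on each axis."""

    very_strong: int = 0
    strong: int = 0
    moderate: int = 0
    supporting: int = 0
    stand_alone: int = 0
    benign_strong: int = 0
    benign_supporting: int = 0

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "CriterionCounts":
        tally = dict.fromkeys(Strength, 0)
        for code in set(codes):
            try:
                tally[CRITERION_STRENGTH[code]] += 1
            except KeyError:
                raise ValueError(f"unknown ACMG/AMP criterion code: {code!r}") from None
        return cls(
            very_strong=tally[Strength.VERY_STRONG],
            strong=tally[Strength.STRONG],
            moderate=tally[Strength.MODERATE],
            supporting=tally[Strength.SUPPORTING],
            stand_alone=tally[Strength.STAND_ALONE],
            benign_strong=tally[Strength.BENIGN_STRONG],
            benign_supporting=tally[Strength.BENIGN_SUPPORTING],
        )


@dataclass(frozen=True)
class Rule:
    label: str
    category: Classification
    requires: str
    test: Callable[[CriterionCounts], bool]


def rule_table(strict_lp3: bool = False) -> list[Rule]:
    """The complete combining-rule table, in canonical evaluation order."""
    lp3_min = 3 if strict_lp3 else 2
    lp3_text = ">2" if strict_lp3 else ">=2"
    return [
        Rule(
            "Pathogenic 1a",
            Classification.PATHOGENIC,
            "1 very strong and >=1 strong",
            lambda c: c.very_strong >= 1 and c.strong >= 1,
        ),
        Rule(
            "Pathogenic 1b",
            Classification.PATHOGENIC,
            "1 very strong and >=2 moderate",
            lambda c: c.very_strong >= 1 and c.moderate >= 2,
        ),
        Rule(
            "Pathogenic 1c",
            Classification.PATHOGENIC,
            "1 very strong, 1 moderate and 1 supporting",
            lambda c: c.very_strong >= 1 and c.moderate >= 1 and c.supporting >= 1,
        ),
        Rule(
            "Pathogenic 1d",
            Classification.PATHOGENIC,
            "1 very strong and >=2 supporting",
            lambda c: c.very_strong >= 1 and c.supporting >= 2,
        ),
        Rule(
            "Pathogenic 2",
            Classification.PATHOGENIC,
            ">=2 strong",
            lambda c: c.strong >= 2,
        ),
        Rule(
            "Pathogenic 3a",
            Classification.PATHOGENIC,
            "1 strong and >=3 moderate",
            lambda c: c.strong == 1 and c.moderate >= 3,
        ),
        Rule(
            "Pathogenic 3b",
            Classification.PATHOGENIC,
            "1 strong, 2 moderate and >=2 supporting",
            lambda c: c.strong == 1 and c.moderate == 2 and c.supporting >= 2,
        ),
        Rule(
            "Pathogenic 3c",
            Classification.PATHOGENIC,
            "1 strong, 1 moderate and >=4 supporting",
            lambda c: c.strong == 1 and c.moderate == 1 and c.supporting >= 4,
        ),
        Rule(
            "Likely Pathogenic 1",
            Classification.LIKELY_PATHOGENIC,
            "1 very strong and 1 moderate",
            lambda c: c.very_strong >= 1 and c.moderate == 1,
        ),
        Rule(
            "Likely Pathogenic 2",
            Classification.LIKELY_PATHOGENIC,
            "1 strong and 1-2 moderate",
            lambda c: c.strong == 1 and 1 <= c.moderate <= 2,
        ),
        Rule(
            "Likely Pathogenic 3",
            Classification.LIKELY_PATHOGENIC,
            f"1 strong and {lp3_text} supporting",
            lambda c: c.strong == 1 and c.supporting >= lp3_min,
        ),
        Rule(
            "Likely Pathogenic 4",
            Classification.LIKELY_PATHOGENIC,
            ">=3 moderate",
            lambda c: c.moderate >= 3,
        ),
        Rule(
            "Likely Pathogenic 5",
            Classification.LIKELY_PATHOGENIC,
            "2 moderate and >=2 supporting",
            lambda c: c.moderate == 2 and c.supporting >= 2,
        ),
        Rule(
            "Likely Pathogenic 6",
            Classification.LIKELY_PATHOGENIC,
            "1 moderate and >=4 supporting",
            lambda c: c.moderate == 1 and c.supporting >= 4,
        ),
        Rule(
            "Benign 1",
            Classification.BENIGN,
            "1 stand-alone",
            lambda c: c.stand_alone >= 1,
        ),
        Rule(
            "Benign 2",
            Classification.BENIGN,
            ">=2 benign strong",
            lambda c: c.benign_strong >= 2,
        ),
        Rule(
            "Likely Benign 1",
            Classification.LIKELY_BENIGN,
            "1 benign strong and 1 benign supporting",
            lambda c: c.benign_strong == 1 and c.benign_supporting >= 1,
        ),
        Rule(
            "Likely Benign 2",
            Classification.LIKELY_BENIGN,
            ">=2 benign supporting",
            lambda c: c.benign_supporting >= 2,
        ),
    ]


@dataclass(frozen=True)
class ClassificationResult:
    category: Classification
    rule_label: str
    counts: CriterionCounts
    conflict: bool = False


_PATHOGENIC_SIDE = (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC)
_BENIGN_SIDE = (Classification.BENIGN, Classification.LIKELY_BENIGN)


def classify(
    criteria: Iterable[str],
    *,
    unmapped: bool = False,
    strict_lp3: bool = False,
) -> ClassificationResult:
    """Combine a set of criterion codes into a significance category.

    Unknown codes raise :class:`ValueError` naming the code.  Variants
    flagged ``unmapped`` bypass the rule table entirely and come back as
    ``Excluded-Unmapped``.
    """
    counts = CriterionCounts.from_codes(criteria)
    if unmapped:
        return ClassificationResult(
            Classification.EXCLUDED_UNMAPPED, "excluded-unmapped", counts
        )
    rules = rule_table(strict_lp3=strict_lp3)
    path_hit = next(
        (r for r in rules if r.category in _PATHOGENIC_SIDE and r.test(counts)), None
    )
    benign_hit = next(
        (r for r in rules if r.category in _BENIGN_SIDE and r.test(counts)), None
    )
    if path_hit and benign_hit:
        return ClassificationResult(Classification.VUS, "conflict-VUS", counts, True)
    if path_hit:
        return ClassificationResult(path_hit.category, path_hit.label, counts)
    if benign_hit:
        return ClassificationResult(benign_hit.category, benign_hit.label, counts)
    return ClassificationResult(Classification.VUS, "default-VUS", counts)


def classify_profile(profile, *, strict_lp3: bool = False) -> ClassificationResult:
    """Classify a :class:`~nbsvar.evidence.CriteriaProfile`."""
    from .variant_parsing import MappingStatus

    unmapped = (
        profile.variant.variant.mapping_status is not MappingStatus.MAPPED
    )
    return classify(profile.criteria, unmapped=unmapped, strict_lp3=strict_lp3)
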