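"""Shared fixtures and independent oracles.

The brute-force classifier below is written independently of the engine's
rule table (plain arithmetic over strength tallies, no shared code) so the
two can be compared over an exhaustive universe of criterion subsets.
"""

from __future__ import annotations

import pytest

from nbsvar import CohortConfig, generate_study, run_pipeline

SMALL_CONFIG = dict(
    n_diseases_per_category={
        "amino_acid": 2,
        "fatty_acid_oxidation": 2,
        "organic_acid": 2,
        "other": 2,
    },
    subjects_per_disease=40,
    seed=101,
)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(CohortConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_run(small_study):
    return run_pipeline(
        small_study.subjects,
        small_study.extract,
        references=small_study.references,
        predictions=small_study.predictions,
        secondary=small_study.secondary,
    )


@pytest.fixture(scope="session")
def default_study():
    """The full-size emulated cohort: 1904 subjects over 32 diseases."""
    return generate_study(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_study):
    return run_pipeline(
        default_study.subjects,
        default_study.extract,
        references=default_study.references,
        predictions=default_study.predictions,
        secondary=default_study.secondary,
    )


# --------------------------------------------------------------------------
# Independent brute-force combining-rule checker
# --------------------------------------------------------------------------

_STRONG = {"PS1", "PS2", "PS3", "PS4"}
_MODERATE = {"PM1", "PM2", "PM3", "PM4", "PM5", "PM6"}
_SUPPORTING = {"PP1", "PP2", "PP3", "PP4", "PP5"}
_BENIGN_STRONG = {"BS1", "BS2", "BS3", "BS4"}
_BENIGN_SUPPORTING = {"BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"}


def brute_force_classify(codes: frozenset[str]) -> tuple[str, bool]:
    """(category, conflict) by direct enumeration of the combining rules."""
    vs = int("PVS1" in codes)
    s = len(codes & _STRONG)
    m = len(codes & _MODERATE)
    p = len(codes & _SUPPORTING)
    ba = int("BA1" in codes)
    bs = len(codes & _BENIGN_STRONG)
    bp = len(codes & _BENIGN_SUPPORTING)

    pathogenic = (
        (vs == 1 and s >= 1)
        or (vs == 1 and m >= 2)
        or (vs == 1 and m >= 1 and p >= 1)
        or (vs == 1 and p >= 2)
        or (s >= 2)
        or (s == 1 and m >= 3)
        or (s == 1 and m == 2 and p >= 2)
        or (s == 1 and m == 1 and p >= 4)
    )
    likely_pathogenic = (
        (vs == 1 and m == 1)
        or (s == 1 and m in (1, 2))
        or (s == 1 and p >= 2)
        or (m >= 3)
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    benign = ba == 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or (bp >= 2)

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "Uncertain Significance", True
    if pathogenic:
        return "Pathogenic", False
    if likely_pathogenic:
        return "Likely Pathogenic", False
    if benign:
        return "Benign", False
    if likely_benign:
        return "Likely Benign", False
    return "Uncertain Significance", False


#: The 12-code universe for exhaustive engine-vs-oracle comparison.
ORACLE_UNIVERSE = [
    "PVS1", "PS1", "PS3", "PM1", "PM3", "PM5",
    "PM6", "PP1", "PP3", "PP5", "BA1", "BP4",
]
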