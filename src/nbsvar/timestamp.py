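"""Time-stamped re-analysis against a later database snapshot.

Variants classified locally as unpublished (absent from the baseline
extract) are re-checked against an updated extract taken at a later date.
The module reports which query variants have since been submitted, compares
the snapshot's significance with the local classification, and tests
whether the overlap is larger than chance with a hypergeometric tail
probability.

Tail convention: the default is the upper tail (enrichment),
``P(X >= n_overlap)`` for X hypergeometric with population ``n_universe``,
``n_added`` successes and ``n_query`` draws, computed with the survival
function.  A ``tail="lower"`` flag gives the depletion tail instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .acmg_engine import Classification, ClassificationResult
from .clinvar_match import ClinVarEntry, DistinctVariant, ExtractIndex

__all__ = [
    "SnapshotComparison",
    "hypergeometric_enrichment",
    "compare_snapshots",
]

_PLP = {"Pathogenic", "Likely Pathogenic"}
_UNCERTAIN = {"Uncertain Significance", "Conflicting Interpretations of Pathogenicity"}


def hypergeometric_enrichment(
    n_universe: int,
    n_added: int,
    n_query: int,
    n_overlap: int,
    *,
    tail: str = "upper",
) -> float:
    """Hypergeometric tail probability of the observed snapshot overlap.

    Draws ``n_query`` variants without replacement from a universe of
    ``n_universe`` of which ``n_added`` are newly submitted; returns
    ``P(X >= n_overlap)`` under the default upper tail.
    """
    for name, value in (
        ("n_universe", n_universe),
        ("n_added", n_added),
        ("n_query", n_query),
        ("n_overlap", n_overlap),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    if n_added > n_universe:
        raise ValueError("n_added exceeds n_universe")
    if n_query > n_universe:
        raise ValueError("n_query exceeds n_universe")
    if n_overlap > min(n_added, n_query):
        raise ValueError("n_overlap exceeds min(n_added, n_query)")
    if tail == "upper":
        return float(hypergeom.sf(n_overlap - 1, n_universe, n_added, n_query))
    if tail == "lower":
        return float(hypergeom.cdf(n_overlap, n_universe, n_added, n_query))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


@dataclass
class SnapshotComparison:
    """Outcome of re-auditing local classifications against a later snapshot."""

    n_universe: int
    n_added: int
    n_query: int
    n_overlap: int
    rows: list[dict] = field(default_factory=list)
    p_value: float = 1.0
    tail: str = "upper"

    @property
    def n_concordant(self) -> int:
        return sum(r["concordant"] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Concordance table: one row per overlapping variant."""
        columns = [
            "variant",
            "snapshot_classification",
            "review_stars",
            "local_classification",
            "concordant",
        ]
        return pd.DataFrame(self.rows, columns=columns)

    def to_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_added": self.n_added,
            "n_query": self.n_query,
            "n_overlap": self.n_overlap,
            "n_concordant": self.n_concordant,
            "p_value": self.p_value,
            "tail": self.tail,
            "rows": self.rows,
        }


def _concordant(local: str, snapshot: str) -> bool:
    """Both pathogenic-side, or both uncertain."""
    if local in _PLP and snapshot in _PLP:
        return True
    return local in _UNCERTAIN and snapshot in _UNCERTAIN


def compare_snapshots(
    classified: Sequence[tuple[DistinctVariant, ClassificationResult]],
    baseline: Iterable[ClinVarEntry],
    updated: Iterable[ClinVarEntry],
    *,
    tail: str = "upper",
) -> SnapshotComparison:
    """Re-audit locally classified variants against an updated extract.

    ``classified`` pairs each distinct variant with its local
    classification; every one of them must be absent from the baseline
    extract (they were classified precisely because they were unpublished),
    otherwise a :class:`ValueError` is raised.
    """
    baseline = list(baseline)
    updated = list(updated)
    baseline_index = ExtractIndex.from_entries(baseline)
    updated_index = ExtractIndex.from_entries(updated)

    baseline_keys = {e.key for e in baseline if e.key}
    universe_keys = baseline_keys | {e.key for e in updated if e.key}
    n_universe = len(universe_keys)
    n_added = n_universe - len(baseline_keys)
    n_query = len(classified)

    rows: list[dict] = []
    for dv, result in sorted(classified, key=lambda pair: pair[0].variant.key or ""):
        if baseline_index.lookup(dv.variant) is not None:
            raise ValueError(
                f"classified variant {dv.variant.key} is present in the baseline "
                "extract; it was supposed to be unpublished"
            )
        entry = updated_index.lookup(dv.variant)
        if entry is None:
            continue
        rows.append(
            {
                "variant": entry.name,
                "snapshot_classification": entry.significance,
                "review_stars": entry.review_stars,
                "local_classification": result.category.value,
                "concordant": _concordant(result.category.value, entry.significance),
            }
        )

    n_overlap = len(rows)
    p_value = hypergeometric_enrichment(
        n_universe, n_added, n_query, n_overlap, tail=tail
    )
    return SnapshotComparison(
        n_universe=n_universe,
        n_added=n_added,
        n_query=n_query,
        n_overlap=n_overlap,
        rows=rows,
        p_value=p_value,
        tail=tail,
    )
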