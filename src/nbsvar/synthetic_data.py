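"""Synthetic registry cohorts with planted ground truth.

The real cohort behind this pipeline (a longitudinal newborn-screening
registry of inborn errors of metabolism) is access-controlled, so this
module emulates its structure: 32 diseases across 4 disorder categories,
roughly half of subjects genotyped, about 28.5% of distinct variants
absent from the reference database, variant strings written in a mix of
dialects, free-text "none"/"negative" tokens, and a small fraction of
submissions whose stated reference residue is wrong.

Everything is derived from per-gene synthetic coding sequences: a random
CDS is generated for each (one-gene) disease, the protein is its
translation, and every planted substitution is a real single-base change
in that CDS, so c./p. pairs in the ClinVar-style extract are internally
consistent and reference-residue validation is self-contained (the
proteins are written as FASTA).

A :class:`TruthManifest` records, for every planted variant, its identity,
published/unpublished status, mapping validity, consequence class, the
evidence criteria the planted clinical data support, and the expected
classification — so downstream recovery is checkable without the real
data.  Identical configs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .acmg_engine import classify
from .case_data import SUBJECT_COLUMNS
from .clinvar_match import convert_extract
from .variant_parsing import (
    AA_LETTERS,
    Consequence,
    NormalizedVariant,
    ReferenceSequence,
    ReferenceSet,
    protein_three_letter,
)

__all__ = [
    "CATEGORIES",
    "CohortConfig",
    "PlantedVariant",
    "TruthManifest",
    "SyntheticStudy",
    "generate_cohort",
    "generate_clinvar_extract",
    "generate_updated_extract",
    "generate_predictions",
    "generate_study",
]

CATEGORIES = ("amino_acid", "fatty_acid_oxidation", "organic_acid", "other")
_CATEGORY_PREFIX = {
    "amino_acid": "AA",
    "fatty_acid_oxidation": "FAO",
    "organic_acid": "OA",
    "other": "OTH",
}

#: Disease counts per category in the emulated cohort (10/8/11/3).
DEFAULT_N_DISEASES = {
    "amino_acid": 10,
    "fatty_acid_oxidation": 8,
    "organic_acid": 11,
    "other": 3,
}

DEFAULT_TOTAL_SUBJECTS = 1904

#: Per-criterion availability among mapped unpublished variants.  PM3/PM6/
#: PP1/PP5 apply to any mapped variant; PM5/PP3/BP4 to missense only
#: (PP3 is the probability of concordant-deleterious predictor calls).
DEFAULT_EVIDENCE_RATES = {
    "PM3": 0.44,
    "PM5": 0.13,
    "PM6": 0.013,
    "PP1": 0.047,
    "PP5": 0.153,
    "PP3": 0.755,
    "BP4": 0.01,
}

#: Dialect distribution over rendered variant strings: single-letter
#: shorthand dominates real registry submissions.
DEFAULT_DIALECT_MIX = {
    "single_letter": 0.50,
    "hgvs_p_three": 0.15,
    "hgvs_c": 0.25,
    "hgvs_c_spaced": 0.10,
}

_DIALECT_NAMES = frozenset(DEFAULT_DIALECT_MIX)
_PLP = ("Pathogenic", "Likely Pathogenic")
_PUB_SIGNIFICANCES = (
    ("Pathogenic", 0.40),
    ("Likely Pathogenic", 0.25),
    ("Uncertain Significance", 0.20),
    ("Likely Benign", 0.10),
    ("Benign", 0.05),
)
_BACKGROUND_SIGNIFICANCES = (
    ("Pathogenic", 0.20),
    ("Likely Pathogenic", 0.15),
    ("Uncertain Significance", 0.30),
    ("Likely Benign", 0.15),
    ("Benign", 0.15),
    ("Conflicting Interpretations of Pathogenicity", 0.05),
)
_STARS_TO_STATUS = {
    0: "no assertion criteria provided",
    1: "criteria provided, single submitter",
    2: "criteria provided, multiple submitters, no conflicts",
    3: "reviewed by expert panel",
    4: "practice guideline",
}

_CODON_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_CODON_TABLE.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _CODON_TABLE.stop_codons})
_SENSE_CODONS = sorted(_CODON_TABLE.forward_table)
_BASES = "ACGT"

EXTRACT_COLUMNS = [
    "Name",
    "Gene",
    "Protein change",
    "Clinical significance",
    "Review status",
]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    ``subjects_per_disease`` fixes an equal size for every disease;
    ``total_subjects`` instead spreads a cohort total as evenly as possible
    across the diseases.  At most one of the two may be set; with neither,
    1904 subjects are distributed over the default 32 diseases.
    """

    n_diseases_per_category: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_DISEASES)
    )
    subjects_per_disease: Optional[int] = None
    total_subjects: Optional[int] = None
    genotyping_rate: float = 0.516
    unpublished_rate: float = 0.285
    unmapped_rate: float = 0.068
    invalid_token_rate: float = 0.03
    two_variant_rate: float = 0.8
    homozygous_rate: float = 0.15
    distinct_per_genotyped: float = 0.574
    null_fraction: float = 44 / 150
    synonymous_fraction: float = 4 / 150
    cdna_only_missense_fraction: float = 0.15
    discordant_prediction_rate: float = 0.10
    synonymous_deleterious_rate: float = 0.10
    dialect_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIALECT_MIX)
    )
    evidence_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_RATES)
    )
    protein_length: tuple[int, int] = (300, 500)
    n_background_per_gene: int = 15
    n_timestamp_added: int = 120
    n_timestamp_overlap: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "genotyping_rate",
            "unpublished_rate",
            "unmapped_rate",
            "invalid_token_rate",
            "two_variant_rate",
            "homozygous_rate",
            "distinct_per_genotyped",
            "null_fraction",
            "synonymous_fraction",
            "cdna_only_missense_fraction",
            "discordant_prediction_rate",
            "synonymous_deleterious_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if set(self.n_diseases_per_category) != set(CATEGORIES):
            raise ValueError(
                "n_diseases_per_category must have exactly the keys "
                f"{sorted(CATEGORIES)}"
            )
        for cat, count in self.n_diseases_per_category.items():
            if count <= 0:
                raise ValueError(f"n_diseases_per_category[{cat!r}] must be positive")
        if self.subjects_per_disease is not None and self.total_subjects is not None:
            raise ValueError(
                "set at most one of subjects_per_disease and total_subjects"
            )
        if self.subjects_per_disease is not None and self.subjects_per_disease <= 0:
            raise ValueError("subjects_per_disease must be positive")
        if self.total_subjects is not None and self.total_subjects <= 0:
            raise ValueError("total_subjects must be positive")
        if set(self.dialect_mix) - _DIALECT_NAMES:
            raise ValueError(
                f"unknown dialects: {sorted(set(self.dialect_mix) - _DIALECT_NAMES)}"
            )
        if abs(sum(self.dialect_mix.values()) - 1.0) > 1e-9:
            raise ValueError("dialect_mix must sum to 1")
        for code, rate in self.evidence_rates.items():
            if code not in DEFAULT_EVIDENCE_RATES:
                raise ValueError(f"evidence_rates has unknown criterion {code!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"evidence_rates[{code!r}] must be in [0, 1]")
        if self.protein_length[0] < 30 or self.protein_length[1] < self.protein_length[0]:
            raise ValueError("protein_length must be an increasing pair >= 30")

    def to_dict(self) -> dict:
        data = asdict(self)
        data["n_diseases_per_category"] = dict(self.n_diseases_per_category)
        data["dialect_mix"] = dict(self.dialect_mix)
        data["evidence_rates"] = dict(self.evidence_rates)
        data["protein_length"] = list(self.protein_length)
        return data

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PlantedVariant:
    """Ground truth for one distinct planted variant."""

    disease: str
    category: str
    gene: str
    transcript: str
    cdna_change: Optional[str]
    protein_change: Optional[str]
    submitted_protein_change: Optional[str]
    level: str  # "cdna" or "protein": which notation subjects report
    consequence: str
    published: bool
    significance: Optional[str] = None
    review_stars: Optional[int] = None
    mapping_valid: bool = True
    evidence_codes: list[str] = field(default_factory=list)
    expected_classification: Optional[str] = None
    expected_rule: Optional[str] = None
    supporting_subjects: list[str] = field(default_factory=list)
    allele_count: int = 0

    @property
    def key(self) -> str:
        gene = self.gene.upper()
        if self.level == "cdna":
            return f"{gene}|c:{self.cdna_change}"
        return f"{gene}|p:{self.submitted_protein_change or self.protein_change}"


@dataclass
class TruthManifest:
    """Everything needed to audit pipeline recovery, JSON-serialisable."""

    config: dict
    config_digest: str
    diseases: list[dict]
    variants: list[PlantedVariant]
    subject_alleles: dict[str, list[str]]
    overlap_keys: list[str] = field(default_factory=list)

    def unpublished(self) -> list[PlantedVariant]:
        return [v for v in self.variants if not v.published]

    def unmapped(self) -> list[PlantedVariant]:
        return [v for v in self.variants if not v.mapping_valid]

    def mapped_unpublished(self) -> list[PlantedVariant]:
        return [v for v in self.variants if not v.published and v.mapping_valid]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "config_digest": self.config_digest,
            "diseases": self.diseases,
            "variants": [asdict(v) for v in self.variants],
            "subject_alleles": self.subject_alleles,
            "overlap_keys": self.overlap_keys,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        data = json.loads(Path(path).read_text())
        data["variants"] = [PlantedVariant(**v) for v in data["variants"]]
        return cls(**data)


# ---------------------------------------------------------------------------
# Low-level random helpers (index-based for determinism across numpy builds)
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(len(seq)))]


def _weighted(rng: np.random.Generator, items: Iterable[tuple[object, float]]):
    items = list(items)
    total = sum(w for _, w in items)
    r = rng.random() * total
    acc = 0.0
    for value, weight in items:
        acc += weight
        if r < acc:
            return value
    return items[-1][0]


@dataclass
class _Gene:
    disease: str
    category: str
    gene: str
    transcript: str
    cds: str
    protein: str
    used_aa: set = field(default_factory=set)
    used_cdna: set = field(default_factory=set)


def _make_gene(rng: np.random.Generator, disease: str, category: str,
               index: int, length_range: tuple[int, int]) -> _Gene:
    n_residues = int(rng.integers(length_range[0], length_range[1] + 1))
    codons = ["ATG"] + [
        _SENSE_CODONS[int(i)] for i in rng.integers(0, len(_SENSE_CODONS), n_residues - 1)
    ]
    cds = "".join(codons) + "TAA"
    protein = "".join(_CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds) - 3, 3))
    return _Gene(
        disease=disease,
        category=category,
        gene=f"{disease}G",
        transcript=f"NM_{900000 + index}.2",
        cds=cds,
        protein=protein,
    )


def _substitution(gene: _Gene, rng: np.random.Generator, want: str) -> Optional[dict]:
    """Find an unused single-base substitution with the wanted protein effect."""
    n_codons = len(gene.protein)
    for ci in rng.permutation(n_codons - 1) + 1:  # skip the start codon
        ci = int(ci)
        aa_pos = ci + 1
        if aa_pos in gene.used_aa:
            continue
        codon = gene.cds[3 * ci : 3 * ci + 3]
        old_aa = _CODON_TO_AA[codon]
        for j in rng.permutation(3):
            j = int(j)
            old = codon[j]
            for b in rng.permutation(4):
                base = _BASES[int(b)]
                if base == old:
                    continue
                new_aa = _CODON_TO_AA[codon[:j] + base + codon[j + 1 :]]
                if want == "missense" and new_aa in ("*", old_aa):
                    continue
                if want == "nonsense" and new_aa != "*":
                    continue
                if want == "synonymous" and new_aa != old_aa:
                    continue
                gene.used_aa.add(aa_pos)
                gene.used_cdna.update({3 * ci + 1, 3 * ci + 2, 3 * ci + 3})
                return {
                    "aa_pos": aa_pos,
                    "ref_aa": old_aa,
                    "alt_aa": new_aa,
                    "cdna_pos": 3 * ci + j + 1,
                    "ref_base": old,
                    "alt_base": base,
                }
    return None


def _neighbor_missense(
    gene: _Gene, rng: np.random.Generator, aa_pos: int, alt_aa: str
) -> Optional[dict]:
    """A different missense change in the same codon (for PM5 planting)."""
    ci = aa_pos - 1
    codon = gene.cds[3 * ci : 3 * ci + 3]
    old_aa = _CODON_TO_AA[codon]
    for j in rng.permutation(3):
        j = int(j)
        old = codon[j]
        for b in rng.permutation(4):
            base = _BASES[int(b)]
            if base == old:
                continue
            new_aa = _CODON_TO_AA[codon[:j] + base + codon[j + 1 :]]
            if new_aa in ("*", old_aa, alt_aa):
                continue
            return {
                "aa_pos": aa_pos,
                "ref_aa": old_aa,
                "alt_aa": new_aa,
                "cdna_pos": 3 * ci + j + 1,
                "ref_base": old,
                "alt_base": base,
            }
    return None


def _splice(gene: _Gene, rng: np.random.Generator) -> Optional[str]:
    for _ in range(200):
        pos = int(rng.integers(10, len(gene.cds) - 3))
        if pos in gene.used_cdna:
            continue
        gene.used_cdna.add(pos)
        offset = _pick(rng, [1, 2, -1, -2])
        ref = _pick(rng, _BASES)
        alt = _pick(rng, [b for b in _BASES if b != ref])
        return f"c.{pos}{offset:+d}{ref}>{alt}"
    return None


def _frameshift(gene: _Gene, rng: np.random.Generator) -> Optional[dict]:
    n_codons = len(gene.protein)
    for ci in rng.permutation(n_codons - 1) + 1:
        ci = int(ci)
        aa_pos = ci + 1
        if aa_pos in gene.used_aa:
            continue
        gene.used_aa.add(aa_pos)
        gene.used_cdna.update({3 * ci + 1, 3 * ci + 2, 3 * ci + 3})
        pos = 3 * ci + 1
        return {
            "aa_pos": aa_pos,
            "ref_aa": gene.protein[ci],
            "cdna_pos": pos,
            "ref_base": gene.cds[pos - 1],
        }
    return None


def _extract_name(gene: _Gene, cdna: Optional[str], protein: Optional[str]) -> str:
    name = f"{gene.transcript}({gene.gene}):{cdna}"
    if protein:
        name += f" (p.{protein_three_letter(protein)})"
    return name


def _extract_row(
    gene: _Gene,
    cdna: Optional[str],
    protein: Optional[str],
    significance: str,
    stars: int,
) -> dict:
    return {
        "Name": _extract_name(gene, cdna, protein),
        "Gene": gene.gene,
        "Protein change": protein or "",
        "Clinical significance": significance,
        "Review status": _STARS_TO_STATUS[stars],
    }


def _render(pv: PlantedVariant, rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    """Render one observation of a planted variant in a sampled dialect."""
    if pv.level == "cdna":
        dialect = _weighted(
            rng,
            [(d, mix.get(d, 0.0)) for d in ("hgvs_c", "hgvs_c_spaced")],
        )
        text = pv.cdna_change or ""
        if dialect == "hgvs_c_spaced" and ">" in text:
            text = text.replace(">", " > ")
        return text
    dialect = _weighted(
        rng,
        [(d, mix.get(d, 0.0)) for d in ("single_letter", "hgvs_p_three")],
    )
    protein = pv.submitted_protein_change or pv.protein_change or ""
    if dialect == "single_letter":
        return protein.replace("*", "X")
    prefix = _pick(rng, ["p.", "p. "])
    ref3 = protein_three_letter_or_submitted(protein)
    return f"{prefix}{ref3}"


def protein_three_letter_or_submitted(protein: str) -> str:
    # Wrong-reference plants are still valid single-letter notation, so the
    # standard three-letter renderer applies.
    return protein_three_letter(protein)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def generate_clinvar_extract(
    genes: Sequence[str],
    n_variants_per_gene: int,
    seed: int,
    references: Optional[ReferenceSet] = None,
) -> pd.DataFrame:
    """A generic ClinVar-style gene extract with consistent c./p. pairs."""
    if not genes:
        raise ValueError("gene list must be nonempty")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, symbol in enumerate(genes):
        gene = _make_gene(rng, symbol.rstrip("G") or symbol, "other", 800000 + gi, (300, 400))
        gene.gene = symbol
        rows.extend(_background_rows(gene, rng, n_variants_per_gene))
    return pd.DataFrame(rows, columns=EXTRACT_COLUMNS)


def _background_rows(gene: _Gene, rng: np.random.Generator, n: int) -> list[dict]:
    rows = []
    for _ in range(n):
        kind = _weighted(rng, [("missense", 0.7), ("nonsense", 0.1), ("synonymous", 0.2)])
        sub = _substitution(gene, rng, kind)
        if sub is None:
            break
        cdna = f"c.{sub['cdna_pos']}{sub['ref_base']}>{sub['alt_base']}"
        protein = f"{sub['ref_aa']}{sub['aa_pos']}{sub['alt_aa']}"
        significance = _weighted(rng, _BACKGROUND_SIGNIFICANCES)
        stars = int(rng.integers(0, 3))
        rows.append(_extract_row(gene, cdna, protein, significance, stars))
    return rows


def generate_updated_extract(
    baseline: pd.DataFrame,
    n_added: int,
    planted_overlap: Sequence[dict],
    seed: int,
) -> pd.DataFrame:
    """Baseline extract plus ``n_added`` new rows including a planted overlap.

    ``planted_overlap`` rows (extract-style dicts) must be absent from the
    baseline; a row already present raises :class:`ValueError`.
    """
    if n_added < len(planted_overlap):
        raise ValueError("n_added must be >= len(planted_overlap)")
    rng = np.random.default_rng(seed)
    baseline_keys = {
        e.key for e in convert_extract(baseline).entries if e.key
    }
    overlap_frame = pd.DataFrame(list(planted_overlap), columns=EXTRACT_COLUMNS)
    for entry in convert_extract(overlap_frame).entries:
        if entry.key in baseline_keys:
            raise ValueError(
                f"planted overlap variant {entry.name!r} already in baseline"
            )
    # Novel padding rows: fresh missense changes at residue positions far
    # beyond any baseline protein, arithmetically consistent c./p. pairs.
    transcripts: dict[str, str] = {}
    for name in baseline["Name"] if len(baseline) else []:
        text = str(name)
        if "(" in text and ":" in text:
            acc, rest = text.split("(", 1)
            transcripts.setdefault(rest.split(")")[0], acc.strip())
    gene_pool = sorted(transcripts) or ["GENE1"]
    rows = list(planted_overlap)
    for i in range(n_added - len(planted_overlap)):
        symbol = _pick(rng, gene_pool)
        aa_pos = 600 + i
        codon = _pick(rng, _SENSE_CODONS)
        old_aa = _CODON_TO_AA[codon]
        found = None
        for j in (int(x) for x in rng.permutation(3)):
            for b in rng.permutation(4):
                base = _BASES[int(b)]
                if base == codon[j]:
                    continue
                candidate = _CODON_TO_AA[codon[:j] + base + codon[j + 1 :]]
                if candidate not in ("*", old_aa):
                    found = (j, base, candidate)
                    break
            if found:
                break
        if found is None:
            continue
        j, alt_base, alt_aa = found
        cdna_pos = 3 * (aa_pos - 1) + j + 1
        cdna = f"c.{cdna_pos}{codon[j]}>{alt_base}"
        protein = f"{old_aa}{aa_pos}{alt_aa}"
        name = f"{transcripts.get(symbol, 'NM_800000.1')}({symbol}):{cdna} (p.{protein_three_letter(protein)})"
        rows.append(
            {
                "Name": name,
                "Gene": symbol,
                "Protein change": protein,
                "Clinical significance": _weighted(rng, _BACKGROUND_SIGNIFICANCES),
                "Review status": _STARS_TO_STATUS[int(rng.integers(0, 3))],
            }
        )
    added = pd.DataFrame(rows, columns=EXTRACT_COLUMNS)
    return pd.concat([baseline, added], ignore_index=True)


def generate_predictions(
    variants: Sequence[NormalizedVariant],
    seed: int,
    concordance: float = 1.0,
    p_deleterious: float = 1.0,
) -> pd.DataFrame:
    """Two predictor calls per missense variant; non-missense get none.

    With probability ``concordance`` the two tools agree (both deleterious
    with probability ``p_deleterious``, both neutral otherwise); otherwise
    they disagree.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for v in variants:
        if v.consequence is not Consequence.MISSENSE:
            continue
        if rng.random() < concordance:
            call = "deleterious" if rng.random() < p_deleterious else "neutral"
            calls = [call, call]
        else:
            calls = ["deleterious", "neutral"]
            if rng.random() < 0.5:
                calls.reverse()
        for tool, call in zip(("FATHMM", "SNPS&GO"), calls):
            rows.append(
                {
                    "gene": v.gene or "",
                    "cdna_change": v.cdna_change or "",
                    "protein_change": v.protein_change or "",
                    "tool": tool,
                    "call": call,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "cdna_change", "protein_change", "tool", "call"]
    )


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """The full synthetic input bundle for one pipeline run."""

    config: CohortConfig
    subjects: pd.DataFrame
    manifest: TruthManifest
    extract: pd.DataFrame
    updated_extract: pd.DataFrame
    predictions: pd.DataFrame
    secondary: pd.DataFrame
    references: ReferenceSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "subjects": outdir / "subjects.csv",
            "extract": outdir / "clinvar_baseline.csv",
            "updated_extract": outdir / "clinvar_updated.csv",
            "predictions": outdir / "predictions.csv",
            "secondary": outdir / "secondary_db.csv",
            "references": outdir / "references.fasta",
            "manifest": outdir / "truth_manifest.json",
        }
        self.subjects.to_csv(paths["subjects"], index=False)
        self.extract.to_csv(paths["extract"], index=False)
        self.updated_extract.to_csv(paths["updated_extract"], index=False)
        self.predictions.to_csv(paths["predictions"], index=False)
        self.secondary.to_csv(paths["secondary"], index=False)
        self.references.to_fasta(paths["references"])
        self.manifest.to_json(paths["manifest"])
        return paths


def _plant_pool_variant(
    gene: _Gene,
    rng: np.random.Generator,
    cfg: CohortConfig,
    published: bool,
) -> Optional[PlantedVariant]:
    """Create one distinct pool variant (evidence planted separately)."""
    base = dict(
        disease=gene.disease,
        category=gene.category,
        gene=gene.gene,
        transcript=gene.transcript,
        published=published,
    )
    if published:
        kind = _weighted(
            rng,
            [("missense", 0.8), ("nonsense", 0.1), ("synonymous", 0.05), ("frameshift", 0.05)],
        )
        significance = _weighted(rng, _PUB_SIGNIFICANCES)
        stars = int(rng.integers(0, 3))
        if kind == "frameshift":
            fs = _frameshift(gene, rng)
            if fs is None:
                return None
            return PlantedVariant(
                cdna_change=f"c.{fs['cdna_pos']}del{fs['ref_base']}",
                protein_change=f"{fs['ref_aa']}{fs['aa_pos']}fs",
                submitted_protein_change=f"{fs['ref_aa']}{fs['aa_pos']}fs",
                level="cdna" if rng.random() < 0.7 else "protein",
                consequence=Consequence.FRAMESHIFT.value,
                significance=significance,
                review_stars=stars,
                **base,
            )
        sub = _substitution(gene, rng, kind)
        if sub is None:
            return None
        protein = f"{sub['ref_aa']}{sub['aa_pos']}{sub['alt_aa']}"
        consequence = {
            "missense": Consequence.MISSENSE,
            "nonsense": Consequence.NONSENSE,
            "synonymous": Consequence.SYNONYMOUS,
        }[kind]
        return PlantedVariant(
            cdna_change=f"c.{sub['cdna_pos']}{sub['ref_base']}>{sub['alt_base']}",
            protein_change=protein,
            submitted_protein_change=protein,
            level="protein" if rng.random() < 0.65 else "cdna",
            consequence=consequence.value,
            significance=significance,
            review_stars=stars,
            **base,
        )

    # Unpublished: maybe an unmapped (wrong reference residue) plant.
    if rng.random() < cfg.unmapped_rate:
        sub = _substitution(gene, rng, "missense")
        if sub is None:
            return None
        wrong_ref = _pick(
            rng, sorted(AA_LETTERS - {sub["ref_aa"], sub["alt_aa"]})
        )
        return PlantedVariant(
            cdna_change=f"c.{sub['cdna_pos']}{sub['ref_base']}>{sub['alt_base']}",
            protein_change=f"{sub['ref_aa']}{sub['aa_pos']}{sub['alt_aa']}",
            submitted_protein_change=f"{wrong_ref}{sub['aa_pos']}{sub['alt_aa']}",
            level="protein",
            consequence=Consequence.MISSENSE.value,
            mapping_valid=False,
            expected_classification="Excluded-Unmapped",
            expected_rule="excluded-unmapped",
            **base,
        )

    r = rng.random()
    if r < cfg.null_fraction:
        subtype = _weighted(rng, [("nonsense", 0.5), ("frameshift", 0.3), ("splice", 0.2)])
        if subtype == "splice":
            cdna = _splice(gene, rng)
            if cdna is None:
                return None
            return PlantedVariant(
                cdna_change=cdna,
                protein_change=None,
                submitted_protein_change=None,
                level="cdna",
                consequence=Consequence.CANONICAL_SPLICE.value,
                **base,
            )
        if subtype == "frameshift":
            fs = _frameshift(gene, rng)
            if fs is None:
                return None
            return PlantedVariant(
                cdna_change=f"c.{fs['cdna_pos']}del{fs['ref_base']}",
                protein_change=f"{fs['ref_aa']}{fs['aa_pos']}fs",
                submitted_protein_change=f"{fs['ref_aa']}{fs['aa_pos']}fs",
                level="cdna" if rng.random() < 0.5 else "protein",
                consequence=Consequence.FRAMESHIFT.value,
                **base,
            )
        sub = _substitution(gene, rng, "nonsense")
        if sub is None:
            return None
        protein = f"{sub['ref_aa']}{sub['aa_pos']}*"
        return PlantedVariant(
            cdna_change=f"c.{sub['cdna_pos']}{sub['ref_base']}>{sub['alt_base']}",
            protein_change=protein,
            submitted_protein_change=protein,
            level="protein",
            consequence=Consequence.NONSENSE.value,
            **base,
        )
    if r < cfg.null_fraction + cfg.synonymous_fraction:
        sub = _substitution(gene, rng, "synonymous")
        if sub is None:
            return None
        protein = f"{sub['ref_aa']}{sub['aa_pos']}{sub['alt_aa']}"
        return PlantedVariant(
            cdna_change=f"c.{sub['cdna_pos']}{sub['ref_base']}>{sub['alt_base']}",
            protein_change=protein,
            submitted_protein_change=protein,
            level="protein",
            consequence=Consequence.SYNONYMOUS.value,
            **base,
        )
    sub = _substitution(gene, rng, "missense")
    if sub is None:
        return None
    protein = f"{sub['ref_aa']}{sub['aa_pos']}{sub['alt_aa']}"
    return PlantedVariant(
        cdna_change=f"c.{sub['cdna_pos']}{sub['ref_base']}>{sub['alt_base']}",
        protein_change=protein,
        submitted_protein_change=protein,
        level="cdna" if rng.random() < cfg.cdna_only_missense_fraction else "protein",
        consequence=Consequence.MISSENSE.value,
        **base,
    )


def _plant_evidence(
    pv: PlantedVariant,
    gene: _Gene,
    rng: np.random.Generator,
    cfg: CohortConfig,
    disease_has_plp: bool,
    extract_rows: list[dict],
    prediction_rows: list[dict],
    secondary_rows: list[dict],
) -> None:
    """Decide and realise the evidence codes for one mapped unpublished variant."""
    er = {**DEFAULT_EVIDENCE_RATES, **cfg.evidence_rates}
    codes = {"PS3", "PP4"}
    consequence = Consequence(pv.consequence)
    if consequence in {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.START_LOSS,
    }:
        codes.add("PVS1")
    if disease_has_plp and rng.random() < er["PM3"]:
        codes.add("PM3")
    if rng.random() < er["PP1"]:
        codes.add("PP1")
    if rng.random() < er["PM6"]:
        codes.add("PM6")
    if rng.random() < er["PP5"]:
        codes.add("PP5")
        secondary_rows.append(
            {
                "gene": pv.gene,
                "cdna_change": pv.cdna_change or "",
                "protein_change": pv.protein_change or "",
                "significance": _pick(rng, _PLP),
            }
        )
    if consequence is Consequence.MISSENSE:
        if pv.level == "protein" and rng.random() < er["PM5"]:
            aa_pos = int("".join(ch for ch in pv.protein_change if ch.isdigit()))
            neighbor = _neighbor_missense(gene, rng, aa_pos, pv.protein_change[-1])
            if neighbor is not None:
                codes.add("PM5")
                extract_rows.append(
                    _extract_row(
                        gene,
                        f"c.{neighbor['cdna_pos']}{neighbor['ref_base']}>{neighbor['alt_base']}",
                        f"{neighbor['ref_aa']}{neighbor['aa_pos']}{neighbor['alt_aa']}",
                        _pick(rng, _PLP),
                        int(rng.integers(1, 3)),
                    )
                )
        r = rng.random()
        outcome = None
        if r < er["PP3"]:
            outcome, calls = "PP3", ["deleterious", "deleterious"]
        elif r < er["PP3"] + er["BP4"]:
            outcome, calls = "BP4", ["neutral", "neutral"]
        elif r < er["PP3"] + er["BP4"] + cfg.discordant_prediction_rate:
            calls = ["deleterious", "neutral"]
        else:
            calls = []
        for tool, call in zip(("FATHMM", "SNPS&GO"), calls):
            prediction_rows.append(
                {
                    "gene": pv.gene,
                    "cdna_change": pv.cdna_change or "",
                    "protein_change": pv.protein_change or "",
                    "tool": tool,
                    "call": call,
                }
            )
        if outcome:
            codes.add(outcome)
    elif consequence is Consequence.SYNONYMOUS:
        if rng.random() < cfg.synonymous_deleterious_rate:
            # A lone deleterious call blocks BP7; pair it with a neutral
            # call so the discordance also rules out PP3.
            for tool, call in (("FATHMM", "deleterious"), ("SNPS&GO", "neutral")):
                prediction_rows.append(
                    {
                        "gene": pv.gene,
                        "cdna_change": pv.cdna_change or "",
                        "protein_change": pv.protein_change or "",
                        "tool": tool,
                        "call": call,
                    }
                )
        else:
            codes.add("BP7")
    pv.evidence_codes = sorted(codes)
    result = classify(codes)
    pv.expected_classification = result.category.value
    pv.expected_rule = result.rule_label


def generate_study(config: Optional[CohortConfig] = None) -> SyntheticStudy:
    """Generate the complete synthetic study bundle for one seed."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # Disease roster, ordered by category then index.
    diseases: list[_Gene] = []
    gene_index = 0
    for category in CATEGORIES:
        prefix = _CATEGORY_PREFIX[category]
        for i in range(cfg.n_diseases_per_category[category]):
            code = f"{prefix}{i + 1:02d}"
            diseases.append(
                _make_gene(rng, code, category, gene_index + 1, cfg.protein_length)
            )
            gene_index += 1

    # Subjects per disease.
    if cfg.subjects_per_disease is not None:
        per_disease = [cfg.subjects_per_disease] * len(diseases)
    else:
        total = cfg.total_subjects or DEFAULT_TOTAL_SUBJECTS
        base, rem = divmod(total, len(diseases))
        per_disease = [base + (1 if i < rem else 0) for i in range(len(diseases))]

    subject_rows: list[dict] = []
    all_variants: list[PlantedVariant] = []
    extract_rows: list[dict] = []
    prediction_rows: list[dict] = []
    secondary_rows: list[dict] = []
    subject_alleles: dict[str, list[str]] = {}
    next_sid = 1

    for gene, n_subjects in zip(diseases, per_disease):
        sids = [f"S{next_sid + i:05d}" for i in range(n_subjects)]
        next_sid += n_subjects
        genotyped_mask = rng.random(n_subjects) < cfg.genotyping_rate
        genotyped = [sid for sid, g in zip(sids, genotyped_mask) if g]

        # Distinct variant pool for this disease.
        pool: list[PlantedVariant] = []
        if genotyped:
            n_distinct = min(
                len(genotyped),
                max(1, int(round(cfg.distinct_per_genotyped * len(genotyped)))),
            )
            for _ in range(n_distinct):
                published = rng.random() >= cfg.unpublished_rate
                pv = _plant_pool_variant(gene, rng, cfg, published)
                if pv is not None:
                    pool.append(pv)
        published_pool = [v for v in pool if v.published]
        pub_plp = [v for v in published_pool if v.significance in _PLP]
        pub_other = [v for v in published_pool if v.significance not in _PLP]
        unpublished_pool = [v for v in pool if not v.published]
        disease_has_plp = bool(pub_plp)

        for pv in unpublished_pool:
            if pv.mapping_valid:
                _plant_evidence(
                    pv, gene, rng, cfg, disease_has_plp,
                    extract_rows, prediction_rows, secondary_rows,
                )
        for pv in published_pool:
            extract_rows.append(
                _extract_row(
                    gene, pv.cdna_change, pv.protein_change,
                    pv.significance, pv.review_stars,
                )
            )
            if rng.random() < 0.1:  # secondary-database decoys, benign to truth
                secondary_rows.append(
                    {
                        "gene": pv.gene,
                        "cdna_change": pv.cdna_change or "",
                        "protein_change": pv.protein_change or "",
                        "significance": "Uncertain Significance",
                    }
                )
        extract_rows.extend(_background_rows(gene, rng, cfg.n_background_per_gene))

        # --- allele assignment -------------------------------------------
        def draw_partner(v1: PlantedVariant) -> PlantedVariant:
            # Keep accidental in-trans (PM3) evidence impossible for
            # variants whose truth says PM3 is absent.
            if not v1.published:
                if "PM3" in v1.evidence_codes:
                    return _pick(rng, pub_plp)
                candidates = pub_other + [
                    u for u in unpublished_pool if u is not v1
                ]
                return _pick(rng, candidates) if candidates else v1
            if v1.significance in _PLP:
                candidates = published_pool + [
                    u
                    for u in unpublished_pool
                    if "PM3" in u.evidence_codes or not u.mapping_valid
                ]
            else:
                candidates = pool
            return _pick(rng, candidates) if candidates else v1

        assignments: dict[str, list[PlantedVariant]] = {}
        order = [int(i) for i in rng.permutation(len(genotyped))]
        anchor_sids = [genotyped[i] for i in order[: len(pool)]]
        anchored = dict(zip((id(v) for v in pool), anchor_sids))
        for pv, sid in zip(pool, anchor_sids):
            assignments[sid] = [pv]
        for i in order[len(pool) :]:
            sid = genotyped[i]
            source = published_pool or pool
            assignments[sid] = [_pick(rng, source)]

        for sid in genotyped:
            v1 = assignments[sid][0]
            force_pm3 = (
                anchored.get(id(v1)) == sid and "PM3" in v1.evidence_codes
            )
            if force_pm3:
                assignments[sid].append(_pick(rng, pub_plp))
            elif rng.random() < cfg.two_variant_rate:
                if rng.random() < cfg.homozygous_rate:
                    assignments[sid].append(v1)
                else:
                    assignments[sid].append(draw_partner(v1))

        # --- render rows ---------------------------------------------------
        for sid in sids:
            variants = assignments.get(sid, [])
            strings: list[str] = []
            keys: list[str] = []
            if len(variants) == 2 and variants[0] is variants[1]:
                text = _render(variants[0], rng, cfg.dialect_mix)
                strings = [text, text]
                keys = [variants[0].key, variants[0].key]
            else:
                for pv in variants:
                    strings.append(_render(pv, rng, cfg.dialect_mix))
                    keys.append(pv.key)
            for pv in variants:
                if sid not in pv.supporting_subjects:
                    pv.supporting_subjects.append(sid)
                pv.allele_count += 1
            if len(strings) == 1 and rng.random() < cfg.invalid_token_rate:
                strings.append(_pick(rng, ["none", "negative"]))
                keys.append("<invalid>")
            if not strings and rng.random() < cfg.invalid_token_rate:
                strings.append(_pick(rng, ["none", "negative"]))
                keys.append("<invalid>")
            subject_alleles[sid] = keys
            row = {
                "subject_id": sid,
                "disease": gene.disease,
                "category": gene.category,
                "gene": gene.gene,
                "transcript": gene.transcript,
                "confirmed_dx": True,
                "variant_1": strings[0] if strings else "",
                "variant_2": strings[1] if len(strings) > 1 else "",
                "fh_affected_carrier_variant": "",
                "fh_de_novo_variant": "",
                "fh_parents_confirmed": False,
                "phase_tested": False,
                "in_trans": False,
            }
            subject_rows.append(row)

        # --- family history and phase fields on anchor subjects ------------
        row_by_sid = {r["subject_id"]: r for r in subject_rows}
        for pv in unpublished_pool:
            if not pv.supporting_subjects:
                continue
            anchor = pv.supporting_subjects[0]
            if "PP1" in pv.evidence_codes:
                row_by_sid[anchor]["fh_affected_carrier_variant"] = _render(
                    pv, rng, cfg.dialect_mix
                )
            if "PM6" in pv.evidence_codes:
                row_by_sid[anchor]["fh_de_novo_variant"] = _render(
                    pv, rng, cfg.dialect_mix
                )
                row_by_sid[anchor]["fh_parents_confirmed"] = False
            if "PM3" in pv.evidence_codes:
                row_by_sid[anchor]["phase_tested"] = True
                row_by_sid[anchor]["in_trans"] = True

        all_variants.extend(pool)

    subjects = pd.DataFrame(subject_rows, columns=SUBJECT_COLUMNS)
    extract = pd.DataFrame(extract_rows, columns=EXTRACT_COLUMNS)
    predictions = pd.DataFrame(
        prediction_rows, columns=["gene", "cdna_change", "protein_change", "tool", "call"]
    )
    secondary = pd.DataFrame(
        secondary_rows, columns=["gene", "cdna_change", "protein_change", "significance"]
    )

    # Time-stamp update: plant a known overlap among the classified
    # (mapped unpublished) variants.
    gene_by_symbol = {g.gene: g for g in diseases}
    candidates = sorted(
        (v for v in all_variants if not v.published and v.mapping_valid
         and v.supporting_subjects),
        key=lambda v: v.key,
    )
    n_overlap = min(cfg.n_timestamp_overlap, len(candidates))
    overlap_idx = sorted(
        int(i) for i in rng.choice(len(candidates), size=n_overlap, replace=False)
    ) if candidates else []
    overlap_rows = []
    overlap_keys = []
    for i in overlap_idx:
        pv = candidates[i]
        sig = _weighted(
            rng,
            [
                ("Pathogenic", 0.3),
                ("Likely Pathogenic", 0.2),
                ("Uncertain Significance", 0.3),
                ("Conflicting Interpretations of Pathogenicity", 0.2),
            ],
        )
        overlap_rows.append(
            _extract_row(
                gene_by_symbol[pv.gene],
                pv.cdna_change,
                pv.submitted_protein_change,
                sig,
                int(rng.integers(1, 3)),
            )
        )
        overlap_keys.append(pv.key)
    updated = generate_updated_extract(
        extract,
        max(cfg.n_timestamp_added, n_overlap),
        overlap_rows,
        seed=int(rng.integers(2**31)),
    )

    references = ReferenceSet(
        {
            g.transcript: ReferenceSequence(
                transcript=g.transcript, protein=g.protein, gene=g.gene
            )
            for g in diseases
        }
    )
    manifest = TruthManifest(
        config=cfg.to_dict(),
        config_digest=cfg.digest(),
        diseases=[
            {
                "disease": g.disease,
                "category": g.category,
                "gene": g.gene,
                "transcript": g.transcript,
                "inheritance": "autosomal_recessive",
            }
            for g in diseases
        ],
        variants=all_variants,
        subject_alleles=subject_alleles,
        overlap_keys=overlap_keys,
    )
    return SyntheticStudy(
        config=cfg,
        subjects=subjects,
        manifest=manifest,
        extract=extract,
        updated_extract=updated,
        predictions=predictions,
        secondary=secondary,
        references=references,
    )


def generate_cohort(config: Optional[CohortConfig] = None) -> tuple[pd.DataFrame, TruthManifest]:
    """Subject table plus truth manifest (the cohort slice of a full study)."""
    study = generate_study(config)
    return study.subjects, study.manifest
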