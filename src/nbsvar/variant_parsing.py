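"""Normalisation of heterogeneous variant strings.

Clinical registries that never enforced a nomenclature standard accumulate
variant submissions in several dialects: HGVS coding-DNA notation
(``c.549A>C``, sometimes with spaces around the ``>``), HGVS three-letter
protein notation (``p.Phe256Leu``, often with a stray space after ``p.``),
bare single-letter protein shorthand (``F256L``), and free-text tokens that
carry no variant at all (``none``, ``negative``).  This module funnels all
of them into one canonical representation so that downstream comparison
against ClinVar-style gene extracts reduces to a plain key lookup.

Conventions
-----------
* Protein residue positions are 1-based, following HGVS.
* Stop codons are spelled ``*`` internally; ``Ter`` and a trailing ``X``
  are accepted on input.  ``X`` is read as a stop only in the alternate
  position of a protein change — anywhere else it makes the string
  unparseable, so that unknown-residue usage is not silently misread.
* Parsing never raises: every input string lands in exactly one
  ``MappingStatus``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AA_3TO1",
    "AA_1TO3",
    "AA_LETTERS",
    "DEFAULT_INVALID_TOKENS",
    "Consequence",
    "MappingStatus",
    "NULL_CONSEQUENCES",
    "NormalizedVariant",
    "ReferenceSequence",
    "ReferenceSet",
    "parse_variant_string",
    "validate_reference",
    "classify_consequence",
    "protein_three_letter",
]

# Three-letter <-> one-letter amino-acid tables (20 residues plus stop).
AA_3TO1: dict[str, str] = dict(protein_letters_3to1)
AA_3TO1["Ter"] = "*"
AA_1TO3: dict[str, str] = {one: three for three, one in AA_3TO1.items()}
AA_LETTERS = frozenset(AA_1TO3) - {"*"}

#: Free-text tokens treated as "no variant reported".  Case-insensitive.
DEFAULT_INVALID_TOKENS = frozenset({"", "none", "negative"})


class Consequence(str, Enum):
    """Molecular consequence classes, assigned from notation alone."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    SYNONYMOUS = "synonymous"
    START_LOSS = "start_loss"
    OTHER = "other"
    UNKNOWN = "unknown"


#: Consequences counted as predicted loss-of-function ("null") for PVS1.
NULL_CONSEQUENCES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.CANONICAL_SPLICE,
        Consequence.START_LOSS,
    }
)


class MappingStatus(str, Enum):
    MAPPED = "mapped"
    UNMAPPED_REFERENCE_MISMATCH = "unmapped_reference_mismatch"
    INVALID_TOKEN = "invalid_token"
    UNPARSEABLE = "unparseable"


@dataclass(frozen=True)
class NormalizedVariant:
    """A parsed, dialect-reconciled variant.

    ``cdna_change`` holds the canonical HGVS c. string (``c.549A>C``) and
    ``protein_change`` the canonical single-letter form: reference residue,
    1-based position, then an alternate residue, ``*`` for a stop, or
    ``fs`` for a frameshift (``F256L``, ``W123*``, ``K123fs``).
    """

    gene: Optional[str] = None
    transcript: Optional[str] = None
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    consequence: Consequence = Consequence.UNKNOWN
    mapping_status: MappingStatus = MappingStatus.MAPPED
    note: str = ""

    @property
    def key(self) -> Optional[str]:
        """Matching key: c.-anchored when present, else protein-level.

        ``None`` for invalid tokens and unparseable strings.
        """
        if self.mapping_status is MappingStatus.INVALID_TOKEN:
            return None
        if self.mapping_status is MappingStatus.UNPARSEABLE:
            return None
        gene = (self.gene or "").upper()
        if self.cdna_change:
            return f"{gene}|c:{self.cdna_change}"
        if self.protein_change:
            return f"{gene}|p:{self.protein_change}"
        return None

    @property
    def is_null(self) -> bool:
        return self.consequence in NULL_CONSEQUENCES


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference protein for one transcript, single-letter alphabet."""

    transcript: str
    protein: str
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValueError("reference protein sequence is empty")
        bad = set(self.protein) - AA_LETTERS - {"*"}
        if bad:
            raise ValueError(f"non-standard residues in reference: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------

_ACCESSION_RE = re.compile(
    r"^\s*(?P<acc>[A-Z]{2}_\d+(?:\.\d+)?)\s*\(\s*(?P<gene>[A-Za-z0-9_.-]+)\s*\)\s*:\s*(?P<rest>.+)$"
)
_CDNA_SUB_RE = re.compile(
    r"c\.\s*(?P<pos>\d+)\s*(?P<off>[+-]\s*\d+)?\s*(?P<ref>[ACGT])\s*>\s*(?P<alt>[ACGT])",
    re.IGNORECASE,
)
_CDNA_INDEL_RE = re.compile(
    r"c\.\s*(?P<start>\d+)(?:\s*_\s*(?P<end>\d+))?\s*(?P<op>delins|del|dup|ins)\s*(?P<seq>[ACGTacgt]*)",
    re.IGNORECASE,
)
_PROT_SEGMENT_RE = re.compile(r"p\.\s*(?P<body>\(?[A-Za-z0-9*=]+\)?)")
_PROT3_BODY_RE = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<rest>.*)$"
)
_PROT1_BODY_RE = re.compile(
    r"^(?P<ref>[A-Z])\s*(?P<pos>\d+)\s*(?P<rest>[A-Za-z*=]*)$"
)
_CANON_PROT_RE = re.compile(r"^(?P<ref>[A-Z])(?P<pos>\d+)(?P<alt>[A-Z*]|fs)$")
_CANON_CDNA_SUB_RE = re.compile(
    r"^c\.(?P<pos>\d+)(?P<off>[+-]\d+)?(?P<ref>[ACGT])>(?P<alt>[ACGT])$"
)
_CANON_CDNA_INDEL_RE = re.compile(
    r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?(?P<op>delins|del|dup|ins)(?P<seq>[ACGT]*)$"
)


def _canonical_cdna(text: str) -> Optional[str]:
    """Extract and canonicalise a c. segment, or return ``None``."""
    m = _CDNA_SUB_RE.search(text)
    if m:
        off = (m.group("off") or "").replace(" ", "")
        off_str = f"{int(off):+d}" if off else ""
        return (
            f"c.{int(m.group('pos'))}{off_str}"
            f"{m.group('ref').upper()}>{m.group('alt').upper()}"
        )
    m = _CDNA_INDEL_RE.search(text)
    if m:
        start = int(m.group("start"))
        end = m.group("end")
        span = f"{start}_{int(end)}" if end else f"{start}"
        return f"c.{span}{m.group('op').lower()}{m.group('seq').upper()}"
    return None


def _alt_from_three_letter_rest(rest: str) -> Optional[str]:
    """Decode the alternate part of a three-letter protein change."""
    rest = rest.strip()
    if "fs" in rest:
        return "fs"
    if rest in {"*", "Ter", "X"}:
        return "*"
    if rest == "=":
        return "="
    if rest in AA_3TO1:
        return AA_3TO1[rest]
    return None


def _canonical_protein(body: str) -> Optional[str]:
    """Canonicalise a protein-change body (``Phe256Leu``, ``F256L`` ...)."""
    body = body.strip().strip("()").replace(" ", "")
    if not body:
        return None
    m = _PROT3_BODY_RE.match(body)
    if m and m.group("ref") in AA_3TO1 and m.group("ref") != "Ter":
        alt = _alt_from_three_letter_rest(m.group("rest"))
        if alt is not None:
            ref = AA_3TO1[m.group("ref")]
            if alt == "=":
                alt = ref
            return f"{ref}{int(m.group('pos'))}{alt}"
    m = _PROT1_BODY_RE.match(body)
    if m:
        ref, rest = m.group("ref"), m.group("rest").strip()
        if ref not in AA_LETTERS:
            return None  # 'X' or other letters are not reference residues
        if rest.startswith("fs"):
            alt = "fs"
        elif rest in {"*", "X"}:
            alt = "*"  # trailing X read as a stop only here
        elif rest == "=":
            alt = ref
        elif rest in AA_LETTERS:
            alt = rest
        else:
            return None
        return f"{ref}{int(m.group('pos'))}{alt}"
    return None


def parse_variant_string(
    raw: object,
    gene: Optional[str] = None,
    *,
    invalid_tokens: Iterable[str] = DEFAULT_INVALID_TOKENS,
) -> NormalizedVariant:
    """Parse one raw variant string into a :class:`NormalizedVariant`.

    The dialect is auto-detected.  Whitespace inside HGVS segments
    (``c.549A > C``, ``p. Phe256Leu``) is tolerated, three-letter residues
    are converted to single-letter, and stop spellings (``Ter``, ``X``,
    ``*``) are unified.  Tokens in ``invalid_tokens`` (case-insensitive)
    yield ``mapping_status=invalid_token``; any other undecodable text
    yields ``unparseable``.  This function never raises on input content.
    """
    text = "" if raw is None or raw != raw else str(raw).strip()
    tokens = {t.lower() for t in invalid_tokens}
    if text.lower() in tokens:
        return NormalizedVariant(
            gene=gene, mapping_status=MappingStatus.INVALID_TOKEN, note=text
        )

    transcript = None
    m = _ACCESSION_RE.match(text)
    if m:
        transcript = m.group("acc")
        gene = m.group("gene")
        text = m.group("rest")

    cdna = _canonical_cdna(text)
    protein = None
    pm = _PROT_SEGMENT_RE.search(text)
    if pm:
        protein = _canonical_protein(pm.group("body"))
    elif cdna is None:
        # No explicit "p." marker: try the whole string as a bare protein
        # change ("F256L", "Phe256Leu", "W123X").
        protein = _canonical_protein(text)

    if cdna is None and protein is None:
        return NormalizedVariant(
            gene=gene,
            transcript=transcript,
            mapping_status=MappingStatus.UNPARSEABLE,
            note=text,
        )

    v = NormalizedVariant(
        gene=gene,
        transcript=transcript,
        cdna_change=cdna,
        protein_change=protein,
        mapping_status=MappingStatus.MAPPED,
    )
    return replace(v, consequence=classify_consequence(v))


def classify_consequence(v: NormalizedVariant) -> Consequence:
    """Assign a molecular consequence from notation alone.

    Protein notation takes precedence: a stop alternate is nonsense, an
    ``fs`` suffix a frameshift, identical residues synonymous, and a change
    at Met1 a start loss.  For c.-only strings, a +-1/+-2 intronic offset is
    a canonical splice change and an indel whose net length change is not a
    multiple of three is a frameshift; an in-frame indel is ``other`` and a
    bare coding substitution without protein information stays ``unknown``.
    """
    if v.protein_change:
        m = _CANON_PROT_RE.match(v.protein_change)
        if m:
            ref, pos, alt = m.group("ref"), int(m.group("pos")), m.group("alt")
            if alt == "fs":
                return Consequence.FRAMESHIFT
            if alt == "*":
                return Consequence.NONSENSE
            if ref == alt:
                return Consequence.SYNONYMOUS
            if pos == 1 and ref == "M":
                return Consequence.START_LOSS
            return Consequence.MISSENSE
        return Consequence.UNKNOWN
    if v.cdna_change:
        m = _CANON_CDNA_SUB_RE.match(v.cdna_change)
        if m:
            off = m.group("off")
            if off and abs(int(off)) in (1, 2):
                return Consequence.CANONICAL_SPLICE
            return Consequence.UNKNOWN
        m = _CANON_CDNA_INDEL_RE.match(v.cdna_change)
        if m:
            start, end = int(m.group("start")), m.group("end")
            span = (int(end) - start + 1) if end else 1
            seq_len = len(m.group("seq"))
            op = m.group("op")
            if op == "del":
                net = span if not m.group("seq") else seq_len
            elif op == "dup":
                net = span if not m.group("seq") else seq_len
            elif op == "ins":
                net = seq_len
            else:  # delins
                net = seq_len - span
            return Consequence.FRAMESHIFT if net % 3 else Consequence.OTHER
    return Consequence.UNKNOWN


def validate_reference(
    v: NormalizedVariant, ref: ReferenceSequence
) -> NormalizedVariant:
    """Check the stated reference residue against the reference protein.

    Returns a copy of ``v`` whose ``mapping_status`` is ``mapped`` when the
    residue at the stated 1-based position equals the stated reference
    letter, and ``unmapped_reference_mismatch`` otherwise (including
    positions beyond the end of the sequence).  Unmapped variants are
    excluded from all criteria assignment downstream.
    """
    if not v.protein_change:
        raise ValueError("validate_reference requires a protein_change")
    m = _CANON_PROT_RE.match(v.protein_change)
    if m is None:
        raise ValueError(f"malformed canonical protein change: {v.protein_change!r}")
    pos = int(m.group("pos"))
    stated = m.group("ref")
    if pos > len(ref.protein):
        return replace(
            v,
            mapping_status=MappingStatus.UNMAPPED_REFERENCE_MISMATCH,
            note=f"position {pos} beyond reference length {len(ref.protein)}",
        )
    actual = ref.protein[pos - 1]
    if actual != stated:
        return replace(
            v,
            mapping_status=MappingStatus.UNMAPPED_REFERENCE_MISMATCH,
            note=f"reference has {actual} at residue {pos}, submitted {stated}",
        )
    return replace(v, mapping_status=MappingStatus.MAPPED, note="")


def protein_three_letter(protein_change: str) -> str:
    """Render a canonical single-letter protein change in three-letter form.

    ``F256L`` -> ``Phe256Leu``; ``W123*`` -> ``Trp123Ter``;
    ``K123fs`` -> ``Lys123fs``.
    """
    m = _CANON_PROT_RE.match(protein_change)
    if m is None:
        raise ValueError(f"malformed protein change: {protein_change!r}")
    ref = AA_1TO3[m.group("ref")]
    alt = m.group("alt")
    alt3 = "fs" if alt == "fs" else AA_1TO3[alt]
    return f"{ref}{m.group('pos')}{alt3}"


@dataclass
class ReferenceSet:
    """Reference proteins keyed by transcript accession and by gene symbol."""

    by_transcript: dict[str, ReferenceSequence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_gene: dict[str, ReferenceSequence] = {
            r.gene.upper(): r for r in self.by_transcript.values() if r.gene
        }

    def add(self, ref: ReferenceSequence) -> None:
        self.by_transcript[ref.transcript] = ref
        if ref.gene:
            self.by_gene[ref.gene.upper()] = ref

    def for_variant(self, v: NormalizedVariant) -> Optional[ReferenceSequence]:
        if v.transcript:
            # Ignore accession version differences on lookup.
            base = v.transcript.split(".")[0]
            for acc, ref in self.by_transcript.items():
                if acc.split(".")[0] == base:
                    return ref
        if v.gene:
            return self.by_gene.get(v.gene.upper())
        return None

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        """Read reference proteins from FASTA.

        Records are keyed by accession (the FASTA id); a ``gene=SYMBOL``
        token in the description attaches the gene symbol.
        """
        refs: dict[str, ReferenceSequence] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            gene = None
            for tok in rec.description.split():
                if tok.startswith("gene="):
                    gene = tok.split("=", 1)[1]
            refs[rec.id] = ReferenceSequence(
                transcript=rec.id, protein=str(rec.seq), gene=gene
            )
        return cls(refs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(ref.protein),
                id=acc,
                description=f"gene={ref.gene}" if ref.gene else "",
            )
            for acc, ref in sorted(self.by_transcript.items())
        ]
        SeqIO.write(records, str(path), "fasta")
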