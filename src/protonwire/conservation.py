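"""Motif scanning and conservation statistics over large-subunit alignments.

Works on multiple sequence alignments in FASTA or Clustal format.
Columns can be mapped onto structure residues so that conservation
categories annotate the residues of a detected pathway.  Pairwise
percentages use the Clustal convention: columns are *identical*,
*strongly similar* or *weakly similar* according to the standard
residue groups; everything else (including gapped columns) counts as
unconserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Optional, Sequence, Union

from Bio import AlignIO, Align
from Bio.Align import substitution_matrices

from .pathway import Pathway
from .structure import Residue, Structure

__all__ = [
    "AlignmentSet",
    "MotifPattern",
    "MotifHit",
    "ConservationProfile",
    "scan_motif",
    "pairwise_stats",
    "column_to_residue_map",
    "annotate_pathway",
    "STRONG_GROUPS",
    "WEAK_GROUPS",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X", "-"}

#: Clustal strong-similarity groups
STRONG_GROUPS = [
    "STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW",
]
#: Clustal weak-similarity groups
WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
    "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # protonation-variant codes map back to their parent type
    "HID": "H", "HIE": "H", "HIP": "H", "ASH": "D", "GLH": "E",
    "LYN": "K", "ARN": "R", "CYM": "C",
}


class InvalidSequenceError(ValueError):
    """Raised for residue letters outside the amino-acid alphabet."""


@dataclass
class AlignmentSet:
    """An in-memory multiple sequence alignment (rows of equal length)."""

    ids: list[str]
    sequences: list[str]
    reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in count")
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("alignment rows differ in length")
        for sid, seq in zip(self.ids, self.sequences):
            bad = sorted({c for c in seq.upper() if c not in ALPHABET})
            if bad:
                raise InvalidSequenceError(f"row {sid}: invalid letters {bad}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    def row(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment")

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    @classmethod
    def from_file(cls, path: Union[str, Path], fmt: Optional[str] = None,
                  reference_id: Optional[str] = None) -> "AlignmentSet":
        """Read a FASTA or Clustal (.aln) alignment."""
        path = Path(path)
        if fmt is None:
            fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls(
            ids=[rec.id for rec in aln],
            sequences=[str(rec.seq) for rec in aln],
            reference_id=reference_id,
        )

    def to_fasta(self) -> str:
        chunks = []
        for sid, seq in zip(self.ids, self.sequences):
            chunks.append(f">{sid}\n{seq}")
        return "\n".join(chunks) + "\n"


@dataclass(frozen=True)
class MotifPattern:
    """A PROSITE-like motif, e.g. ``H-x-H-x(2)-H-x(2)-H-x-H`` or ``Hx6L``.

    Compact strings without dashes are also accepted: each letter is a
    literal and ``x`` a wildcard (``HxHxxHxxHxH``).
    """

    pattern: str

    def elements(self) -> list[str]:
        """Expand to per-position character classes."""
        text = self.pattern.strip()
        out: list[str] = []
        if "-" in text:
            for token in text.split("-"):
                token = token.strip()
                m = re.fullmatch(r"([A-Za-z]|x|\[[A-Z]+\]|\{[A-Z]+\})(?:\((\d+)\))?", token)
                if m is None:
                    raise ValueError(f"unparseable motif token {token!r}")
                element, repeat = m.group(1), int(m.group(2) or 1)
                out.extend([element] * repeat)
        else:
            i = 0
            while i < len(text):
                c = text[i]
                # compact Hx6L style: a digit repeats the previous element
                j = i + 1
                digits = ""
                while j < len(text) and text[j].isdigit():
                    digits += text[j]
                    j += 1
                repeat = int(digits) if digits else 1
                out.extend([c] * repeat)
                i = j
        if all(e == "x" for e in out):
            raise ValueError("motif needs at least one literal position")
        return out

    def to_regex(self) -> str:
        parts = []
        for e in self.elements():
            if e == "x":
                parts.append("[A-Z]")
            elif e.startswith("["):
                parts.append(e)
            elif e.startswith("{"):
                parts.append("[^" + e[1:-1] + "]")
            else:
                parts.append(e.upper())
        return "".join(parts)

    def __len__(self) -> int:
        return len(self.elements())


@dataclass(frozen=True)
class MotifHit:
    """One motif match in ungapped 1-based coordinates."""

    sequence_id: str
    start: int
    matched: str


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("-", "")
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in AMINO_ACIDS | {"X"}]
    if bad:
        raise InvalidSequenceError(f"invalid residue letters at positions {bad[:10]}")
    return seq


def scan_motif(
    sequence: str,
    pattern: Union[str, MotifPattern],
    sequence_id: str = "",
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches in an ungapped sequence."""
    if not isinstance(pattern, MotifPattern):
        pattern = MotifPattern(pattern)
    seq = _validate_sequence(sequence)
    regex = re.compile("(?=(" + pattern.to_regex() + "))")
    return [
        MotifHit(sequence_id=sequence_id, start=m.start() + 1, matched=m.group(1))
        for m in regex.finditer(seq)
    ]


# ---------------------------------------------------------------------------
# pairwise statistics


def _column_category(a: str, b: str) -> str:
    if a == "-" or b == "-":
        return "none"
    if a == b:
        return "identical"
    pair = {a, b}
    for group in STRONG_GROUPS:
        if pair <= set(group):
            return "strong"
    for group in WEAK_GROUPS:
        if pair <= set(group):
            return "weak"
    return "none"


def _make_aligner() -> Align.PairwiseAligner:
    """Gonnet scores, affine gaps, free end gaps (Clustal-like)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("GONNET1992")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.2
    if hasattr(aligner, "open_end_gap_score"):
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    else:  # pragma: no cover - older biopython
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def _global_align(a: str, b: str) -> tuple[str, str]:
    alignment = _make_aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def pairwise_stats(
    a: str,
    b: str,
    mode: str = "global-align",
    alignment: Optional[tuple[str, str]] = None,
    denominator: str = "alignment",
) -> dict[str, float]:
    """Percent identical / strongly similar / weakly similar columns.

    ``mode="global-align"`` aligns the two sequences with Gonnet scores
    and affine gaps (end gaps free); ``mode="precomputed-alignment"``
    takes a 2-row alignment so exact external aligner output can be
    scored.  ``denominator`` is either ``"alignment"`` (all columns) or
    ``"shorter"`` (length of the shorter ungapped sequence).
    """
    if mode == "precomputed-alignment":
        if alignment is None:
            raise ValueError("precomputed-alignment mode requires alignment=")
        row_a, row_b = alignment[0].upper(), alignment[1].upper()
        if len(row_a) != len(row_b):
            raise ValueError("alignment rows differ in length")
    elif mode == "global-align":
        seq_a, seq_b = _validate_sequence(a), _validate_sequence(b)
        if not seq_a or not seq_b:
            raise ValueError("empty sequence")
        row_a, row_b = _global_align(seq_a, seq_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts = {"identical": 0, "strong": 0, "weak": 0, "none": 0}
    n_columns = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" and cb == "-":
            continue
        n_columns += 1
        counts[_column_category(ca, cb)] += 1
    if denominator == "alignment":
        denom = n_columns
    elif denominator == "shorter":
        denom = min(len(row_a.replace("-", "")), len(row_b.replace("-", "")))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("empty alignment")
    return {
        "identical_pct": 100.0 * counts["identical"] / denom,
        "strong_pct": 100.0 * counts["strong"] / denom,
        "weak_pct": 100.0 * counts["weak"] / denom,
        "none_pct": 100.0 * counts["none"] / denom,
        "n_columns": float(n_columns),
    }


# ---------------------------------------------------------------------------
# conservation profile


@dataclass
class ConservationProfile:
    """Per-column conservation over a multiple alignment."""

    identity: list[float]
    consensus: list[str]
    category: list[str]  # '*' identical, ':' strong, '.' weak, ' ' none

    @classmethod
    def from_alignment(cls, alignment: AlignmentSet) -> "ConservationProfile":
        identity, consensus, category = [], [], []
        for col in range(alignment.length):
            letters = [seq[col] for seq in alignment.sequences]
            residues = [c for c in letters if c != "-"]
            if not residues:
                identity.append(0.0)
                consensus.append("-")
                category.append(" ")
                continue
            best = max(sorted(set(residues)), key=residues.count)
            identity.append(residues.count(best) / len(letters))
            consensus.append(best)
            unique = set(residues)
            if len(unique) == 1 and len(residues) == len(letters):
                category.append("*")
            elif len(residues) == len(letters) and any(
                unique <= set(g) for g in STRONG_GROUPS
            ):
                category.append(":")
            elif len(residues) == len(letters) and any(
                unique <= set(g) for g in WEAK_GROUPS
            ):
                category.append(".")
            else:
                category.append(" ")
        return cls(identity=identity, consensus=consensus, category=category)

    def to_tsv(self) -> str:
        lines = ["column\tconsensus\tidentity\tcategory"]
        for i, (c, f, cat) in enumerate(zip(self.consensus, self.identity, self.category), 1):
            lines.append(f"{i}\t{c}\t{f:.3f}\t{cat}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# mapping columns onto structure residues


def _chain_sequence(structure: Structure, chain_id: str) -> tuple[str, list[Residue]]:
    residues = [
        r for r in structure.chains.get(chain_id, [])
        if r.name in THREE_TO_ONE
    ]
    return "".join(THREE_TO_ONE[r.name] for r in residues), residues


def column_to_residue_map(
    alignment: AlignmentSet,
    reference_id: str,
    structure: Structure,
    chain_id: str,
    min_identity: float = 0.95,
) -> dict[int, Residue]:
    """Map alignment columns (0-based) to structure residues.

    The reference row's ungapped sequence must match the chain sequence
    at >= ``min_identity`` over the aligned span; positions that still
    mismatch are kept but flagged via the ``mismatches`` attribute on
    the returned dict.
    """
    ref_row = alignment.row(reference_id)
    ref_seq = ref_row.replace("-", "")
    chain_seq, chain_residues = _chain_sequence(structure, chain_id)
    if not chain_seq:
        raise ValueError(f"chain {chain_id!r} has no standard residues")

    if len(ref_seq) == len(chain_seq):
        pairs = list(zip(range(len(ref_seq)), range(len(chain_seq))))
    else:
        result = _make_aligner().align(ref_seq, chain_seq)[0]
        pairs = [
            (i, j)
            for block_a, block_b in zip(result.aligned[0], result.aligned[1])
            for i, j in zip(range(block_a[0], block_a[1]), range(block_b[0], block_b[1]))
        ]
    matches = sum(1 for i, j in pairs if ref_seq[i] == chain_seq[j])
    identity = matches / max(1, len(pairs))
    if identity < min_identity:
        raise ValueError(
            f"reference row matches chain {chain_id!r} at only {identity:.1%}; "
            f"is this the right chain?"
        )

    seq_to_residue = {i: chain_residues[j] for i, j in pairs}
    mismatches = {i for i, j in pairs if ref_seq[i] != chain_seq[j]}

    mapping: dict[int, Residue] = {}
    flagged: set[int] = set()
    seq_pos = 0
    for col, letter in enumerate(ref_row):
        if letter == "-":
            continue
        if seq_pos in seq_to_residue:
            mapping[col] = seq_to_residue[seq_pos]
            if seq_pos in mismatches:
                flagged.add(col)
        seq_pos += 1
    mapping_with_flags = _MappingWithFlags(mapping)
    mapping_with_flags.mismatches = flagged
    return mapping_with_flags


class _MappingWithFlags(dict):
    """dict[column -> Residue] carrying the set of mismatching columns."""

    mismatches: set[int] = frozenset()


def annotate_pathway(
    pathway: Pathway,
    profile: ConservationProfile,
    mapping: dict[int, Residue],
) -> Pathway:
    """Attach per-residue conservation to a pathway (in place and returned).

    Waters are annotated ``structural water``; residues absent from the
    mapping are annotated ``unaligned``.
    """
    residue_to_col = {res.key: col for col, res in mapping.items()}
    annotations = {}
    for node in pathway.nodes:
        if node.startswith("W:"):
            annotations[node] = {"note": "structural water"}
            continue
        if node.startswith("M:") or node.startswith("X:"):
            annotations[node] = {"note": "metal/hetero site"}
            continue
        chain, resdesc, _part = node.split(":")
        m = re.match(r"([A-Z]{2,3})(-?\d+)(\D?)$", resdesc)
        key = (chain, int(m.group(2)), m.group(3)) if m else None
        col = residue_to_col.get(key)
        if col is None:
            annotations[node] = {"note": "unaligned"}
        else:
            annotations[node] = {
                "column": col,
                "identity": profile.identity[col],
                "category": profile.category[col],
            }
    pathway.annotations = annotations
    return pathway
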