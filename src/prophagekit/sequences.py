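"""Nucleotide/protein sequence primitives, FASTA I/O and pairwise global alignment.

Alignment follows the EMBOSS Needle conventions: BLOSUM62 scoring, affine
gaps (open 10, extend 0.5) and unpenalized terminal gaps, with percent
identity computed over all alignment columns, gaps included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "ProteinSequence",
    "PairwiseAlignment",
    "AlphabetError",
    "ScoringError",
    "reverse_complement",
    "translate",
    "global_align",
    "percent_identity",
    "collapse_to_reference",
    "CollapsedAlignment",
    "read_dna_fasta",
    "read_protein_fasta",
    "write_fasta",
    "needle_report",
]

_DNA_ALPHABET = frozenset("ACGTN")
_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


class AlphabetError(ValueError):
    """A residue outside the permitted alphabet."""


class ScoringError(ValueError):
    """A residue has no entry in the substitution matrix."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A DNA sequence; residues are uppercased and 'U' is mapped to 'T' on ingest."""

    identifier: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        normalized = self.residues.upper().replace("U", "T")
        object.__setattr__(self, "residues", normalized)
        bad = set(normalized) - _DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.identifier!r}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence (20 standard residues, X, and '*' for stops)."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        normalized = self.residues.upper()
        object.__setattr__(self, "residues", normalized)
        bad = set(normalized) - _PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"{self.identifier!r}: invalid protein characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of two sequences.

    ``aligned_a``/``aligned_b`` have equal length, removing gaps recovers the
    inputs and no column is gap-vs-gap.
    """

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap-vs-gap column in alignment")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement; an involution."""
    return NucleotideSequence(
        identifier=seq.identifier,
        residues=str(Seq(seq.residues).reverse_complement()),
        circular=seq.circular,
    )


def translate(seq: NucleotideSequence, frame_offset: int = 0) -> ProteinSequence:
    """Translate with the standard genetic code from ``frame_offset`` (0, 1 or 2).

    The trailing partial codon is dropped; stop codons are rendered ``*``.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    coding = seq.residues[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    return ProteinSequence(
        identifier=seq.identifier,
        residues=str(Seq(coding).translate()),
    )


def _build_aligner(
    matrix_name: str,
    gap_open: float,
    gap_extend: float,
    end_gaps_penalized: bool,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython semantics: first gap residue scores open_gap_score, each
    # further residue extend_gap_score, i.e. a length-L gap costs
    # open + (L-1)*extend — the Needle convention for open 10 / extend 0.5.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if not end_gaps_penalized:
        aligner.end_gap_score = 0.0
    return aligner


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_penalized: bool = False,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two proteins.

    Defaults reproduce the EMBOSS Needle webserver defaults (EBLOSUM62,
    gap open 10, gap extend 0.5, terminal gaps free). Among co-optimal
    alignments the aligner's first traceback is returned.
    """
    if not a.residues or not b.residues:
        raise ValueError("global_align requires non-empty sequences")
    aligner = _build_aligner(matrix, gap_open, gap_extend, end_gaps_penalized)
    covered = set(aligner.substitution_matrix.alphabet)
    missing = (set(a.residues) | set(b.residues)) - covered
    if missing:
        raise ScoringError(
            f"residues {sorted(missing)} absent from matrix {matrix}"
        )
    best = aligner.align(a.residues, b.residues)[0]
    return PairwiseAlignment(
        aligned_a=str(best[0]), aligned_b=str(best[1]), score=float(best.score)
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """Percent identical columns over *all* alignment columns (gaps included).

    This is the EMBOSS Needle "Identity" line convention, reported to one
    decimal place.
    """
    if aln.columns == 0:
        raise ValueError("percent identity undefined for a zero-length alignment")
    identical = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
    )
    return round(100.0 * identical / aln.columns, 1)


@dataclass(frozen=True)
class CollapsedAlignment:
    """A reference-collapsed MSA plus the removed column ranges (1-based)."""

    rows: tuple[tuple[str, str], ...]
    removed_ranges: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def collapse_to_reference(
    msa: Sequence[tuple[str, str]], reference_id: str
) -> CollapsedAlignment:
    """Drop every MSA column in which the reference row holds a gap.

    Row order is preserved; the removed column ranges are reported (1-based,
    inclusive) for annotation of the collapsed alignment.
    """
    lengths = {len(row) for _, row in msa}
    if len(lengths) > 1:
        raise ValueError("MSA rows differ in length")
    ref_rows = [row for rid, row in msa if rid == reference_id]
    if not ref_rows:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    reference = ref_rows[0]
    keep = [i for i, c in enumerate(reference) if c != "-"]
    dropped = [i for i, c in enumerate(reference) if c == "-"]
    ranges: list[tuple[int, int]] = []
    for i in dropped:
        if ranges and i == ranges[-1][1]:
            ranges[-1] = (ranges[-1][0], i + 1)
        else:
            ranges.append((i + 1, i + 1))
    rows = tuple(
        (rid, "".join(row[i] for i in keep)) for rid, row in msa
    )
    return CollapsedAlignment(rows=rows, removed_ranges=tuple(ranges))


def read_dna_fasta(path: str | Path, circular: bool = False) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(rec.id, str(rec.seq), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_protein_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        ProteinSequence(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(
    sequences: Iterable[NucleotideSequence | ProteinSequence], path: str | Path
) -> None:
    """Write FASTA with 60-column wrapping and '>' headers."""
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="")
        for s in sequences
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def needle_report(aln: PairwiseAlignment, id_a: str, id_b: str) -> str:
    """A compact Needle-like pair report with an identity line."""
    identical = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
    )
    gaps = aln.aligned_a.count("-") + aln.aligned_b.count("-")
    lines = [
        f"# 1: {id_a}",
        f"# 2: {id_b}",
        f"# Length: {aln.columns}",
        f"# Identity: {identical}/{aln.columns} ({percent_identity(aln):.1f}%)",
        f"# Gaps: {gaps}/{aln.columns}",
        f"# Score: {aln.score:.1f}",
        "",
    ]
    width = 60
    for i in range(0, aln.columns, width):
        seg_a = aln.aligned_a[i : i + width]
        seg_b = aln.aligned_b[i : i + width]
        marks = "".join(
            "|" if x == y and x != "-" else " " for x, y in zip(seg_a, seg_b)
        )
        lines += [seg_a, marks, seg_b, ""]
    return "\n".join(lines)
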