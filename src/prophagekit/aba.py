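"""Sequence-level analysis of anti-BstA (aba) self-immunity elements.

An aba element is a short DNA locus overlapping a bstA start codon: an
upstream stretch followed by the first bases of the coding sequence, flanked
at its terminal ends by a short direct repeat (the hexamer CCCGCC in the
BTP1 element). The module partitions elements at the start codon, finds
maximal direct repeats and the terminal repeat pair, applies point
substitutions (the repeat-disrupting mutants), and scans for short ORFs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .sequences import NucleotideSequence

__all__ = [
    "ABA_BTP1",
    "AbaElement",
    "DirectRepeat",
    "Orf",
    "PartitionError",
    "partition_element",
    "find_direct_repeats",
    "find_terminal_repeat",
    "apply_substitution",
    "substitute_repeat_base",
    "scan_orfs",
    "aba_report_rows",
    "write_aba_report",
    "element_diagram",
]

#: The 63-bp anti-BstA element of the Salmonella prophage BTP1: 29 bp of
#: upstream sequence plus the first 34 bp of the bstA coding sequence, with
#: a direct CCCGCC repeat at the terminal ends.
ABA_BTP1 = "GCCCGCCACACTTTAACAAGGAAAATCAAATGGTTAATCAGATAAGGTCCATATCACCCCGCC"

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PartitionError(ValueError):
    """No usable start codon for partitioning an element."""


@dataclass(frozen=True)
class AbaElement:
    """A self-immunity locus partitioned at its start codon."""

    sequence: NucleotideSequence
    start_codon_offset: int  # 0-based position of the A of ATG
    upstream_length: int
    coding_length: int


@dataclass(frozen=True)
class DirectRepeat:
    """A maximal repeated motif with all its forward-strand occurrences.

    ``occurrences`` are 1-based start positions; ``terminal`` is set only by
    :func:`find_terminal_repeat`.
    """

    motif: str
    occurrences: tuple[int, ...]
    terminal: bool = False

    @property
    def length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated reading frame.

    ``start``/``end`` are 1-based inclusive on the forward axis of the input
    (for minus-strand ORFs the span still uses forward coordinates);
    ``frame`` is 0-2 relative to the reading strand's 5' end. Complete ORFs
    end at an in-frame stop (included in the span); incomplete ones run off
    the sequence end.
    """

    strand: str
    frame: int
    start: int
    end: int
    complete: bool

    @property
    def n_codons(self) -> int:
        """Codons from ATG up to, not including, any stop codon."""
        span = self.end - self.start + 1
        return (span - 3) // 3 if self.complete else span // 3


def partition_element(
    seq: NucleotideSequence, start: int | str = "auto"
) -> AbaElement:
    """Partition an element into upstream and coding portions at an ATG.

    ``start="auto"`` uses the first forward-strand ATG; an explicit 0-based
    offset must point at an ATG. The upstream length equals the offset and
    the coding portion runs from the ATG through the final base.
    """
    s = seq.residues
    if start == "auto":
        offset = s.find("ATG")
        if offset < 0:
            raise PartitionError(f"{seq.identifier!r}: no ATG start codon found")
    else:
        offset = int(start)
        if s[offset : offset + 3] != "ATG":
            raise PartitionError(
                f"{seq.identifier!r}: offset {offset} does not read ATG"
            )
    return AbaElement(
        sequence=seq,
        start_codon_offset=offset,
        upstream_length=offset,
        coding_length=len(s) - offset,
    )


def find_direct_repeats(seq: NucleotideSequence, k_min: int = 6) -> list[DirectRepeat]:
    """All maximal direct repeats of length >= ``k_min`` on the forward strand.

    A repeat is a substring occurring at least twice (overlaps permitted);
    it is maximal when any single-base extension, left or right, loses at
    least one occurrence. Results are ordered by first occurrence, then by
    motif length descending.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    s = seq.residues
    n = len(s)
    occ: dict[str, list[int]] = defaultdict(list)
    for k in range(k_min, n):
        for i in range(n - k + 1):
            occ[s[i : i + k]].append(i)
    repeats: list[DirectRepeat] = []
    for motif, positions in occ.items():
        if len(positions) < 2:
            continue
        count = len(positions)
        k = len(motif)
        # right-maximal: every right extension drops an occurrence
        right_ext = defaultdict(int)
        right_lost = 0
        for i in positions:
            if i + k < n:
                right_ext[s[i + k]] += 1
            else:
                right_lost += 1
        if right_lost == 0 and max(right_ext.values()) == count:
            continue
        left_ext = defaultdict(int)
        left_lost = 0
        for i in positions:
            if i > 0:
                left_ext[s[i - 1]] += 1
            else:
                left_lost += 1
        if left_lost == 0 and max(left_ext.values()) == count:
            continue
        repeats.append(
            DirectRepeat(motif=motif, occurrences=tuple(p + 1 for p in positions))
        )
    repeats.sort(key=lambda r: (r.occurrences[0], -r.length, r.motif))
    return repeats


def find_terminal_repeat(
    seq: NucleotideSequence, k_min: int = 6, margin: int = 10
) -> Optional[DirectRepeat]:
    """The longest direct repeat with occurrences at both terminal ends.

    A repeat qualifies when one occurrence starts within the first
    ``margin`` bases and another ends within the last ``margin`` bases.
    Returns ``None`` when no repeat spans the ends.
    """
    if margin < k_min:
        raise ValueError("margin must be >= k_min")
    n = len(seq.residues)
    best: Optional[DirectRepeat] = None
    for rep in find_direct_repeats(seq, k_min=k_min):
        starts_early = any(p <= margin for p in rep.occurrences)
        ends_late = any(p + rep.length - 1 >= n - margin + 1 for p in rep.occurrences)
        if starts_early and ends_late:
            if best is None or rep.length > best.length:
                best = rep
    return replace(best, terminal=True) if best is not None else None


def apply_substitution(
    seq: NucleotideSequence, position: int, new_base: str
) -> NucleotideSequence:
    """Replace the base at a 1-based position; length is preserved."""
    if new_base not in "ACGT":
        raise ValueError(f"new_base must be one of A/C/G/T, got {new_base!r}")
    if not 1 <= position <= len(seq.residues):
        raise IndexError(
            f"position {position} outside sequence of length {len(seq.residues)}"
        )
    s = seq.residues
    return NucleotideSequence(
        identifier=seq.identifier,
        residues=s[: position - 1] + new_base + s[position:],
        circular=seq.circular,
    )


def substitute_repeat_base(
    seq: NucleotideSequence,
    repeat: DirectRepeat,
    occurrence: int,
    new_base: str = "T",
    motif_offset: Optional[int] = None,
) -> NucleotideSequence:
    """Point-mutate one occurrence of a repeat (CCCGCC -> CCCTCC style).

    ``occurrence`` is 1-based among the repeat's occurrences. By default the
    mutated position is the first G of the motif, located programmatically,
    so the operation generalizes beyond the BTP1 element.
    """
    if not 1 <= occurrence <= len(repeat.occurrences):
        raise IndexError(
            f"occurrence {occurrence} of {len(repeat.occurrences)}"
        )
    if motif_offset is None:
        motif_offset = repeat.motif.find("G")
        if motif_offset < 0:
            raise ValueError(f"no G in motif {repeat.motif!r}; pass motif_offset")
    position = repeat.occurrences[occurrence - 1] + motif_offset
    return apply_substitution(seq, position, new_base)


def _scan_strand(s: str, min_codons: int, strand: str, allow_runoff: bool,
                 n_forward: int) -> list[Orf]:
    out: list[Orf] = []
    n = len(s)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if s[i : i + 3] == "ATG":
                j = i + 3
                end = None
                while j + 3 <= n:
                    if s[j : j + 3] in _STOP_CODONS:
                        end = j + 3
                        break
                    j += 3
                if end is not None:
                    n_codons = (end - i - 3) // 3
                    if n_codons >= min_codons:
                        out.append(_orient(i, end, strand, frame, True, n_forward))
                elif allow_runoff:
                    run_end = i + ((n - i) // 3) * 3
                    n_codons = (run_end - i) // 3
                    if n_codons >= min_codons:
                        out.append(
                            _orient(i, run_end, strand, frame, False, n_forward)
                        )
            i += 3
    return out


def _orient(i: int, end: int, strand: str, frame: int, complete: bool,
            n_forward: int) -> Orf:
    if strand == "+":
        return Orf(strand, frame, i + 1, end, complete)
    # map reverse-strand 0-based [i, end) back to forward 1-based coordinates
    return Orf(strand, frame, n_forward - end + 1, n_forward - i, complete)


def scan_orfs(
    seq: NucleotideSequence,
    min_codons: int = 1,
    strands: str = "forward",
    allow_runoff: bool = False,
) -> list[Orf]:
    """ATG-initiated ORFs of at least ``min_codons`` codons (stop excluded).

    Complete ORFs end at an in-frame stop within the sequence; with
    ``allow_runoff`` frames reaching the sequence end without a stop are
    reported as incomplete. ``strands`` is ``"forward"`` or ``"both"``.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    n = len(seq.residues)
    orfs = _scan_strand(seq.residues, min_codons, "+", allow_runoff, n)
    if strands == "both":
        rc = seq.residues.translate(_COMPLEMENT)[::-1]
        orfs += _scan_strand(rc, min_codons, "-", allow_runoff, n)
    orfs.sort(key=lambda o: (o.start, o.strand, o.frame))
    return orfs


def aba_report_rows(
    elements: Sequence[NucleotideSequence],
    k_min: int = 6,
    margin: int = 10,
) -> tuple[list[dict], list[str]]:
    """Per-element report rows plus warnings for elements that fail to partition."""
    rows: list[dict] = []
    warnings: list[str] = []
    for seq in elements:
        try:
            element = partition_element(seq)
        except PartitionError as exc:
            warnings.append(str(exc))
            continue
        terminal = find_terminal_repeat(seq, k_min=k_min, margin=margin)
        rows.append(
            {
                "element": seq.identifier,
                "length": len(seq),
                "upstream_length": element.upstream_length,
                "coding_length": element.coding_length,
                "terminal_repeat": terminal.motif if terminal else "",
                "repeat_positions": ",".join(
                    str(p) for p in (terminal.occurrences if terminal else ())
                ),
            }
        )
    return rows, warnings


def write_aba_report(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(
        rows,
        columns=[
            "element",
            "length",
            "upstream_length",
            "coding_length",
            "terminal_repeat",
            "repeat_positions",
        ],
    ).to_csv(path, sep="\t", index=False)


def element_diagram(seq: NucleotideSequence, k_min: int = 6, margin: int = 10) -> str:
    """A human-readable annotated diagram of one element."""
    element = partition_element(seq)
    terminal = find_terminal_repeat(seq, k_min=k_min, margin=margin)
    marks = [" "] * len(seq)
    for j in range(element.start_codon_offset, element.start_codon_offset + 3):
        marks[j] = "M"
    if terminal:
        for p in terminal.occurrences:
            for j in range(p - 1, p - 1 + terminal.length):
                if marks[j] == " ":
                    marks[j] = "R"
    lines = [
        f"{seq.identifier}  ({len(seq)} bp: {element.upstream_length} bp upstream"
        f" + {element.coding_length} bp coding)",
        seq.residues,
        "".join(marks) + "   (M = start codon, R = terminal repeat)",
    ]
    if terminal:
        lines.append(
            f"terminal repeat {terminal.motif} at "
            + ", ".join(str(p) for p in terminal.occurrences)
        )
    return "\n".join(lines)
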