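"""Independent brute-force oracles used by the test suite.

Each oracle is written against the problem definition, not against the
package's implementation: alignments are enumerated and scored as complete
objects, repeats are found by scanning every substring pair, and window
membership is decided by direct interval overlap (with sequence doubling
for circular contigs).
"""

from __future__ import annotations

from typing import Optional, Sequence


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b) strings.

    No gap-vs-gap columns; both sequences fully consumed.
    """
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment(
    row_a: str,
    row_b: str,
    matrix,
    gap_open: float,
    gap_extend: float,
    end_gaps_penalized: bool = False,
) -> float:
    """Score a complete alignment: affine gap runs cost open + (L-1)*extend.

    With free end gaps, a gap run touching either end of the alignment
    costs nothing.
    """
    n = len(row_a)
    score = 0.0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            score += matrix[x, y]
    for row in (row_a, row_b):
        i = 0
        while i < n:
            if row[i] == "-":
                j = i
                while j < n and row[j] == "-":
                    j += 1
                terminal = i == 0 or j == n
                if end_gaps_penalized or not terminal:
                    score -= gap_open + (j - i - 1) * gap_extend
                i = j
            else:
                i += 1
    return score


def best_alignment_score(
    a: str, b: str, matrix, gap_open: float = 10.0, gap_extend: float = 0.5,
    end_gaps_penalized: bool = False,
) -> float:
    return max(
        score_alignment(ra, rb, matrix, gap_open, gap_extend, end_gaps_penalized)
        for ra, rb in enumerate_alignments(a, b)
    )


def count_occurrences(s: str, motif: str) -> int:
    """Overlap-counting substring occurrences."""
    count = start = 0
    while True:
        i = s.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def brute_force_maximal_repeats(s: str, k_min: int) -> dict[str, tuple[int, ...]]:
    """All maximal repeats of length >= k_min, motif -> 1-based positions.

    A substring w is maximal when it occurs at least twice and every
    one-character extension cw or wc occurs strictly fewer times than w.
    """
    n = len(s)
    alphabet = sorted(set(s))
    out: dict[str, tuple[int, ...]] = {}
    seen: set[str] = set()
    for k in range(k_min, n):
        for i in range(n - k + 1):
            w = s[i : i + k]
            if w in seen:
                continue
            seen.add(w)
            c = count_occurrences(s, w)
            if c < 2:
                continue
            extendable = any(
                count_occurrences(s, x + w) == c or count_occurrences(s, w + x) == c
                for x in alphabet
            )
            if not extendable:
                positions = []
                start = 0
                while True:
                    j = s.find(w, start)
                    if j < 0:
                        break
                    positions.append(j + 1)
                    start = j + 1
                out[w] = tuple(positions)
    return out


def window_members(
    genes: Sequence[tuple[str, int, int]],
    focal: tuple[str, int, int],
    flank: int,
    contig_length: Optional[int],
    circular: bool,
) -> set[str]:
    """Feature ids overlapping the focal window, by direct interval checks.

    Genes are (id, start, end) 1-based inclusive. Circular contigs are
    handled by doubling: every gene also exists shifted by +L, and the raw
    window is normalized into [1, 2L].
    """
    fid, fs, fe = focal
    w_start, w_end = fs - flank, fe + flank
    members: set[str] = set()
    if not circular:
        w_start = max(w_start, 1)
        if contig_length is not None:
            w_end = min(w_end, contig_length)
        for gid, gs, ge in genes:
            if gid != fid and gs <= w_end and ge >= w_start:
                members.add(gid)
        return members
    assert contig_length is not None
    L = contig_length
    shift = 0
    while w_start < 1:
        w_start += L
        w_end += L
        shift += L
    doubled = [
        (gid, gs + k, ge + k)
        for gid, gs, ge in genes
        for k in (0, L, 2 * L)
    ]
    for gid, gs, ge in doubled:
        if gid != fid and gs <= w_end and ge >= w_start:
            members.add(gid)
    return members


def brute_force_best_hits(hits, evalue_threshold: float):
    """Best-hit-per-ORF by full sort: the independent tie-break oracle."""
    surviving = [h for h in hits if h.i_evalue <= evalue_threshold]
    by_orf: dict[str, list] = {}
    for h in surviving:
        by_orf.setdefault(h.orf_id, []).append(h)
    return {
        orf: sorted(
            group,
            key=lambda h: (-h.bit_score, h.i_evalue, h.domain_accession,
                           h.domain_name, h.env_from, h.env_to),
        )[0]
        for orf, group in by_orf.items()
    }
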