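"""Domain-homology tables: HMMER3 domtblout parsing and best-hit reduction.

The survey annotates every ORF of a neighborhood with its highest-scoring
significant profile-HMM hit (Pfam plus a custom-model namespace); these
per-ORF calls feed the domain co-occurrence tallies and the domain-evidence
classifier mode.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SearchIO

__all__ = [
    "DomainHit",
    "DomtbloutParseError",
    "read_domtblout",
    "best_hit_per_orf",
    "write_best_hits_tsv",
]

# A domtblout data row has 22 fixed whitespace-delimited fields followed by
# a free-text description.
_N_FIXED_FIELDS = 22


class DomtbloutParseError(ValueError):
    """A malformed domtblout row; the message names the line number."""


@dataclass(frozen=True)
class DomainHit:
    """One domain-vs-ORF homology hit.

    ``i_evalue`` is HMMER's independent E-value for the domain;
    ``env_from``/``env_to`` are 1-based envelope coordinates on the ORF.
    """

    orf_id: str
    domain_accession: str
    domain_name: str
    bit_score: float
    i_evalue: float
    env_from: int
    env_to: int

    def __post_init__(self) -> None:
        if self.env_from > self.env_to:
            raise ValueError(
                f"{self.orf_id}/{self.domain_name}: env_from > env_to"
            )
        if not (self.i_evalue >= 0):
            raise ValueError("i_evalue must be a finite non-negative real")


def read_domtblout(source: str | Path | io.TextIOBase) -> list[DomainHit]:
    """Parse an hmmscan per-domain table into :class:`DomainHit` records.

    The target of each row is the profile model and the query the protein,
    so ``orf_id`` is the query name. Raises :class:`DomtbloutParseError`
    naming the line number of any truncated data row.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split(None, _N_FIXED_FIELDS)) < _N_FIXED_FIELDS:
            raise DomtbloutParseError(
                f"line {lineno}: expected {_N_FIXED_FIELDS} fixed fields, "
                f"got {len(line.split())}"
            )
    hits: list[DomainHit] = []
    for query in SearchIO.parse(io.StringIO(text), "hmmscan3-domtab"):
        for hit in query:
            for hsp in hit:
                hits.append(
                    DomainHit(
                        orf_id=query.id,
                        domain_accession=hit.accession,
                        domain_name=hit.id,
                        bit_score=float(hsp.bitscore),
                        i_evalue=float(hsp.evalue),
                        env_from=hsp.env_start + 1,
                        env_to=hsp.env_end,
                    )
                )
    return hits


def best_hit_per_orf(
    hits: Iterable[DomainHit],
    evalue_threshold: float = 1e-3,
    rank_by: str = "bit_score",
) -> dict[str, DomainHit]:
    """Reduce domain hits to the highest-scoring significant hit per ORF.

    Hits with ``i_evalue`` above the threshold are discarded; among the
    survivors of each ORF the maximum bit score wins (``rank_by="i_evalue"``
    ranks by smallest E-value instead). Ties break by lower E-value, then
    lexicographic domain accession. ORFs with no significant hit are absent
    from the mapping.
    """
    if not evalue_threshold > 0:
        raise ValueError("evalue_threshold must be positive")
    if rank_by not in ("bit_score", "i_evalue"):
        raise ValueError(f"unknown rank_by {rank_by!r}")

    def sort_key(h: DomainHit) -> tuple:
        # trailing name/coordinate keys keep the winner deterministic even
        # for fully tied accessions
        if rank_by == "bit_score":
            return (-h.bit_score, h.i_evalue, h.domain_accession,
                    h.domain_name, h.env_from, h.env_to)
        return (h.i_evalue, -h.bit_score, h.domain_accession,
                h.domain_name, h.env_from, h.env_to)

    best: dict[str, DomainHit] = {}
    for hit in hits:
        if hit.i_evalue > evalue_threshold:
            continue
        incumbent = best.get(hit.orf_id)
        if incumbent is None or sort_key(hit) < sort_key(incumbent):
            best[hit.orf_id] = hit
    return best


def write_best_hits_tsv(best: Mapping[str, DomainHit], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "orf_id": h.orf_id,
                "domain_accession": h.domain_accession,
                "domain_name": h.domain_name,
                "bit_score": h.bit_score,
                "i_evalue": h.i_evalue,
                "env_from": h.env_from,
                "env_to": h.env_to,
            }
            for h in sorted(best.values(), key=lambda h: h.orf_id)
        ],
        columns=[
            "orf_id",
            "domain_accession",
            "domain_name",
            "bit_score",
            "i_evalue",
            "env_from",
            "env_to",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
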