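"""Gene-neighborhood extraction around a focal homolog.

The survey's unit of evidence is the 40-kb window spanning 20 kb either side
of a focal gene. Extraction handles contig-edge truncation on linear contigs
and coordinate wrap-around on circular ones; flanking genes are assigned to
the left or right flank by midpoint relative to the focal gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .domains import DomainHit

__all__ = [
    "GeneFeature",
    "Neighborhood",
    "FocalGeneError",
    "WindowConfigurationError",
    "extract_neighborhood",
    "read_gff3",
    "read_feature_table",
    "write_gff3",
]


class FocalGeneError(KeyError):
    """Focal gene absent from, or duplicated in, the feature table."""


class WindowConfigurationError(ValueError):
    """Requested window is impossible (e.g. longer than a circular contig)."""


@dataclass
class GeneFeature:
    """One annotated gene on the forward coordinate axis of a contig.

    Coordinates are 1-based inclusive (GFF convention), ``start <= end``
    regardless of strand.
    """

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    domain_hit: Optional[DomainHit] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.feature_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Neighborhood:
    """A focal gene plus the flanking genes inside its window.

    ``left_genes``/``right_genes`` are ordered 5'→3' along the forward axis
    (wrap-adjusted on circular contigs); the focal gene is in neither list.
    """

    focal: GeneFeature
    left_genes: list[GeneFeature] = field(default_factory=list)
    right_genes: list[GeneFeature] = field(default_factory=list)
    window_start: int = 0
    window_end: int = 0
    left_truncated: bool = False
    right_truncated: bool = False
    wrapped: bool = False

    @property
    def flank_genes(self) -> list[GeneFeature]:
        return self.left_genes + self.right_genes


def _signed_offset(gene_mid: float, focal_mid: float, contig_length: Optional[int],
                   circular: bool) -> float:
    """Signed distance gene-vs-focal midpoint; wrap-aware on circular contigs."""
    d = gene_mid - focal_mid
    if circular and contig_length:
        d = d % contig_length
        if d > contig_length / 2:
            d -= contig_length
    return d


def _overlaps_circular(gene: GeneFeature, w_start: int, w_end: int,
                       contig_length: int) -> bool:
    # Compare against the raw (possibly out-of-range) window by shifting the
    # gene by -L, 0, +L: any shifted copy intersecting the window counts.
    for shift in (-contig_length, 0, contig_length):
        if gene.start + shift <= w_end and gene.end + shift >= w_start:
            return True
    return False


def extract_neighborhood(
    features: Iterable[GeneFeature],
    focal_id: str,
    flank: int = 20_000,
    contig_length: Optional[int] = None,
    circular: bool = False,
    orient_by_strand: bool = False,
) -> Neighborhood:
    """Extract the ±``flank`` bp neighborhood around ``focal_id``.

    The window is anchored to the focal gene's outer coordinates:
    ``[focal.start - flank, focal.end + flank]``. On linear contigs it is
    clipped to the contig and the truncation flags record lost flank; on
    circular contigs it wraps modulo the contig length. A flanking gene is
    included if it overlaps the window by at least one base; assignment to
    the left or right flank is by midpoint relative to the focal gene.

    With ``orient_by_strand`` the left/right flanks are swapped for focal
    genes on the minus strand, so "left" reads as the focal gene's 5' side.
    """
    features = list(features)
    focal_matches = [f for f in features if f.feature_id == focal_id]
    if len(focal_matches) != 1:
        raise FocalGeneError(
            f"focal gene {focal_id!r} matched {len(focal_matches)} features"
        )
    focal = focal_matches[0]
    same_contig = [f for f in features if f.contig_id == focal.contig_id]

    raw_start = focal.start - flank
    raw_end = focal.end + flank

    if circular:
        if contig_length is None:
            raise WindowConfigurationError("circular extraction needs contig_length")
        if raw_end - raw_start + 1 > contig_length:
            raise WindowConfigurationError(
                f"window of {raw_end - raw_start + 1} bp exceeds circular "
                f"contig of {contig_length} bp"
            )
        wrapped = raw_start < 1 or raw_end > contig_length
        nbhd = Neighborhood(
            focal=focal,
            window_start=raw_start,
            window_end=raw_end,
            wrapped=wrapped,
        )
        members = [
            f
            for f in same_contig
            if f.feature_id != focal_id
            and _overlaps_circular(f, raw_start, raw_end, contig_length)
        ]
    else:
        left_truncated = raw_start < 1
        w_start = max(raw_start, 1)
        if contig_length is not None:
            right_truncated = raw_end > contig_length
            w_end = min(raw_end, contig_length)
        else:
            right_truncated = False
            w_end = raw_end
        nbhd = Neighborhood(
            focal=focal,
            window_start=w_start,
            window_end=w_end,
            left_truncated=left_truncated,
            right_truncated=right_truncated,
        )
        members = [
            f
            for f in same_contig
            if f.feature_id != focal_id
            and f.start <= w_end
            and f.end >= w_start
        ]

    keyed = sorted(
        (
            (_signed_offset(f.midpoint, focal.midpoint, contig_length, circular), f)
            for f in members
        ),
        key=lambda pair: (pair[0], pair[1].start, pair[1].feature_id),
    )
    for d, f in keyed:
        (nbhd.left_genes if d < 0 else nbhd.right_genes).append(f)

    if orient_by_strand and focal.strand == "-":
        nbhd.left_genes, nbhd.right_genes = (
            list(reversed(nbhd.right_genes)),
            list(reversed(nbhd.left_genes)),
        )
    return nbhd


def read_gff3(path: str | Path, feature_types: Sequence[str] = ("CDS",)) -> list[GeneFeature]:
    """Read gene features from GFF3 (columns 1, 4, 5, 7 and the attributes).

    The product is taken from the ``product`` attribute; the feature id from
    ``ID`` or, failing that, ``locus_tag``.
    """
    wanted = set(feature_types)
    out: list[GeneFeature] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                break  # trailing FASTA section (Prokka-style GFF)
            feat = feature_from_line(line)
            if wanted and feat.featuretype not in wanted:
                continue
            attrs = feat.attributes
            feature_id = (attrs.get("ID") or attrs.get("locus_tag") or [feat.id])[0]
            product = (attrs.get("product") or [""])[0]
            out.append(
                GeneFeature(
                    feature_id=feature_id,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    product=product,
                )
            )
    return out


def read_feature_table(path: str | Path) -> list[GeneFeature]:
    """TSV fallback: columns feature_id, contig, start, end, strand, product."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "contig": str})
    return [
        GeneFeature(
            feature_id=row.feature_id,
            contig_id=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            product="" if pd.isna(row.product) else str(row.product),
        )
        for row in df.itertuples()
    ]


def write_gff3(features: Sequence[GeneFeature], path: str | Path,
               source: str = "prophagekit") -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in features:
            product = f.product.replace(";", "%3B").replace("=", "%3D")
            attrs = f"ID={f.feature_id};product={product}"
            handle.write(
                "\t".join(
                    [
                        f.contig_id,
                        source,
                        "CDS",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )
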