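"""Prophage-association classification of homolog neighborhoods.

A homolog is called prophage-associated when phage-indicative annotations
("phage", "terminase" by default, as case-insensitive substrings) occur
among its flanking genes: on both sides of the focal gene the call is high
confidence, on one side only it is low confidence, and with no evidence at
all the homolog is putatively prophage independent. The module also tallies
the most commonly co-occurring Pfam domains per category, detects
repressor-adjacent synteny (the cI-bstA architecture) and summarizes whole
surveys.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .neighborhood import GeneFeature, Neighborhood

__all__ = [
    "DEFAULT_KEYWORDS",
    "AssociationCall",
    "CoOccurrenceSummary",
    "SurveySummary",
    "RepressorEvidence",
    "is_phage_annotation",
    "classify_association",
    "tally_cooccurring_domains",
    "detect_repressor_adjacency",
    "summarize_survey",
    "write_survey_tsv",
    "write_cooccurrence_tsv",
]

DEFAULT_KEYWORDS = frozenset({"phage", "terminase"})

PROPHAGE_ASSOCIATED = "prophage_associated"
PROPHAGE_INDEPENDENT = "prophage_independent"


@dataclass(frozen=True)
class AssociationCall:
    """Per-homolog prophage-association classification.

    Invariants: the category is independent iff both evidence lists are
    empty iff confidence is not_applicable; high confidence means evidence
    on both sides, low means exactly one side.
    """

    homolog_id: str
    category: str
    confidence: str
    plasmid: bool
    left_evidence: tuple[str, ...]
    right_evidence: tuple[str, ...]


@dataclass(frozen=True)
class CoOccurrenceSummary:
    """Domain co-occurrence counts for one association category."""

    category: str
    counts: dict[str, int]
    top: tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class SurveySummary:
    """Aggregate counts and integer-rounded percentages for a survey."""

    n_total: int
    n_associated: int
    n_independent: int
    n_plasmid: int
    pct_associated: int
    pct_independent: int


@dataclass(frozen=True)
class RepressorEvidence:
    """A putative prophage repressor gene immediately 5' of the focal gene."""

    feature_id: str
    product: str
    gap: int
    matched_on: str  # "keyword" or "domain"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def is_phage_annotation(
    product: str,
    keywords: Iterable[str] = DEFAULT_KEYWORDS,
    exclusions: Iterable[str] = (),
) -> bool:
    """True iff any keyword occurs as a case-insensitive substring of the product.

    The deliberately loose substring rule matches "Prophage integrase" and
    "bacteriophage"; exclusion substrings (e.g. "macrophage") are removed
    from the text before the keywords are searched, vetoing matches that
    occur only inside them. The exclusion list defaults to empty.
    """
    text = product.lower()
    for excl in exclusions:
        text = text.replace(excl.lower(), "")
    return any(kw.lower() in text for kw in keywords)


def _gene_matches(
    gene: GeneFeature,
    keywords: Iterable[str],
    exclusions: Iterable[str],
    mode: str,
    phage_domains: frozenset[str],
) -> bool:
    if mode == "keyword":
        return is_phage_annotation(gene.product, keywords, exclusions)
    if mode == "domain":
        hit = gene.domain_hit
        return hit is not None and (
            hit.domain_accession in phage_domains or hit.domain_name in phage_domains
        )
    raise ValueError(f"unknown classifier mode {mode!r}")


def classify_association(
    nbhd: Neighborhood,
    keywords: Iterable[str] = DEFAULT_KEYWORDS,
    exclusions: Iterable[str] = (),
    plasmid: bool = False,
    mode: str = "keyword",
    phage_domains: Iterable[str] = (),
) -> AssociationCall:
    """Classify one neighborhood as prophage associated/independent.

    Evidence genes on both flanks give a high-confidence association call,
    on exactly one flank a low-confidence call, and none at all a
    prophage-independent call. ``mode="domain"`` matches each gene's best
    domain hit against ``phage_domains`` instead of the annotation text.
    The plasmid flag is metadata from the sequence record, passed through.
    """
    domains = frozenset(phage_domains)
    left = tuple(
        g.feature_id
        for g in nbhd.left_genes
        if _gene_matches(g, keywords, exclusions, mode, domains)
    )
    right = tuple(
        g.feature_id
        for g in nbhd.right_genes
        if _gene_matches(g, keywords, exclusions, mode, domains)
    )
    if left and right:
        category, confidence = PROPHAGE_ASSOCIATED, "high"
    elif left or right:
        category, confidence = PROPHAGE_ASSOCIATED, "low"
    else:
        category, confidence = PROPHAGE_INDEPENDENT, "not_applicable"
    return AssociationCall(
        homolog_id=nbhd.focal.feature_id,
        category=category,
        confidence=confidence,
        plasmid=plasmid,
        left_evidence=left,
        right_evidence=right,
    )


def tally_cooccurring_domains(
    neighborhoods: Sequence[Neighborhood],
    calls: Sequence[AssociationCall],
    category: str,
    n: int = 10,
    unit: str = "per_neighborhood",
) -> CoOccurrenceSummary:
    """Tally domain names over flank genes of all neighborhoods in a category.

    The focal homolog's own hit is excluded (it is not a flank gene). With
    ``unit="per_neighborhood"`` (default) a domain counts at most once per
    neighborhood; ``unit="per_gene"`` counts every flank gene carrying it.
    The top-``n`` list is sorted by count descending, ties alphabetical.
    """
    if category not in (PROPHAGE_ASSOCIATED, PROPHAGE_INDEPENDENT):
        raise ValueError(f"unknown category {category!r}")
    if unit not in ("per_neighborhood", "per_gene"):
        raise ValueError(f"unknown unit {unit!r}")
    counts: Counter[str] = Counter()
    for nbhd, call in zip(neighborhoods, calls):
        if call.category != category:
            continue
        names = [
            g.domain_hit.domain_name
            for g in nbhd.flank_genes
            if g.domain_hit is not None
        ]
        if unit == "per_neighborhood":
            names = sorted(set(names))
        counts.update(names)
    top = tuple(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    )
    return CoOccurrenceSummary(category=category, counts=dict(counts), top=top)


def detect_repressor_adjacency(
    nbhd: Neighborhood,
    repressor_keywords: Iterable[str] = frozenset({"repressor"}),
    repressor_domains: Iterable[str] = (),
    max_gap: int = 1000,
    require_same_strand: bool = True,
) -> Optional[RepressorEvidence]:
    """Find a putative prophage repressor gene immediately 5' of the focal gene.

    Looks at the nearest gene on the focal gene's 5' side (upstream in the
    focal gene's own orientation), requires the intergenic gap to be at most
    ``max_gap`` bp and, by default, the same strand as the focal gene, and
    matches the gene's product against ``repressor_keywords`` (substring,
    case-insensitive) or its best domain against ``repressor_domains``.
    """
    focal = nbhd.focal
    domains = frozenset(repressor_domains)
    if focal.strand == "+":
        candidates = [g for g in nbhd.flank_genes if g.end < focal.start]
        candidates.sort(key=lambda g: focal.start - g.end)
        gap_of = lambda g: focal.start - g.end - 1
    else:
        candidates = [g for g in nbhd.flank_genes if g.start > focal.end]
        candidates.sort(key=lambda g: g.start - focal.end)
        gap_of = lambda g: g.start - focal.end - 1
    if not candidates:
        return None
    nearest = candidates[0]
    if gap_of(nearest) > max_gap:
        return None
    if require_same_strand and nearest.strand != focal.strand:
        return None
    keyword_match = is_phage_annotation(nearest.product, repressor_keywords)
    domain_match = nearest.domain_hit is not None and (
        nearest.domain_hit.domain_accession in domains
        or nearest.domain_hit.domain_name in domains
    )
    if keyword_match or domain_match:
        return RepressorEvidence(
            feature_id=nearest.feature_id,
            product=nearest.product,
            gap=gap_of(nearest),
            matched_on="keyword" if keyword_match else "domain",
        )
    return None


def summarize_survey(calls: Sequence[AssociationCall]) -> SurveySummary:
    """Aggregate a survey into counts and nearest-integer percentages."""
    if not calls:
        raise ValueError("summarize_survey requires at least one call")
    n_total = len(calls)
    n_assoc = sum(1 for c in calls if c.category == PROPHAGE_ASSOCIATED)
    n_indep = n_total - n_assoc
    n_plasmid = sum(1 for c in calls if c.plasmid)
    return SurveySummary(
        n_total=n_total,
        n_associated=n_assoc,
        n_independent=n_indep,
        n_plasmid=n_plasmid,
        pct_associated=_round_half_up(100.0 * n_assoc / n_total),
        pct_independent=_round_half_up(100.0 * n_indep / n_total),
    )


def write_survey_tsv(
    calls: Sequence[AssociationCall],
    repressor: dict[str, Optional[RepressorEvidence]],
    path: str | Path,
) -> None:
    df = pd.DataFrame(
        [
            {
                "homolog_id": c.homolog_id,
                "category": c.category,
                "confidence": c.confidence,
                "plasmid": c.plasmid,
                "n_left_evidence": len(c.left_evidence),
                "n_right_evidence": len(c.right_evidence),
                "repressor_adjacent": repressor.get(c.homolog_id) is not None,
            }
            for c in calls
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_cooccurrence_tsv(
    summaries: Sequence[CoOccurrenceSummary], path: str | Path
) -> None:
    rows = [
        {
            "category": s.category,
            "rank": rank,
            "domain_name": name,
            "count": count,
        }
        for s in summaries
        for rank, (name, count) in enumerate(s.top, start=1)
    ]
    pd.DataFrame(
        rows, columns=["category", "rank", "domain_name", "count"]
    ).to_csv(path, sep="\t", index=False)
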