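"""Deterministic synthetic surveys with known ground truth.

The generator emulates the curated homolog survey: each bundle is one
contig carrying a focal defense-gene homolog with a configurable flank gene
complement, in which phage-keyword products and phage-associated domain
hits are planted on both sides (high-confidence association), one side
(low confidence) or neither side (prophage independent) of the focal gene.
All draws come from a single seeded stream with per-bundle sub-seeds, so
identical configurations produce byte-identical bundles.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .neighborhood import GeneFeature, write_gff3
from .sequences import NucleotideSequence, write_fasta

__all__ = [
    "SurveyConfig",
    "TruthLabel",
    "Bundle",
    "PHAGE_PRODUCTS",
    "NEUTRAL_PRODUCTS",
    "largest_remainder",
    "plan_labels",
    "generate_neighborhood_bundle",
    "generate_survey_bundle",
    "write_survey",
]

# (product, Pfam-style domain name, accession) triples for planted phage
# genes; products all satisfy the phage/terminase keyword rule.
PHAGE_PRODUCTS: tuple[tuple[str, str, str], ...] = (
    ("phage tail protein", "Phage_tail", "PF03906"),
    ("terminase small subunit", "Terminase_2", "PF03592"),
    ("phage portal protein", "Phage_portal", "PF04860"),
    ("terminase large subunit", "Terminase_6", "PF03237"),
    ("phage major capsid protein", "Phage_capsid", "PF05065"),
    ("prophage integrase", "Phage_integrase", "PF00589"),
    ("phage tail fiber protein", "Phage_fiber", "PF03406"),
    ("bacteriophage holin", "Phage_holin_1", "PF05106"),
)

# Neutral products never contain the phage keywords.
NEUTRAL_PRODUCTS: tuple[tuple[str, str, str], ...] = (
    ("hypothetical protein", "", ""),
    ("ABC transporter ATP-binding protein", "ABC_tran", "PF00005"),
    ("LysR family transcriptional regulator", "HTH_1", "PF00126"),
    ("MFS transporter", "MFS_1", "PF07690"),
    ("aminotransferase class I", "Aminotran_1_2", "PF00155"),
    ("two-component sensor histidine kinase", "HATPase_c", "PF02518"),
    ("acyl-CoA dehydrogenase", "Acyl-CoA_dh_1", "PF00441"),
    ("outer membrane porin", "Porin_1", "PF00267"),
)

FOCAL_PRODUCT = "BstA family phage-defense protein"
FOCAL_DOMAIN = ("BstA", "CUSTOM0001")


@dataclass(frozen=True)
class SurveyConfig:
    """Study conditions for a synthetic survey.

    Defaults mirror the curated 72-homolog survey: 79% of homologs
    prophage-associated and a small plasmid-encoded subset, with zero
    annotation noise so the planted labels are exactly recoverable.
    """

    n_homologs: int = 72
    fraction_associated: float = 0.79
    fraction_high_confidence: float = 0.7  # of the associated homologs
    fraction_plasmid: float = 0.1
    flank_gene_count: int = 12  # per side
    phage_keyword_rate: float = 0.5  # inside planted prophage flanks
    background_keyword_rate: float = 0.0
    annotation_noise_rate: float = 0.0  # per-gene keyword flips
    score_noise_sd: float = 0.0  # bit-score jitter, bits
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_associated",
            "fraction_high_confidence",
            "fraction_plasmid",
            "phage_keyword_rate",
            "background_keyword_rate",
            "annotation_noise_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_homologs < 1:
            raise ValueError("n_homologs must be >= 1")
        if self.flank_gene_count < 1:
            raise ValueError("flank_gene_count must be >= 1")


@dataclass(frozen=True)
class TruthLabel:
    homolog_id: str
    true_category: str  # prophage_associated | prophage_independent
    true_confidence: str  # high | low | not_applicable
    plasmid: bool


@dataclass
class Bundle:
    """One generated homolog neighborhood: annotation, domains, contig, metadata."""

    label: TruthLabel
    features: list[GeneFeature]
    domtblout: str
    contig: NucleotideSequence
    metadata: dict = field(default_factory=dict)


def largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer counts as close to ``fractions`` as possible."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def plan_labels(config: SurveyConfig) -> list[TruthLabel]:
    """Deterministic, seed-independent truth labels for one survey.

    Category counts come from largest-remainder apportionment of the
    configured fractions; label assignment is by index, plasmid flags are
    spread evenly across the survey.
    """
    n = config.n_homologs
    n_assoc, n_indep = largest_remainder(
        n, [config.fraction_associated, 1.0 - config.fraction_associated]
    )
    n_high, n_low = largest_remainder(
        n_assoc,
        [config.fraction_high_confidence, 1.0 - config.fraction_high_confidence],
    )
    n_plasmid = largest_remainder(
        n, [config.fraction_plasmid, 1.0 - config.fraction_plasmid]
    )[0]
    plasmid_idx = (
        set(np.linspace(0, n - 1, n_plasmid).round().astype(int).tolist())
        if n_plasmid
        else set()
    )
    labels: list[TruthLabel] = []
    width = len(str(n))
    for i in range(n):
        if i < n_high:
            cat, conf = "prophage_associated", "high"
        elif i < n_high + n_low:
            cat, conf = "prophage_associated", "low"
        else:
            cat, conf = "prophage_independent", "not_applicable"
        labels.append(
            TruthLabel(
                homolog_id=f"hom_{i + 1:0{width}d}",
                true_category=cat,
                true_confidence=conf,
                plasmid=i in plasmid_idx,
            )
        )
    return labels


def _format_domtblout_row(
    orf_id: str,
    orf_len: int,
    domain_name: str,
    accession: str,
    bits: float,
    i_evalue: float,
    description: str,
) -> str:
    env_to = max(10, orf_len - 5)
    fields = [
        f"{domain_name:<20}",
        f"{accession:<10}",
        f"{orf_len + 20:>5}",
        f"{orf_id:<20}",
        "-",
        f"{orf_len:>5}",
        f"{i_evalue:9.2g}",
        f"{bits:6.1f}",
        "0.1",
        "1",
        "1",
        f"{i_evalue / 10:9.2g}",
        f"{i_evalue:9.2g}",
        f"{bits:6.1f}",
        "0.1",
        "2",
        f"{orf_len - 6:>5}",
        "8",
        f"{env_to:>5}",
        "5",
        f"{env_to:>5}",
        "0.90",
        description,
    ]
    return " ".join(fields)


_DOMTBLOUT_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------\n"
    "# target name        accession   tlen query name           acc"
    "ession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue"
    "  score  bias  from    to  from    to  from    to  acc description"
    " of target\n"
    "#------------------- ---------- ----- -------------------- ------"
    "---- ----- --------- ------ ----- --- --- --------- --------- ----"
    "-- ----- ----- ----- ----- ----- ----- ----- ---- ---------------"
    "------\n"
)


def generate_neighborhood_bundle(
    label: TruthLabel, config: SurveyConfig, seed: int
) -> Bundle:
    """One synthetic contig + annotation + domain table for one truth label.

    Gene lengths are uniform on 300-1500 bp and intergenic gaps on
    20-200 bp. On the label's designated prophage side(s) each flank gene
    carries a phage-keyword product with probability ``phage_keyword_rate``
    (at least one per designated side is guaranteed); elsewhere keywords
    appear at ``background_keyword_rate``. ``annotation_noise_rate`` then
    flips each flank gene's product class independently. Fully
    deterministic given the seed.
    """
    # crc32 sub-seed: stable across processes, unlike Python's hash()
    rng = np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(label.homolog_id.encode()) & 0x7FFFFFFF]
    )
    n_side = config.flank_gene_count

    if label.true_category == "prophage_associated":
        if label.true_confidence == "high":
            phage_sides = {"left", "right"}
        elif label.true_confidence == "low":
            phage_sides = {("left", "right")[int(rng.integers(2))]}
        else:
            raise ValueError(
                f"{label.homolog_id}: associated label needs high/low confidence"
            )
    elif label.true_category == "prophage_independent":
        if label.true_confidence != "not_applicable":
            raise ValueError(
                f"{label.homolog_id}: independent label must be not_applicable"
            )
        phage_sides = set()
    else:
        raise ValueError(f"unknown category {label.true_category!r}")

    # lay out genes left flank -> focal -> right flank
    lengths = rng.integers(300, 1501, size=2 * n_side + 1)
    gaps = rng.integers(20, 201, size=2 * n_side + 2)
    contig_id = f"contig_{label.homolog_id}"
    features: list[GeneFeature] = []
    pos = 1 + int(gaps[0])
    for i in range(2 * n_side + 1):
        start = pos
        end = pos + int(lengths[i]) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            GeneFeature(
                feature_id=f"{label.homolog_id}_orf{i + 1:03d}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                product="",
            )
        )
        pos = end + 1 + int(gaps[i + 1])
    contig_length = pos
    focal = features[n_side]
    focal.product = FOCAL_PRODUCT
    focal.strand = "+"

    # assign flank products; coupled uniforms keep noise levels comparable
    sides = [("left", features[:n_side]), ("right", features[n_side + 1 :])]
    domain_rows: list[str] = []
    for side, genes in sides:
        planted = side in phage_sides
        base_rate = config.phage_keyword_rate if planted else config.background_keyword_rate
        u_keyword = rng.random(len(genes))
        is_phage = u_keyword < base_rate
        if planted and not is_phage.any():
            is_phage[int(rng.integers(len(genes)))] = True
        u_noise = rng.random(len(genes))
        flip = u_noise < config.annotation_noise_rate
        is_phage = np.logical_xor(is_phage, flip)
        for gene, phage in zip(genes, is_phage):
            vocab = PHAGE_PRODUCTS if phage else NEUTRAL_PRODUCTS
            product, domain_name, accession = vocab[int(rng.integers(len(vocab)))]
            gene.product = product
            if domain_name:
                orf_len = gene.length // 3
                bits = float(rng.uniform(40, 200))
                if config.score_noise_sd > 0:
                    bits += float(rng.normal(0.0, config.score_noise_sd))
                i_evalue = float(10.0 ** (-max(bits, 1.0) / 10.0))
                domain_rows.append(
                    _format_domtblout_row(
                        gene.feature_id, orf_len, domain_name, accession,
                        bits, i_evalue, product,
                    )
                )

    focal_len = focal.length // 3
    domain_rows.append(
        _format_domtblout_row(
            focal.feature_id, focal_len, FOCAL_DOMAIN[0], FOCAL_DOMAIN[1],
            150.0, 1e-45, FOCAL_PRODUCT,
        )
    )

    contig = NucleotideSequence(
        identifier=contig_id,
        residues="".join(rng.choice(list("ACGT"), size=contig_length).tolist()),
    )
    metadata = {
        "homolog_id": label.homolog_id,
        "focal_id": focal.feature_id,
        "contig_id": contig_id,
        "contig_length": contig_length,
        "circular": False,
        "plasmid": label.plasmid,
    }
    return Bundle(
        label=label,
        features=features,
        domtblout=_DOMTBLOUT_HEADER + "\n".join(domain_rows) + "\n#\n",
        contig=contig,
        metadata=metadata,
    )


def generate_survey_bundle(config: SurveyConfig) -> tuple[list[Bundle], pd.DataFrame]:
    """All bundles of a survey plus the ground-truth table."""
    labels = plan_labels(config)
    bundles = [
        generate_neighborhood_bundle(label, config, seed=config.seed)
        for label in labels
    ]
    truth = pd.DataFrame(
        [
            {
                "homolog_id": lab.homolog_id,
                "true_category": lab.true_category,
                "true_confidence": lab.true_confidence,
                "plasmid": lab.plasmid,
            }
            for lab in labels
        ]
    )
    return bundles, truth


def write_survey(bundles: Sequence[Bundle], truth: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write a survey to disk in the pipeline's bundle-directory layout.

    Layout: ``<out>/truth.tsv`` plus one directory per homolog containing
    ``features.gff3``, ``contig.fna``, ``domains.domtblout`` and
    ``record.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for bundle in bundles:
        bdir = out / bundle.label.homolog_id
        bdir.mkdir(exist_ok=True)
        write_gff3(bundle.features, bdir / "features.gff3")
        write_fasta([bundle.contig], bdir / "contig.fna")
        (bdir / "domains.domtblout").write_text(bundle.domtblout)
        (bdir / "record.json").write_text(
            json.dumps(bundle.metadata, indent=1, sort_keys=True) + "\n"
        )
    return out
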