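"""End-to-end orchestration of the homolog survey, aba report and identity runs.

A survey input is a directory of per-homolog bundles, each holding
``features.gff3``, ``domains.domtblout``, ``contig.fna`` and ``record.json``
(metadata: focal_id, contig_length, circular, plasmid) — the layout written
by :mod:`prophagekit.synth` and equally producible from downloaded records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import aba as aba_mod
from .classify import (
    DEFAULT_KEYWORDS,
    PROPHAGE_ASSOCIATED,
    PROPHAGE_INDEPENDENT,
    AssociationCall,
    CoOccurrenceSummary,
    RepressorEvidence,
    SurveySummary,
    classify_association,
    detect_repressor_adjacency,
    summarize_survey,
    tally_cooccurring_domains,
    write_cooccurrence_tsv,
    write_survey_tsv,
)
from .domains import best_hit_per_orf, read_domtblout
from .neighborhood import Neighborhood, extract_neighborhood, read_gff3
from .sequences import (
    global_align,
    percent_identity,
    read_dna_fasta,
    read_protein_fasta,
)

logger = logging.getLogger("prophagekit")

__all__ = [
    "RunConfig",
    "SurveyResult",
    "run_survey",
    "run_aba_report",
    "run_identity",
]


@dataclass
class RunConfig:
    """Survey run parameters; defaults encode the published analysis choices."""

    input_dir: Path
    output_dir: Path
    flank: int = 20_000
    evalue_threshold: float = 1e-3
    keywords: frozenset[str] = DEFAULT_KEYWORDS
    exclusions: tuple[str, ...] = ()
    top_n: int = 10
    mode: str = "keyword"  # or "domain"
    phage_domains: frozenset[str] = frozenset()
    tally_unit: str = "per_neighborhood"

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.flank <= 0:
            raise ValueError("flank must be positive")


@dataclass
class SurveyResult:
    summary: SurveySummary
    calls: list[AssociationCall]
    neighborhoods: list[Neighborhood]
    cooccurrence: list[CoOccurrenceSummary]
    repressor: dict[str, Optional[RepressorEvidence]]
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _bundle_dirs(input_dir: Path) -> list[Path]:
    return sorted(
        d for d in input_dir.iterdir() if d.is_dir() and (d / "record.json").exists()
    )


def _process_bundle(bdir: Path, config: RunConfig) -> tuple[Neighborhood, AssociationCall]:
    meta = json.loads((bdir / "record.json").read_text())
    features = read_gff3(bdir / "features.gff3")
    best = best_hit_per_orf(
        read_domtblout(bdir / "domains.domtblout"),
        evalue_threshold=config.evalue_threshold,
    )
    for f in features:
        f.domain_hit = best.get(f.feature_id)
    nbhd = extract_neighborhood(
        features,
        focal_id=meta["focal_id"],
        flank=config.flank,
        contig_length=meta.get("contig_length"),
        circular=bool(meta.get("circular", False)),
    )
    call = classify_association(
        nbhd,
        keywords=config.keywords,
        exclusions=config.exclusions,
        plasmid=bool(meta.get("plasmid", False)),
        mode=config.mode,
        phage_domains=config.phage_domains,
    )
    # report under the bundle's homolog id, not the focal ORF id
    return nbhd, replace(call, homolog_id=meta.get("homolog_id", call.homolog_id))


def run_survey(config: RunConfig) -> SurveyResult:
    """Run the full survey: neighborhoods, best hits, calls, tallies, summary.

    Homologs whose bundle fails to parse or extract are reported and
    skipped; an entirely empty survey raises ``ValueError``.
    """
    bundle_dirs = _bundle_dirs(config.input_dir)
    neighborhoods: list[Neighborhood] = []
    calls: list[AssociationCall] = []
    skipped: list[tuple[str, str]] = []
    for bdir in bundle_dirs:
        try:
            nbhd, call = _process_bundle(bdir, config)
        except Exception as exc:  # noqa: BLE001 — skip-and-report contract
            logger.warning("skipping %s: %s", bdir.name, exc)
            skipped.append((bdir.name, str(exc)))
            continue
        neighborhoods.append(nbhd)
        calls.append(call)
    if not calls:
        raise ValueError(f"no processable homolog bundles under {config.input_dir}")

    summary = summarize_survey(calls)
    cooccurrence = [
        tally_cooccurring_domains(
            neighborhoods, calls, category, n=config.top_n, unit=config.tally_unit
        )
        for category in (PROPHAGE_ASSOCIATED, PROPHAGE_INDEPENDENT)
    ]
    repressor = {
        call.homolog_id: detect_repressor_adjacency(nbhd)
        for nbhd, call in zip(neighborhoods, calls)
    }

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    write_survey_tsv(calls, repressor, out / "survey.tsv")
    write_cooccurrence_tsv(cooccurrence, out / "cooccurrence.tsv")
    summary_dict = {
        "n_total": summary.n_total,
        "n_associated": summary.n_associated,
        "n_independent": summary.n_independent,
        "n_plasmid": summary.n_plasmid,
        "pct_associated": summary.pct_associated,
        "pct_independent": summary.pct_independent,
        "n_skipped": len(skipped),
    }
    (out / "summary.json").write_text(json.dumps(summary_dict, indent=1) + "\n")
    return SurveyResult(
        summary=summary,
        calls=calls,
        neighborhoods=neighborhoods,
        cooccurrence=cooccurrence,
        repressor=repressor,
        skipped=skipped,
    )


def run_aba_report(
    fasta: str | Path, output_dir: str | Path, k_min: int = 6, margin: int = 10
) -> tuple[list[dict], list[str]]:
    """Per-element partition/repeat report for a FASTA of candidate elements."""
    elements = read_dna_fasta(fasta)
    rows, warnings = aba_mod.aba_report_rows(elements, k_min=k_min, margin=margin)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    aba_mod.write_aba_report(rows, out / "aba_report.tsv")
    diagrams = []
    for seq in elements:
        try:
            diagrams.append(aba_mod.element_diagram(seq, k_min=k_min, margin=margin))
        except aba_mod.PartitionError:
            continue
    (out / "aba_diagrams.txt").write_text("\n\n".join(diagrams) + "\n")
    for warning in warnings:
        logger.warning("aba report: %s", warning)
    return rows, warnings


def run_identity(
    fasta: str | Path,
    output_path: str | Path,
    reference_id: Optional[str] = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> pd.DataFrame:
    """Needle-convention percent identities, reference-vs-all or all-vs-all."""
    proteins = read_protein_fasta(fasta)
    ids = [p.identifier for p in proteins]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence identifiers in protein FASTA")
    if len(proteins) < 2:
        raise ValueError("identity run requires at least two sequences")
    by_id = {p.identifier: p for p in proteins}
    if reference_id is not None:
        if reference_id not in by_id:
            raise KeyError(f"reference {reference_id!r} not in FASTA")
        pairs = [
            (by_id[reference_id], p) for p in proteins if p.identifier != reference_id
        ]
    else:
        pairs = [
            (proteins[i], proteins[j])
            for i in range(len(proteins))
            for j in range(i + 1, len(proteins))
        ]
    rows = []
    for a, b in pairs:
        aln = global_align(a, b, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
        rows.append(
            {
                "seq_a": a.identifier,
                "seq_b": b.identifier,
                "percent_identity": percent_identity(aln),
                "score": aln.score,
                "columns": aln.columns,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(output_path, sep="\t", index=False)
    return df
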