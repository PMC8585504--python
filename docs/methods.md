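# Methods

## Neighborhood model

The unit of analysis is the gene neighborhood of a focal homolog: the
window `[focal.start − flank, focal.end + flank]` with `flank = 20 000 bp`
(a 40-kb window plus the focal gene itself). The window is anchored to the
focal gene's outer coordinates, not its midpoint, reading "either side of
the gene" as flanking the gene body. A flanking gene belongs to the
neighborhood if it overlaps the window by at least one base — partially
overlapping genes are kept because their annotations still carry evidence.
Genes are assigned to the left or right flank by midpoint relative to the
focal gene; an optional mode (`orient_by_strand`) re-labels the flanks by
the focal gene's orientation, default off because genome-coordinate sides
are the conventional reading.

On linear contigs the window is clipped at the contig ends and
`left_truncated`/`right_truncated` record lost flank — truncated
neighborhoods are surfaced, never silently discarded, since whether the
original analysis clipped or skipped edge cases is not derivable from the
data formats involved. On circular contigs coordinates wrap modulo the
contig length (a window longer than the contig is a configuration error);
correctness of the wrap is property-tested against an interval oracle on a
doubled-coordinate representation. Neighborhoods never cross contig
boundaries of draft assemblies.

## Association classifier

The default classifier is textual: a gene is phage-indicative when its
product contains any configured keyword ("phage", "terminase") as a
case-insensitive substring. The rule is deliberately loose — it matches
"Prophage integrase" and "bacteriophage holin" — and an exclusion list
(default empty) removes pathological carriers such as "macrophage" from
the text before keywords are searched. Decision rule:

| evidence | category | confidence |
|---|---|---|
| both flanks | prophage_associated | high |
| one flank | prophage_associated | low |
| neither | prophage_independent | not_applicable |

The two-sided requirement for high confidence guards against a
prophage-independent homolog that merely sits next to a prophage region by
chance. A second mode (`mode="domain"`) takes evidence from each gene's
best domain hit matched against a configurable list of phage-associated
domain accessions; it exists because domain co-occurrence is the natural
alternative evidence channel, and the two modes can disagree on noisy
annotations. Plasmid status is metadata carried by the sequence record —
no replicon prediction is attempted.

Survey percentages are reported as nearest integers (half rounds up:
20.83 → 21, 79.17 → 79).

## Domain assignment

HMMER3 `domtblout` tables (hmmscan orientation: target = model, query =
protein) are reduced to one hit per ORF: hits with independent (i-)
E-value above the threshold are discarded, and the maximum bit score wins
among survivors. The i-E-value is used rather than the full-sequence
E-value because selection is per domain hit; the default threshold of
10⁻³ is the conventional HMMER reporting cutoff, configurable. Bit score
is the primary ranking (the stabler statistic across database sizes);
`rank_by="i_evalue"` is exposed as the alternative. Ties break by lower
E-value, then lexicographic accession, then name and envelope coordinates,
making the winner deterministic under any input permutation. Custom
(non-Pfam) models are supported transparently — the focal-family model is
reported under its own accession namespace alongside Pfam hits.

Co-occurrence tallies count domain names over flank genes of all
neighborhoods in a category, the focal gene excluded. The default unit
counts a domain at most once per neighborhood, so one tail-fiber cassette
cannot dominate the ranking; `per_gene` counts every gene. Both units are
provided because the choice is not determined by the published figure
legends; ties in the top-N list are broken alphabetically.

## Repressor-adjacent synteny

Many homologs sit immediately downstream of a prophage repressor (the
cI–bstA architecture). The detector reports the nearest gene on the focal
gene's 5′ side when it is on the same strand (configurable), the
intergenic gap is ≤ 1 000 bp (configurable), and its product or best
domain matches the repressor rules. The gap and strand defaults were
chosen once to capture the canonical architecture; there is no published
numeric criterion for "adjacent".

## Alignment conventions

Pairwise identities use optimal global alignment with affine gaps:
BLOSUM62, gap open 10, gap extend 0.5, terminal gaps unpenalized — the
EMBOSS Needle webserver defaults. A gap of length L costs
`open + (L−1)·extend` internally and nothing at the ends. Percent identity
is identical columns over all alignment columns including gaps (Needle's
"Identity" line), reported to one decimal; the denominator choice matters
and is fixed to reproduce that tool. Among co-optimal alignments the
aligner's first traceback is returned and identity is reported for that
alignment only. The aligner is validated against an exhaustive
alignment-enumeration oracle on small instances. Sequences are uppercased
and U→T-mapped on ingest. Reference-collapsing of an MSA removes every
column in which the reference row holds a gap and reports the removed
column ranges; the collapsed width always equals the reference's ungapped
length.

## aba element analysis

An element is partitioned at its start codon: auto mode takes the first
forward-strand ATG (correct for the packaged 63-bp element, whose first
ATG sits at offset 29) and an explicit offset overrides it. Direct repeats
are maximal repeated substrings of length ≥ k_min (default 6) on the
forward strand, overlaps permitted; maximal means any one-base extension
loses an occurrence. The repeat search is forward-strand only — the
biological signal is a direct, not inverted, repeat. "Terminal" is
operationalized as: one occurrence starting within the first `margin`
bases and one ending within the last `margin` bases (default 10 bp); the
published figures show but do not define the criterion. Point mutants are
located programmatically as the first G inside a chosen repeat occurrence
(CCCGCC→CCCTCC), so the operation generalizes to other elements.

The ORF scanner reports ATG-initiated frames with an in-frame stop
(complete) or, with `allow_runoff`, frames reaching the sequence end
(incomplete — the packaged element's coding frame runs off its 3′ end, as
expected for a truncated gene start). `min_codons` counts codons from the
ATG excluding the stop. Strand, minimum length and completeness criteria
for "short ORFs within the element" are not published, so no fixed ORF
count is asserted anywhere; the parameters are exposed instead.

## Synthetic surveys

The generator emulates a curated homolog survey with planted truth. Label
proportions use largest-remainder apportionment, so 72 homologs at
fraction 0.79 give exactly 57 associated / 15 independent; apportionment
and label assignment are seed-independent, while all sequence-level draws
come from a numpy PCG64 stream seeded per bundle (survey seed + CRC32 of
the homolog id), making every bundle independently reproducible and whole
surveys byte-identical across runs.

Defaults are the study conditions: n = 72, fraction associated 0.79,
plasmid fraction 0.1 (the published survey reports only "a small subset"
plasmid-encoded), high-confidence fraction 0.7 of associated homologs (the
published split is shown but not quantified), 12 flank genes per side,
phage-keyword rate 0.5 inside planted prophage flanks with at least one
keyword gene guaranteed per designated side, background keyword rate 0,
annotation noise 0. Gene lengths are uniform on 300–1500 bp and
intergenic gaps on 20–200 bp — typical bacterial scales, otherwise
unconstrained. Planted phage genes carry matching phage-domain hits in the
emitted `domtblout`; neutral genes carry housekeeping domains or none.

`annotation_noise_rate` flips each flank gene's product class
independently; classifier agreement with truth is 100 % at zero noise
(property-tested over random configurations with zero background keyword
rate — a positive background rate plants ambient keywords that are
legitimate, not erroneous, evidence, so perfect recovery is only defined
without it) and degrades monotonically as noise rises (checked at fixed
seeds). The generator does not emulate real phage genome architecture,
sequence homology between planted genes, or HMMER score distributions
beyond configurable jitter — passing the closed-loop tests demonstrates
the pipeline's logic, not performance on real annotation quality.

## Problem sizes and scope

Tests and the acceptance script run at desk scale: surveys of 12–72
synthetic homologs, alignment oracles on sequences of length ≤ 6 over a
reduced alphabet, repeat-finder oracles on sequences ≤ 40 bp. The
published identities between named homologs (48.4 %, 41.7 %) and the real
72-homolog proportions require downloading the deposited accessions and
are not recomputed offline; the alignment and survey machinery that would
process them is exactly what the synthetic and in-package data exercise.

## Known limitations

- The keyword rule inherits annotation vocabulary bias: unannotated or
  atypically annotated prophages are invisible to the default mode.
- Truncated neighborhoods near contig ends lose evidence on one side and
  can only downgrade confidence; they are flagged, not corrected.
- The terminal-repeat margin rule is a heuristic operationalization; with
  margins much larger than the element, interior repeats qualify.
- The domtblout writer in the generator produces a minimal valid dialect
  (fixed 22 fields + description), not every field HMMER populates.
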