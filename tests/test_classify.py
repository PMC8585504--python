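"""Prophage-association classification, co-occurrence tallies, repressor
synteny and survey summaries."""

from collections import Counter

import pytest

from prophagekit.classify import (
    AssociationCall,
    classify_association,
    detect_repressor_adjacency,
    is_phage_annotation,
    summarize_survey,
    tally_cooccurring_domains,
)
from prophagekit.domains import DomainHit
from prophagekit.neighborhood import extract_neighborhood


def hit(name, acc="PF00000"):
    return DomainHit(
        orf_id="x", domain_accession=acc, domain_name=name,
        bit_score=50.0, i_evalue=1e-10, env_from=1, env_to=50,
    )


def build_nbhd(make, left_products, right_products, focal_strand="+"):
    features = []
    pos = 1000
    for i, product in enumerate(left_products):
        features.append(make(f"L{i}", pos, pos + 800, product=product))
        pos += 1000
    focal = make("focal", pos, pos + 800, strand=focal_strand,
                 product="BstA family phage-defense protein")
    features.append(focal)
    pos += 1000
    for i, product in enumerate(right_products):
        features.append(make(f"R{i}", pos, pos + 800, product=product))
        pos += 1000
    return extract_neighborhood(features, "focal", flank=20_000)


class TestIsPhageAnnotation:
    @pytest.mark.parametrize(
        "product,expected",
        [
            ("terminase large subunit", True),
            ("hypothetical protein", False),
            ("Prophage integrase", True),        # substring semantics
            ("Bacteriophage holin", True),
            ("PHAGE tail fiber", True),          # case-insensitive
            ("", False),
        ],
    )
    def test_keyword_rule(self, product, expected):
        assert is_phage_annotation(product) is expected

    def test_exclusion_vetoes_substring(self):
        assert is_phage_annotation("macrophage stimulating factor")
        assert not is_phage_annotation(
            "macrophage stimulating factor", exclusions=["macrophage"]
        )
        # a veto does not suppress an independent keyword occurrence
        assert is_phage_annotation(
            "macrophage-like phage protein", exclusions=["macrophage"]
        )


class TestClassifyAssociation:
    def test_both_sides_is_high_confidence(self, gene_factory):
        nbhd = build_nbhd(gene_factory,
                          ["phage tail protein", "hypothetical protein"],
                          ["terminase small subunit"])
        call = classify_association(nbhd)
        assert (call.category, call.confidence) == ("prophage_associated", "high")
        assert call.left_evidence == ("L0",)
        assert call.right_evidence == ("R0",)

    def test_one_side_is_low_confidence(self, gene_factory):
        nbhd = build_nbhd(gene_factory, ["phage portal protein"],
                          ["hypothetical protein"])
        call = classify_association(nbhd)
        assert (call.category, call.confidence) == ("prophage_associated", "low")

    def test_no_evidence_is_independent(self, gene_factory):
        nbhd = build_nbhd(gene_factory, ["hypothetical protein"],
                          ["MFS transporter"])
        call = classify_association(nbhd)
        assert (call.category, call.confidence) == (
            "prophage_independent", "not_applicable",
        )
        assert call.left_evidence == call.right_evidence == ()

    def test_adding_non_keyword_gene_does_not_change_call(self, gene_factory):
        left = ["phage tail protein"]
        base = classify_association(build_nbhd(gene_factory, left, []))
        extended = classify_association(
            build_nbhd(gene_factory, left + ["chaperone GroEL"], ["porin"])
        )
        assert (base.category, base.confidence) == (
            extended.category, extended.confidence,
        )

    def test_domain_mode_uses_best_hits(self, gene_factory):
        nbhd = build_nbhd(gene_factory, ["unannotated orf"], ["unannotated orf"])
        for g in nbhd.left_genes:
            g.domain_hit = hit("Phage_portal", "PF04860")
        call = classify_association(nbhd, mode="domain",
                                    phage_domains={"PF04860"})
        assert (call.category, call.confidence) == ("prophage_associated", "low")
        # keyword mode sees nothing in the products
        assert classify_association(nbhd).category == "prophage_independent"


class TestTally:
    def plant(self, gene_factory, domain_plan):
        """domain_plan: list of per-neighborhood lists of domain names."""
        pairs = []
        for names in domain_plan:
            nbhd = build_nbhd(gene_factory,
                              ["phage tail protein"] * len(names), ["terminase"])
            for g, name in zip(nbhd.left_genes, names):
                g.domain_hit = hit(name)
            pairs.append((nbhd, classify_association(nbhd)))
        return zip(*pairs)

    def test_counts_match_brute_force(self, gene_factory):
        plan = [["A", "B", "A"], ["B", "C"], ["A"]]
        nbhds, calls = self.plant(gene_factory, plan)
        summary = tally_cooccurring_domains(
            list(nbhds), list(calls), "prophage_associated", unit="per_gene"
        )
        assert summary.counts == dict(Counter(n for ns in plan for n in ns))

    def test_per_neighborhood_counts_once(self, gene_factory):
        plan = [["A", "A", "A"], ["A", "B"]]
        nbhds, calls = self.plant(gene_factory, plan)
        summary = tally_cooccurring_domains(
            list(nbhds), list(calls), "prophage_associated",
            unit="per_neighborhood",
        )
        assert summary.counts == {"A": 2, "B": 1}

    def test_ties_alphabetical_and_top_n(self, gene_factory):
        plan = [["B", "A", "C"], ["C", "A", "B"]]
        nbhds, calls = self.plant(gene_factory, plan)
        summary = tally_cooccurring_domains(
            list(nbhds), list(calls), "prophage_associated", n=2
        )
        assert summary.top == (("A", 2), ("B", 2))

    def test_empty_category(self, gene_factory):
        nbhds, calls = self.plant(gene_factory, [["A"]])
        summary = tally_cooccurring_domains(
            list(nbhds), list(calls), "prophage_independent"
        )
        assert summary.counts == {} and summary.top == ()

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            tally_cooccurring_domains([], [], "weird")


class TestRepressorAdjacency:
    def test_ci_repressor_immediately_upstream(self, gene_factory):
        features = [
            gene_factory("rep", 1000, 1800, product="cI repressor"),
            gene_factory("focal", 1851, 2700),  # gap 50 bp, same strand
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000)
        evidence = detect_repressor_adjacency(nbhd)
        assert evidence is not None
        assert evidence.feature_id == "rep"
        assert evidence.gap == 50
        assert evidence.matched_on == "keyword"

    def test_minus_strand_focal_looks_downstream_in_genome_coords(self, gene_factory):
        features = [
            gene_factory("focal", 1000, 1800, strand="-"),
            gene_factory("rep", 1851, 2700, strand="-", product="phage repressor"),
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000)
        assert detect_repressor_adjacency(nbhd).feature_id == "rep"

    def test_no_repressor_annotation(self, gene_factory):
        features = [
            gene_factory("up", 1000, 1800, product="hypothetical protein"),
            gene_factory("focal", 1851, 2700),
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000)
        assert detect_repressor_adjacency(nbhd) is None

    def test_distant_repressor_rejected_by_max_gap(self, gene_factory):
        features = [
            gene_factory("rep", 1000, 1800, product="cI repressor"),
            gene_factory("focal", 6_801, 7_700),  # gap 5000 bp
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000)
        assert detect_repressor_adjacency(nbhd, max_gap=1000) is None
        assert detect_repressor_adjacency(nbhd, max_gap=6000) is not None

    def test_opposite_strand_rejected_by_default(self, gene_factory):
        features = [
            gene_factory("rep", 1000, 1800, strand="-", product="cI repressor"),
            gene_factory("focal", 1851, 2700),
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000)
        assert detect_repressor_adjacency(nbhd) is None
        assert detect_repressor_adjacency(
            nbhd, require_same_strand=False
        ) is not None


def call(category, confidence, plasmid=False):
    evidence = {
        "high": (("a",), ("b",)),
        "low": (("a",), ()),
        "not_applicable": ((), ()),
    }[confidence]
    return AssociationCall("h", category, confidence, plasmid, *evidence)


class TestSummarizeSurvey:
    def test_fifteen_of_seventy_two_rounds_to_21(self):
        calls = [call("prophage_associated", "high")] * 57 + [
            call("prophage_independent", "not_applicable")
        ] * 15
        s = summarize_survey(calls)
        assert (s.n_total, s.n_associated, s.n_independent) == (72, 57, 15)
        assert (s.pct_associated, s.pct_independent) == (79, 21)

    def test_all_associated(self):
        s = summarize_survey([call("prophage_associated", "low")] * 4)
        assert (s.pct_associated, s.pct_independent) == (100, 0)

    def test_plasmid_count(self):
        calls = [
            call("prophage_associated", "high", plasmid=True),
            call("prophage_independent", "not_applicable"),
        ]
        assert summarize_survey(calls).n_plasmid == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_survey([])
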