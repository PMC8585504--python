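"""Neighborhood extraction: window clipping, circular wrap-around and
equivalence with a direct interval-overlap oracle."""

import random

import pytest

from oracles import window_members
from prophagekit.neighborhood import (
    FocalGeneError,
    WindowConfigurationError,
    extract_neighborhood,
)


def spaced_genes(make, n=50, gene_len=1000, spacing=2000):
    """Genes of gene_len bp starting every spacing bp: g0 at 1, g1 at 2001, ..."""
    return [
        make(f"g{i}", spacing * i + 1, spacing * i + gene_len) for i in range(n)
    ]


class TestLinear:
    def test_left_edge_clipping(self, gene_factory):
        features = [
            gene_factory("focal", 100, 1000),
            gene_factory("far", 40_000, 41_000),
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000,
                                    contig_length=50_000)
        assert nbhd.window_start == 1
        assert nbhd.left_truncated and not nbhd.right_truncated
        assert nbhd.window_end == 21_000

    def test_spaced_fixture_ten_genes_per_side(self, gene_factory):
        features = spaced_genes(gene_factory)
        nbhd = extract_neighborhood(features, "g25", flank=20_000,
                                    contig_length=100_000)
        assert [g.feature_id for g in nbhd.left_genes] == [
            f"g{i}" for i in range(15, 25)
        ]
        assert [g.feature_id for g in nbhd.right_genes] == [
            f"g{i}" for i in range(26, 36)
        ]
        expected = window_members(
            [(f.feature_id, f.start, f.end) for f in features],
            ("g25", features[25].start, features[25].end),
            20_000, 100_000, False,
        )
        assert {g.feature_id for g in nbhd.flank_genes} == expected

    def test_partial_overlap_included(self, gene_factory):
        # gene pokes 1 bp into the window
        features = [
            gene_factory("focal", 30_000, 31_000),
            gene_factory("edge", 9_000, 10_000),   # overlaps window start 10000
            gene_factory("out", 8_000, 9_999),     # ends 1 bp short
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000)
        assert {g.feature_id for g in nbhd.flank_genes} == {"edge"}

    def test_window_span_bound(self, gene_factory):
        features = spaced_genes(gene_factory)
        nbhd = extract_neighborhood(features, "g25", flank=20_000,
                                    contig_length=100_000)
        focal = features[25]
        assert nbhd.window_end - nbhd.window_start + 1 == 2 * 20_000 + focal.length

    def test_focal_absent_or_duplicated(self, gene_factory):
        features = spaced_genes(gene_factory, n=5)
        with pytest.raises(FocalGeneError):
            extract_neighborhood(features, "missing")
        with pytest.raises(FocalGeneError):
            extract_neighborhood(features + [features[0]], "g0")

    def test_other_contigs_ignored(self, gene_factory):
        features = spaced_genes(gene_factory, n=5)
        features.append(gene_factory("alien", 1, 900, contig="contig2"))
        nbhd = extract_neighborhood(features, "g2", flank=20_000)
        assert "alien" not in {g.feature_id for g in nbhd.flank_genes}


class TestCircular:
    def test_wrap_at_origin_matches_doubling_oracle(self, gene_factory):
        L = 50_000
        features = [
            gene_factory("focal", 500, 1500),
            gene_factory("tail", 48_000, 48_900),  # reachable only by wrapping
            gene_factory("mid", 24_000, 24_900),   # unreachable
            gene_factory("head", 5_000, 5_900),
        ]
        nbhd = extract_neighborhood(features, "focal", flank=20_000,
                                    contig_length=L, circular=True)
        assert nbhd.wrapped
        expected = window_members(
            [(f.feature_id, f.start, f.end) for f in features],
            ("focal", 500, 1500), 20_000, L, True,
        )
        assert {g.feature_id for g in nbhd.flank_genes} == expected == {
            "tail", "head",
        }
        # the wrapped gene sits on the focal gene's left (5') side
        assert [g.feature_id for g in nbhd.left_genes] == ["tail"]
        assert [g.feature_id for g in nbhd.right_genes] == ["head"]

    def test_window_longer_than_contig_rejected(self, gene_factory):
        features = [gene_factory("focal", 100, 900)]
        with pytest.raises(WindowConfigurationError):
            extract_neighborhood(features, "focal", flank=20_000,
                                 contig_length=10_000, circular=True)

    def test_linear_and_circular_agree_away_from_origin(self, gene_factory):
        features = spaced_genes(gene_factory)
        lin = extract_neighborhood(features, "g25", flank=20_000,
                                   contig_length=100_000)
        circ = extract_neighborhood(features, "g25", flank=20_000,
                                    contig_length=100_000, circular=True)
        assert not circ.wrapped
        assert [g.feature_id for g in lin.flank_genes] == [
            g.feature_id for g in circ.flank_genes
        ]


class TestProperties:
    def test_invariant_under_input_order(self, gene_factory):
        features = spaced_genes(gene_factory)
        nbhd = extract_neighborhood(features, "g25", flank=20_000)
        rng = random.Random(7)
        for _ in range(5):
            shuffled = features[:]
            rng.shuffle(shuffled)
            other = extract_neighborhood(shuffled, "g25", flank=20_000)
            assert [g.feature_id for g in other.left_genes] == [
                g.feature_id for g in nbhd.left_genes
            ]
            assert [g.feature_id for g in other.right_genes] == [
                g.feature_id for g in nbhd.right_genes
            ]

    @pytest.mark.parametrize("circular", [False, True])
    def test_random_fixtures_match_interval_oracle(self, gene_factory, circular):
        rng = random.Random(11)
        L = 60_000
        for trial in range(20):
            genes = []
            pos = 1
            i = 0
            while pos < L - 1500:
                length = rng.randint(200, 1400)
                genes.append(gene_factory(f"t{trial}g{i}", pos, pos + length - 1))
                pos += length + rng.randint(10, 400)
                i += 1
            focal = rng.choice(genes)
            flank = rng.choice([5_000, 12_000, 20_000])
            nbhd = extract_neighborhood(genes, focal.feature_id, flank=flank,
                                        contig_length=L, circular=circular)
            expected = window_members(
                [(g.feature_id, g.start, g.end) for g in genes],
                (focal.feature_id, focal.start, focal.end),
                flank, L, circular,
            )
            assert {g.feature_id for g in nbhd.flank_genes} == expected

    def test_orient_by_strand_swaps_flanks_for_minus_focal(self, gene_factory):
        features = [
            gene_factory("up", 1_000, 1_800),
            gene_factory("focal", 3_000, 3_800, strand="-"),
            gene_factory("down", 5_000, 5_800),
        ]
        plain = extract_neighborhood(features, "focal", flank=10_000)
        oriented = extract_neighborhood(features, "focal", flank=10_000,
                                        orient_by_strand=True)
        assert [g.feature_id for g in plain.left_genes] == ["up"]
        assert [g.feature_id for g in oriented.left_genes] == ["down"]
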