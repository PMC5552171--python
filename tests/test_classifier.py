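"""Insertion classification: categories, ordinals, distances, chromatin, summaries."""

import math

import numpy as np
import pytest

from tgmap.classify import (
    AnnotationIndex,
    annotate_chromatin,
    chromatin_context,
    classify_site,
    cohort_summary,
)
from tgmap.errors import TgmapError
from tgmap.models import GeneModel, InsertionAnnotation, InsertionSite, TranscriptModel


def mk_gene(gene_id, chrom, strand, exons, cds=None):
    t = TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand, exons, cds or [])
    return GeneModel(gene_id, chrom, strand, (exons[0][0], exons[-1][1]), [t])


def site(chrom, left, mid="m"):
    return InsertionSite(mid, chrom, left, "+", "unique")


@pytest.fixture
def two_exon_gene_index():
    return AnnotationIndex([mk_gene("g1", "c1", "+", [(101, 200), (301, 400)])])


class TestClassifySite:
    def test_published_upstream_convention(self):
        # printed coordinates: insertion Gm18:39,611,234-39,611,235; gene
        # Glyma.18G169500 at 39,611,506-39,611,853 -> "272 bp upstream"
        gene = mk_gene("Glyma.18G169500", "Gm18", "+", [(39_611_506, 39_611_853)])
        ann = classify_site(site("Gm18", 39_611_234), AnnotationIndex([gene]))
        assert (ann.category, ann.distance, ann.gene_id) == (
            "upstream", 272, "Glyma.18G169500",
        )

    def test_intron_with_ordinal(self, two_exon_gene_index):
        ann = classify_site(site("c1", 250), two_exon_gene_index)
        assert (ann.category, ann.ordinal, ann.gene_id) == ("intron", 1, "g1")

    def test_exon_ordinals_strand_aware(self):
        exons = [(101, 200), (301, 400), (501, 600)]
        for strand, expected in (("+", 3), ("-", 1)):
            idx = AnnotationIndex([mk_gene("g", "c1", strand, exons)])
            ann = classify_site(site("c1", 550), idx)
            assert (ann.category, ann.ordinal) == ("exon", expected)

    def test_boundary_junction_assigned_to_left_feature(self, two_exon_gene_index):
        # junction between base 200 (last of exon 1) and 201 (first of intron 1)
        assert classify_site(site("c1", 200), two_exon_gene_index).category == "exon"
        # junction between base 300 (last of intron 1) and 301 (first of exon 2)
        assert classify_site(site("c1", 300), two_exon_gene_index).category == "intron"

    def test_gene_edges(self, two_exon_gene_index):
        up = classify_site(site("c1", 100), two_exon_gene_index)
        assert (up.category, up.distance) == ("upstream", 1)
        dn = classify_site(site("c1", 400), two_exon_gene_index)
        assert (dn.category, dn.distance) == ("downstream", 1)
        assert classify_site(site("c1", 101), two_exon_gene_index).category == "exon"

    def test_minus_strand_up_downstream_mirrored(self):
        idx = AnnotationIndex([mk_gene("g", "c1", "-", [(1_000, 2_000)])])
        ann = classify_site(site("c1", 2_100), idx)
        assert (ann.category, ann.distance) == ("upstream", 101)
        ann = classify_site(site("c1", 900), idx)
        assert (ann.category, ann.distance) == ("downstream", 100)

    def test_outside_window_is_intergenic(self, two_exon_gene_index):
        assert classify_site(site("c1", 5_000), two_exon_gene_index).category == "intergenic"

    def test_chromosome_without_genes_is_intergenic(self, two_exon_gene_index):
        assert classify_site(site("c9", 500), two_exon_gene_index).category == "intergenic"

    def test_nearest_gene_wins_ties_to_smaller_id(self):
        a = mk_gene("gA", "c1", "+", [(2_000, 2_500)])
        b = mk_gene("gB", "c1", "+", [(500, 900)])
        idx = AnnotationIndex([a, b])
        ann = classify_site(site("c1", 1_200), idx)  # 301 after gB, 800 before gA
        assert (ann.category, ann.gene_id, ann.distance) == ("downstream", "gB", 301)
        # equidistant: 100 after gB (left=1000) vs 100 before gA at 1100? use symmetric pair
        c = mk_gene("gC", "c1", "+", [(1_301, 1_700)])
        idx = AnnotationIndex([c, b])  # gB ends 900, gC starts 1301; left=1100
        ann = classify_site(site("c1", 1_100), idx)
        # downstream distance (1100+1)-900=201, upstream distance 1301-1100=201
        assert ann.distance == 201 and ann.gene_id == "gB"

    def test_refuses_unmapped_site(self, two_exon_gene_index):
        with pytest.raises(TgmapError):
            classify_site(
                InsertionSite("m", None, None, None, "multi"), two_exon_gene_index
            )

    def test_matches_per_base_oracle(self, toy_bundle):
        """Classification equals an independent per-base label array on a toy genome."""
        from tgmap.partition import select_longest_variant

        chrom = next(iter(toy_bundle.sequences))
        L = len(toy_bundle.sequences[chrom])
        window = 2_000
        # oracle: per-junction category via explicit arrays and linear scans
        feat = {}
        for g in toy_bundle.genes:
            t = select_longest_variant(g)
            for left in range(t.span[0], t.span[1]):
                lab = "intron"
                for xs, xe in t.exons:
                    if xs <= left <= xe:
                        lab = "exon"
                        break
                feat[left] = (lab, g.gene_id)
        idx = AnnotationIndex(toy_bundle.genes, window)
        genes = sorted(toy_bundle.genes, key=lambda g: g.start)
        for left in range(1, L, 7):  # stride keeps the scan fast, covers boundaries
            ann = classify_site(site(chrom, left), idx)
            if left in feat:
                assert (ann.category, ann.gene_id) == feat[left]
            else:
                cands = []
                for g in genes:
                    t = select_longest_variant(g)
                    s, e = t.span
                    if left < s and s - left <= window:
                        cands.append((s - left, g.gene_id,
                                      "upstream" if g.strand == "+" else "downstream"))
                    elif left >= e and left + 1 - e <= window:
                        cands.append((left + 1 - e, g.gene_id,
                                      "downstream" if g.strand == "+" else "upstream"))
                if cands:
                    d, gid, cat = sorted(cands)[0]
                    assert (ann.category, ann.gene_id, ann.distance) == (cat, gid, d)
                else:
                    assert ann.category == "intergenic"


class TestChromatinContext:
    PERI = [("c1", 5_000_001, 15_000_000)]

    def test_containment(self):
        assert chromatin_context(site("c1", 7_000_000), self.PERI) == "pericentromeric"

    def test_boundary_one_before_interval(self):
        assert chromatin_context(site("c1", 5_000_000), self.PERI) == "euchromatic"
        assert chromatin_context(site("c1", 5_000_001), self.PERI) == "pericentromeric"
        assert chromatin_context(site("c1", 15_000_000), self.PERI) == "pericentromeric"
        assert chromatin_context(site("c1", 15_000_001), self.PERI) == "euchromatic"

    def test_missing_chromosome_warns_euchromatic(self):
        with pytest.warns(UserWarning):
            assert chromatin_context(site("c9", 100), self.PERI) == "euchromatic"

    def test_empty_track_all_euchromatic(self):
        with pytest.warns(UserWarning):
            assert chromatin_context(site("c1", 100), []) == "euchromatic"


class TestCohortSummary:
    def test_published_percentages(self):
        anns = (
            [InsertionAnnotation(f"e{i}", "c1", i, "exon", "g", 1) for i in range(17)]
            + [InsertionAnnotation(f"i{i}", "c1", i, "intron", "g", 1) for i in range(10)]
            + [InsertionAnnotation(f"x{i}", "c1", i, "intergenic") for i in range(78)]
        )
        s = cohort_summary(anns)
        assert s["n"] == 105
        assert s["percent"]["exon"] == 16.2
        assert s["percent"]["intron"] == 9.5
        assert s["genic_percent"] == 25.7

    def test_empty_cohort_all_zero(self):
        s = cohort_summary([])
        assert s["n"] == 0 and s["genic_percent"] == 0.0
        assert s["euchromatic_percent"] is None

    def test_uniform_cohort_genic_rate_within_3se(self, small_bundle):
        from tgmap.partition import genome_partition
        from tgmap.synthetic import simulate_insertions

        totals, _ = genome_partition(small_bundle.genes, small_bundle.chromosome_lengths)
        idx = AnnotationIndex(small_bundle.genes)
        n = 10_000
        ins = simulate_insertions(small_bundle, n, seed=31)
        anns = [classify_site(site(t.chromosome, t.left, t.mutant_id), idx) for t in ins]
        anns = annotate_chromatin(anns, small_bundle.pericentromeres)
        s = cohort_summary(anns)
        g = totals.genic_fraction
        se = math.sqrt(g * (1 - g) / n)
        assert abs(s["genic_percent"] / 100 - g) < 3 * se
        assert sum(s["counts"].values()) == n  # categories partition the cohort
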