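"""Longest-variant selection and UTR/CDS/intron length accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgmap.errors import MalformedAnnotationError, UnknownChromosomeError
from tgmap.models import GeneModel, TranscriptModel
from tgmap.partition import (
    genome_partition,
    partition_transcript,
    select_longest_variant,
)


def mk_transcript(tid, exons, cds, strand="+", gene_id="g1", chrom="c1"):
    return TranscriptModel(tid, gene_id, chrom, strand, exons, cds)


def mk_gene(transcripts, gene_id="g1", chrom="c1", strand="+"):
    span = (min(t.exons[0][0] for t in transcripts), max(t.exons[-1][1] for t in transcripts))
    return GeneModel(gene_id, chrom, strand, span, transcripts)


class TestSelectLongestVariant:
    def test_strict_maximum_span(self):
        a = mk_transcript("m1", [(1, 3000)], [])
        b = mk_transcript("m2", [(1, 2400)], [])
        assert select_longest_variant(mk_gene([a, b])).transcript_id == "m1"
        assert select_longest_variant(mk_gene([b, a])).transcript_id == "m1"

    def test_single_transcript_identity(self):
        t = mk_transcript("only", [(10, 100)], [])
        assert select_longest_variant(mk_gene([t])) is t

    @pytest.mark.parametrize("order", [("m2", "m1"), ("m1", "m2")])
    def test_tie_breaks_to_smaller_id(self, order):
        ts = [mk_transcript(tid, [(1, 500)], []) for tid in order]
        assert select_longest_variant(mk_gene(ts)).transcript_id == "m1"

    def test_exonic_rule_differs_from_span_rule(self):
        # same span, different exonic content: the switchable rule matters
        a = mk_transcript("m1", [(1, 100), (901, 1000)], [])
        b = mk_transcript("m2", [(1, 1000)], [])
        g = mk_gene([a, b])
        assert select_longest_variant(g, by="span").transcript_id == "m1"  # tie -> id
        assert select_longest_variant(g, by="exonic").transcript_id == "m2"

    def test_zero_transcripts_rejected(self):
        g = GeneModel("g0", "c1", "+", (1, 10), [])
        with pytest.raises(MalformedAnnotationError):
            select_longest_variant(g)


class TestPartitionTranscript:
    def test_hand_computed_plus_strand(self):
        t = mk_transcript("t", [(101, 200), (301, 400)], [(151, 200), (301, 350)])
        p = partition_transcript(t)
        assert (p.full_length, p.cds_length, p.utr5_length, p.utr3_length, p.intron_length) == (
            300, 100, 50, 50, 100,
        )

    def test_minus_strand_swaps_utrs_by_symmetry(self):
        t = mk_transcript(
            "t", [(101, 200), (301, 400)], [(151, 200), (301, 350)], strand="-"
        )
        p = partition_transcript(t)
        assert (p.utr5_length, p.utr3_length) == (50, 50)
        assert (p.full_length, p.cds_length, p.intron_length) == (300, 100, 100)

    def test_asymmetric_utrs_flip_with_strand(self):
        exons, cds = [(1, 100), (201, 300)], [(81, 100), (201, 240)]
        plus = partition_transcript(mk_transcript("t", exons, cds, "+"))
        minus = partition_transcript(mk_transcript("t", exons, cds, "-"))
        assert (plus.utr5_length, plus.utr3_length) == (80, 60)
        assert (minus.utr5_length, minus.utr3_length) == (60, 80)

    def test_single_exon_fully_coding(self):
        p = partition_transcript(mk_transcript("t", [(1, 90)], [(1, 90)]))
        assert (p.full_length, p.cds_length, p.utr5_length, p.utr3_length, p.intron_length) == (
            90, 90, 0, 0, 0,
        )

    def test_noncoding_keeps_conservation_identity(self):
        p = partition_transcript(mk_transcript("t", [(1, 100), (201, 250)], []))
        assert not p.coding
        assert p.full_length == p.utr5_length + p.cds_length + p.utr3_length + p.intron_length

    def test_cds_outside_exons_rejected(self):
        t = mk_transcript("t", [(1, 100)], [(50, 150)])
        with pytest.raises(MalformedAnnotationError):
            partition_transcript(t)

    @given(data=st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_conservation_identity_property(self, data):
        n_exons = data.draw(st.integers(1, 5))
        pos = 1
        exons = []
        for _ in range(n_exons):
            length = data.draw(st.integers(1, 200))
            exons.append((pos, pos + length - 1))
            pos += length + data.draw(st.integers(1, 100))
        strand = data.draw(st.sampled_from("+-"))
        exonic = sum(e - s + 1 for s, e in exons)
        a = data.draw(st.integers(0, exonic - 1))
        b = data.draw(st.integers(a, exonic - 1))
        # map transcript-positions [a, b] to genomic CDS segments
        from tgmap.synthetic import _tx_slice

        cds = _tx_slice(exons, strand, a, b - a + 1)
        p = partition_transcript(mk_transcript("t", exons, cds, strand))
        assert p.full_length == p.utr5_length + p.cds_length + p.utr3_length + p.intron_length
        assert p.exon_length == exonic
        assert p.cds_length == b - a + 1


class TestGenomePartition:
    def test_empty_gene_list(self):
        totals, parts = genome_partition([], {"c1": 1000})
        assert totals.exon_fraction == 0.0 and totals.intron_fraction == 0.0
        assert parts == []

    def test_unknown_chromosome_names_the_gene(self):
        g = mk_gene([mk_transcript("t", [(1, 100)], [])], gene_id="orphan", chrom="scaffold_7")
        with pytest.raises(UnknownChromosomeError, match="orphan"):
            genome_partition([g], {"c1": 1000})

    def test_matches_per_base_labeling_oracle(self, toy_bundle):
        from tgmap.partition import select_longest_variant

        L = len(next(iter(toy_bundle.sequences.values())))
        label = np.zeros(L + 1, dtype=np.int8)  # 0 intergenic, 1 exon, 2 intron
        for g in toy_bundle.genes:
            t = select_longest_variant(g)
            s, e = t.span
            label[s : e + 1] = 2
            for xs, xe in t.exons:
                label[xs : xe + 1] = 1
        totals, _ = genome_partition(toy_bundle.genes, toy_bundle.chromosome_lengths)
        assert totals.total_exon == int((label == 1).sum())
        assert totals.total_intron == int((label == 2).sum())

    def test_dedup_mode_counts_shared_bases_once(self):
        t1 = mk_transcript("a.1", [(1, 100)], [], gene_id="a")
        t2 = mk_transcript("b.1", [(51, 150)], [], gene_id="b")
        genes = [mk_gene([t1], gene_id="a"), mk_gene([t2], gene_id="b")]
        per_gene, _ = genome_partition(genes, {"c1": 1000}, mode="per_gene")
        dedup, _ = genome_partition(genes, {"c1": 1000}, mode="dedup")
        assert per_gene.total_exon == 200  # paper-faithful: summed per gene
        assert dedup.total_exon == 150

    def test_synthetic_bundle_recovers_generator_targets(self, small_bundle):
        totals, _ = genome_partition(small_bundle.genes, small_bundle.chromosome_lengths)
        assert abs(totals.exon_fraction - small_bundle.spec.target_exon_fraction) < 0.01
        assert abs(totals.intron_fraction - small_bundle.spec.target_intron_fraction) < 0.01


def test_gff3_round_trip_preserves_partition(tmp_path, toy_bundle):
    from tgmap import io as tio

    path = tmp_path / "ann.gff3"
    tio.write_gff3(toy_bundle.genes, path)
    reread = tio.read_gff3(path)
    direct, _ = genome_partition(toy_bundle.genes, toy_bundle.chromosome_lengths)
    loaded, _ = genome_partition(reread, toy_bundle.chromosome_lengths)
    assert direct.total_exon == loaded.total_exon
    assert direct.total_intron == loaded.total_intron
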