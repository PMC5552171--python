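"""Gene-model partitioning: the random-insertion expectation.

For each gene the longest splice variant (greatest transcribed span) is
decomposed into 5'UTR, CDS, 3'UTR and intron lengths; summing these over all
gene models and dividing by the chromosome-mapped genome length yields the
expected exon and intron fractions under random insertion. The sum of the
5'UTR, CDS and 3'UTR lengths is the total exon length.

Two summing modes exist: ``per_gene`` (default) sums each gene independently,
so bases shared by overlapping gene models are counted once per gene;
``dedup`` counts each genomic base at most once (union of exon intervals;
intron = genic union minus exon union). Synthetic genomes have no overlapping
genes, so the modes agree there.
"""

from __future__ import annotations

from .errors import MalformedAnnotationError, UnknownChromosomeError
from .models import GeneModel, GenePartition, Interval, PartitionTotals, TranscriptModel, interval_len


def select_longest_variant(gene: GeneModel, by: str = "span") -> TranscriptModel:
    """The gene's representative transcript.

    ``by="span"`` (default) maximizes the transcribed span (region transcribed,
    first exon start to last exon end); ``by="exonic"`` maximizes summed exon
    length instead. Ties break to the lexicographically smallest transcript id.
    """
    if not gene.transcripts:
        raise MalformedAnnotationError(f"{gene.gene_id}: gene has zero transcripts")
    if by == "span":
        key = lambda t: (-t.span_length, t.transcript_id)
    elif by == "exonic":
        key = lambda t: (-t.exonic_length, t.transcript_id)
    else:
        raise ValueError(f"unknown longest-variant rule {by!r}")
    return sorted(gene.transcripts, key=key)[0]


def partition_transcript(t: TranscriptModel) -> GenePartition:
    """Decompose one transcript into UTR/CDS/intron lengths (strand-aware).

    The 5'UTR is the exonic sequence 5' of the first CDS base, the 3'UTR the
    exonic sequence 3' of the last CDS base; introns are everything transcribed
    but not exonic. A non-coding transcript (no CDS) keeps the conservation
    identity by reporting its whole exonic length as CDS with ``coding=False``.
    """
    t.validate()
    full = t.span_length
    exonic = t.exonic_length
    intron = full - exonic
    if not t.cds_segments:
        return GenePartition(t.gene_id, t.transcript_id, full, exonic, 0, 0, intron, coding=False)
    cds = sum(interval_len(c) for c in t.cds_segments)
    cds_gstart = min(s for s, _ in t.cds_segments)
    cds_gend = max(e for _, e in t.cds_segments)
    before = after = 0
    for s, e in t.exons:
        before += max(0, min(e, cds_gstart - 1) - s + 1)
        after += max(0, e - max(s, cds_gend + 1) + 1)
    if t.strand == "+":
        utr5, utr3 = before, after
    else:
        utr5, utr3 = after, before
    return GenePartition(t.gene_id, t.transcript_id, full, cds, utr5, utr3, intron)


def partition_gene(gene: GeneModel, by: str = "span") -> GenePartition:
    return partition_transcript(select_longest_variant(gene, by=by))


def _merge(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def genome_partition(
    genes: list[GeneModel],
    chromosome_lengths: dict[str, int],
    mode: str = "per_gene",
    by: str = "span",
) -> tuple[PartitionTotals, list[GenePartition]]:
    """Sum longest-variant partitions over all gene models.

    The denominator is the summed length of the listed (chromosome-mapped)
    sequences; a gene on an unlisted chromosome (e.g. an unplaced scaffold)
    raises rather than silently shifting the fractions.
    """
    genome_length = sum(chromosome_lengths.values())
    parts: list[GenePartition] = []
    for g in genes:
        if g.chromosome not in chromosome_lengths:
            raise UnknownChromosomeError(
                f"gene {g.gene_id} lies on {g.chromosome!r}, absent from the length table"
            )
        parts.append(partition_gene(g, by=by))
    if mode == "per_gene":
        total_exon = sum(p.exon_length for p in parts)
        total_intron = sum(p.intron_length for p in parts)
    elif mode == "dedup":
        total_exon = total_intron = 0
        by_chrom_exons: dict[str, list[Interval]] = {}
        by_chrom_spans: dict[str, list[Interval]] = {}
        for g in genes:
            t = select_longest_variant(g, by=by)
            by_chrom_exons.setdefault(g.chromosome, []).extend(t.exons)
            by_chrom_spans.setdefault(g.chromosome, []).append(t.span)
        for chrom in by_chrom_spans:
            exon_bp = sum(interval_len(iv) for iv in _merge(by_chrom_exons[chrom]))
            genic_bp = sum(interval_len(iv) for iv in _merge(by_chrom_spans[chrom]))
            total_exon += exon_bp
            total_intron += genic_bp - exon_bp
    else:
        raise ValueError(f"unknown partition mode {mode!r}")
    totals = PartitionTotals(
        total_exon=total_exon,
        total_intron=total_intron,
        genome_length=genome_length,
        n_genes=len(parts),
        n_noncoding=sum(1 for p in parts if not p.coding),
    )
    return totals, parts
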