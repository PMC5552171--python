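"""Classification of mapped insertions against annotation and chromatin context.

Each mapped junction (the inter-base gap between ``left`` and ``left+1``) is
assigned exactly one category — exon or intron (with a strand-aware ordinal
counted from the gene's 5' end), upstream or downstream of a gene within a
configurable window (with distance), or intergenic — always against each
gene's longest splice variant, consistently with the partition module.

Conventions (fixed and tested):
- a junction strictly inside a gene's transcribed span is genic; gene-body
  categories take precedence over a neighboring gene's upstream/downstream;
- a junction exactly on an exon/intron boundary belongs to the feature on its
  left (lower-coordinate) side, i.e. the feature containing base ``left``;
- upstream distance = gene_start − left for a + strand gene (this uniquely
  reproduces published adjacent-pair/gene-start bookkeeping), mirrored as
  (left+1) − gene_end for a − strand gene; downstream mirrored likewise;
- among several window hits the nearest gene wins, ties to the smaller
  gene_id; UTR bases count as exon.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right

from intervaltree import IntervalTree

from .errors import TgmapError
from .models import GeneModel, InsertionAnnotation, InsertionSite, TranscriptModel
from .partition import select_longest_variant

DEFAULT_WINDOW = 2_000


class AnnotationIndex:
    """Per-chromosome interval trees over longest-variant gene models."""

    def __init__(self, genes: list[GeneModel], window: int = DEFAULT_WINDOW):
        self.window = window
        self.representative: dict[str, TranscriptModel] = {}
        self.genes: dict[str, GeneModel] = {}
        self.body_trees: dict[str, IntervalTree] = {}
        self.near_trees: dict[str, IntervalTree] = {}
        for g in genes:
            t = select_longest_variant(g)
            self.representative[g.gene_id] = t
            self.genes[g.gene_id] = g
            span_s, span_e = t.span
            bt = self.body_trees.setdefault(g.chromosome, IntervalTree())
            nt = self.near_trees.setdefault(g.chromosome, IntervalTree())
            # interval tree is half-open; store [start, end+1)
            bt[span_s : span_e + 1] = g.gene_id
            nt[max(1, span_s - window) : span_e + 1 + window] = g.gene_id


def _feature_at(t: TranscriptModel, base: int) -> tuple[str, int]:
    """(category, ordinal) of the exon/intron containing ``base`` (genomic order),
    with ordinals counted from the gene's 5' end."""
    starts = [s for s, _ in t.exons]
    i = bisect_right(starts, base) - 1  # last exon starting at or before base
    n_exons = len(t.exons)
    if i >= 0 and t.exons[i][0] <= base <= t.exons[i][1]:
        genomic_ordinal = i + 1
        ordinal = genomic_ordinal if t.strand == "+" else n_exons - i
        return "exon", ordinal
    # in the intron after exon i (genomic order)
    genomic_intron = i + 1  # 1-based, between exon i and i+1
    ordinal = genomic_intron if t.strand == "+" else n_exons - genomic_intron
    return "intron", ordinal


def classify_site(
    site: InsertionSite, index: AnnotationIndex, window: int | None = None
) -> InsertionAnnotation:
    """Assign the single category of one unique-mapped insertion."""
    if site.mapping_status != "unique":
        raise TgmapError(
            f"{site.mutant_id}: cannot classify a {site.mapping_status} site"
        )
    window = index.window if window is None else window
    chrom, left = site.chromosome, site.left

    body = index.body_trees.get(chrom, IntervalTree())[left] if chrom in index.body_trees else set()
    inside = []
    for iv in body:
        g = index.genes[iv.data]
        t = index.representative[iv.data]
        if t.span[0] <= left < t.span[1]:  # junction strictly inside the span
            inside.append(iv.data)
    if inside:
        gene_id = sorted(inside)[0]
        t = index.representative[gene_id]
        category, ordinal = _feature_at(t, left)  # left-side rule at boundaries
        return InsertionAnnotation(
            site.mutant_id, chrom, left, category, gene_id=gene_id, ordinal=ordinal
        )

    near = index.near_trees.get(chrom, IntervalTree())[left] if chrom in index.near_trees else set()
    candidates = []  # (distance, gene_id, category)
    for iv in near:
        gene_id = iv.data
        t = index.representative[gene_id]
        s, e = t.span
        if left < s:
            d = s - left
            category = "upstream" if t.strand == "+" else "downstream"
        elif left >= e:
            d = (left + 1) - e
            category = "downstream" if t.strand == "+" else "upstream"
        else:
            continue
        if 1 <= d <= window:
            candidates.append((d, gene_id, category))
    if candidates:
        d, gene_id, category = sorted(candidates)[0]
        return InsertionAnnotation(
            site.mutant_id, chrom, left, category, gene_id=gene_id, distance=d
        )
    return InsertionAnnotation(site.mutant_id, chrom, left, "intergenic")


def chromatin_context(
    site: InsertionSite | InsertionAnnotation,
    pericentromeres: list[tuple[str, int, int]],
) -> str:
    """euchromatic / pericentromeric by containment of the left coordinate."""
    chrom, left = site.chromosome, site.left
    listed = {c for c, _, _ in pericentromeres}
    if chrom not in listed:
        warnings.warn(f"chromosome {chrom!r} absent from the pericentromere track; "
                      "calling euchromatic")
        return "euchromatic"
    for c, s, e in pericentromeres:
        if c == chrom and s <= left <= e:
            return "pericentromeric"
    return "euchromatic"


def annotate_chromatin(
    annotations: list[InsertionAnnotation],
    pericentromeres: list[tuple[str, int, int]],
) -> list[InsertionAnnotation]:
    for a in annotations:
        a.chromatin = chromatin_context(a, pericentromeres)
    return annotations


CATEGORIES = ("exon", "intron", "upstream", "downstream", "intergenic")


def cohort_summary(annotations: list[InsertionAnnotation]) -> dict:
    """Counts and percentages by category and chromosome (1 decimal place).

    The genic percentage (exon + intron) is the headline number compared with
    the genome's genic fraction under random insertion.
    """
    n = len(annotations)
    counts = {c: 0 for c in CATEGORIES}
    by_chrom: dict[str, int] = {}
    eu = pc = 0
    for a in annotations:
        counts[a.category] += 1
        by_chrom[a.chromosome] = by_chrom.get(a.chromosome, 0) + 1
        if a.chromatin == "euchromatic":
            eu += 1
        elif a.chromatin == "pericentromeric":
            pc += 1
    pct = {c: round(100.0 * counts[c] / n, 1) if n else 0.0 for c in CATEGORIES}
    genic = counts["exon"] + counts["intron"]
    return {
        "n": n,
        "counts": counts,
        "percent": pct,
        "genic_count": genic,
        "genic_percent": round(100.0 * genic / n, 1) if n else 0.0,
        "by_chromosome": dict(sorted(by_chrom.items())),
        "euchromatic_count": eu,
        "pericentromeric_count": pc,
        "euchromatic_percent": round(100.0 * eu / (eu + pc), 1) if (eu + pc) else None,
    }
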