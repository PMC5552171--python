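"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout the in-memory model (GFF3
convention); conversions to BED's 0-based half-open intervals happen only at
I/O boundaries. An insertion is stored as the adjacent coordinate pair
(left, left+1): the element sits in the inter-base gap between the two
reference bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InfeasibleSpecError, MalformedAnnotationError

Interval = tuple[int, int]  # 1-based inclusive (start, end)


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """One splice variant: ordered exon and CDS intervals on a chromosome.

    ``exons`` are sorted by genomic coordinate and non-overlapping; every CDS
    segment must be contained in some exon. The transcribed span runs from the
    first exon start to the last exon end.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[Interval]
    cds_segments: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def span_length(self) -> int:
        return self.exons[-1][1] - self.exons[0][0] + 1

    @property
    def exonic_length(self) -> int:
        return sum(interval_len(e) for e in self.exons)

    def validate(self) -> None:
        if not self.exons:
            raise MalformedAnnotationError(f"{self.transcript_id}: no exons")
        if self.strand not in "+-":
            raise MalformedAnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise MalformedAnnotationError(f"{self.transcript_id}: inverted exon {s}-{e}")
            if s <= prev_end:
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at {s}-{e}"
                )
            prev_end = e
        for cs, ce in self.cds_segments:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise MalformedAnnotationError(
                    f"{self.transcript_id}: CDS segment {cs}-{ce} outside exons"
                )


@dataclass
class GeneModel:
    """A stranded gene with one or more splice variants."""

    gene_id: str
    chromosome: str
    strand: str
    span: Interval
    transcripts: list[TranscriptModel]

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    def validate(self) -> None:
        if not self.transcripts:
            raise MalformedAnnotationError(f"{self.gene_id}: gene has zero transcripts")
        for t in self.transcripts:
            t.validate()
            if t.span[0] < self.span[0] or t.span[1] > self.span[1]:
                raise MalformedAnnotationError(
                    f"{self.gene_id}: transcript {t.transcript_id} outside gene span"
                )


# ---------------------------------------------------------------------------
# Partition results
# ---------------------------------------------------------------------------


@dataclass
class GenePartition:
    """Length decomposition of one gene's representative transcript.

    Conservation identity: full = utr5 + cds + utr3 + intron. For non-coding
    transcripts the entire exonic length is carried in ``cds_length`` (with
    ``coding=False``) so the identity still holds; reports flag these genes.
    """

    gene_id: str
    transcript_id: str
    full_length: int
    cds_length: int
    utr5_length: int
    utr3_length: int
    intron_length: int
    coding: bool = True

    @property
    def exon_length(self) -> int:
        return self.utr5_length + self.cds_length + self.utr3_length


@dataclass
class PartitionTotals:
    """Genome-wide summed lengths: the random-insertion expectation."""

    total_exon: int
    total_intron: int
    genome_length: int
    n_genes: int = 0
    n_noncoding: int = 0

    @property
    def exon_fraction(self) -> float:
        return self.total_exon / self.genome_length if self.genome_length else 0.0

    @property
    def intron_fraction(self) -> float:
        return self.total_intron / self.genome_length if self.genome_length else 0.0

    @property
    def genic_fraction(self) -> float:
        return self.exon_fraction + self.intron_fraction

    def as_dict(self) -> dict:
        return {
            "total_exon": self.total_exon,
            "total_intron": self.total_intron,
            "genome_length": self.genome_length,
            "n_genes": self.n_genes,
            "n_noncoding": self.n_noncoding,
            "exon_fraction": round(self.exon_fraction, 6),
            "intron_fraction": round(self.intron_fraction, 6),
            "genic_fraction": round(self.genic_fraction, 6),
        }


# ---------------------------------------------------------------------------
# Synthetic genome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the synthetic genome emulating the study's composition.

    Defaults mirror the soybean Wm82.a2 assembly statistics used as the
    random-insertion expectation: 11.6% exon, 10.5% intron, and
    pericentromeric heterochromatin covering 57% of the genome (euchromatin
    43%).
    """

    n_chromosomes: int = 4
    chromosome_length: int = 2_000_000
    target_exon_fraction: float = 0.116
    target_intron_fraction: float = 0.105
    pericentromere_fraction: float = 0.57
    mean_exons_per_gene: int = 5
    multi_isoform_gene_fraction: float = 0.3
    gc_content: float = 0.35
    seed: int = 42

    def validate(self) -> None:
        for name in (
            "target_exon_fraction",
            "target_intron_fraction",
            "pericentromere_fraction",
            "multi_isoform_gene_fraction",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleSpecError(f"{name}={v} outside [0, 1]")
        if self.target_exon_fraction + self.target_intron_fraction >= 1.0:
            raise InfeasibleSpecError("exon + intron fractions must be < 1")
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise InfeasibleSpecError("chromosome count and length must be positive")
        if self.mean_exons_per_gene <= 0:
            raise InfeasibleSpecError("mean_exons_per_gene must be positive")
        if self.target_exon_fraction == 0.0 and self.target_intron_fraction > 0.0:
            raise InfeasibleSpecError("introns require exons (genes must transcribe something)")


@dataclass
class PrimerSite:
    """An element-internal primer binding site.

    ``offset`` is the distance (bp) from the assayed element terminus to the
    element-distal edge of the site, i.e. the element-sequence contribution of
    a product primed here.
    """

    offset: int
    length: int


@dataclass
class ElementSpec:
    """The transposable element as the display assay sees it.

    A CACTA-family class II element: 20,548 bp by default, bounded by short
    terminal inverted repeats, with nested display primers (outer R1, nested
    R2) binding near one terminus. R2 must sit closer to the terminus than R1.
    ``tsd_length`` is the target-site duplication created on insertion.
    """

    sequence: str
    tir_length: int = 13
    primer_sites: dict[str, PrimerSite] = field(default_factory=dict)
    assay_end: str = "5p"  # which element terminus carries the display primers
    tsd_length: int = 3

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if self.assay_end not in ("5p", "3p"):
            raise ValueError(f"assay_end must be 5p or 3p, got {self.assay_end!r}")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        for name, ps in self.primer_sites.items():
            if not 0 < ps.offset <= self.length:
                raise ValueError(f"primer {name} lies outside the element")
            if ps.length <= 0 or ps.length > ps.offset:
                raise ValueError(f"primer {name}: bad length {ps.length}")
        if "R1" in self.primer_sites and "R2" in self.primer_sites:
            if self.primer_sites["R2"].offset >= self.primer_sites["R1"].offset:
                raise ValueError("nested primer R2 must be closer to the terminus than outer R1")


@dataclass
class GenomeBundle:
    """A generated genome: sequences, annotation, chromatin track, residual copies."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    pericentromeres: list[tuple[str, int, int]]
    residual_copies: list[tuple[str, int, int]]  # (chromosome, start, length), 1-based
    spec: SyntheticGenomeSpec | None = None

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class TrueInsertion:
    """Simulator ground truth: the element sits between ``left`` and ``left+1``."""

    mutant_id: str
    chromosome: str
    left: int
    orientation: str = "+"


@dataclass
class ElementCopy:
    """An element occurrence inside a mutant genome (mutant coordinates)."""

    chromosome: str
    start: int
    end: int
    orientation: str
    kind: str  # "new" | "residual"
    has_primer_end: bool = True


@dataclass
class MutantGenome:
    """Per-mutant sequences plus the locations of all element copies."""

    mutant_id: str
    sequences: dict[str, str]
    copies: list[ElementCopy]


# ---------------------------------------------------------------------------
# Display / mapping / classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A blunt-end cutter: cuts after ``cut_offset`` bases of each site occurrence."""

    name: str
    recognition_sequence: str
    cut_offset: int

    def __post_init__(self):
        if not 0 < self.cut_offset < len(self.recognition_sequence):
            raise ValueError(f"{self.name}: cut_offset outside recognition sequence")


@dataclass
class Fragment:
    """One restriction fragment; fragments tile their source sequence exactly."""

    source: str
    start: int  # 1-based inclusive on the digested sequence
    end: int
    sequence: str


@dataclass
class DisplayBand:
    """A predicted nested-PCR product from the in-silico transposon display."""

    sample_id: str
    enzyme: str
    product_length: int
    source_locus: tuple[str, int] | str  # (chromosome, mutant-coord junction left) or "residual"
    element_part: str  # element sequence from the junction inward (terminus first)
    flank: str  # genomic sequence reading away from the element (junction at 5' end)
    unique: bool | None = None
    flank_match_strand: str | None = None


@dataclass
class InsertionSite:
    """A mapped insertion: 1-based adjacent pair (left, left+1)."""

    mutant_id: str
    chromosome: str | None
    left: int | None
    strand: str | None
    mapping_status: str  # "unique" | "multi" | "unmapped"

    @property
    def right(self) -> int | None:
        return None if self.left is None else self.left + 1


@dataclass
class InsertionAnnotation:
    """Classification of one insertion against the gene annotation and chromatin track."""

    mutant_id: str
    chromosome: str
    left: int
    category: str  # exon | intron | upstream | downstream | intergenic
    gene_id: str | None = None
    ordinal: int | None = None  # exon/intron number from the gene's 5' end
    distance: int | None = None  # bp, upstream/downstream only
    chromatin: str | None = None  # euchromatic | pericentromeric


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class ChiSqResult:
    mode: str  # "paper_faithful" | "count_based"
    observed: tuple
    expected: tuple
    statistic: float
    df: int
    p_value: float

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "observed": list(self.observed),
            "expected": [round(x, 6) for x in self.expected],
            "statistic": round(self.statistic, 6),
            "df": self.df,
            "p_value": round(self.p_value, 6),
        }


@dataclass
class HotspotRegion:
    chromosome: str
    start: int
    end: int
    insertion_count: int
    mutant_ids: list[str]

    @property
    def span(self) -> int:
        return self.end - self.start + 1
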