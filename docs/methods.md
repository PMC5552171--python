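# Methods

## The system being modeled

A single active CACTA-family DNA transposon (20,548 bp, bounded by short
terminal inverted repeats beginning with the conserved CACTA motif) excises
from a reporter locus and reinserts elsewhere in the genome, one new
insertion per germinal-revertant mutant. The computational task is to recover
each insertion's junction coordinate from a transposon-display assay, place
it in its gene-annotation and chromatin context, and test the null hypothesis
that insertions hit exon and intron sequence at the rate expected from the
genome's composition.

## Genome partition (the random-insertion expectation)

For every gene, one representative transcript — the *longest splice variant*,
defined as the variant with the greatest transcribed span (first exon start
to last exon end) — is decomposed into 5′UTR, CDS, 3′UTR and intron lengths.
The identity `full = utr5 + cds + utr3 + intron` is asserted for every gene;
`exon = utr5 + cds + utr3`. Summing over all gene models and dividing by the
summed length of the chromosome-mapped sequences (unplaced scaffolds are
rejected, not silently dropped) yields the exon and intron fractions used as
the expectation under random insertion.

Choices made where the convention was genuinely open:

- *Longest variant*: greatest transcribed span, not greatest summed exon
  length; the alternative is implemented and switchable (`by="exonic"`)
  because the two differ for variants that skip internal exons.
- *Non-coding transcripts*: their whole exonic length is reported in the CDS
  slot with a `coding=False` flag, keeping the conservation identity; reports
  count these genes separately.
- *Overlapping genes*: the default (`per_gene`) sums each gene independently,
  so shared bases can be counted more than once — this mirrors summing
  per-gene values without deduplication. A `dedup` mode counts each base at
  most once. Synthetic genomes have non-overlapping genes, so the modes
  coincide there.

## Display simulation

The assay is modeled as geometry, not chemistry. Each mutant genome is
digested with four blunt cutters (DraI TTT^AAA, EcoRV GAT^ATC, PvuII
CAG^CTG, StuI AGG^CCT — all palindromic central cutters, so cut geometry is
strand-symmetric); every cut is an adaptor-ligation site. Only the element
end carrying the display primers is assayed (single-side display, one
element-specific primer pair): a band is emitted for an element copy iff the
fragment containing the primer-bearing terminus carries both complete primer
sites (outer R1 at 222 bp, nested R2 at 132 bp from the terminus; exact,
full-length binding — no mismatch model) and ends in a genomic cut beyond the
junction. The nested product length is

    product = R2 offset + genomic flank length + adaptor-primer contribution (25 bp).

The amplifiable window (default 100–6,000 bp) is applied to this product
length rather than to the raw restriction fragment, since PCR length limits
constrain the amplicon, not the fragment. Nesting is modeled as a constraint
(R1 must also sit inside the fragment) rather than as two explicit
amplifications, because only the nested product is observable on the gel.

Bands are compared across samples: a band is *common* iff every sample shows
a band of the same enzyme within a configurable length tolerance (default 0
— in-silico lengths are exact; a "gel mode" tolerance exists for realism).
Residual truncated element copies are fixed in the background genome and
identical in every mutant, so they surface as common bands; new insertions
give unique bands. A unique band is validated like a sequenced product: it
must carry more than 100 bp exactly matching the element terminus, and its
genomic-side flank is passed to the mapper.

Which element terminus (5′ or 3′) the primers target is not determinate
biology here; it is a configuration axis (`assay_end`, default `5p`).

## Flank mapping and the junction convention

The mapper is an exact seed-and-extend search: a 2-bit-packed k-mer index
(default k = 21; small k allowed for toy inputs) over the forward strand,
seeds from both ends of the query, full-length verification on both strands
with at most `max_mismatches` mismatches (default 0). A unique best hit
yields the insertion as the 1-based adjacent pair (left, left+1) — the
element sits in the inter-base gap. The caller states which flank end is
element-proximal (`junction_end`); strand symmetry holds as
`map(x, "5p") == map(revcomp(x), "3p")`.

Insertion creates a target-site duplication (default 3 bp, configurable —
the duplication length is a family-level convention, not measured here): the
bases immediately left of the junction recur on the element's far side. Both
flanks therefore remain contiguous reference substrings, but the two element
boundaries differ by the duplication length; the raw mapper reports the
element-proximal boundary of whichever side it saw. The pipeline, which
knows the configured duplication length and the flank-match strand,
canonicalizes every call to the left junction, so recovered coordinates are
directly comparable with simulator truth (and with published adjacent-pair
notation, which never resolves this ±3 bp ambiguity).

## Classification

A junction strictly inside a gene's transcribed span is exonic or intronic
by the feature containing the base `left` — i.e. a junction exactly on a
feature boundary belongs to the feature on its lower-coordinate side (an
arbitrary but fixed, tested convention). Ordinals count exons/introns from
the gene's 5′ end, strand-aware. Outside gene bodies, a gene within the
window (default 2,000 bp; the window is unbounded in the source convention,
so it is explicit configuration) gives upstream/downstream with

    distance = gene_start − left        (+ strand, upstream; mirrored elsewhere)

— the unique convention that reproduces the published "272 bp upstream" from
the printed coordinate pair and gene start. Gene-body categories take
precedence over a neighbor's upstream/downstream; among several window hits
the nearest gene wins, ties to the smaller gene id. UTR bases count as exon,
consistently with the partition. Chromatin context is containment of `left`
in any pericentromere interval; a chromosome absent from the track is called
euchromatic with a warning.

## Randomness statistics

Two χ² forms are reported side by side:

- *Percentage-scale, df = 1* (`chisq_paper`): Σ over {exon, intron} of
  (obs% − exp%)²/exp%. This is the arithmetic that reproduces the published
  statistic (1.92 from observed 16.2/9.5 vs expected 11.6/10.5). It is kept
  for reproduction only: a percentage-scale statistic does not scale with
  sample size and is not a calibrated test. (The source prints 1.92 in the
  text and 1.7752 in a figure caption for the same comparison; this package
  reproduces the in-text value and does not guess the caption's inputs.)
- *Count-based, df = 2* (`chisq_counts`): the standard multinomial
  goodness-of-fit over (exon, intron, other) counts. Its type-I error at
  α = 0.05 is verified by simulation (1,000 null cohorts of n = 105) to lie
  in [0.03, 0.08].

p-values come from the χ² upper tail, no continuity correction. Hotspots are
maximal sets of ≥ `min_count` insertions whose tight span is ≤ `window`
(default 1 Mb, boundary inclusive), found by a two-pointer sweep per
chromosome and verified against exhaustive window enumeration; overlapping
qualifying sets are merged, so a merged region's span may exceed the window.
On scaled-down genomes the 1 Mb default is broad relative to chromosome
length and merges readily; for genome-scale data the default matches the
cluster sizes the method is meant to find.

## The synthetic-data generator

The generator emulates the *statistical structure* the pipeline depends on,
not sequence biology. Defaults are the study conditions: exon fraction
0.116, intron fraction 0.105, pericentromeric fraction 0.57 (one contiguous
central block per chromosome), 4 chromosomes × 2 Mb (a scaled-down stand-in
for a ~1 Gb assembly, chosen so the full cohort runs in seconds), mean 5
exons per gene, 30% of genes with a second splice variant (truncated or
exon-skipping, so longest-variant selection is exercised), GC content 0.35
(legume-like, which also sets realistic restriction-site densities), one
3′-truncated residual element copy (2.5 kb, retaining the primer-bearing
terminus so it yields common bands). Exon/intron base budgets are allocated
exactly before placement, so realized fractions equal targets to rounding —
the composition recovery is tested through the partition module as oracle.

Genes are non-overlapping and separated by ≥ 1 bp on both strands, so
classification is single-valued; insertion orientation is drawn 50/50 (no
orientation bias is asserted as biology).

The cohort generator reproduces the study's ascertainment: the published
sites are by definition the recoverable ones, so the n − 19 "recoverable"
insertions are drawn from the insertion model conditional on actual
display-and-mapping recoverability (each candidate is verified by running
digestion, band prediction, validation and mapping against truth), and the
19 unrecoverable mutants get their flank reads replaced by noise. This
conditioning slightly biases recoverable sites toward regions with nearby
restriction sites — exactly as in the real assay — and is not used by the
mapper correctness tests, which run on unconditioned insertions.

What passing tests on synthetic data do **not** show: behavior on real
repeat landscapes (paralogy, nested elements, multi-mapping flanks are rare
in random sequence), annotation pathologies (trans-splicing, overlapping
gene models are only covered by targeted unit tests), chromosome-scale
insertion biases, or the element's real chromatin preference — the uniform
null deliberately lacks it, which is why a simulated cohort's euchromatic
fraction sits near the genome's euchromatin share rather than the elevated
fraction a real element shows.

## Numerical and degenerate-input conventions

Deterministic outputs under a fixed seed (byte-identical files, tested); all
randomness flows from one `numpy` generator per run. Empty inputs return
empty results (empty cohort → all-zero summary, undefined euchromatic
fraction reported as missing); a zero expectation makes χ² an explicit
error, not NaN; a flank shorter than the seed length is an error distinct
from "unmapped"; a single-sample band comparison warns and flags everything
unique. Coordinates are 1-based inclusive in memory and in GFF3, converted
to 0-based half-open only at BED boundaries (round-tripped in tests).

## Known limitations

- Primer binding is exact and full-length; degenerate or mismatched binding
  and PCR chemistry (efficiency, bias, polymerase error) are out of scope.
- Only one element terminus is assayed; the opposite junction is not
  simulated.
- The mapper is not a general read aligner: no gaps, no qualities, no SAM.
- Cross-assembly coordinate reporting (dual-assembly studies) is out of
  scope; one reference per run.
- The percentage-scale χ² is reproduction-only, as discussed above.
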