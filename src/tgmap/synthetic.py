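"""Synthetic genome, annotation, and insertion-cohort generation.

Builds reproducible multi-chromosome genomes whose exon/intron composition,
pericentromere geometry, splice-variant structure, and residual (truncated,
immobile) element copies emulate the statistical structure of the soybean
study system, so every downstream stage — display simulation, flank mapping,
classification, randomness statistics — is testable without downloads.

Exon and intron base totals are allocated exactly (to rounding of the target
fraction times chromosome length) before genes are placed, so the realized
composition of a generated genome matches the requested fractions to within
one part per chromosome length.
"""

from __future__ import annotations

import numpy as np

from .display import DEFAULT_ENZYMES
from .errors import InfeasibleSpecError, OverlapError
from .models import (
    ElementCopy,
    ElementSpec,
    GeneModel,
    GenomeBundle,
    Interval,
    MutantGenome,
    PrimerSite,
    SyntheticGenomeSpec,
    TranscriptModel,
    TrueInsertion,
)
from .seq import find_occurrences, random_dna, revcomp

AVG_EXON_LEN = 240
MIN_EXON_LEN = 60
MIN_INTRON_LEN = 60
MIN_INTERGENIC_GAP = 2
DEFAULT_RESIDUAL_LENGTH = 2_500


# ---------------------------------------------------------------------------
# Element construction
# ---------------------------------------------------------------------------


def _scrub_enzyme_sites(seq: str, margin: int) -> str:
    """Mutate away default-enzyme recognition sites within ``margin`` bp of both ends.

    Keeps the region between the display primers and the element terminus free
    of cuts, so the primer-bearing fragment always spans the junction.
    """
    order = "ACGT"
    chars = list(seq)
    for _ in range(50):  # bounded; converges in a couple of passes
        text = "".join(chars)
        dirty = False
        for enz in DEFAULT_ENZYMES.values():
            m = enz.recognition_sequence
            for i in find_occurrences(text, m):
                if i < margin or i + len(m) > len(text) - margin:
                    j = i + len(m) // 2
                    chars[j] = order[(order.index(chars[j]) + 1) % 4]
                    dirty = True
        if not dirty:
            return "".join(chars)
    return "".join(chars)


def default_element(
    length: int = 20_548,
    seed: int = 20_548,
    tsd_length: int = 3,
    assay_end: str = "5p",
) -> ElementSpec:
    """Build the default CACTA-type element: 20,548 bp, terminal inverted
    repeats starting with the conserved CACTA motif, and nested display
    primers R1 (outer, 222 bp from the assayed terminus) and R2 (nested,
    132 bp) so a validated product carries >100 bp of element-end evidence.
    """
    rng = np.random.default_rng(seed)
    tir = "CACTA" + random_dna(rng, 8, 0.4)
    core = random_dna(rng, length - 2 * len(tir), 0.42)
    seq = _scrub_enzyme_sites(tir + core + revcomp(tir), 400)
    element = ElementSpec(
        sequence=seq,
        tir_length=len(tir),
        primer_sites={"R1": PrimerSite(222, 22), "R2": PrimerSite(132, 22)},
        assay_end=assay_end,
        tsd_length=tsd_length,
    )
    element.validate()
    return element


# ---------------------------------------------------------------------------
# Gene-structure allocation
# ---------------------------------------------------------------------------


def _split_total(rng: np.random.Generator, total: int, parts: int, min_len: int) -> np.ndarray:
    """Random composition of ``total`` into ``parts`` integers, each >= min_len."""
    if parts == 0:
        if total != 0:
            raise InfeasibleSpecError("cannot allocate bases to zero parts")
        return np.zeros(0, dtype=int)
    extra = total - parts * min_len
    if extra < 0:
        raise InfeasibleSpecError(f"cannot split {total} bp into {parts} parts of >= {min_len} bp")
    weights = rng.dirichlet(np.ones(parts))
    return rng.multinomial(extra, weights) + min_len


def _draw_gene_structs(
    rng: np.random.Generator, exon_bp: int, intron_bp: int, mean_exons: int
) -> list[tuple[list[int], list[int]]]:
    """Allocate exact exon/intron base budgets into per-gene structures."""
    if exon_bp <= 0:
        if intron_bp > 0:
            raise InfeasibleSpecError("intron bases requested without exon bases")
        return []
    n_genes = max(1, int(round(exon_bp / (mean_exons * AVG_EXON_LEN))))
    k = 1 + rng.poisson(max(mean_exons - 1, 0), n_genes)
    k = np.maximum(k, 1)
    if intron_bp == 0:
        k[:] = 1
    elif (k <= 1).all():
        k[0] = 2
    while k.sum() * MIN_EXON_LEN > exon_bp and len(k) > 1:
        k = k[:-1]
        if intron_bp > 0 and (k <= 1).all():
            k[0] = 2
    while k.sum() * MIN_EXON_LEN > exon_bp and k.max() > 1:
        k[int(np.argmax(k))] -= 1
    if k.sum() * MIN_EXON_LEN > exon_bp:
        if intron_bp > 0:
            raise InfeasibleSpecError("exon budget too small to host any intron")
        return [([exon_bp], [])]
    n_slots = int((k - 1).sum())
    while intron_bp and n_slots > intron_bp:  # degenerate tiny budgets
        j = int(np.argmax(k))
        k[j] -= 1
        n_slots -= 1
    exon_lens = _split_total(rng, exon_bp, int(k.sum()), MIN_EXON_LEN)
    if n_slots > 0:
        min_intron = MIN_INTRON_LEN if intron_bp >= n_slots * MIN_INTRON_LEN else 1
        intron_lens = _split_total(rng, intron_bp, n_slots, min_intron)
    else:
        intron_lens = np.zeros(0, dtype=int)
    structs = []
    ei = ii = 0
    for kj in k:
        structs.append(
            (
                [int(x) for x in exon_lens[ei : ei + kj]],
                [int(x) for x in intron_lens[ii : ii + kj - 1]],
            )
        )
        ei += kj
        ii += kj - 1
    return structs


def _tx_slice(exons: list[Interval], strand: str, offset: int, length: int) -> list[Interval]:
    """Genomic intervals of the transcript-coordinate window [offset+1, offset+length]."""
    if length <= 0:
        return []
    tx_order = exons if strand == "+" else list(reversed(exons))
    lo, hi = offset + 1, offset + length
    out = []
    c = 0
    for s, e in tx_order:
        n = e - s + 1
        a, b = max(lo, c + 1), min(hi, c + n)
        if a <= b:
            if strand == "+":
                out.append((s + (a - c - 1), s + (b - c - 1)))
            else:
                out.append((e - (b - c - 1), e - (a - c - 1)))
        c += n
    out.sort()
    return out


def _clip_to_exons(segments: list[Interval], exons: list[Interval]) -> list[Interval]:
    out = []
    for cs, ce in segments:
        for s, e in exons:
            a, b = max(cs, s), min(ce, e)
            if a <= b:
                out.append((a, b))
    out.sort()
    return out


def _make_gene(
    chrom: str,
    idx: int,
    start: int,
    exon_lens: list[int],
    intron_lens: list[int],
    rng: np.random.Generator,
    multi_isoform_fraction: float,
) -> GeneModel:
    exons: list[Interval] = []
    pos = start
    for j, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if j < len(intron_lens):
            pos += intron_lens[j]
    strand = "+" if rng.random() < 0.5 else "-"
    gene_id = f"{chrom}g{idx:05d}"

    exonic = sum(e - s + 1 for s, e in exons)
    if exonic >= 120:
        utr5 = int(rng.integers(20, min(250, exonic // 4) + 1))
        utr3 = int(rng.integers(20, min(300, exonic // 4) + 1))
        cds_len = exonic - utr5 - utr3
        cds_len -= cds_len % 3
        utr3 = exonic - utr5 - cds_len
    else:
        utr5, cds_len = 0, exonic
    cds = _tx_slice(exons, strand, utr5, cds_len)
    primary = TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand, list(exons), cds)

    transcripts = [primary]
    if len(exons) >= 2 and rng.random() < multi_isoform_fraction:
        # Alternative variant: truncate the 3'-most exon (shorter span, exercises
        # longest-variant selection) or skip an internal exon (same span; the
        # id tie-break keeps the primary representative).
        if len(exons) >= 3 and rng.random() < 0.5:
            drop = int(rng.integers(1, len(exons) - 1))
            exons2 = [iv for j, iv in enumerate(exons) if j != drop]
        else:
            exons2 = exons[:-1] if strand == "+" else exons[1:]
        cds2 = _clip_to_exons(cds, exons2)
        transcripts.append(TranscriptModel(f"{gene_id}.2", gene_id, chrom, strand, exons2, cds2))

    gene = GeneModel(gene_id, chrom, strand, (exons[0][0], exons[-1][1]), transcripts)
    gene.validate()
    return gene


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(
    spec: SyntheticGenomeSpec,
    element: ElementSpec | None = None,
    residual_length: int = DEFAULT_RESIDUAL_LENGTH,
) -> GenomeBundle:
    """Generate a deterministic genome bundle from ``spec``.

    Per chromosome, exon/intron budgets of round(fraction * length) bp are
    allocated into non-overlapping genes on both strands, a configurable
    fraction of which carry a second, shorter splice variant; intergenic space
    is distributed randomly; one contiguous central pericentromere covers the
    requested fraction; and (if ``residual_length`` > 0) one 3'-truncated
    residual element copy retaining the primer-bearing terminus is planted in
    the largest intergenic gap of the first chromosome.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if element is None and residual_length > 0:
        element = default_element()

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    pericentromeres: list[tuple[str, int, int]] = []

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1:02d}"
        L = spec.chromosome_length
        exon_bp = int(round(spec.target_exon_fraction * L))
        intron_bp = int(round(spec.target_intron_fraction * L))
        structs = _draw_gene_structs(rng, exon_bp, intron_bp, spec.mean_exons_per_gene)
        genic_bp = sum(sum(ex) + sum(intr) for ex, intr in structs)
        n_g = len(structs)
        gap_total = L - genic_bp
        if gap_total < MIN_INTERGENIC_GAP * (n_g + 1):
            raise InfeasibleSpecError(
                f"{chrom}: {genic_bp} genic bp in {n_g} genes cannot fit {L} bp chromosome"
            )
        gaps = _split_total(rng, gap_total, n_g + 1, MIN_INTERGENIC_GAP)
        cursor = 0
        for gi, ((exon_lens, intron_lens), gap) in enumerate(zip(structs, gaps)):
            start = cursor + int(gap) + 1
            gene = _make_gene(
                chrom, gi + 1, start, exon_lens, intron_lens, rng, spec.multi_isoform_gene_fraction
            )
            genes.append(gene)
            cursor = gene.end
        sequences[chrom] = random_dna(rng, L, spec.gc_content)
        pc = int(round(spec.pericentromere_fraction * L))
        if pc > 0:
            s = (L - pc) // 2 + 1
            pericentromeres.append((chrom, s, s + pc - 1))

    residual_copies: list[tuple[str, int, int]] = []
    if residual_length > 0:
        assert element is not None
        chrom = f"chr{1:02d}"
        residual_copies.append(
            _plant_residual(sequences, genes, chrom, element, residual_length)
        )

    return GenomeBundle(
        sequences=sequences,
        genes=genes,
        pericentromeres=pericentromeres,
        residual_copies=residual_copies,
        spec=spec,
    )


def _plant_residual(
    sequences: dict[str, str],
    genes: list[GeneModel],
    chrom: str,
    element: ElementSpec,
    residual_length: int,
) -> tuple[str, int, int]:
    """Overwrite the largest intergenic gap of ``chrom`` with a truncated element copy.

    The copy keeps the primer-bearing terminus (5'-end prefix under the default
    assay), so it yields the "common bands" shared by every sample in display.
    """
    L = len(sequences[chrom])
    spans = sorted((g.start, g.end) for g in genes if g.chromosome == chrom)
    bounds = [0] + [e for _, e in spans] + [L + 1]
    starts = [s for s, _ in spans] + [L + 1]
    gaps = []  # (length, first_free, last_free)
    prev_end = 0
    for s, e in spans:
        gaps.append((s - prev_end - 1, prev_end + 1, s - 1))
        prev_end = e
    gaps.append((L - prev_end, prev_end + 1, L))
    gaps = [g for g in gaps if g[0] >= residual_length + 200]
    if not gaps:
        raise InfeasibleSpecError(
            f"no intergenic gap on {chrom} can host a {residual_length} bp residual copy"
        )
    glen, lo, hi = max(gaps, key=lambda g: g[0])
    start = lo + (glen - residual_length) // 2  # 1-based start of the copy
    if element.assay_end == "5p":
        copy_seq = element.sequence[:residual_length]
    else:
        copy_seq = element.sequence[-residual_length:]
    s = sequences[chrom]
    sequences[chrom] = s[: start - 1] + copy_seq + s[start - 1 + residual_length :]
    return (chrom, start, residual_length)


# ---------------------------------------------------------------------------
# Insertion simulation and implantation
# ---------------------------------------------------------------------------


def simulate_insertions(
    bundle: GenomeBundle,
    n: int,
    model: str = "uniform",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    hotspot_intervals: list[tuple[str, int, int]] | None = None,
    hotspot_weight: float = 0.8,
    id_prefix: str = "T9",
    id_start: int = 1,
) -> list[TrueInsertion]:
    """Draw ``n`` single-insertion mutants.

    ``uniform`` draws each junction uniformly over the genome; ``hotspot``
    draws with probability ``hotspot_weight`` from the union of the supplied
    intervals and uniformly otherwise. Orientation is unbiased (the element's
    own orientation preference is unknown biology; see docs).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = list(bundle.sequences)
    lens = np.array([len(bundle.sequences[c]) for c in chroms], dtype=np.int64)
    if model == "hotspot":
        if not hotspot_intervals:
            raise ValueError("hotspot model requires hotspot_intervals")
        clens = dict(zip(chroms, lens.tolist()))
        for c, s, e in hotspot_intervals:
            if c not in clens or s < 1 or e >= clens[c] or s > e:
                raise ValueError(f"hotspot interval {(c, s, e)} outside genome bounds")
        hs_lens = np.array([e - s + 1 for _, s, e in hotspot_intervals], dtype=float)
        hs_w = hs_lens / hs_lens.sum()
    elif model != "uniform":
        raise ValueError(f"unknown insertion model {model!r}")
    weights = (lens - 1) / float((lens - 1).sum())
    out = []
    for i in range(n):
        if model == "hotspot" and rng.random() < hotspot_weight:
            j = int(rng.choice(len(hotspot_intervals), p=hs_w))
            c, s, e = hotspot_intervals[j]
            left = int(rng.integers(s, e + 1))
        else:
            ci = int(rng.choice(len(chroms), p=weights))
            c = chroms[ci]
            left = int(rng.integers(1, lens[ci]))  # 1 <= left < chromosome length
        orientation = "+" if rng.random() < 0.5 else "-"
        out.append(TrueInsertion(f"{id_prefix}{id_start + i:04d}", c, left, orientation))
    return out


def implant_element(
    bundle: GenomeBundle, insertion: TrueInsertion, element: ElementSpec
) -> MutantGenome:
    """Insert the element (with its target-site duplication) between
    ``left`` and ``left+1`` of the reference, returning the mutant genome.

    The TSD duplicates the ``tsd_length`` reference bases immediately left of
    the junction on the element's far side, so both flanks remain contiguous
    reference substrings. Residual copies are present identically in every
    mutant (shifted if downstream of the insertion on the same chromosome).
    """
    chrom = insertion.chromosome
    if chrom not in bundle.sequences:
        raise ValueError(f"unknown chromosome {chrom!r}")
    ref = bundle.sequences[chrom]
    left = insertion.left
    if not 1 <= left < len(ref):
        raise ValueError(f"insertion left={left} outside chromosome bounds")
    for rc, rs, rl in bundle.residual_copies:
        if rc == chrom and rs <= left < rs + rl:
            raise OverlapError(
                f"{insertion.mutant_id}: insertion at {chrom}:{left} inside residual copy"
            )
    d = element.tsd_length
    if d > left:
        raise ValueError(f"left={left} smaller than target-site duplication {d}")
    elem_seq = element.sequence if insertion.orientation == "+" else revcomp(element.sequence)
    mutant_seq = ref[:left] + elem_seq + ref[left - d : left] + ref[left:]
    sequences = dict(bundle.sequences)
    sequences[chrom] = mutant_seq
    shift = len(elem_seq) + d
    copies = [
        ElementCopy(chrom, left + 1, left + len(elem_seq), insertion.orientation, "new")
    ] if elem_seq else []
    for rc, rs, rl in bundle.residual_copies:
        start = rs + shift if (rc == chrom and rs > left) else rs
        copies.append(ElementCopy(rc, start, start + rl - 1, "+", "residual"))
    return MutantGenome(insertion.mutant_id, sequences, copies)
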