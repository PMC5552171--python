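"""End-to-end pipeline: simulate → display → map → classify → stats.

The synthetic run emulates the study design: a cohort of independent single-
insertion mutants, a fixed number of which are "unrecoverable" (their
sequenced flanks are corrupted, mirroring the published cohort in which
insertion sites could be determined for only part of the mutants). The
recoverable mutants' insertion positions are drawn from the insertion model
*conditional on display recoverability* — each candidate is verified by
actually running digestion, band prediction, flank validation and mapping —
because the published sites are by construction the recoverable subset
(ascertainment), and the accounting (n in = mapped + unmapped) must be exact.

Junction normalization: the raw mapper reports the element-proximal boundary,
which on the target-site-duplication side of the element is shifted by the
duplication length. The pipeline knows the configured TSD length and the
flank-match strand, and canonicalizes every call to the left junction of the
implantation, so recovered coordinates are directly comparable with truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .classify import AnnotationIndex, annotate_chromatin, classify_site, cohort_summary
from .display import (
    DEFAULT_ADAPTOR_LENGTH,
    DEFAULT_ENZYMES,
    DEFAULT_PRODUCT_WINDOW,
    compare_band_sets,
    extract_and_validate_flank,
    predict_display_products,
)
from .errors import ConfigError, PipelineStageError, TgmapError
from .mapper import SeedIndex, build_index, map_flank, summarize_mapping
from .models import (
    ElementCopy,
    ElementSpec,
    GenomeBundle,
    InsertionAnnotation,
    InsertionSite,
    MutantGenome,
    SyntheticGenomeSpec,
    TrueInsertion,
)
from .partition import genome_partition
from .seq import random_dna
from .stats import chisq_counts, chisq_paper, detect_hotspots, euchromatic_fraction
from .synthetic import (
    DEFAULT_RESIDUAL_LENGTH,
    default_element,
    generate_genome,
    implant_element,
    simulate_insertions,
)

__version__ = tio.__version__

RESIDUAL_EXCLUSION_BUFFER = 20_000  # bp around residual copies kept insertion-free


@dataclass
class PipelineConfig:
    """Everything a synthetic end-to-end run needs, seeded and hashable."""

    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    residual_length: int = DEFAULT_RESIDUAL_LENGTH
    tsd_length: int = 3
    assay_end: str = "5p"
    n_mutants: int = 124
    n_unrecoverable: int = 19
    insertion_model: str = "uniform"
    hotspot_intervals: list[tuple[str, int, int]] | None = None
    hotspot_weight: float = 0.8
    enzymes: list[str] = field(default_factory=lambda: list(DEFAULT_ENZYMES))
    adaptor_length: int = DEFAULT_ADAPTOR_LENGTH
    product_window: tuple[int, int] = DEFAULT_PRODUCT_WINDOW
    min_element_evidence: int = 100
    band_length_tolerance: int = 0
    seed_length: int = 21
    max_mismatches: int = 0
    min_flank: int = 25
    classifier_window: int = 2_000
    hotspot_window: int = 1_000_000
    hotspot_min_count: int = 3
    seed: int = 1

    def validate(self) -> None:
        self.genome.validate()
        if self.n_unrecoverable > self.n_mutants:
            raise ConfigError("n_unrecoverable exceeds n_mutants")
        for e in self.enzymes:
            if e not in DEFAULT_ENZYMES:
                raise ConfigError(f"unknown enzyme {e!r}")

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["genome"] = dict(self.genome.__dict__)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        genome = SyntheticGenomeSpec(**raw.pop("genome", {}))
        cfg = cls(genome=genome, **raw)
        cfg.validate()
        return cfg


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"tgmap {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]


def normalize_junction(site: InsertionSite, tsd_length: int) -> InsertionSite:
    """Canonicalize a mapped junction to the left boundary of the implantation.

    A flank that maps on the '+' strand came from the element side carrying
    the second target-site-duplication copy, so its element-proximal boundary
    is shifted left by the duplication length relative to the canonical
    junction; shift it back. '-'-strand flanks already report the canonical
    junction.
    """
    if site.mapping_status == "unique" and site.strand == "+" and tsd_length:
        site = InsertionSite(
            site.mutant_id, site.chromosome, site.left + tsd_length, site.strand, "unique"
        )
    return site


def _recover_site(
    mutant_id: str,
    flanks: list[str],
    index: SeedIndex,
    sequences: dict[str, str],
    tsd_length: int,
    max_mismatches: int,
    seed_length: int,
) -> InsertionSite:
    """Aggregate per-band mapping calls into one site per mutant.

    Exactly one distinct unique-mapped junction across the mutant's validated
    bands → unique; none → unmapped; conflicting junctions → multi.
    """
    calls: set[tuple[str, int]] = set()
    strands: dict[tuple[str, int], str] = {}
    saw_multi = False
    for flank in flanks:
        if len(flank) < seed_length:
            continue
        site = map_flank(flank, index, sequences, mutant_id, "5p", max_mismatches)
        site = normalize_junction(site, tsd_length)
        if site.mapping_status == "unique":
            key = (site.chromosome, site.left)
            calls.add(key)
            strands[key] = site.strand
        elif site.mapping_status == "multi":
            saw_multi = True
    if len(calls) == 1:
        chrom, left = next(iter(calls))
        return InsertionSite(mutant_id, chrom, left, strands[(chrom, left)], "unique")
    if len(calls) > 1:
        return InsertionSite(mutant_id, None, None, None, "multi")
    return InsertionSite(mutant_id, None, None, None, "multi" if saw_multi else "unmapped")


class _DisplayRunner:
    """Runs the display assay for one mutant across the enzyme panel."""

    def __init__(self, config: PipelineConfig, element: ElementSpec, bundle: GenomeBundle):
        self.config = config
        self.element = element
        self.bundle = bundle
        self.enzymes = [DEFAULT_ENZYMES[e] for e in config.enzymes]
        # reference cut positions never change off the insertion chromosome
        self._ref_cuts: dict[tuple[str, str], list[int]] = {}

    def bands_for(self, mutant: MutantGenome) -> list:
        bands = []
        touched = {c.chromosome for c in mutant.copies if c.kind == "new"}
        for enz in self.enzymes:
            cuts_cache: dict[str, list[int]] = {}
            for copy in mutant.copies:
                chrom = copy.chromosome
                if chrom in cuts_cache:
                    continue
                if chrom in touched:
                    continue  # let predict_display_products digest the mutant sequence
                key = (enz.name, chrom)
                if key not in self._ref_cuts:
                    from .display import cut_positions

                    self._ref_cuts[key] = cut_positions(self.bundle.sequences[chrom], enz)
                cuts_cache[chrom] = self._ref_cuts[key]
            bands.extend(
                predict_display_products(
                    mutant,
                    self.element,
                    enz,
                    adaptor_length=self.config.adaptor_length,
                    product_window=self.config.product_window,
                    cuts_by_chrom=cuts_cache,
                )
            )
        return bands

    def residual_band_lengths(self) -> dict[str, set[int]]:
        """Band lengths the residual copies produce in every sample."""
        copies = [
            ElementCopy(c, s, s + l - 1, "+", "residual")
            for c, s, l in self.bundle.residual_copies
        ]
        pseudo = MutantGenome("__reference__", self.bundle.sequences, copies)
        out: dict[str, set[int]] = {e: set() for e in self.config.enzymes}
        for b in self.bands_for(pseudo):
            out[b.enzyme].add(b.product_length)
        return out


def _new_insertion_flanks(
    bands: list, element: ElementSpec, config: PipelineConfig,
    residual_lengths: dict[str, set[int]],
) -> list[str]:
    """Validated flanks of a mutant's new-insertion bands, excluding bands
    indistinguishable from a residual (common) band on the gel."""
    flanks = []
    for b in bands:
        if b.source_locus == "residual":
            continue
        tol = config.band_length_tolerance
        if any(abs(b.product_length - r) <= tol for r in residual_lengths.get(b.enzyme, ())):
            continue
        try:
            flank = extract_and_validate_flank(b, element, config.min_element_evidence)
        except TgmapError:
            continue
        if len(flank) >= config.min_flank:
            flanks.append(flank)
    return flanks


def _excluded(bundle: GenomeBundle, ins: TrueInsertion, tsd: int) -> bool:
    if ins.left <= tsd:
        return True
    for c, s, l in bundle.residual_copies:
        if ins.chromosome == c and s - RESIDUAL_EXCLUSION_BUFFER <= ins.left < s + l + RESIDUAL_EXCLUSION_BUFFER:
            return True
    return False


def sample_cohort(
    bundle: GenomeBundle,
    element: ElementSpec,
    config: PipelineConfig,
    index: SeedIndex,
    rng: np.random.Generator,
) -> tuple[list[TrueInsertion], set[str]]:
    """Draw the cohort: recoverable insertions (verified by running the full
    display → validate → map path against truth) plus unconditioned insertions
    whose flanks will be corrupted. Returns (cohort, corrupted mutant ids)."""
    runner = _DisplayRunner(config, element, bundle)
    residual_lengths = runner.residual_band_lengths()
    n_ok = config.n_mutants - config.n_unrecoverable
    used: set[tuple[str, int]] = set()
    accepted: list[TrueInsertion] = []
    rejected = 0
    while len(accepted) < n_ok:
        if rejected > 50 * config.n_mutants + 1000:
            raise PipelineStageError("simulate", "recoverable-insertion sampling stalled")
        cand = simulate_insertions(
            bundle, 1, config.insertion_model, rng=rng,
            hotspot_intervals=config.hotspot_intervals,
            hotspot_weight=config.hotspot_weight,
        )[0]
        if _excluded(bundle, cand, element.tsd_length) or (cand.chromosome, cand.left) in used:
            rejected += 1
            continue
        mutant = implant_element(bundle, cand, element)
        bands = runner.bands_for(mutant)
        flanks = _new_insertion_flanks(bands, element, config, residual_lengths)
        site = _recover_site(
            "cand", flanks, index, bundle.sequences, element.tsd_length,
            config.max_mismatches, config.seed_length,
        )
        if (
            site.mapping_status == "unique"
            and site.chromosome == cand.chromosome
            and site.left == cand.left
        ):
            used.add((cand.chromosome, cand.left))
            accepted.append(cand)
        else:
            rejected += 1
    corrupted_draws: list[TrueInsertion] = []
    while len(corrupted_draws) < config.n_unrecoverable:
        cand = simulate_insertions(
            bundle, 1, config.insertion_model, rng=rng,
            hotspot_intervals=config.hotspot_intervals,
            hotspot_weight=config.hotspot_weight,
        )[0]
        if _excluded(bundle, cand, element.tsd_length) or (cand.chromosome, cand.left) in used:
            continue
        used.add((cand.chromosome, cand.left))
        corrupted_draws.append(cand)
    combined = [(t, False) for t in accepted] + [(t, True) for t in corrupted_draws]
    order = rng.permutation(len(combined))
    cohort: list[TrueInsertion] = []
    corrupted_ids: set[str] = set()
    for rank, idx in enumerate(order, 1):
        t, corrupt = combined[int(idx)]
        t = TrueInsertion(f"T9{rank:04d}", t.chromosome, t.left, t.orientation)
        cohort.append(t)
        if corrupt:
            corrupted_ids.add(t.mutant_id)
    return cohort, corrupted_ids


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the synthetic end-to-end pipeline and write all stage outputs.

    Returns the run manifest (also written to ``manifest.json``). Identical
    config + seed produce byte-identical outputs.
    """
    config.validate()
    out = tio.ensure_dir(outdir)
    header = _header(config)
    rng = np.random.default_rng(config.seed)
    element = default_element(tsd_length=config.tsd_length, assay_end=config.assay_end)

    # --- stage: simulate genome -------------------------------------------
    try:
        bundle = generate_genome(config.genome, element, config.residual_length)
    except TgmapError as exc:
        raise PipelineStageError("simulate_genome", str(exc)) from exc
    tio.write_fasta(bundle.sequences, out / "reference.fasta")
    tio.write_gff3(bundle.genes, out / "annotation.gff3", header)
    tio.write_bed(bundle.pericentromeres, out / "pericentromeres.bed", header)

    # --- stage: partition --------------------------------------------------
    totals, parts = genome_partition(bundle.genes, bundle.chromosome_lengths)
    with open(out / "partition_totals.json", "w") as fh:
        json.dump(totals.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    tio.write_partitions_tsv(parts, out / "partition_genes.tsv", header)

    # --- stage: cohort + display ------------------------------------------
    index = build_index(bundle.sequences, config.seed_length)
    cohort, corrupted_ids = sample_cohort(bundle, element, config, index, rng)
    tio.write_truth_tsv(cohort, out / "truth.tsv", header)

    runner = _DisplayRunner(config, element, bundle)
    residual_lengths = runner.residual_band_lengths()
    bands_by_sample = {}
    flanks_by_sample: dict[str, list[str]] = {}
    for ins in cohort:
        mutant = implant_element(bundle, ins, element)
        bands_by_sample[ins.mutant_id] = runner.bands_for(mutant)
    compare_band_sets(bands_by_sample, config.band_length_tolerance)
    n_bands = sum(len(b) for b in bands_by_sample.values())
    n_unique_bands = sum(
        1 for bands in bands_by_sample.values() for b in bands if b.unique
    )
    for ins in cohort:
        bands = [b for b in bands_by_sample[ins.mutant_id] if b.unique]
        flanks = _new_insertion_flanks(bands, element, config, residual_lengths)
        if ins.mutant_id in corrupted_ids:
            # sequencing failure: the read is noise of the same length
            flanks = [random_dna(rng, len(f), 0.5) for f in flanks]
        flanks_by_sample[ins.mutant_id] = flanks

    # --- stage: map ---------------------------------------------------------
    sites = [
        _recover_site(
            ins.mutant_id, flanks_by_sample[ins.mutant_id], index, bundle.sequences,
            element.tsd_length, config.max_mismatches, config.seed_length,
        )
        for ins in cohort
    ]
    mapping = summarize_mapping(sites)
    tio.write_sites_tsv(sites, out / "insertions.tsv", header)
    unique_sites = [s for s in sites if s.mapping_status == "unique"]
    tio.write_bed(
        [(s.chromosome, s.left, s.left + 1, s.mutant_id) for s in unique_sites],
        out / "insertions.bed",
        header,
    )

    # --- stage: classify ----------------------------------------------------
    ann_index = AnnotationIndex(bundle.genes, config.classifier_window)
    annotations = [classify_site(s, ann_index) for s in unique_sites]
    annotate_chromatin(annotations, bundle.pericentromeres)
    summary = cohort_summary(annotations)
    tio.write_annotations_tsv(annotations, out / "annotations.tsv", header)
    export_browser_tracks(annotations, out / "insertions_browser.gff3",
                          out / "insertions_browser.bed", header)

    # --- stage: stats -------------------------------------------------------
    stats_blob = compute_stats(annotations, unique_sites, totals, config)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_blob, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tio.write_bed(
        [(h["chromosome"], h["start"], h["end"], f"hotspot_{i+1}")
         for i, h in enumerate(stats_blob["hotspots"])],
        out / "hotspots.bed",
        header,
    )

    manifest = {
        "tool": "tgmap",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.as_dict(),
        "records": {
            "mutants": len(cohort),
            "corrupted_flanks": len(corrupted_ids),
            "bands": n_bands,
            "unique_bands": n_unique_bands,
            "mapped_unique": mapping["unique"],
            "mapped_multi": mapping["multi"],
            "unmapped": mapping["unmapped"],
            "classified": len(annotations),
        },
        "partition": totals.as_dict(),
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def compute_stats(
    annotations: list[InsertionAnnotation],
    sites: list[InsertionSite],
    totals,
    config: PipelineConfig,
) -> dict:
    """Both χ² modes, hotspot regions and the euchromatic fraction."""
    summary = cohort_summary(annotations)
    exp_e = round(100.0 * totals.exon_fraction, 1)
    exp_i = round(100.0 * totals.intron_fraction, 1)
    blob: dict = {"summary": summary}
    if summary["n"]:
        paper = chisq_paper(
            (summary["percent"]["exon"], summary["percent"]["intron"]), (exp_e, exp_i)
        )
        other = summary["n"] - summary["genic_count"]
        counts = chisq_counts(
            (summary["counts"]["exon"], summary["counts"]["intron"], other),
            summary["n"],
            (totals.exon_fraction, totals.intron_fraction,
             1.0 - totals.genic_fraction),
        )
        blob["chisq_paper"] = paper.as_dict()
        blob["chisq_counts"] = counts.as_dict()
    hotspots = detect_hotspots(sites, config.hotspot_window, config.hotspot_min_count)
    blob["hotspots"] = [
        {
            "chromosome": h.chromosome,
            "start": h.start,
            "end": h.end,
            "span": h.span,
            "insertion_count": h.insertion_count,
            "mutant_ids": h.mutant_ids,
        }
        for h in hotspots
    ]
    ef = euchromatic_fraction(annotations)
    blob["euchromatic_percent"] = round(ef, 1) if ef is not None else None
    return blob


def export_browser_tracks(
    annotations: list[InsertionAnnotation],
    gff3_path: str | Path,
    bed_path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """One genome-browser feature per mutant (GFF3 + BED mirror)."""
    tio.write_insertion_gff3(annotations, gff3_path, header_lines)
    tio.write_bed(
        [(a.chromosome, a.left, a.left + 1, a.mutant_id) for a in annotations],
        bed_path,
        header_lines,
    )


# ---------------------------------------------------------------------------
# File-driven (real-data) mode
# ---------------------------------------------------------------------------


def run_annotation_analysis(
    annotation_gff3: str | Path,
    chromosome_lengths: str | Path,
    outdir: str | Path,
    sites_tsv: str | Path | None = None,
    pericentromere_bed: str | Path | None = None,
    classifier_window: int = 2_000,
    hotspot_window: int = 1_000_000,
    hotspot_min_count: int = 3,
    partition_mode: str = "per_gene",
) -> dict:
    """Partition + (optionally) classify + stats from files on disk.

    This is the path a real assembly/annotation and a published insertion
    table run through, unmodified; inputs are standard GFF3, FASTA or length
    TSV, BED, and the insertion-site TSV.
    """
    for p in (annotation_gff3, chromosome_lengths):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    for p in (sites_tsv, pericentromere_bed):
        if p is not None and not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    out = tio.ensure_dir(outdir)
    genes = tio.read_gff3(annotation_gff3)
    lengths = tio.read_chromosome_lengths(chromosome_lengths)
    totals, parts = genome_partition(genes, lengths, mode=partition_mode)
    with open(out / "partition_totals.json", "w") as fh:
        json.dump(totals.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    result: dict = {"partition": totals.as_dict()}
    if sites_tsv is not None:
        sites = tio.read_sites_tsv(sites_tsv)
        unique_sites = [s for s in sites if s.mapping_status == "unique"]
        ann_index = AnnotationIndex(genes, classifier_window)
        annotations = [classify_site(s, ann_index) for s in unique_sites]
        peri = tio.read_bed(pericentromere_bed) if pericentromere_bed else []
        if peri:
            annotate_chromatin(annotations, peri)
        tio.write_annotations_tsv(annotations, out / "annotations.tsv")
        cfg = PipelineConfig(hotspot_window=hotspot_window,
                             hotspot_min_count=hotspot_min_count)
        stats_blob = compute_stats(annotations, unique_sites, totals, cfg)
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_blob, fh, indent=2, sort_keys=True)
            fh.write("\n")
        result["summary"] = stats_blob["summary"]
        result["stats"] = {k: v for k, v in stats_blob.items() if k != "summary"}
    return result
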