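"""Readers and writers for the standard formats at the pipeline boundary.

GFF3 is 1-based inclusive; BED is 0-based half-open. All in-memory
coordinates are 1-based inclusive, and conversions happen here and only here.
Tabular outputs carry commented header lines (tool version, seed, config
hash) so every stochastic stage is reproducible from its own output.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .models import GeneModel, InsertionAnnotation, InsertionSite, TranscriptModel, TrueInsertion

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chromosome, length) or a FASTA file."""
    path = str(path)
    if path.endswith((".fa", ".fasta", ".fna")):
        return {name: len(seq) for name, seq in read_fasta(path).items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _utr_segments(t: TranscriptModel) -> tuple[list, list]:
    """(five_prime_UTR, three_prime_UTR) genomic intervals of a coding transcript."""
    if not t.cds_segments:
        return [], []
    cds_s = min(s for s, _ in t.cds_segments)
    cds_e = max(e for _, e in t.cds_segments)
    before, after = [], []
    for s, e in t.exons:
        if s < cds_s:
            before.append((s, min(e, cds_s - 1)))
        if e > cds_e:
            after.append((max(s, cds_e + 1), e))
    return (before, after) if t.strand == "+" else (after, before)


def write_gff3(genes: list[GeneModel], path: str | Path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\ttgmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                s, e = t.span
                fh.write(
                    f"{g.chromosome}\ttgmap\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (xs, xe) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chromosome}\ttgmap\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                phase = 0
                cds_tx_order = t.cds_segments if t.strand == "+" else list(reversed(t.cds_segments))
                for cs, ce in cds_tx_order:
                    fh.write(
                        f"{g.chromosome}\ttgmap\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t{phase}\t"
                        f"Parent={t.transcript_id}\n"
                    )
                    phase = (3 - ((ce - cs + 1) - phase) % 3) % 3
                utr5, utr3 = _utr_segments(t)
                for us, ue in utr5:
                    fh.write(
                        f"{g.chromosome}\ttgmap\tfive_prime_UTR\t{us}\t{ue}\t.\t{g.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for us, ue in utr3:
                    fh.write(
                        f"{g.chromosome}\ttgmap\tthree_prime_UTR\t{us}\t{ue}\t.\t{g.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene/mRNA/exon/CDS) from a GFF3 file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = sorted(
                (f.start, f.end) for f in db.children(t, featuretype="exon")
            )
            cds = sorted((f.start, f.end) for f in db.children(t, featuretype="CDS"))
            if not exons:  # single-feature transcripts: fall back to the span
                exons = [(t.start, t.end)]
            transcripts.append(
                TranscriptModel(t.id, g.id, g.seqid, t.strand, exons, cds)
            )
        if not transcripts:
            transcripts = [TranscriptModel(g.id + ".t1", g.id, g.seqid, g.strand,
                                           [(g.start, g.end)], [])]
        gene = GeneModel(g.id, g.seqid, g.strand, (g.start, g.end), transcripts)
        gene.validate()
        genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(
    intervals: list[tuple[str, int, int]] | list[tuple[str, int, int, str]],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else None
            fh.write(f"{chrom}\t{start - 1}\t{end}" + (f"\t{name}\n" if name else "\n"))


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals back to 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_truth_tsv(
    insertions: list[TrueInsertion], path: str | Path, header_lines: list[str] | None = None
) -> None:
    df = pd.DataFrame(
        [(t.mutant_id, t.chromosome, t.left, t.orientation) for t in insertions],
        columns=["mutant_id", "chromosome", "left", "orientation"],
    )
    _write_tsv(df, path, header_lines)


def read_truth_tsv(path: str | Path) -> list[TrueInsertion]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TrueInsertion(r.mutant_id, r.chromosome, int(r.left), r.orientation)
        for r in df.itertuples()
    ]


def write_sites_tsv(
    sites: list[InsertionSite], path: str | Path, header_lines: list[str] | None = None
) -> None:
    rows = []
    for s in sites:
        rows.append(
            (s.mutant_id, s.chromosome or ".", s.left if s.left is not None else ".",
             s.right if s.left is not None else ".", s.strand or ".", s.mapping_status)
        )
    df = pd.DataFrame(rows, columns=["mutant_id", "chromosome", "left", "right",
                                     "strand", "mapping_status"])
    _write_tsv(df, path, header_lines)


def read_sites_tsv(path: str | Path) -> list[InsertionSite]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for r in df.itertuples():
        mapped = r.mapping_status == "unique"
        out.append(
            InsertionSite(
                r.mutant_id,
                r.chromosome if mapped else None,
                int(r.left) if mapped else None,
                r.strand if mapped else None,
                r.mapping_status,
            )
        )
    return out


def write_annotations_tsv(
    annotations: list[InsertionAnnotation], path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    rows = []
    for a in annotations:
        rows.append(
            (a.mutant_id, a.chromosome, a.left, a.left + 1, a.category,
             a.gene_id or ".", a.ordinal if a.ordinal is not None else ".",
             a.distance if a.distance is not None else ".", a.chromatin or ".")
        )
    df = pd.DataFrame(rows, columns=["mutant_id", "chromosome", "left", "right",
                                     "category", "gene_id", "ordinal", "distance",
                                     "chromatin"])
    _write_tsv(df, path, header_lines)


def write_partitions_tsv(parts, path: str | Path, header_lines: list[str] | None = None) -> None:
    df = pd.DataFrame(
        [(p.gene_id, p.transcript_id, p.full_length, p.utr5_length, p.cds_length,
          p.utr3_length, p.intron_length, p.exon_length, p.coding) for p in parts],
        columns=["gene_id", "transcript_id", "full_length", "utr5", "cds", "utr3",
                 "intron", "exon", "coding"],
    )
    _write_tsv(df, path, header_lines)


def write_insertion_gff3(
    annotations: list[InsertionAnnotation], path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    """Browser-ready track: one feature per mutant, category and gene in attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        for a in annotations:
            attrs = [f"ID={a.mutant_id}", f"category={a.category}"]
            if a.gene_id:
                attrs.append(f"gene={a.gene_id}")
            if a.ordinal is not None:
                attrs.append(f"ordinal={a.ordinal}")
            if a.distance is not None:
                attrs.append(f"distance={a.distance}")
            if a.chromatin:
                attrs.append(f"chromatin={a.chromatin}")
            fh.write(
                f"{a.chromosome}\ttgmap\ttransposon_insertion\t{a.left}\t{a.left + 1}"
                f"\t.\t.\t.\t{';'.join(attrs)}\n"
            )


def ensure_dir(path: str | Path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
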