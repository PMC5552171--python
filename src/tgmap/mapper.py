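"""Exact seed-and-extend mapping of flanking sequences to the reference.

Replaces a BLAST step with a small, fully specified mapper: an exact k-mer
index (2-bit packed, numpy-sorted hash array) over the forward strand, seeds
taken from both ends of the query, and full-length verification with at most
``max_mismatches`` mismatches on either strand. A unique best full-length hit
fixes the insertion as the 1-based adjacent pair (left, left+1): the element
lies on the junction side of the flank, which the caller names via
``junction_end`` (the flank end adjacent to the element).

Seed-and-extend with exact seeds can miss a hit whose every seed k-mer is
mutated; with the default ``max_mismatches=0`` mapping is exact and complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FlankTooShortError
from .models import InsertionSite
from .seq import revcomp

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
for i, b in enumerate(b"acgt"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class SeedIndex:
    """Sorted (hash, position) arrays over every valid k-mer of the reference."""

    k: int
    chromosomes: list[str]
    chrom_offsets: np.ndarray  # global 0-based start of each chromosome
    chrom_lengths: np.ndarray
    sorted_hashes: np.ndarray
    sorted_positions: np.ndarray  # global 0-based k-mer start positions

    def lookup(self, h: int) -> np.ndarray:
        h = np.uint64(h)  # matching dtype avoids a full-array comparison cast
        lo = np.searchsorted(self.sorted_hashes, h, side="left")
        hi = np.searchsorted(self.sorted_hashes, h, side="right")
        return self.sorted_positions[lo:hi]

    def locate(self, gpos: int) -> tuple[str, int]:
        """(chromosome, local 0-based position) of a global position."""
        ci = int(np.searchsorted(self.chrom_offsets, gpos, side="right")) - 1
        return self.chromosomes[ci], gpos - int(self.chrom_offsets[ci])


def _window_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(hashes, valid) for all length-k windows of a code array."""
    n = len(codes) - k + 1
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h = (h << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    bad = (codes >= 4).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[k:] - cbad[:-k]) == 0
    return h, valid


def build_index(sequences: dict[str, str], k: int = 21) -> SeedIndex:
    """Index every valid k-mer of every chromosome (forward strand).

    Seeds shorter than ~11 bp are unspecific on genome-scale references; tiny
    k is permitted for toy inputs but the default is 21. k is capped at 31
    (2-bit packing into 64 bits) and must not exceed the shortest chromosome.
    k-mers touching an N are excluded.
    """
    if not 2 <= k <= 31:
        raise ValueError(f"seed length k={k} outside [2, 31]")
    shortest = min(len(s) for s in sequences.values())
    if k > shortest:
        raise ValueError(f"k={k} longer than the shortest chromosome ({shortest} bp)")
    chroms = list(sequences)
    offsets = np.zeros(len(chroms), dtype=np.int64)
    all_h, all_p = [], []
    g = 0
    for i, c in enumerate(chroms):
        offsets[i] = g
        codes = _encode(sequences[c])
        h, valid = _window_hashes(codes, k)
        pos = np.nonzero(valid)[0].astype(np.int64) + g
        all_h.append(h[valid])
        all_p.append(pos)
        g += len(codes)
    hashes = np.concatenate(all_h) if all_h else np.zeros(0, dtype=np.uint64)
    positions = np.concatenate(all_p) if all_p else np.zeros(0, dtype=np.int64)
    order = np.argsort(hashes, kind="stable")
    return SeedIndex(
        k=k,
        chromosomes=chroms,
        chrom_offsets=offsets,
        chrom_lengths=np.array([len(sequences[c]) for c in chroms], dtype=np.int64),
        sorted_hashes=hashes[order],
        sorted_positions=positions[order],
    )


def _seed_offsets(codes: np.ndarray, k: int) -> list[int]:
    """Candidate seed start offsets: first and last valid k-mer of the query."""
    n = len(codes) - k + 1
    offs = []
    for off in range(n):  # first valid
        if (codes[off : off + k] < 4).all():
            offs.append(off)
            break
    for off in range(n - 1, -1, -1):  # last valid
        if (codes[off : off + k] < 4).all():
            if off not in offs:
                offs.append(off)
            break
    return offs


def _mismatches(a: str, b: str, limit: int) -> int:
    if limit == 0:
        return 0 if a == b else limit + 1
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def map_flank(
    flank: str,
    index: SeedIndex,
    sequences: dict[str, str],
    mutant_id: str = "query",
    junction_end: str = "5p",
    max_mismatches: int = 0,
) -> InsertionSite:
    """Locate ``flank`` on the reference and report the insertion junction.

    ``junction_end`` names the flank end adjacent to the element ("5p": the
    element precedes the flank as given). A unique best full-length hit yields
    status ``unique`` with the adjacent coordinate pair; equally good multiple
    hits yield ``multi`` (no coordinate); no hit yields ``unmapped``. A flank
    shorter than the seed length raises (distinct from unmapped).
    """
    if junction_end not in ("5p", "3p"):
        raise ValueError(f"junction_end must be 5p or 3p, got {junction_end!r}")
    k = index.k
    if len(flank) < k:
        raise FlankTooShortError(f"flank of {len(flank)} bp shorter than seed length {k}")
    hits: set[tuple[str, int, str, int]] = set()  # (chrom, start0, strand, mismatches)
    for strand, seq in (("+", flank), ("-", revcomp(flank))):
        codes = _encode(seq)
        for off in _seed_offsets(codes, k):
            h = 0
            for c in codes[off : off + k]:
                h = (h << 2) | int(c)
            for gpos in index.lookup(h):
                chrom, local = index.locate(int(gpos))
                local_start = local - off
                if local_start < 0 or local_start + len(seq) > len(sequences[chrom]):
                    continue
                ref = sequences[chrom][local_start : local_start + len(seq)]
                mm = _mismatches(seq, ref, max_mismatches)
                if mm <= max_mismatches:
                    hits.add((chrom, local_start, strand, mm))
    if not hits:
        return InsertionSite(mutant_id, None, None, None, "unmapped")
    best = min(mm for *_, mm in hits)
    top = sorted(h for h in hits if h[3] == best)
    if len(top) > 1:
        return InsertionSite(mutant_id, None, None, None, "multi")
    chrom, start0, strand, _ = top[0]
    s, e = start0 + 1, start0 + len(flank)  # 1-based match interval
    if (strand == "+") == (junction_end == "5p"):
        left = s - 1  # element immediately left of the match
    else:
        left = e  # element immediately right of the match
    if not 1 <= left < len(sequences[chrom]):
        return InsertionSite(mutant_id, None, None, None, "unmapped")
    return InsertionSite(mutant_id, chrom, left, strand, "unique")


def summarize_mapping(sites: list[InsertionSite]) -> dict[str, int]:
    """Cohort accounting: counts of unique / multi / unmapped sites."""
    out = {"total": len(sites), "unique": 0, "multi": 0, "unmapped": 0}
    for s in sites:
        out[s.mapping_status] += 1
    return out
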