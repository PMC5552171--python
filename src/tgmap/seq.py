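"""Small sequence utilities used across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int, gc_content: float = 0.5) -> str:
    """Random DNA with the requested GC content, drawn from ``rng``."""
    if length <= 0:
        return ""
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    cum = np.cumsum([at, gc, gc, at])  # A, C, G, T
    codes = np.searchsorted(cum, rng.random(length), side="right")
    codes = np.clip(codes, 0, 3)
    return _BASES[codes].tobytes().decode("ascii")


def find_occurrences(seq: str, motif: str) -> list[int]:
    """0-based start positions of every (possibly overlapping) occurrence of ``motif``."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits
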