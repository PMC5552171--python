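"""Randomness statistics: goodness-of-fit tests and hotspot detection.

Two χ² forms are implemented side by side. The *paper-faithful* form works on
the percentage scale with df=1 over the exon and intron classes — the exact
arithmetic behind the published randomness conclusion — and is intended for
reproduction only: a percentage-scale statistic is not sample-size calibrated,
so it is not a valid hypothesis test in general. The *count-based* form is
the standard multinomial goodness-of-fit over (exon, intron, other) counts
with df=2, which is what the same question looks like as a calibrated test.
"""

from __future__ import annotations

import warnings

from scipy import stats as sps

from .errors import UndefinedStatisticError
from .models import ChiSqResult, HotspotRegion, InsertionAnnotation, InsertionSite

DEFAULT_HOTSPOT_WINDOW = 1_000_000
DEFAULT_HOTSPOT_MIN_COUNT = 3


def chisq_paper(
    observed_pct: tuple[float, float], expected_pct: tuple[float, float]
) -> ChiSqResult:
    """Percentage-scale χ² over the exon and intron classes, df=1.

    statistic = Σ (obs% − exp%)² / exp% over {exon, intron}; p from the upper
    tail of χ²(1), no continuity correction.
    """
    if any(e <= 0 for e in expected_pct):
        raise UndefinedStatisticError("expected percentage of zero leaves χ² undefined")
    if any(o < 0 for o in observed_pct):
        raise ValueError("observed percentages must be >= 0")
    stat = sum((o - e) ** 2 / e for o, e in zip(observed_pct, expected_pct))
    return ChiSqResult(
        mode="paper_faithful",
        observed=tuple(observed_pct),
        expected=tuple(expected_pct),
        statistic=stat,
        df=1,
        p_value=float(sps.chi2.sf(stat, 1)),
    )


def chisq_counts(
    observed: tuple[int, int, int], n: int, expected_fractions: tuple[float, float, float]
) -> ChiSqResult:
    """Multinomial goodness-of-fit over (exon, intron, other) counts, df=2."""
    if sum(observed) != n:
        raise ValueError(f"counts {observed} do not sum to n={n}")
    if abs(sum(expected_fractions) - 1.0) > 1e-9:
        raise ValueError("expected fractions must sum to 1")
    expected = tuple(n * f for f in expected_fractions)
    if any(e <= 0 for e in expected):
        raise UndefinedStatisticError("expected count of zero leaves χ² undefined")
    if any(e < 1 for e in expected):
        warnings.warn("expected count below 1 in some class; χ² approximation is weak")
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return ChiSqResult(
        mode="count_based",
        observed=tuple(observed),
        expected=expected,
        statistic=stat,
        df=2,
        p_value=float(sps.chi2.sf(stat, 2)),
    )


def detect_hotspots(
    sites: list[InsertionSite],
    window: int = DEFAULT_HOTSPOT_WINDOW,
    min_count: int = DEFAULT_HOTSPOT_MIN_COUNT,
) -> list[HotspotRegion]:
    """Clustered-insertion regions per chromosome.

    A qualifying set is >= ``min_count`` insertions whose tight span
    (last − first + 1) is <= ``window`` bp (boundary inclusive). Overlapping
    qualifying sets are merged, and each merged region reports the tight span
    of its member sites — so a merged region may exceed ``window``. Equivalent
    to exhaustive enumeration of all windows (tested against it).
    """
    by_chrom: dict[str, list[InsertionSite]] = {}
    for s in sites:
        if s.mapping_status == "unique":
            by_chrom.setdefault(s.chromosome, []).append(s)
    regions: list[HotspotRegion] = []
    for chrom in sorted(by_chrom):
        pts = sorted(by_chrom[chrom], key=lambda s: (s.left, s.mutant_id))
        pos = [s.left for s in pts]
        n = len(pos)
        ranges = []  # qualifying (i, j) index ranges, two-pointer sweep
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and pos[j + 1] - pos[i] + 1 <= window:
                j += 1
            if j - i + 1 >= min_count:
                ranges.append((i, j))
        merged: list[list[int]] = []
        for i, j in ranges:
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            members = pts[i : j + 1]
            regions.append(
                HotspotRegion(
                    chromosome=chrom,
                    start=pos[i],
                    end=pos[j],
                    insertion_count=j - i + 1,
                    mutant_ids=[m.mutant_id for m in members],
                )
            )
    return regions


def euchromatic_fraction(annotations: list[InsertionAnnotation]) -> float | None:
    """Euchromatic share of classified insertions, as a percentage (None if empty)."""
    assigned = [a for a in annotations if a.chromatin is not None]
    if not assigned:
        return None
    eu = sum(1 for a in assigned if a.chromatin == "euchromatic")
    return 100.0 * eu / len(assigned)
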