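"""In-silico transposon display (genome-walking) simulation.

Models the assay as geometry rather than chemistry: blunt-end restriction
digestion of the mutant genome, adaptor ligation at every cut, then nested
PCR anchored by element-specific primers (outer R1, nested R2) near one
element terminus. A band is predicted for an element copy iff the restriction
fragment containing the primer-bearing terminus (i) carries both complete
primer sites and (ii) ends in an adaptor-ligated genomic cut beyond the
junction; its length is the nested amplicon (R2 site through the junction to
the genomic cut) plus the nested-adaptor-primer contribution.

Residual truncated copies are identical in every sample and therefore show up
as "common" bands; new insertions give sample-unique bands, which are the
ones whose flanks are sequenced and mapped downstream.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right

from .errors import InsufficientElementEvidenceError, NoGenomicSideError
from .models import DisplayBand, ElementSpec, Fragment, MutantGenome, RestrictionEnzyme
from .seq import find_occurrences, revcomp

#: The four blunt cutters of the assay. All are palindromic central cutters,
#: so cut geometry is strand-symmetric.
DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {
    "DraI": RestrictionEnzyme("DraI", "TTTAAA", 3),
    "EcoRV": RestrictionEnzyme("EcoRV", "GATATC", 3),
    "PvuII": RestrictionEnzyme("PvuII", "CAGCTG", 3),
    "StuI": RestrictionEnzyme("StuI", "AGGCCT", 3),
}

DEFAULT_ADAPTOR_LENGTH = 25  # bp contributed by the nested adaptor primer (AP2)
DEFAULT_PRODUCT_WINDOW = (100, 6_000)  # amplifiable nested-product lengths, bp


def cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Sorted cut positions: a value c means the cut falls between base c and
    c+1 (1-based). Overlapping recognition-site occurrences are all honored;
    duplicate cut positions are collapsed."""
    cuts = {start0 + enzyme.cut_offset for start0 in
            find_occurrences(sequence, enzyme.recognition_sequence)}
    return sorted(cuts)


def digest(sequence: str, enzyme: RestrictionEnzyme, source: str = "seq") -> list[Fragment]:
    """Digest ``sequence``; the returned fragments tile it exactly."""
    if not sequence:
        return []
    bounds = [0] + cut_positions(sequence, enzyme) + [len(sequence)]
    frags = []
    for a, b in zip(bounds, bounds[1:]):
        if b > a:
            frags.append(Fragment(source, a + 1, b, sequence[a:b]))
    return frags


def _primer_extents(element: ElementSpec) -> tuple[int, int]:
    """(outer R1 offset, nested R2 offset) from the assayed terminus."""
    r1 = element.primer_sites["R1"].offset
    r2 = element.primer_sites["R2"].offset
    return r1, r2


def predict_display_products(
    mutant: MutantGenome,
    element: ElementSpec,
    enzyme: RestrictionEnzyme,
    adaptor_length: int = DEFAULT_ADAPTOR_LENGTH,
    product_window: tuple[int, int] = DEFAULT_PRODUCT_WINDOW,
    cuts_by_chrom: dict[str, list[int]] | None = None,
) -> list[DisplayBand]:
    """Predict nested-PCR bands for every element copy in ``mutant``.

    Only the primer-bearing element end is assayed (single-side display,
    matching the single element-specific primer pair). Copies whose
    primer-bearing end is truncated away yield no band; so do copies whose
    fragment runs to a sequence end on the genomic side (no blunt cut to
    ligate the adaptor to), and products outside the amplifiable window.
    ``cuts_by_chrom`` may carry precomputed cut positions to avoid re-digestion.
    """
    r1_off, r2_off = _primer_extents(element)
    bands: list[DisplayBand] = []
    cuts_cache: dict[str, list[int]] = cuts_by_chrom if cuts_by_chrom is not None else {}
    for copy in mutant.copies:
        if not copy.has_primer_end:
            continue
        seq = mutant.sequences[copy.chromosome]
        if copy.chromosome not in cuts_cache:
            cuts_cache[copy.chromosome] = cut_positions(seq, enzyme)
        cuts = cuts_cache[copy.chromosome]

        # Locate the assayed terminus in mutant coordinates. assay_end names a
        # terminus of the element in its own orientation; a '-' copy mirrors
        # it on the chromosome, so the terminus sits at copy.start iff
        # orientation and assay_end "agree".
        if (copy.orientation == "+") == (element.assay_end == "5p"):
            # assayed terminus at copy.start; genomic flank to the left
            t = copy.start
            i = bisect_left(cuts, t)
            g = cuts[i - 1] if i > 0 else None  # last cut strictly left of terminus
            c2 = cuts[i] if i < len(cuts) else None  # element-side fragment end
            if g is None:
                continue  # fragment runs to chromosome start: no adaptor end
            flank_len = t - 1 - g
            avail = (c2 if c2 is not None else len(seq)) - t + 1
            flank_seq = revcomp(seq[g : t - 1])  # junction at the flank's 5' end
            junction_left_mutant = t - 1
        else:
            # assayed terminus at copy.end; genomic flank to the right
            t = copy.end
            i = bisect_right(cuts, t)
            g2 = cuts[i] if i < len(cuts) else None  # first cut right of terminus
            c1 = cuts[i - 1] if i > 0 else None
            if g2 is None:
                continue
            flank_len = g2 - t
            avail = t - (c1 if c1 is not None else 0)
            flank_seq = seq[t : g2]  # already reads away from the element
            junction_left_mutant = t

        if flank_len < 1:
            continue  # cut flush with the junction: no genomic side survives
        if avail < r1_off:
            continue  # outer primer site cut off: nesting constraint fails
        product_length = r2_off + flank_len + adaptor_length
        if not product_window[0] <= product_length <= product_window[1]:
            continue
        if element.assay_end == "5p":
            element_part = element.sequence[:r2_off]
        else:
            element_part = revcomp(element.sequence[-r2_off:])
        bands.append(
            DisplayBand(
                sample_id=mutant.mutant_id,
                enzyme=enzyme.name,
                product_length=product_length,
                source_locus="residual" if copy.kind == "residual"
                else (copy.chromosome, junction_left_mutant),
                element_part=element_part,
                flank=flank_seq,
            )
        )
    return bands


def compare_band_sets(
    bands_by_sample: dict[str, list[DisplayBand]], length_tolerance: int = 0
) -> dict[str, list[DisplayBand]]:
    """Flag each band unique/common across samples.

    A band is *common* iff every sample shows a band of the same enzyme within
    ±``length_tolerance`` bp — the in-silico analogue of a gel band present in
    all lanes (a residual-copy signature). Everything else is unique. With a
    single sample all bands are flagged unique, with a warning.
    """
    samples = list(bands_by_sample)
    if len(samples) < 2:
        warnings.warn("band comparison with a single sample: all bands flagged unique")
        for bands in bands_by_sample.values():
            for b in bands:
                b.unique = True
        return bands_by_sample
    lengths = {
        s: {} for s in samples
    }  # sample -> enzyme -> sorted lengths
    for s, bands in bands_by_sample.items():
        for b in bands:
            lengths[s].setdefault(b.enzyme, []).append(b.product_length)
    for s in samples:
        for v in lengths[s].values():
            v.sort()
    for s, bands in bands_by_sample.items():
        for b in bands:
            common = True
            for other in samples:
                lens = lengths[other].get(b.enzyme, [])
                i = bisect_left(lens, b.product_length - length_tolerance)
                if i >= len(lens) or lens[i] > b.product_length + length_tolerance:
                    common = False
                    break
            b.unique = not common
    return bands_by_sample


def extract_and_validate_flank(
    band: DisplayBand, element: ElementSpec, min_element_evidence: int = 100
) -> str:
    """Validate a band the way sequenced products were screened: the product
    must carry more than ``min_element_evidence`` bp exactly matching the
    element terminus adjacent to the junction. Returns the genomic-side flank.
    """
    if not band.flank:
        raise NoGenomicSideError(f"{band.sample_id}/{band.enzyme}: product is pure element")
    if element.assay_end == "5p":
        terminus = element.sequence
    else:
        terminus = revcomp(element.sequence)
    ev = band.element_part
    matched = 0
    for a, b in zip(ev, terminus):
        if a != b:
            break
        matched += 1
    if matched <= min_element_evidence:
        raise InsufficientElementEvidenceError(
            f"{band.sample_id}/{band.enzyme}: only {matched} bp of element-end evidence "
            f"(need > {min_element_evidence})"
        )
    return band.flank
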