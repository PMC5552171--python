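"""Restriction digestion, band prediction, cross-sample comparison, flank validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgmap.display import (
    DEFAULT_ENZYMES,
    compare_band_sets,
    cut_positions,
    digest,
    extract_and_validate_flank,
    predict_display_products,
)
from tgmap.errors import InsufficientElementEvidenceError, NoGenomicSideError
from tgmap.models import (
    DisplayBand,
    ElementCopy,
    ElementSpec,
    MutantGenome,
    PrimerSite,
    RestrictionEnzyme,
)
from tgmap.seq import random_dna, revcomp

DRA1 = DEFAULT_ENZYMES["DraI"]


def naive_cuts(seq, enz):
    """O(n*m) sliding-window digestion oracle."""
    cuts = set()
    m = enz.recognition_sequence
    for i in range(len(seq) - len(m) + 1):
        if seq[i : i + len(m)] == m:
            cuts.add(i + enz.cut_offset)
    return sorted(cuts)


class TestDigest:
    def test_manual_scan_example(self):
        frags = digest("AAATTTAAACCC", DRA1)
        assert [f.sequence for f in frags] == ["AAATTT", "AAACCC"]
        assert [(f.start, f.end) for f in frags] == [(1, 6), (7, 12)]

    def test_no_site_returns_whole_input(self):
        frags = digest("ACGTACGT", DRA1)
        assert len(frags) == 1 and frags[0].sequence == "ACGTACGT"

    def test_empty_sequence(self):
        assert digest("", DRA1) == []

    def test_n_never_matches(self):
        assert cut_positions("TTTANATTTAAA".replace("TTTAAA", "TTTANA"), DRA1) == []

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_fragments_tile_input_and_match_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich short sequences make DraI sites (incl. overlapping ones) common
        seq = random_dna(rng, int(rng.integers(0, 400)), 0.2)
        enz = list(DEFAULT_ENZYMES.values())[seed % 4]
        frags = digest(seq, enz)
        assert "".join(f.sequence for f in frags) == seq
        assert cut_positions(seq, enz) == naive_cuts(seq, enz)

    def test_overlapping_occurrences_all_honored(self):
        enz = RestrictionEnzyme("toy", "AAA", 1)
        # AAAA holds two overlapping occurrences -> cuts after base 1 and 2
        assert cut_positions("AAAA", enz) == [1, 2]


def toy_element(seq_len=300, r1=80, r2=60, seed=5):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, seq_len, 0.5)
    while any(enz.recognition_sequence in seq for enz in DEFAULT_ENZYMES.values()):
        seq = random_dna(rng, seq_len, 0.5)
    return ElementSpec(
        sequence=seq,
        primer_sites={"R1": PrimerSite(r1, 20), "R2": PrimerSite(r2, 20)},
        tsd_length=0,
    )


def toy_mutant(element, left_flank=200, right_flank=160, cut_at=60, seed=6):
    """A single '+' element copy; one DraI site cut position ``cut_at`` in the
    left flank and no other sites anywhere."""
    rng = np.random.default_rng(seed)
    while True:
        flank_l = random_dna(rng, left_flank, 0.5)
        flank_r = random_dna(rng, right_flank, 0.5)
        chrom = flank_l + element.sequence + flank_r
        # plant TTTAAA so that its cut (recognition start + 3) is at cut_at
        chrom = chrom[: cut_at - 3] + "TTTAAA" + chrom[cut_at + 3 :]
        if cut_positions(chrom, DRA1) == [cut_at] and all(
            not cut_positions(chrom, e) for n, e in DEFAULT_ENZYMES.items() if n != "DraI"
        ):
            break
    copy = ElementCopy("c1", left_flank + 1, left_flank + element.length, "+", "new")
    return MutantGenome("m1", {"c1": chrom}, [copy])


class TestPredictDisplayProducts:
    def test_product_length_arithmetic(self):
        # R2 site 60 bp from the terminus, flank-side cut 140 bp from the
        # junction, AP2 tail 25 bp -> 60 + 140 + 25 = 225
        element = toy_element()
        mutant = toy_mutant(element, left_flank=200, cut_at=60)
        bands = predict_display_products(mutant, element, DRA1, adaptor_length=25)
        assert len(bands) == 1
        assert bands[0].product_length == 225
        assert len(bands[0].flank) == 140
        assert bands[0].source_locus == ("c1", 200)

    def test_fractured_primer_end_yields_no_band(self):
        element = toy_element()
        mutant = toy_mutant(element)
        mutant.copies[0].has_primer_end = False
        assert predict_display_products(mutant, element, DRA1) == []

    def test_no_flank_side_cut_yields_no_band(self):
        element = toy_element()
        mutant = toy_mutant(element)
        # remove the only cut: the fragment runs to the sequence start
        chrom = mutant.sequences["c1"].replace("TTTAAA", "TTTGAA")
        mutant.sequences["c1"] = chrom
        assert predict_display_products(mutant, element, DRA1) == []

    def test_junction_consistent_across_enzymes(self, small_bundle, element):
        from tgmap.synthetic import implant_element, simulate_insertions

        ins = simulate_insertions(small_bundle, 6, seed=21)
        for t in ins:
            mutant = implant_element(small_bundle, t, element)
            loci = {}
            for enz in DEFAULT_ENZYMES.values():
                for b in predict_display_products(mutant, element, enz):
                    if b.source_locus != "residual":
                        loci.setdefault(b.source_locus, set()).add((enz.name, b.product_length))
            if sum(len(v) for v in loci.values()) >= 2:
                assert len(loci) == 1  # same junction, lengths differ by enzyme

    def test_flank_reads_away_from_element(self):
        element = toy_element()
        mutant = toy_mutant(element, left_flank=200, cut_at=60)
        band = predict_display_products(mutant, element, DRA1)[0]
        # '+' copy assayed at its 5' terminus: flank is the revcomp of the
        # genomic sequence left of the junction
        assert band.flank == revcomp(mutant.sequences["c1"][60:200])


def mk_band(sample, enzyme, length):
    return DisplayBand(sample, enzyme, length, ("c1", 1), "", "A" * 30)


class TestCompareBandSets:
    def test_shared_band_common_private_bands_unique(self):
        bands = {
            "s1": [mk_band("s1", "DraI", 300), mk_band("s1", "DraI", 550)],
            "s2": [mk_band("s2", "DraI", 300), mk_band("s2", "DraI", 720)],
        }
        compare_band_sets(bands)
        flags = {(b.sample_id, b.product_length): b.unique
                 for bs in bands.values() for b in bs}
        assert flags[("s1", 300)] is False and flags[("s2", 300)] is False
        assert flags[("s1", 550)] is True and flags[("s2", 720)] is True

    def test_identical_sets_have_no_unique_bands(self):
        bands = {s: [mk_band(s, "EcoRV", 410)] for s in ("a", "b", "c")}
        compare_band_sets(bands)
        assert all(not b.unique for bs in bands.values() for b in bs)

    def test_tolerance_boundary(self):
        bands = {
            "s1": [mk_band("s1", "DraI", 300)],
            "s2": [mk_band("s2", "DraI", 304)],
        }
        compare_band_sets(bands, length_tolerance=5)
        assert all(not b.unique for bs in bands.values() for b in bs)
        compare_band_sets(bands, length_tolerance=3)
        assert all(b.unique for bs in bands.values() for b in bs)

    def test_same_length_different_enzyme_not_common(self):
        bands = {
            "s1": [mk_band("s1", "DraI", 300)],
            "s2": [mk_band("s2", "StuI", 300)],
        }
        compare_band_sets(bands)
        assert all(b.unique for bs in bands.values() for b in bs)

    def test_single_sample_warns_and_flags_unique(self):
        bands = {"s1": [mk_band("s1", "DraI", 300)]}
        with pytest.warns(UserWarning):
            compare_band_sets(bands)
        assert bands["s1"][0].unique is True


class TestExtractAndValidateFlank:
    def test_validated_flank_returned(self, element):
        band = DisplayBand("s", "DraI", 375, ("c", 1), element.sequence[:150], "G" * 200)
        assert extract_and_validate_flank(band, element) == "G" * 200

    def test_insufficient_evidence_rejected(self, element):
        band = DisplayBand("s", "DraI", 305, ("c", 1), element.sequence[:80], "G" * 200)
        with pytest.raises(InsufficientElementEvidenceError):
            extract_and_validate_flank(band, element)

    def test_mismatching_evidence_rejected(self, element):
        fake = revcomp(element.sequence[:150])
        band = DisplayBand("s", "DraI", 375, ("c", 1), fake, "G" * 200)
        with pytest.raises(InsufficientElementEvidenceError):
            extract_and_validate_flank(band, element)

    def test_pure_element_product_distinct_error(self, element):
        band = DisplayBand("s", "DraI", 150, ("c", 1), element.sequence[:150], "")
        with pytest.raises(NoGenomicSideError):
            extract_and_validate_flank(band, element)
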