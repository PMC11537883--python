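"""Derived-allele reconstruction, copy-number arithmetic, and the
brute-force per-base counting oracle."""

from collections import Counter

import numpy as np
import pytest

from rp17sv import fixtures
from rp17sv.allele import (CopyNumberProfile, amplified_regions,
                           build_derived_allele, copy_number_profile,
                           diploid_profile, identity_allele,
                           junction_sequences, reverse_complement,
                           shared_amplified_region, shared_amplified_regions)
from rp17sv.fixtures import StringReference
from rp17sv.nomenclature import (ComplexSV, GenomicInterval, InsertedElement,
                                 parse_hgvs_sv)


def brute_force_counts(sv, locus):
    """Independent per-base oracle: enumerate every reference base of the
    derived allele directly from the rearrangement rules and count."""
    def expand(element):
        if element.kind == "novel_sequence":
            return []
        iv = element.interval
        return list(range(iv.start, iv.end + 1))

    if sv is None:
        positions = list(range(locus.start, locus.end + 1))
    elif sv.anchor_kind == "dup":
        a, b = sv.anchor.start, sv.anchor.end
        positions = (list(range(locus.start, b + 1))
                     + list(range(a, b + 1))
                     + list(range(b + 1, locus.end + 1)))
    elif sv.anchor_kind == "ins":
        a = sv.anchor.start
        positions = list(range(locus.start, a + 1))
        for el in sv.elements:
            positions += expand(el)
        positions += list(range(a + 1, locus.end + 1))
    else:  # delins
        positions = list(range(locus.start, sv.anchor.start))
        for el in sv.elements:
            positions += expand(el)
        positions += list(range(sv.anchor.end + 1, locus.end + 1))
    return Counter(positions)


def profile_as_array(profile):
    """Expand a piecewise profile to one count per base."""
    out = np.empty(profile.locus.length(), dtype=int)
    for iv, c in profile.partitions():
        out[iv.start - profile.locus.start: iv.end - profile.locus.start + 1] = c
    return out


def oracle_as_array(counter, locus):
    out = np.zeros(locus.length(), dtype=int)
    for pos, c in counter.items():
        out[pos - locus.start] = c
    return out


class TestBuildDerivedAllele:
    def test_tandem_dup_three_segments_one_junction(self, sv_by_id, locus):
        allele = build_derived_allele(sv_by_id["NL-SV1"], locus)
        assert len(allele.segments) == 3
        assert len(allele.junctions) == 1
        jn = allele.junctions[0]
        assert (jn.left.pos, jn.left.side, jn.left.orientation) == \
            (59440776, "3'", "+")
        assert (jn.right.pos, jn.right.side, jn.right.orientation) == \
            (59214554, "5'", "+")
        assert jn.linker == ""

    def test_delins_inversion_with_linker(self, sv_by_id, locus):
        allele = build_derived_allele(sv_by_id["UK-SV2"], locus)
        ref_segments = [s for s in allele.segments if not s.is_novel]
        assert len(ref_segments) == 3  # left flank, inversion, right flank
        assert len(allele.segments) == 4  # plus the 9-bp linker tile
        assert ref_segments[1].inverted
        assert len(allele.junctions) == 2
        assert allele.junctions[0].linker == ""
        assert allele.junctions[1].linker == "AGGCTGGTC"

    def test_identity_single_segment_no_junctions(self, locus):
        allele = build_derived_allele(None, locus)
        assert allele.is_identity
        assert allele.length() == locus.length()

    def test_length_conservation_catalogue(self, catalogue_svs, locus):
        for sv in catalogue_svs:
            allele = build_derived_allele(sv, locus)
            extra = (sv.anchor.length() if sv.anchor_kind == "dup"
                     else sv.inserted_length())
            expected = locus.length() + extra - sv.deleted_length()
            assert allele.length() == expected, sv.id

    def test_segment_outside_locus_rejected(self):
        locus = GenomicInterval("chr17", 1000, 2000)
        sv = ComplexSV(id="x", anchor_kind="dup",
                       anchor=GenomicInterval("chr17", 500, 1500))
        with pytest.raises(ValueError, match="outside"):
            build_derived_allele(sv, locus)


class TestCopyNumberProfile:
    def test_simple_dup_profile(self, sv_by_id, locus):
        profile = copy_number_profile(sv_by_id["NL-SV1"], locus)
        assert [(iv.start, iv.end, c) for iv, c in profile.partitions()] == [
            (59100000, 59214553, 1),
            (59214554, 59440776, 2),
            (59440777, 59700000, 1),
        ]

    def test_dup_trip_profile(self, sv_by_id, locus):
        """The insertion of an inverted and a direct long segment yields a
        duplication over GDPD1 and a triplication over the enhancers."""
        profile = copy_number_profile(sv_by_id["DE-SV9"], locus)
        assert profile.count_at(59_200_000) == 2   # GDPD1 side
        assert profile.count_at(59_336_281) == 2
        assert profile.count_at(59_336_282) == 3
        assert profile.count_at(59_427_000) == 3   # enhancer cluster
        assert profile.count_at(59_545_765) == 3
        assert profile.count_at(59_545_766) == 1

    def test_delins_restored_by_inserted_inversion(self, sv_by_id, locus):
        """A replaced interval covered once by the inserted inversion has
        net count 1: deleted once, restored once."""
        profile = copy_number_profile(sv_by_id["US-SV10"], locus)
        regions = amplified_regions(profile)
        assert [(iv.start, iv.end) for iv in regions] == [
            (59220112, 59288295), (59362562, 59478159)]
        assert profile.count_at(59_300_000) == 1  # inside replaced interval

    def test_identity_profile_constant_one(self, locus):
        profile = copy_number_profile(None, locus)
        assert profile.counts == (1,)
        assert amplified_regions(profile) == []

    def test_oracle_equivalence_random_svs(self, toy, rng):
        """Interval arithmetic equals per-base counting on 200 random SVs
        over the 10-kb toy locus."""
        for i in range(200):
            sv = fixtures.random_complex_sv(rng, toy.locus, sv_id=f"r{i}")
            profile = copy_number_profile(sv, toy.locus)
            oracle = brute_force_counts(sv, toy.locus)
            assert np.array_equal(profile_as_array(profile),
                                  oracle_as_array(oracle, toy.locus)), sv

    def test_oracle_equivalence_mapped_catalogue(self, catalogue_svs, toy):
        for sv in catalogue_svs:
            mapped = toy.map_sv(sv)
            profile = copy_number_profile(mapped, toy.locus)
            oracle = brute_force_counts(mapped, toy.locus)
            assert np.array_equal(profile_as_array(profile),
                                  oracle_as_array(oracle, toy.locus)), sv.id

    def test_integral_conservation(self, toy, rng):
        """Sum of count x partition length = reference-derived bases of
        the derived allele (linkers excluded)."""
        for i in range(50):
            sv = fixtures.random_complex_sv(rng, toy.locus, sv_id=f"r{i}")
            profile = copy_number_profile(sv, toy.locus)
            integral = sum(c * iv.length() for iv, c in profile.partitions())
            allele = build_derived_allele(sv, toy.locus)
            ref_bases = sum(s.length() for s in allele.segments
                            if not s.is_novel)
            assert integral == ref_bases

    def test_profile_invariants_enforced(self, locus):
        with pytest.raises(ValueError):
            CopyNumberProfile(locus=locus, breakpoints=(59_200_000,),
                              counts=(1, 1))  # not maximally merged
        with pytest.raises(ValueError):
            CopyNumberProfile(locus=locus, breakpoints=(), counts=(-1,))


class TestAmplifiedRegions:
    def test_min_count_three_selects_triplicated(self, sv_by_id, locus):
        profile = copy_number_profile(sv_by_id["UK-SV6"], locus)
        regions = amplified_regions(profile, min_count=3)
        assert [(iv.start, iv.end) for iv in regions] == [
            (59218621, 59247345), (59362745, 59433393)]

    def test_single_sv_intersection_is_its_own_region(self, sv_by_id, locus):
        region = shared_amplified_region([sv_by_id["NL-SV1"]], locus)
        assert (region.start, region.end) == (59214554, 59440776)

    def test_catalogue_shared_region(self, catalogue_svs, locus):
        """All 10 catalogued SVs amplify one common interval of ~11.5 kb
        starting at chr17:59,421,853."""
        pieces = shared_amplified_regions(catalogue_svs, locus)
        assert len(pieces) == 1
        region = pieces[0]
        assert region.start == 59_421_853
        assert region.end == 59_433_393
        assert round(region.length() / 1000, 1) == 11.5

    def test_disjoint_svs_share_nothing(self, locus):
        a = ComplexSV(id="a", anchor_kind="dup",
                      anchor=GenomicInterval("chr17", 59_150_000, 59_160_000))
        b = ComplexSV(id="b", anchor_kind="dup",
                      anchor=GenomicInterval("chr17", 59_600_000, 59_610_000))
        assert shared_amplified_region([a, b], locus) is None


class TestJunctionSequences:
    def test_dup_junction_by_construction(self, toy):
        sv = ComplexSV(id="d", anchor_kind="dup",
                       anchor=GenomicInterval("toy", 201, 400))
        allele = build_derived_allele(sv, toy.locus)
        [js] = junction_sequences(allele, toy.reference, flank=10)
        ref = toy.reference.seq
        assert js.sequence == ref[390:400] + ref[200:210]
        assert not js.truncated

    def test_inverted_upstream_flank_is_reverse_complemented(self, toy):
        sv = parse_hgvs_sv("g.4001_5000delins[2001_7000inv;AGGCTGGTC]",
                           id="t", chrom="toy")
        allele = build_derived_allele(sv, toy.locus)
        seqs = junction_sequences(allele, toy.reference, flank=5)
        assert len(seqs) == 2
        ref = toy.reference.seq
        # junction 2: inverted segment exits at its 5' end (ref 2001),
        # so the upstream flank is the reverse complement of ref[2001..2005]
        js = seqs[1]
        assert js.junction.linker == "AGGCTGGTC"
        expected = reverse_complement(ref[2000:2005]) + "AGGCTGGTC" + ref[5000:5005]
        assert js.sequence == expected

    def test_identity_has_no_junction_sequences(self, toy):
        allele = identity_allele(toy.locus)
        assert junction_sequences(allele, toy.reference, flank=10) == []

    def test_overlong_flank_truncated_with_flag(self, toy):
        sv = parse_hgvs_sv("g.5000_5001ins[ACGT;6000_6004;TT]", id="t",
                           chrom="toy")
        allele = build_derived_allele(sv, toy.locus)
        seqs = junction_sequences(allele, toy.reference, flank=50)
        assert any(js.truncated for js in seqs)

    def test_inversion_involution(self, toy):
        """Re-inverting an inverted insert restores direct-orientation
        junction sequence at the re-entry point."""
        direct = parse_hgvs_sv("g.4000_4001ins[6000_6499]", id="d",
                               chrom="toy")
        # insert the same segment inverted, then build the equivalent of
        # inverting it again: the doubly-inverted allele equals the direct one
        twice = ComplexSV(
            id="dd", anchor_kind="ins",
            anchor=GenomicInterval("toy", 4000, 4001),
            elements=(InsertedElement(
                kind="ref_segment",
                interval=GenomicInterval("toy", 6000, 6499),
                inverted=False),))
        a1 = build_derived_allele(direct, toy.locus)
        a2 = build_derived_allele(twice, toy.locus)
        s1 = [j.sequence for j in junction_sequences(a1, toy.reference, 8)]
        s2 = [j.sequence for j in junction_sequences(a2, toy.reference, 8)]
        assert s1 == s2


class TestDiploidProfile:
    def test_adds_wild_type_allele(self, sv_by_id, locus):
        single = copy_number_profile(sv_by_id["DE-SV9"], locus)
        dip = diploid_profile(single)
        assert dip.count_at(59_200_000) == 3   # duplication: total CN 3
        assert dip.count_at(59_427_000) == 4   # triplication: total CN 4
        assert dip.count_at(59_100_000) == 2

    def test_identity_diploid_two(self, locus):
        dip = diploid_profile(copy_number_profile(None, locus))
        assert dip.counts == (2,)

    def test_bed_export_is_zero_based_half_open(self, sv_by_id, locus):
        bed = copy_number_profile(sv_by_id["NL-SV1"], locus).to_bed()
        lines = [l.split("\t") for l in bed.strip().split("\n")]
        assert lines[1] == ["chr17", "59214553", "59440776", "CN", "2"]
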