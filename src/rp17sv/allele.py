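"""Derived-allele reconstruction and copy-number arithmetic.

A :class:`ComplexSV` is turned into the rearranged haplotype it describes:
an ordered list of oriented reference segments (and novel linker
sequences) tiling the derived allele, together with the novel breakpoint
junctions between them. Per-base copy counts over the reference locus
follow by interval arithmetic:

    count(base) = 1  - [base in delins anchor]
                     + [base in dup anchor (dup only)]
                     + #(inserted reference segments covering base)

Counts are reported per derived allele; the diploid view (one wild-type
allele added, the configuration seen by qPCR and SNP arrays under dominant
inheritance) is an explicit transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Protocol, Sequence

from rp17sv.nomenclature import ComplexSV, GenomicInterval, InsertedElement

__all__ = [
    "OrientedSegment", "Junction", "JunctionEnd", "JunctionSequence",
    "DerivedAllele", "CopyNumberProfile", "build_derived_allele",
    "identity_allele", "copy_number_profile", "amplified_regions",
    "shared_amplified_regions", "shared_amplified_region",
    "junction_sequences", "diploid_profile", "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrientedSegment:
    """One tile of the derived allele: a reference interval in a given
    orientation, or a stretch of novel sequence."""

    source: Optional[GenomicInterval]  # None for novel sequence
    inverted: bool
    derived_start: int  # 1-based on the derived allele
    derived_end: int
    novel_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        length = self.derived_end - self.derived_start + 1
        if self.source is not None and length != self.source.length():
            raise ValueError("derived span must match source length")
        if self.novel_sequence is not None and length != len(self.novel_sequence):
            raise ValueError("derived span must match novel sequence length")

    @property
    def is_novel(self) -> bool:
        return self.source is None

    def length(self) -> int:
        return self.derived_end - self.derived_start + 1

    def map_ref_to_derived(self, pos: int) -> int:
        """Map a reference position inside this segment onto the derived
        allele (reflecting map for inverted segments)."""
        assert self.source is not None and self.source.contains_pos(pos)
        if self.inverted:
            return self.derived_start + (self.source.end - pos)
        return self.derived_start + (pos - self.source.start)


@dataclass(frozen=True)
class JunctionEnd:
    """One side of a breakpoint junction: the reference base at which a
    derived-allele segment is entered or exited, which end of that segment
    it is (5' or 3' in reference orientation), and the segment's
    orientation on the derived allele."""

    pos: int
    side: str  # "5'" | "3'"
    orientation: str  # "+" (direct) | "-" (inverted)


@dataclass(frozen=True)
class Junction:
    """A novel adjacency between two reference positions on the derived
    allele, optionally with inserted linker sequence between them."""

    left: JunctionEnd
    right: JunctionEnd
    linker: str = ""
    derived_pos: int = 0  # derived coordinate of the last base before the junction

    def describe(self) -> str:
        lk = f";{self.linker};" if self.linker else "|"
        return (f"{self.left.side}({self.left.orientation}) of {self.left.pos}"
                f" {lk} {self.right.side}({self.right.orientation}) of "
                f"{self.right.pos}")


@dataclass(frozen=True)
class JunctionSequence:
    junction: Junction
    sequence: str
    truncated: bool  # a flank exceeded its segment and was shortened


@dataclass(frozen=True)
class DerivedAllele:
    """The reconstructed rearranged haplotype over a modeled locus window."""

    locus: GenomicInterval
    segments: tuple[OrientedSegment, ...]
    junctions: tuple[Junction, ...]

    def __post_init__(self) -> None:
        pos = 1
        for seg in self.segments:
            if seg.derived_start != pos:
                raise ValueError("segments must tile the derived allele")
            pos = seg.derived_end + 1

    def length(self) -> int:
        return self.segments[-1].derived_end if self.segments else 0

    @property
    def is_identity(self) -> bool:
        return not self.junctions and len(self.segments) == 1


def _exit_end(seg: OrientedSegment) -> JunctionEnd:
    assert seg.source is not None
    if seg.inverted:
        return JunctionEnd(seg.source.start, "5'", "-")
    return JunctionEnd(seg.source.end, "3'", "+")


def _entry_end(seg: OrientedSegment) -> JunctionEnd:
    assert seg.source is not None
    if seg.inverted:
        return JunctionEnd(seg.source.end, "3'", "-")
    return JunctionEnd(seg.source.start, "5'", "+")


def _reference_contiguous(a: OrientedSegment, b: OrientedSegment) -> bool:
    assert a.source is not None and b.source is not None
    if a.inverted != b.inverted:
        return False
    if not a.inverted:
        return b.source.start == a.source.end + 1
    return b.source.end == a.source.start - 1


def identity_allele(locus: GenomicInterval) -> DerivedAllele:
    """The wild-type allele: one direct segment spanning the locus."""
    seg = OrientedSegment(source=locus, inverted=False, derived_start=1,
                          derived_end=locus.length())
    return DerivedAllele(locus=locus, segments=(seg,), junctions=())


def build_derived_allele(sv: Optional[ComplexSV],
                         locus: GenomicInterval) -> DerivedAllele:
    """Reconstruct the derived allele for ``sv`` over the modeled window.

    ``None`` yields the identity (wild-type) allele. Raises ValueError if
    the anchor or any element interval is not fully inside ``locus``.
    """
    if sv is None:
        return identity_allele(locus)
    if not locus.contains(sv.anchor):
        raise ValueError(f"{sv.id or 'SV'}: anchor {sv.anchor} outside "
                         f"locus {locus}")
    for el in sv.elements:
        if el.kind == "ref_segment" and not locus.contains(el.interval):
            raise ValueError(f"{sv.id or 'SV'}: element {el.interval} "
                             f"outside locus {locus}")

    # (interval-or-None, inverted, novel_seq-or-None) tiles, in order
    pieces: list[tuple[Optional[GenomicInterval], bool, Optional[str]]] = []

    def add_ref(start: int, end: int, inverted: bool = False) -> None:
        if start > end:
            return  # empty flank at a window edge
        pieces.append((GenomicInterval(locus.chrom, start, end), inverted, None))

    if sv.anchor_kind == "dup":
        add_ref(locus.start, sv.anchor.end)
        add_ref(sv.anchor.start, sv.anchor.end)
        add_ref(sv.anchor.end + 1, locus.end)
    else:
        if sv.anchor_kind == "ins":
            left_end, right_start = sv.anchor.start, sv.anchor.end
        else:  # delins
            left_end, right_start = sv.anchor.start - 1, sv.anchor.end + 1
        add_ref(locus.start, left_end)
        for el in sv.elements:
            if el.kind == "ref_segment":
                pieces.append((el.interval, el.inverted, None))
            else:
                pieces.append((None, False, el.sequence))
        add_ref(right_start, locus.end)

    segments: list[OrientedSegment] = []
    pos = 1
    for interval, inverted, seq in pieces:
        length = interval.length() if interval is not None else len(seq)
        segments.append(OrientedSegment(
            source=interval, inverted=inverted, derived_start=pos,
            derived_end=pos + length - 1, novel_sequence=seq))
        pos += length

    junctions: list[Junction] = []
    prev: Optional[OrientedSegment] = None
    linker_parts: list[str] = []
    for seg in segments:
        if seg.is_novel:
            linker_parts.append(seg.novel_sequence or "")
            continue
        if prev is not None:
            linker = "".join(linker_parts)
            if linker or not _reference_contiguous(prev, seg):
                junctions.append(Junction(
                    left=_exit_end(prev), right=_entry_end(seg),
                    linker=linker, derived_pos=prev.derived_end))
        prev = seg
        linker_parts = []
    if linker_parts:
        raise ValueError(f"{sv.id or 'SV'}: trailing novel sequence with no "
                         "following reference segment")

    return DerivedAllele(locus=locus, segments=tuple(segments),
                         junctions=tuple(junctions))


@dataclass(frozen=True)
class CopyNumberProfile:
    """Piecewise-constant per-base copy count over the locus, maximally
    merged (adjacent partitions always differ). ``breakpoints`` are the
    start positions of every partition after the first."""

    locus: GenomicInterval
    breakpoints: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one count per partition")
        if any(c < 0 for c in self.counts):
            raise ValueError("copy counts must be non-negative")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        for a, b in zip(self.counts, self.counts[1:]):
            if a == b:
                raise ValueError("profile not maximally merged")

    def partitions(self) -> Iterator[tuple[GenomicInterval, int]]:
        starts = (self.locus.start,) + self.breakpoints
        ends = tuple(b - 1 for b in self.breakpoints) + (self.locus.end,)
        for s, e, c in zip(starts, ends, self.counts):
            yield GenomicInterval(self.locus.chrom, s, e), c

    def count_at(self, pos: int) -> int:
        if not self.locus.contains_pos(pos):
            raise ValueError(f"position {pos} outside locus {self.locus}")
        idx = 0
        for b in self.breakpoints:
            if pos >= b:
                idx += 1
        return self.counts[idx]

    def to_bed(self) -> str:
        """BED (0-based half-open) with the copy count in the score column."""
        lines = []
        for iv, c in self.partitions():
            lines.append(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tCN\t{c}")
        return "\n".join(lines) + "\n"


def _merged_profile(locus: GenomicInterval,
                    deltas: dict[int, int]) -> CopyNumberProfile:
    positions = sorted(p for p in deltas if locus.start < p <= locus.end)
    breakpoints: list[int] = []
    counts: list[int] = []
    running = deltas.get(locus.start, 0)
    counts.append(running)
    for p in positions:
        running += deltas[p]
        if running != counts[-1]:
            breakpoints.append(p)
            counts.append(running)
    return CopyNumberProfile(locus=locus, breakpoints=tuple(breakpoints),
                             counts=tuple(counts))


def copy_number_profile(sv: Optional[ComplexSV],
                        locus: GenomicInterval) -> CopyNumberProfile:
    """Per-base copy count of the derived allele over the reference locus,
    by interval (difference-array) arithmetic."""
    deltas: dict[int, int] = {locus.start: 1}

    def add(interval: GenomicInterval, weight: int) -> None:
        deltas[interval.start] = deltas.get(interval.start, 0) + weight
        deltas[interval.end + 1] = deltas.get(interval.end + 1, 0) - weight

    if sv is not None:
        if not locus.contains(sv.anchor):
            raise ValueError(f"anchor {sv.anchor} outside locus {locus}")
        if sv.anchor_kind == "dup":
            add(sv.anchor, +1)
        elif sv.anchor_kind == "delins":
            add(sv.anchor, -1)
        for el in sv.elements:
            if el.kind == "ref_segment":
                if not locus.contains(el.interval):
                    raise ValueError(f"element {el.interval} outside locus")
                add(el.interval, +1)
    return _merged_profile(locus, deltas)


def amplified_regions(profile: CopyNumberProfile,
                      min_count: int = 2) -> list[GenomicInterval]:
    """Maximal intervals where the allele copy count is >= ``min_count``."""
    out: list[GenomicInterval] = []
    for iv, c in profile.partitions():
        if c < min_count:
            continue
        if out and out[-1].end + 1 == iv.start:
            out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def _intersect_sets(a: Sequence[GenomicInterval],
                    b: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    out = []
    for x in a:
        for y in b:
            z = x.intersect(y)
            if z is not None:
                out.append(z)
    return sorted(out)


def shared_amplified_regions(svs: Sequence[ComplexSV],
                             locus: GenomicInterval,
                             min_count: int = 2) -> list[GenomicInterval]:
    """Intersection, over every SV, of the union of its amplified regions."""
    if not svs:
        raise ValueError("catalogue must be non-empty")
    current: Optional[list[GenomicInterval]] = None
    for sv in svs:
        regions = amplified_regions(copy_number_profile(sv, locus), min_count)
        current = regions if current is None else _intersect_sets(current, regions)
        if not current:
            return []
    return current


def shared_amplified_region(svs: Sequence[ComplexSV],
                            locus: GenomicInterval,
                            min_count: int = 2) -> Optional[GenomicInterval]:
    """The genomic interval amplified (copy >= ``min_count``) in every SV
    of the catalogue, or None when no base is shared. If the intersection
    is fragmented the longest piece is returned."""
    pieces = shared_amplified_regions(svs, locus, min_count)
    if not pieces:
        return None
    return max(pieces, key=lambda iv: (iv.length(), -iv.start))


class SequenceProvider(Protocol):
    """Anything that can hand back reference sequence for an interval."""

    def sequence(self, interval: GenomicInterval) -> str: ...


def junction_sequences(allele: DerivedAllele, reference: SequenceProvider,
                       flank: int) -> list[JunctionSequence]:
    """Junction-spanning sequences in derived orientation: ``flank`` bases
    upstream of each junction (reverse-complemented where the upstream
    segment is inverted), the linker, and ``flank`` bases downstream.
    Flanks longer than their segment are truncated and flagged."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    # locate the ref segments flanking each junction by derived position
    ref_segments = [s for s in allele.segments if not s.is_novel]
    out: list[JunctionSequence] = []
    for jn in allele.junctions:
        left = next(s for s in ref_segments if s.derived_end == jn.derived_pos)
        left_idx = ref_segments.index(left)
        right = ref_segments[left_idx + 1]
        truncated = False

        lf = min(flank, left.length())
        rf = min(flank, right.length())
        truncated = lf < flank or rf < flank

        src = left.source
        if left.inverted:
            up = reverse_complement(reference.sequence(
                GenomicInterval(src.chrom, src.start, src.start + lf - 1)))
        else:
            up = reference.sequence(
                GenomicInterval(src.chrom, src.end - lf + 1, src.end))
        src = right.source
        if right.inverted:
            down = reverse_complement(reference.sequence(
                GenomicInterval(src.chrom, src.end - rf + 1, src.end)))
        else:
            down = reference.sequence(
                GenomicInterval(src.chrom, src.start, src.start + rf - 1))
        out.append(JunctionSequence(junction=jn,
                                    sequence=up + jn.linker + down,
                                    truncated=truncated))
    return out


def diploid_profile(profile: CopyNumberProfile) -> CopyNumberProfile:
    """Add the wild-type allele: total copy number seen by qPCR / arrays."""
    return CopyNumberProfile(locus=profile.locus,
                             breakpoints=profile.breakpoints,
                             counts=tuple(c + 1 for c in profile.counts))
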