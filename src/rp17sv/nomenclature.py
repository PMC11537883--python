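"""Parsing and serialization of the HGVS-style complex-SV dialect used for
the RP17 catalogue, plus loading of the packaged 10-SV catalogue.

The dialect covers exactly the constructs that appear in the catalogue:

    sv     := "g." (dup | ins | delins)
    dup    := INT "_" INT "dup"
    ins    := INT "_" INT "ins[" elems "]"
    delins := INT "_" INT "delins[" elems "]"
    elems  := elem (";" elem)*
    elem   := SEQ | [SEQ] INT "_" INT ["inv"]
    SEQ    := [ACGT]+

Coordinates are 1-based inclusive (HGVS g. convention) on an implicit
chromosome (chr17 by default; the catalogue strings omit it). Whitespace
after ";" is tolerated on input, and a novel-sequence run may be fused
directly to a following segment (as printed for SA-SV3); the canonical
serialization always separates elements with ";" and contains no spaces.
Anything outside this dialect (breakends, transcript-level HGVS, ...) is
rejected rather than silently accepted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "GenomicInterval", "InsertedElement", "ComplexSV", "SVCatalogueEntry",
    "SVParseError", "parse_hgvs_sv", "serialize_hgvs_sv", "load_catalogue",
    "packaged_catalogue_path",
]

DEFAULT_CHROM = "chr17"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [start, end] of 1-based reference coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


_VALID_SEQ = re.compile(r"[ACGT]+\Z")


@dataclass(frozen=True)
class InsertedElement:
    """One element of an ins/delins payload: either a reference segment
    (possibly inverted) or a stretch of novel linker sequence."""

    kind: str  # "ref_segment" | "novel_sequence"
    interval: Optional[GenomicInterval] = None
    inverted: bool = False
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "ref_segment":
            if self.interval is None or self.sequence is not None:
                raise ValueError("ref_segment requires interval, no sequence")
        elif self.kind == "novel_sequence":
            if self.sequence is None or self.interval is not None:
                raise ValueError("novel_sequence requires sequence, no interval")
            if self.inverted:
                raise ValueError("novel_sequence cannot be inverted")
            if not _VALID_SEQ.match(self.sequence):
                raise ValueError(
                    f"novel sequence must be non-empty over ACGT: {self.sequence!r}"
                )
        else:
            raise ValueError(f"unknown element kind: {self.kind!r}")

    @classmethod
    def segment(
        cls, start: int, end: int, inverted: bool = False,
        chrom: str = DEFAULT_CHROM,
    ) -> "InsertedElement":
        return cls(
            kind="ref_segment",
            interval=GenomicInterval(chrom, start, end),
            inverted=inverted,
        )

    @classmethod
    def novel(cls, sequence: str) -> "InsertedElement":
        return cls(kind="novel_sequence", sequence=sequence)

    def length(self) -> int:
        if self.kind == "ref_segment":
            assert self.interval is not None
            return self.interval.length()
        assert self.sequence is not None
        return len(self.sequence)


@dataclass(frozen=True)
class ComplexSV:
    """A parsed structural variant: an anchor edit plus its ordered payload.

    anchor_kind "dup": the anchor is the tandem-duplicated interval and the
    payload is empty. "ins": the anchor is the pair of flanking bases
    (end = start + 1) between which the payload is inserted. "delins": the
    anchor interval is replaced by the payload.
    """

    id: str
    anchor_kind: str  # "dup" | "ins" | "delins"
    anchor: GenomicInterval
    elements: tuple[InsertedElement, ...] = ()

    def __post_init__(self) -> None:
        if self.anchor_kind == "dup":
            if self.elements:
                raise ValueError("dup takes no inserted elements")
        elif self.anchor_kind == "ins":
            if self.anchor.end != self.anchor.start + 1:
                raise ValueError(
                    "ins anchor must be two adjacent bases "
                    f"(got {self.anchor.start}_{self.anchor.end})"
                )
            if not self.elements:
                raise ValueError("ins requires a non-empty element list")
        elif self.anchor_kind == "delins":
            if not self.elements:
                raise ValueError("delins requires a non-empty element list")
        else:
            raise ValueError(f"unknown anchor kind: {self.anchor_kind!r}")

    @property
    def chrom(self) -> str:
        return self.anchor.chrom

    def inserted_length(self) -> int:
        return sum(e.length() for e in self.elements)

    def deleted_length(self) -> int:
        return self.anchor.length() if self.anchor_kind == "delins" else 0


@dataclass(frozen=True)
class SVCatalogueEntry:
    """One row of the RP17 catalogue: the variant plus its epidemiology."""

    sv: ComplexSV
    origin: str
    n_affected: int
    n_families: int
    previously_described: bool
    identified_in_current_study: bool

    def __post_init__(self) -> None:
        if self.n_affected < 0 or self.n_families < 0:
            raise ValueError("counts must be non-negative")
        if self.n_families > 0 and self.n_affected < self.n_families:
            raise ValueError("n_affected must be >= n_families")


class SVParseError(ValueError):
    """Raised on input outside the catalogue dialect; carries the offending
    token and its position in the input string."""

    def __init__(self, message: str, text: str, pos: int) -> None:
        super().__init__(f"{message} at position {pos} in {text!r}")
        self.text = text
        self.pos = pos


_SV_RE = re.compile(
    r"g\.(?P<start>\d+)_(?P<end>\d+)"
    r"(?P<kind>dup|delins|ins)"
    r"(?:\[(?P<elems>[^\]]*)\])?\Z"
)
_ELEM_RE = re.compile(
    r"(?:(?P<seq>[ACGT]+)(?=\d|\Z))?"
    r"(?:(?P<s>\d+)_(?P<e>\d+)(?P<inv>inv)?)?\Z"
)


def parse_hgvs_sv(text: str, id: str = "", chrom: str = DEFAULT_CHROM) -> ComplexSV:
    """Parse one catalogue-dialect SV string into a :class:`ComplexSV`.

    Tolerates whitespace after ";" separators and a novel-sequence run fused
    directly to a following segment inside one element (split into two
    elements, order preserved). Any other deviation raises
    :class:`SVParseError` naming the offending token and position.
    """
    stripped = text.strip()
    m = _SV_RE.match(stripped)
    if not m:
        raise SVParseError("not a recognized g. dup/ins/delins description",
                           text, 0)
    kind = m.group("kind")
    start, end = int(m.group("start")), int(m.group("end"))
    if end < start:
        raise SVParseError(f"anchor end {end} precedes start {start}", text,
                           m.start("end"))
    if kind == "ins" and end != start + 1:
        raise SVParseError(
            f"ins anchor bases {start}_{end} are not adjacent", text,
            m.start("start"))

    elems_text = m.group("elems")
    if kind == "dup":
        if elems_text is not None:
            raise SVParseError("dup takes no [..] payload", text,
                               m.start("elems") - 1)
        return ComplexSV(id=id, anchor_kind="dup",
                         anchor=GenomicInterval(chrom, start, end))

    if elems_text is None:
        raise SVParseError(f"{kind} requires a [..] payload", text,
                           len(stripped))
    elements: list[InsertedElement] = []
    offset = m.start("elems")
    for token in elems_text.split(";"):
        tok_pos = offset + elems_text.find(token)
        token = token.strip()
        if not token:
            raise SVParseError("empty element", text, tok_pos)
        em = _ELEM_RE.match(token)
        if not em or (em.group("seq") is None and em.group("s") is None):
            raise SVParseError(f"malformed element {token!r}", text, tok_pos)
        if em.group("seq"):
            elements.append(InsertedElement.novel(em.group("seq")))
        if em.group("s"):
            s, e = int(em.group("s")), int(em.group("e"))
            if e < s:
                raise SVParseError(
                    f"segment end {e} precedes start {s}", text, tok_pos)
            elements.append(
                InsertedElement.segment(s, e, inverted=bool(em.group("inv")),
                                        chrom=chrom))
    if not elements:
        raise SVParseError(f"{kind} requires at least one element", text,
                           offset)
    return ComplexSV(id=id, anchor_kind=kind,
                     anchor=GenomicInterval(chrom, start, end),
                     elements=tuple(elements))


def serialize_hgvs_sv(sv: ComplexSV) -> str:
    """Emit the canonical dialect string: no whitespace, every element
    ";"-separated, "inv" suffixed on inverted segments."""
    head = f"g.{sv.anchor.start}_{sv.anchor.end}{sv.anchor_kind}"
    if sv.anchor_kind == "dup":
        return head
    parts = []
    for el in sv.elements:
        if el.kind == "novel_sequence":
            parts.append(el.sequence)
        else:
            assert el.interval is not None
            inv = "inv" if el.inverted else ""
            parts.append(f"{el.interval.start}_{el.interval.end}{inv}")
    return f"{head}[{';'.join(parts)}]"


_CATALOGUE_COLUMNS = [
    "id", "hgvs", "origin", "n_affected", "n_families",
    "previously_described", "identified_in_current_study",
]


def packaged_catalogue_path() -> Path:
    """Path to the packaged RP17 catalogue TSV (10 variants)."""
    return Path(resources.files("rp17sv").joinpath("data/rp17_catalogue.tsv"))


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def load_catalogue(path: str | Path | None = None,
                   chrom: str = DEFAULT_CHROM) -> list[SVCatalogueEntry]:
    """Load an SV catalogue from TSV or JSON.

    With no path, loads the packaged RP17 catalogue (the 10 reported
    variants with affected-individual counts). Raises ValueError naming the
    row id on any unparseable row.
    """
    if path is None:
        path = packaged_catalogue_path()
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        lines = path.read_text().rstrip("\n").split("\n")
        header = lines[0].split("\t")
        missing = set(_CATALOGUE_COLUMNS) - set(header)
        if missing:
            raise ValueError(f"catalogue missing columns: {sorted(missing)}")
        rows = [dict(zip(header, line.split("\t"))) for line in lines[1:]]
    entries = []
    for row in rows:
        sv_id = row.get("id", "<missing id>")
        try:
            entries.append(SVCatalogueEntry(
                sv=parse_hgvs_sv(row["hgvs"], id=sv_id, chrom=chrom),
                origin=row["origin"],
                n_affected=int(row["n_affected"]),
                n_families=int(row["n_families"]),
                previously_described=_parse_bool(row["previously_described"]),
                identified_in_current_study=_parse_bool(
                    row["identified_in_current_study"]),
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"catalogue row {sv_id!r}: {exc}") from exc
    return entries
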