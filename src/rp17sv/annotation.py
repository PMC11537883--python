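"""Regulatory annotation of the locus and its projection onto a derived
allele.

Features (genes, promoters, retinal enhancers, CTCF-enriched boundary
elements) live on reference coordinates; a rearrangement carries each
feature onto the derived allele once per overlapping segment, through that
segment's affine (possibly reflecting) coordinate map. A projection is
``truncated`` when a breakpoint falls inside the feature — for a boundary
element this is what "boundary disruption" means downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from rp17sv.allele import DerivedAllele
from rp17sv.nomenclature import GenomicInterval

__all__ = [
    "Feature", "LocusModel", "ProjectedFeature", "read_bed_track",
    "project_features", "load_locus_model", "packaged_locus_model_path",
]

FEATURE_KINDS = ("gene", "promoter", "enhancer", "boundary")


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str
    interval: GenomicInterval
    strand: str = "."

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; "
                             f"expected one of {FEATURE_KINDS}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class LocusModel:
    """Annotation tracks over the modeled reference window."""

    locus: GenomicInterval
    features: tuple[Feature, ...]
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        for f in self.features:
            if not self.locus.contains(f.interval):
                raise ValueError(f"feature {f.name} {f.interval} outside "
                                 f"locus {self.locus}")

    def by_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def by_name(self, name: str) -> Feature:
        hits = [f for f in self.features if f.name == name]
        if not hits:
            raise KeyError(f"no feature named {name!r} in locus model")
        if len(hits) > 1:
            raise KeyError(f"feature name {name!r} is ambiguous")
        return hits[0]

    def without(self, name: str) -> "LocusModel":
        return LocusModel(self.locus,
                          tuple(f for f in self.features if f.name != name),
                          self.build)


@dataclass(frozen=True)
class ProjectedFeature:
    """One copy of a reference feature on the derived allele."""

    source: Feature
    derived_interval: GenomicInterval  # chrom "derived"
    inverted: bool
    truncated: bool
    copy_index: int  # ordinal of this copy along the derived allele, >= 1

    @property
    def derived_midpoint(self) -> int:
        iv = self.derived_interval
        return (iv.start + iv.end) // 2


def read_bed_track(path: str | Path, kind: str) -> list[Feature]:
    """Read a BED3+ track (0-based half-open; optional name and strand
    columns) into 1-based-inclusive :class:`Feature` records of ``kind``."""
    features: list[Feature] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
        try:
            chrom, start0, end0 = cols[0], int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
        if end0 <= start0:
            raise ValueError(f"{path}:{lineno}: end <= start")
        name = cols[3] if len(cols) > 3 and cols[3] else f"{kind}_{lineno}"
        strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
        features.append(Feature(name=name, kind=kind,
                                interval=GenomicInterval(chrom, start0 + 1, end0),
                                strand=strand))
    return features


def packaged_locus_model_path() -> Path:
    return Path(resources.files("rp17sv").joinpath("data/rp17_locus_model.json"))


def load_locus_model(path: str | Path | None = None) -> LocusModel:
    """Load a locus model from its JSON bundle (packaged RP17 fixture by
    default: GDPD1 with promoter, YPEL2, LINC01476, one CTCF boundary, and
    three retinal enhancers at documented approximate coordinates)."""
    if path is None:
        path = packaged_locus_model_path()
    doc = json.loads(Path(path).read_text())
    loc = doc["locus"]
    locus = GenomicInterval(loc["chrom"], int(loc["start"]), int(loc["end"]))
    features = tuple(
        Feature(name=f["name"], kind=f["kind"],
                interval=GenomicInterval(loc["chrom"], int(f["start"]),
                                         int(f["end"])),
                strand=f.get("strand", "."))
        for f in doc["features"])
    return LocusModel(locus=locus, features=features,
                      build=doc.get("build", "GRCh38"))


def project_features(model: LocusModel,
                     allele: DerivedAllele) -> list[ProjectedFeature]:
    """Project every feature onto the derived allele, one projection per
    overlapping segment. ``inverted`` is the segment orientation XOR the
    feature being on the minus strand (strandless features never flip from
    strand); ``truncated`` marks copies cut by a breakpoint."""
    if model.locus != allele.locus:
        raise ValueError("locus model and allele windows differ")
    projections: list[ProjectedFeature] = []
    copy_counter: dict[str, int] = {}
    for seg in allele.segments:
        if seg.is_novel:
            continue  # linkers are novel sequence: no features by construction
        for feat in model.features:
            clipped = feat.interval.intersect(seg.source)
            if clipped is None:
                continue
            d1 = seg.map_ref_to_derived(clipped.start)
            d2 = seg.map_ref_to_derived(clipped.end)
            derived = GenomicInterval("derived", min(d1, d2), max(d1, d2))
            idx = copy_counter.get(feat.name, 0) + 1
            copy_counter[feat.name] = idx
            projections.append(ProjectedFeature(
                source=feat,
                derived_interval=derived,
                inverted=seg.inverted != (feat.strand == "-"),
                truncated=clipped != feat.interval,
                copy_index=idx,
            ))
    return projections
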