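"""Synthetic inputs for the whole pipeline: the packaged catalogue and
locus annotation, noisy qPCR / SNP-array / smMIPs measurement tables
conditioned on a chosen SV, and a toy reference sequence with an affine
map from the real locus for cheap per-base testing.

Every generator is a pure function of (config, inputs); one seed governs
a named substream per generator, so adding a generator never perturbs the
values an existing one produces. At zero noise every generated
measurement equals its closed-form expectation.

The measurement model is deliberately simple: Gaussian noise on Ct values
and on log2 ratios, no overdispersion, no probe GC effects, no PCR
efficiency deviation from 2. The smMIPs Bayes factor is a Gaussian
log-marginal-likelihood ratio between copy-number hypotheses on the
simulated probe ratios — a documented stand-in for the calling pipeline
whose output tables this package consumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from rp17sv.allele import copy_number_profile, diploid_profile, amplified_regions
from rp17sv.annotation import Feature, LocusModel, load_locus_model, \
    packaged_locus_model_path
from rp17sv.nomenclature import (ComplexSV, GenomicInterval, InsertedElement,
                                 SVCatalogueEntry, load_catalogue,
                                 packaged_catalogue_path)

__all__ = [
    "FixtureConfig", "StringReference", "ToyLocus", "rp17_locus_fixture",
    "qpcr_amplicons", "generate_qpcr_table", "generate_array_profile",
    "generate_smmips_calls", "toy_locus", "random_complex_sv",
    "write_fixture_bundle",
]

DEFAULT_LOCUS = GenomicInterval("chr17", 59_100_000, 59_700_000)

# qPCR baselines (cycles): arbitrary plateau constants; only differences
# of Ct values matter downstream.
CT_BASELINE_TARGET = 26.0
CT_BASELINE_REFERENCE = 21.0
REFERENCE_AMPLICON = "RPPH1"

# substream ids for the named per-generator RNG streams
_STREAMS = {"qpcr": 1, "array": 2, "smmips": 3, "toy": 4}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic generators.

    sigma_ct is the replicate-level Ct noise SD in cycles; sigma_log2 the
    per-probe array noise SD; probe_spacing the array probe pitch in bp.
    """

    seed: int = 0
    locus: GenomicInterval = DEFAULT_LOCUS
    probe_spacing: int = 1_000
    sigma_ct: float = 0.05
    sigma_log2: float = 0.1
    n_negative_samples: int = 9
    n_replicates: int = 2
    smmips_probe_spacing: int = 2_000
    smmips_sigma_log2: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma_ct < 0 or self.sigma_log2 < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.probe_spacing < 1 or self.smmips_probe_spacing < 1:
            raise ValueError("probe spacing must be >= 1")


def _rng(config: FixtureConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


def rp17_locus_fixture() -> tuple[LocusModel, list[SVCatalogueEntry]]:
    """The packaged RP17 fixture: approximate locus annotation (genes,
    GDPD1 promoter, CTCF boundary, three retinal enhancers in the minimal
    shared interval) plus the 10-variant catalogue."""
    return load_locus_model(), load_catalogue()


def qpcr_amplicons(path: str | Path | None = None) -> dict[str, GenomicInterval]:
    """The two RP17 qPCR target amplicons (GDPD1 exon3/intron3 and
    LINC01476 intron 2) from the locus-model bundle."""
    doc = json.loads(Path(path or packaged_locus_model_path()).read_text())
    chrom = doc["locus"]["chrom"]
    return {name: GenomicInterval(chrom, int(spec["start"]), int(spec["end"]))
            for name, spec in doc["qpcr_amplicons"].items()
            if isinstance(spec, dict)}


def _diploid_cn(sv: Optional[ComplexSV], locus: GenomicInterval,
                interval: GenomicInterval) -> float:
    """Mean diploid copy number over an amplicon/probe interval."""
    if sv is None:
        return 2.0
    dip = diploid_profile(copy_number_profile(sv, locus))
    total = 0
    for part, count in dip.partitions():
        ov = part.intersect(interval)
        if ov is not None:
            total += count * ov.length()
    return total / interval.length()


def generate_qpcr_table(config: FixtureConfig,
                        sv: Optional[ComplexSV],
                        sample: str = "index",
                        calibrator: str = "calibrator",
                        amplicons: dict[str, GenomicInterval] | None = None,
                        ) -> pd.DataFrame:
    """Replicate Ct table (columns sample, target, ct) for an SV carrier
    (or a copy-normal sample when ``sv`` is None) plus a copy-normal
    calibrator, at the two RP17 target amplicons and the off-locus
    reference amplicon.

    Ct = baseline - log2(diploid CN / 2) + N(0, sigma_ct); the reference
    amplicon is unaffected by locus copy number.
    """
    amplicons = amplicons or qpcr_amplicons()
    rng = _rng(config, "qpcr")
    rows = []
    for who, who_sv in ((sample, sv), (calibrator, None)):
        for target, interval in amplicons.items():
            cn = _diploid_cn(who_sv, config.locus, interval)
            expected = CT_BASELINE_TARGET - math.log2(cn / 2.0)
            for _ in range(config.n_replicates):
                noise = rng.normal(0.0, config.sigma_ct) if config.sigma_ct else 0.0
                rows.append((who, target, expected + noise))
        for _ in range(config.n_replicates):
            noise = rng.normal(0.0, config.sigma_ct) if config.sigma_ct else 0.0
            rows.append((who, REFERENCE_AMPLICON, CT_BASELINE_REFERENCE + noise))
    return pd.DataFrame(rows, columns=["sample", "target", "ct"])


def generate_array_profile(config: FixtureConfig,
                           sv: Optional[ComplexSV],
                           sample: str = "index") -> "pd.DataFrame":
    """Per-probe log2-ratio table (columns sample, position, log2_ratio)
    on a regular probe grid: log2(diploid CN / 2) + N(0, sigma_log2)."""
    rng = _rng(config, "array")
    positions = np.arange(config.locus.start, config.locus.end + 1,
                          config.probe_spacing, dtype=int)
    if sv is None:
        expected = np.zeros(len(positions))
    else:
        dip = diploid_profile(copy_number_profile(sv, config.locus))
        expected = np.empty(len(positions))
        i = 0
        for part, count in dip.partitions():
            while i < len(positions) and positions[i] <= part.end:
                expected[i] = math.log2(count / 2.0)
                i += 1
    noise = (rng.normal(0.0, config.sigma_log2, size=len(positions))
             if config.sigma_log2 else np.zeros(len(positions)))
    return pd.DataFrame({"sample": sample, "position": positions,
                         "log2_ratio": expected + noise})


def _gaussian_log_bf(observed: np.ndarray, expected_alt: np.ndarray,
                     sigma: float) -> float:
    """Log evidence ratio, alternative CN model vs diploid, for Gaussian
    probe log2 ratios."""
    if sigma <= 0:
        sigma = 1e-9
    alt = -0.5 * ((observed - expected_alt) / sigma) ** 2
    null = -0.5 * (observed / sigma) ** 2
    return float(np.sum(alt - null))


def generate_smmips_calls(config: FixtureConfig,
                          cohort: Sequence[tuple[str, Optional[ComplexSV]]],
                          n_false_positives: int = 0) -> pd.DataFrame:
    """CNV-call table (columns sample, chrom, start, end, state, bf,
    internal_freq) for a cohort of (sample, SV-or-None) pairs.

    Carriers get one gain call per amplified region, with a Bayes factor
    from the Gaussian evidence model over simulated probe ratios; optional
    false-positive gain calls are sprinkled on random samples. The
    internal frequency of each call is the fraction of cohort samples
    sharing an overlapping call.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rng = _rng(config, "smmips")
    sigma = config.smmips_sigma_log2
    locus = config.locus
    raw: list[dict] = []
    for sample, sv in cohort:
        if sv is None:
            continue
        profile = copy_number_profile(sv, locus)
        dip = diploid_profile(profile)
        for region in amplified_regions(profile, min_count=2):
            probes = np.arange(region.start, region.end + 1,
                               config.smmips_probe_spacing, dtype=int)
            expected = np.array([math.log2(dip.count_at(int(p)) / 2.0)
                                 for p in probes])
            observed = expected + (rng.normal(0.0, sigma, size=len(probes))
                                   if sigma else 0.0)
            log_bf = _gaussian_log_bf(observed, expected, sigma)
            raw.append({"sample": sample, "chrom": region.chrom,
                        "start": region.start, "end": region.end,
                        "state": "gain",
                        "bf": float(np.exp(min(log_bf, 700.0)))})
    samples = [s for s, _ in cohort]
    for _ in range(n_false_positives):
        sample = samples[int(rng.integers(len(samples)))]
        start = int(rng.integers(locus.start, locus.end - 20_000))
        raw.append({"sample": sample, "chrom": locus.chrom, "start": start,
                    "end": start + 20_000, "state": "gain",
                    "bf": float(rng.uniform(50.0, 300.0))})
    n = len(cohort)
    for call in raw:
        sharing = {other["sample"] for other in raw
                   if other["start"] <= call["end"]
                   and call["start"] <= other["end"]}
        call["internal_freq"] = len(sharing) / n
    return pd.DataFrame(raw, columns=["sample", "chrom", "start", "end",
                                      "state", "bf", "internal_freq"])


@dataclass(frozen=True)
class StringReference:
    """In-memory sequence provider for a single contiguous window."""

    chrom: str
    start: int  # reference coordinate of seq[0]
    seq: str

    def sequence(self, interval: GenomicInterval) -> str:
        if interval.chrom != self.chrom:
            raise ValueError(f"no sequence for {interval.chrom}")
        lo = interval.start - self.start
        hi = interval.end - self.start + 1
        if lo < 0 or hi > len(self.seq):
            raise ValueError(f"{interval} outside reference window")
        return self.seq[lo:hi]

    def to_fasta(self, name: str | None = None) -> str:
        header = name or f"{self.chrom}:{self.start}-{self.start + len(self.seq) - 1}"
        body = "\n".join(self.seq[i:i + 70] for i in range(0, len(self.seq), 70))
        return f">{header}\n{body}\n"


@dataclass(frozen=True)
class ToyLocus:
    """A 10-kb random reference with an affine, containment-preserving
    coordinate map from the real locus, for cheap per-base oracles and
    junction-sequence tests."""

    locus: GenomicInterval
    reference: StringReference
    real_locus: GenomicInterval

    def map_position(self, pos: int) -> int:
        span_real = self.real_locus.length() - 1
        span_toy = self.locus.length() - 1
        frac = (pos - self.real_locus.start) / span_real
        return self.locus.start + round(frac * span_toy)

    def map_interval(self, iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(self.locus.chrom, self.map_position(iv.start),
                               self.map_position(iv.end))

    def map_sv(self, sv: ComplexSV) -> ComplexSV:
        if sv.anchor_kind == "ins":
            a = self.map_position(sv.anchor.start)
            anchor = GenomicInterval(self.locus.chrom, a, a + 1)
        else:
            anchor = self.map_interval(sv.anchor)
        elements = tuple(
            el if el.kind == "novel_sequence" else InsertedElement(
                kind="ref_segment", interval=self.map_interval(el.interval),
                inverted=el.inverted)
            for el in sv.elements)
        return ComplexSV(id=sv.id, anchor_kind=sv.anchor_kind, anchor=anchor,
                         elements=elements)


def toy_locus(seed: int = 0, length: int = 10_000,
              real_locus: GenomicInterval = DEFAULT_LOCUS) -> ToyLocus:
    """Deterministic 10-kb random ACGT sequence on chromosome "toy"."""
    rng = np.random.default_rng([_STREAMS["toy"], seed])
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    locus = GenomicInterval("toy", 1, length)
    return ToyLocus(locus=locus,
                    reference=StringReference("toy", 1, seq),
                    real_locus=real_locus)


def random_complex_sv(rng: np.random.Generator, locus: GenomicInterval,
                      sv_id: str = "random",
                      max_elements: int = 4) -> ComplexSV:
    """A random valid dup/ins/delins over the interior of ``locus``, for
    grammar fuzzing and copy-number oracle checks."""
    lo, hi = locus.start + 1, locus.end - 1

    def interval() -> GenomicInterval:
        a, b = sorted(int(x) for x in rng.integers(lo, hi + 1, size=2))
        return GenomicInterval(locus.chrom, a, b)

    def element() -> InsertedElement:
        if rng.random() < 0.3:
            n = int(rng.integers(1, 30))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
            return InsertedElement.novel(seq)
        iv = interval()
        return InsertedElement(kind="ref_segment", interval=iv,
                               inverted=bool(rng.random() < 0.5))

    kind = ("dup", "ins", "delins")[int(rng.integers(3))]
    if kind == "dup":
        return ComplexSV(id=sv_id, anchor_kind="dup", anchor=interval())
    n_el = int(rng.integers(1, max_elements + 1))
    elements = tuple(element() for _ in range(n_el))
    if kind == "ins":
        a = int(rng.integers(lo, hi))
        anchor = GenomicInterval(locus.chrom, a, a + 1)
    else:
        anchor = interval()
    return ComplexSV(id=sv_id, anchor_kind=kind, anchor=anchor,
                     elements=elements)


def write_fixture_bundle(outdir: str | Path,
                         config: FixtureConfig | None = None,
                         sv_id: str = "DE-SV9") -> list[Path]:
    """Materialize the full set of pipeline inputs under ``outdir``:
    catalogue TSV, locus-model JSON, per-kind BED tracks, toy reference
    FASTA, and synthetic qPCR / array / smMIPs tables for one carrier of
    ``sv_id`` in an otherwise negative cohort."""
    config = config or FixtureConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, catalogue = rp17_locus_fixture()
    by_id = {e.sv.id: e.sv for e in catalogue}
    sv = by_id[sv_id]
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written.append(path)

    emit("rp17_catalogue.tsv", packaged_catalogue_path().read_text())
    emit("rp17_locus_model.json", packaged_locus_model_path().read_text())
    for kind in ("gene", "promoter", "enhancer", "boundary"):
        lines = [f"{f.interval.chrom}\t{f.interval.start - 1}"
                 f"\t{f.interval.end}\t{f.name}\t0\t{f.strand}"
                 for f in model.by_kind(kind)]
        emit(f"{kind}s.bed", "\n".join(lines) + "\n")
    toy = toy_locus(config.seed)
    emit("toy_reference.fa", toy.reference.to_fasta("toy"))

    qpcr = generate_qpcr_table(config, sv, sample=sv_id)
    emit("qpcr.tsv", qpcr.to_csv(sep="\t", index=False))
    array = generate_array_profile(config, sv, sample=sv_id)
    emit("array.tsv", array.to_csv(sep="\t", index=False))
    cohort = [(sv_id, sv)] + [(f"negative_{i}", None)
                              for i in range(config.n_negative_samples)]
    calls = generate_smmips_calls(config, cohort)
    emit("smmips_calls.tsv", calls.to_csv(sep="\t", index=False))
    return written
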