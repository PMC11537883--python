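"""Prescreening and validation decision rules: qPCR ddCt copy-state
calls, smMIPs CNV-call filtering, SNP-array signature matching against the
SV catalogue, and SNV prioritization.

All thresholds that the underlying assays leave implicit are module-level
defaults and keyword arguments, never hard-wired inside the logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from rp17sv.allele import amplified_regions, copy_number_profile, diploid_profile
from rp17sv.nomenclature import ComplexSV, GenomicInterval

__all__ = [
    "QPCRMeasurement", "QPCRResult", "CNVCall", "ArrayProfile",
    "VariantRecord", "ddct_fold_change", "qpcr_calls_from_table",
    "filter_cnv_calls",
    "segment_array_profile", "match_array_signature", "prioritize_snvs",
    "QPCR_STATE_THRESHOLDS", "ARRAY_LOG2_CUT_CN3", "ARRAY_LOG2_CUT_CN4",
    "ARRAY_WINDOW_BP", "ARRAY_MATCH_THRESHOLD", "NO_MATCH",
]

# qPCR copy-state bands around the theoretical diploid ratios 1.0 (2n),
# 1.5 (3n) and 2.0 (4n): cut at the midpoints, with guard bands outside.
QPCR_STATE_THRESHOLDS = {
    "normal": (0.8, 1.25),
    "duplication": (1.25, 1.75),
    "triplication": (1.75, 2.3),
}

# Array segmentation: fixed windows, log2-ratio cuts at the midpoints of
# log2(2/2)=0, log2(3/2)~0.585 and log2(4/2)=1.
ARRAY_WINDOW_BP = 10_000
ARRAY_LOG2_CUT_CN3 = 0.32
ARRAY_LOG2_CUT_CN4 = 0.70
ARRAY_MATCH_THRESHOLD = 0.8
NO_MATCH = "novel/no-match"


@dataclass(frozen=True)
class QPCRMeasurement:
    """Replicate Ct values for one (sample, amplicon) pair."""

    sample: str
    target: str
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_replicates:
            raise ValueError(f"{self.sample}/{self.target}: no Ct replicates")
        for ct in self.ct_replicates:
            if not math.isfinite(ct):
                raise ValueError(f"{self.sample}/{self.target}: non-finite Ct")
            if ct < 0:
                raise ValueError(f"{self.sample}/{self.target}: negative Ct")

    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass(frozen=True)
class QPCRResult:
    sample: str
    target: str
    fold_change: float
    state: str  # normal | duplication | triplication | no_call

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def _call_state(fold: float,
                thresholds: dict[str, tuple[float, float]]) -> str:
    for state, (lo, hi) in thresholds.items():
        if lo <= fold < hi or (state == "triplication" and fold == hi):
            return state
    return "no_call"


def ddct_fold_change(sample_target: QPCRMeasurement,
                     sample_reference: QPCRMeasurement,
                     calibrator_target: QPCRMeasurement,
                     calibrator_reference: QPCRMeasurement,
                     thresholds: dict[str, tuple[float, float]] | None = None,
                     ) -> QPCRResult:
    """Relative quantification by the ddCt method (amplification
    efficiency 2 assumed):

        dCt        = mean Ct(target) - mean Ct(reference amplicon)
        ddCt       = dCt(sample) - dCt(calibrator)
        fold       = 2 ** (-ddCt)

    The calibrator must be a copy-number-normal sample; a fold change of
    1.5 / 2.0 is the diploid expectation for one extra / two extra copies.
    """
    if sample_target.target != calibrator_target.target:
        raise ValueError("sample and calibrator target amplicons differ")
    if sample_reference.target != calibrator_reference.target:
        raise ValueError("sample and calibrator reference amplicons differ")
    d_sample = sample_target.mean_ct() - sample_reference.mean_ct()
    d_cal = calibrator_target.mean_ct() - calibrator_reference.mean_ct()
    fold = float(2.0 ** (-(d_sample - d_cal)))
    state = _call_state(fold, thresholds or QPCR_STATE_THRESHOLDS)
    return QPCRResult(sample=sample_target.sample,
                      target=sample_target.target,
                      fold_change=fold, state=state)


def qpcr_calls_from_table(table, sample: str, calibrator: str,
                          reference_target: str = "RPPH1",
                          thresholds: dict[str, tuple[float, float]] | None = None,
                          ) -> list[QPCRResult]:
    """Run the ddCt calculation for every non-reference amplicon in a
    replicate-level Ct table (columns sample, target, ct)."""
    def measurement(who: str, target: str) -> QPCRMeasurement:
        sel = table[(table["sample"] == who) & (table["target"] == target)]
        if sel.empty:
            raise ValueError(f"no Ct replicates for {who}/{target}")
        return QPCRMeasurement(sample=who, target=target,
                               ct_replicates=tuple(float(x)
                                                   for x in sel["ct"]))

    targets = [t for t in table["target"].unique() if t != reference_target]
    results = []
    for target in targets:
        results.append(ddct_fold_change(
            measurement(sample, target),
            measurement(sample, reference_target),
            measurement(calibrator, target),
            measurement(calibrator, reference_target),
            thresholds=thresholds))
    return results


@dataclass(frozen=True)
class CNVCall:
    """One call from the smMIPs CNV pipeline's output table."""

    sample: str
    interval: GenomicInterval
    copy_state: str  # gain | loss
    bayes_factor: float
    internal_frequency: float

    def __post_init__(self) -> None:
        if self.copy_state not in ("gain", "loss"):
            raise ValueError(f"bad copy state {self.copy_state!r}")
        if self.bayes_factor < 0:
            raise ValueError("Bayes factor must be >= 0")
        if not 0.0 <= self.internal_frequency <= 1.0:
            raise ValueError("internal frequency must be in [0, 1]")


def filter_cnv_calls(calls: Sequence[CNVCall], locus: GenomicInterval,
                     bf_min: float = 100.0,
                     freq_max: float = 0.10) -> list[CNVCall]:
    """Prescreening filter: keep calls overlapping the locus with Bayes
    factor >= ``bf_min`` and internal cohort frequency <= ``freq_max``.
    Order is preserved; the filter is idempotent."""
    return [c for c in calls
            if c.interval.overlaps(locus)
            and c.bayes_factor >= bf_min
            and c.internal_frequency <= freq_max]


@dataclass(frozen=True)
class ArrayProfile:
    """SNP-array log2-ratio profile over the locus for one sample."""

    sample: str
    positions: tuple[int, ...]
    log2_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.log2_ratios):
            raise ValueError("positions and ratios differ in length")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("probe positions must be strictly increasing")


def segment_array_profile(profile: ArrayProfile, locus: GenomicInterval,
                          window_bp: int = ARRAY_WINDOW_BP,
                          cut_cn3: float = ARRAY_LOG2_CUT_CN3,
                          cut_cn4: float = ARRAY_LOG2_CUT_CN4,
                          ) -> dict[int, int]:
    """Classify fixed windows over the locus into diploid copy-number
    states {2, 3, 4} by thresholding the mean probe log2 ratio. Returns
    {window index: CN}; probe-free windows are omitted."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for pos, ratio in zip(profile.positions, profile.log2_ratios):
        if not locus.contains_pos(pos):
            continue
        w = (pos - locus.start) // window_bp
        sums[w] = sums.get(w, 0.0) + ratio
        counts[w] = counts.get(w, 0) + 1
    states = {}
    for w, total in sums.items():
        mean = total / counts[w]
        states[w] = 4 if mean > cut_cn4 else 3 if mean > cut_cn3 else 2
    return states


def _expected_profile(sv: ComplexSV, locus: GenomicInterval,
                      positions: Sequence[int]) -> ArrayProfile:
    """Noise-free expected array profile of an SV carrier at the observed
    probe positions."""
    dip = diploid_profile(copy_number_profile(sv, locus))
    ratios = tuple(math.log2(dip.count_at(p) / 2.0) for p in positions)
    return ArrayProfile(sample=f"expected:{sv.id}",
                        positions=tuple(positions), log2_ratios=ratios)


def _stratum_jaccard(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def match_array_signature(profile: ArrayProfile,
                          catalogue: Sequence[ComplexSV],
                          locus: GenomicInterval,
                          window_bp: int = ARRAY_WINDOW_BP,
                          match_threshold: float = ARRAY_MATCH_THRESHOLD,
                          min_probes: int = 20,
                          ) -> list[tuple[str, float]]:
    """One-to-one comparison of an observed array signature against the
    expected signatures of the catalogued SVs.

    Both the observed profile and each expected profile are passed through
    the same window segmentation, so breakpoint fuzziness affects both
    sides alike. Similarity is the mean of the Jaccard indices of the
    CN=3 and CN=4 window sets (each stratum of two empty sets scores 1).
    Returns (sv_id, similarity) ranked descending; entries below
    ``match_threshold`` are relabeled "novel/no-match".
    """
    in_locus = [p for p in profile.positions if locus.contains_pos(p)]
    if len(in_locus) < min_probes:
        raise ValueError(f"need >= {min_probes} probes in locus, "
                         f"got {len(in_locus)}")
    observed = segment_array_profile(profile, locus, window_bp)
    obs3 = {w for w, cn in observed.items() if cn == 3}
    obs4 = {w for w, cn in observed.items() if cn == 4}
    scored = []
    for sv in catalogue:
        expected = segment_array_profile(
            _expected_profile(sv, locus, profile.positions), locus, window_bp)
        exp3 = {w for w, cn in expected.items() if cn == 3}
        exp4 = {w for w, cn in expected.items() if cn == 4}
        score = 0.5 * (_stratum_jaccard(obs3, exp3)
                       + _stratum_jaccard(obs4, exp4))
        scored.append((sv.id, score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [(sv_id if score >= match_threshold else NO_MATCH, score)
            for sv_id, score in scored]


CONSEQUENCES = ("stop_gain", "stop_loss", "frameshift", "start_loss",
                "canonical_splice", "inframe_indel", "missense",
                "splice_region", "other")
_TIER1 = {"stop_gain", "stop_loss", "frameshift", "start_loss",
          "canonical_splice"}

MAF_CAP = {"AR": 0.005, "AD": 0.001}
CADD_MIN = 15.0
REVEL_MIN = 0.3
SPLICEAI_MIN = 0.2


@dataclass(frozen=True)
class VariantRecord:
    """One annotated SNV/indel from a call table."""

    gene: str
    inheritance: str  # AD | AR
    consequence: str
    maf: float
    cadd: Optional[float] = None
    revel: Optional[float] = None
    spliceai: Optional[float] = None

    def __post_init__(self) -> None:
        if self.inheritance not in MAF_CAP:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("MAF must be in [0, 1]")
        if self.cadd is not None and not 0.0 <= self.cadd <= 48.0:
            raise ValueError("CADD-PHRED must be in [0, 48]")
        for name, score in (("revel", self.revel), ("spliceai", self.spliceai)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _tier(rec: VariantRecord) -> Optional[int]:
    if rec.consequence in _TIER1:
        return 1
    if rec.consequence == "inframe_indel":
        return 2
    splice_hit = rec.spliceai is not None and rec.spliceai >= SPLICEAI_MIN
    if rec.consequence == "missense":
        insilico = ((rec.cadd is not None and rec.cadd >= CADD_MIN)
                    or (rec.revel is not None and rec.revel >= REVEL_MIN))
        if insilico or splice_hit:
            return 3
        return None
    return 3 if splice_hit else None  # putative splice-altering variants


def prioritize_snvs(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Frequency-filter and rank SNVs: drop records above the
    inheritance-specific MAF cap (0.005 recessive / 0.001 dominant), then
    rank protein-truncating and canonical-splice variants first, in-frame
    indels second, then missense supported by at least one in-silico tool
    (CADD-PHRED >= 15 or REVEL >= 0.3) and putative splice-altering
    variants (SpliceAI >= 0.2). Missing scores never qualify. Stable
    order within tiers."""
    kept = [(rec, _tier(rec)) for rec in variants
            if rec.maf <= MAF_CAP[rec.inheritance]]
    kept = [(rec, tier) for rec, tier in kept if tier is not None]
    kept.sort(key=lambda t: t[1])  # stable: preserves input order in ties
    return [rec for rec, _ in kept]
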