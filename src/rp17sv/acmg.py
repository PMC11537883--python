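"""ACMG/AMP evidence combination into the five-tier classification.

Evidence codes carry a default strength from their prefix (PVS very
strong, PS strong, PM moderate, PP supporting; BA stand-alone, BS strong,
BP supporting) and may be applied at a modified strength (e.g. PP1
upgraded to strong for extensive cosegregation), recorded as an explicit
override. The combining rules implemented are the standard ones:

Pathogenic
    (Ia)  1 very-strong AND >=1 strong
    (Ib)  1 very-strong AND >=2 moderate
    (Ic)  1 very-strong AND 1 moderate AND 1 supporting
    (Id)  1 very-strong AND >=2 supporting
    (II)  >=2 strong
    (IIIa) 1 strong AND >=3 moderate
    (IIIb) 1 strong AND 2 moderate AND >=2 supporting
    (IIIc) 1 strong AND 1 moderate AND >=4 supporting
Likely pathogenic
    (I)   1 very-strong AND 1 moderate
    (II)  1 strong AND 1-2 moderate
    (III) 1 strong AND >=2 supporting
    (IV)  >=3 moderate
    (V)   2 moderate AND >=2 supporting
    (VI)  1 moderate AND >=4 supporting
Benign: 1 stand-alone, or >=2 strong benign.
Likely benign: 1 strong benign AND 1 supporting benign, or >=2 supporting
benign. Criteria met for both directions conflict to uncertain
significance, as does insufficient evidence.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = ["EvidenceCode", "ACMGClass", "combine_acmg_evidence",
           "classify_variant", "Classification"]

STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")

_PREFIX_STRENGTH = {
    "PVS": ("pathogenic", "very_strong"),
    "PS": ("pathogenic", "strong"),
    "PM": ("pathogenic", "moderate"),
    "PP": ("pathogenic", "supporting"),
    "BA": ("benign", "stand_alone"),
    "BS": ("benign", "strong"),
    "BP": ("benign", "supporting"),
}
_CODE_RE = re.compile(r"(PVS|PS|PM|PP|BA|BS|BP)\d+\Z")


@dataclass(frozen=True)
class EvidenceCode:
    """One applied ACMG/AMP evidence item, possibly at modified strength."""

    code: str
    strength: str
    direction: str

    def __post_init__(self) -> None:
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength {self.strength!r}")
        if self.direction not in ("pathogenic", "benign"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_label(cls, label: str,
                   strength_override: Optional[str] = None) -> "EvidenceCode":
        """Build from a label like "PM2", "PP1_strong" or ("PP1", "strong")."""
        label = label.strip()
        if "_" in label:
            base, _, suffix = label.partition("_")
            if strength_override is None:
                strength_override = suffix
            label = base
        m = _CODE_RE.match(label)
        if not m:
            raise ValueError(
                f"unknown evidence code {label!r}; give an explicit strength "
                "for non-standard codes")
        direction, strength = _PREFIX_STRENGTH[m.group(1)]
        if strength_override is not None:
            if strength_override not in STRENGTHS:
                raise ValueError(f"unknown strength {strength_override!r}")
            strength = strength_override
        return cls(code=label, strength=strength, direction=direction)


class ACMGClass:
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


def _pathogenic_tier(n: Counter) -> Optional[str]:
    pvs, ps, pm, pp = (n["very_strong"], n["strong"], n["moderate"],
                       n["supporting"])
    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2)
                         or (pm == 1 and pp >= 4)))
    )
    if pathogenic:
        return ACMGClass.PATHOGENIC
    likely = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    if likely:
        return ACMGClass.LIKELY_PATHOGENIC
    return None


def _benign_tier(n: Counter) -> Optional[str]:
    if n["stand_alone"] >= 1 or n["strong"] >= 2:
        return ACMGClass.BENIGN
    if (n["strong"] == 1 and n["supporting"] >= 1) or n["supporting"] >= 2:
        return ACMGClass.LIKELY_BENIGN
    return None


def _coerce(evidence: Iterable[EvidenceCode | str]) -> list[EvidenceCode]:
    out = []
    for ev in evidence:
        out.append(ev if isinstance(ev, EvidenceCode)
                   else EvidenceCode.from_label(ev))
    codes = [e.code for e in out]
    if len(codes) != len(set(codes)):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate evidence codes: {dup}")
    return out


def combine_acmg_evidence(evidence: Sequence[EvidenceCode | str]) -> str:
    """Combine applied evidence codes into one of the five ACMG classes.

    Accepts :class:`EvidenceCode` items or labels ("PM2", "PP1_strong").
    Conflicting pathogenic and benign criteria, or insufficient evidence,
    yield uncertain significance.
    """
    items = _coerce(evidence)
    path_counts = Counter(e.strength for e in items
                          if e.direction == "pathogenic")
    ben_counts = Counter(e.strength for e in items if e.direction == "benign")
    p = _pathogenic_tier(path_counts)
    b = _benign_tier(ben_counts)
    if p and b:
        return ACMGClass.UNCERTAIN
    return p or b or ACMGClass.UNCERTAIN


# The combination reported for one catalogued RP17 allele does not reach
# "pathogenic" under the strict combining table (1 strong + 2 moderate +
# 1 supporting -> likely pathogenic); the report carries a note when the
# input matches it so the discrepancy is visible instead of silently
# resolved either way.
_DISCREPANT_SET = frozenset([("PP1", "strong"), ("PM2", "moderate"),
                             ("PM5", "moderate"), ("PP3", "supporting")])


@dataclass(frozen=True)
class Classification:
    acmg_class: str
    evidence: tuple[EvidenceCode, ...]
    notes: tuple[str, ...] = ()


def classify_variant(evidence: Sequence[EvidenceCode | str]) -> Classification:
    """Classify and attach documentation notes where applicable."""
    items = tuple(_coerce(evidence))
    cls = combine_acmg_evidence(items)
    notes: tuple[str, ...] = ()
    if frozenset((e.code, e.strength) for e in items) == _DISCREPANT_SET:
        notes = (
            "strict combining rules yield likely_pathogenic for "
            "PP1_strong + PM2 + PM5 + PP3; this combination has been "
            "reported as pathogenic for an RP17 allele under an "
            "SV-adapted reading of the guidelines",
        )
    return Classification(acmg_class=cls, evidence=items, notes=notes)
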