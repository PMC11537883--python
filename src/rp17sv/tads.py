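"""Schematic TAD repartitioning of a derived allele and the ectopic
enhancer-promoter contact verdict.

The model is deliberately simple, mirroring the hypothetical modeling used
to interpret RP17 rearrangements: the derived allele is cut at the
midpoint of every *intact* boundary-element projection (a boundary copy
bisected by a breakpoint is disrupted and imposes no cut; an intact copy
inside an inserted segment still insulates). Two elements are "in
contact" when they fall in the same predicted domain. A rearrangement is
a candidate pathogenic RP17 allele when some predicted domain contains
both a copy of the GDPD1 promoter and a retinal enhancer copy while the
wild-type locus keeps them insulated — enhancer hijacking through a
neo-TAD. Distance decay, loop extrusion and contact-frequency matrices
are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from rp17sv.allele import DerivedAllele, build_derived_allele, identity_allele
from rp17sv.annotation import LocusModel, ProjectedFeature, project_features
from rp17sv.nomenclature import ComplexSV, GenomicInterval

__all__ = [
    "PredictedDomain", "ContactAssessment", "partition_domains",
    "assess_ectopic_contact", "predict_rp17_pathogenicity",
    "CANDIDATE_PATHOGENIC", "LIKELY_BENIGN",
]

CANDIDATE_PATHOGENIC = "candidate_pathogenic"
LIKELY_BENIGN = "likely_benign"


@dataclass(frozen=True)
class PredictedDomain:
    """A predicted self-interacting domain on the derived allele."""

    derived_interval: GenomicInterval
    contained: tuple[ProjectedFeature, ...]
    contains_junction: bool

    def contains_kind(self, kind: str) -> bool:
        return any(p.source.kind == kind for p in self.contained)


@dataclass(frozen=True)
class ContactAssessment:
    """Verdict on TAD rearrangement and ectopic promoter-enhancer contact
    for one SV relative to the wild-type locus."""

    sv_id: str
    domains: tuple[PredictedDomain, ...]
    reference_contact: bool
    derived_contact: bool
    ectopic_contact: bool
    neo_tad: bool
    contacting_pairs: tuple[tuple[ProjectedFeature, ProjectedFeature], ...]

    def summary(self) -> str:
        verdict = "ectopic contact" if self.ectopic_contact else "no ectopic contact"
        neo = "neo-TAD formed" if self.neo_tad else "no neo-TAD"
        return (f"{self.sv_id}: {len(self.domains)} predicted domains, "
                f"{neo}, {verdict}")


def partition_domains(projections: list[ProjectedFeature],
                      allele: DerivedAllele) -> list[PredictedDomain]:
    """Tile the derived allele into predicted domains.

    Cut points are the midpoints of untruncated boundary projections;
    truncated boundary copies are disrupted and impose no cut. Non-boundary
    projections are assigned to domains by midpoint containment (a feature
    whose midpoint sits exactly on a cut goes to the left domain).
    """
    cuts = sorted(p.derived_midpoint for p in projections
                  if p.source.kind == "boundary" and not p.truncated)
    total = allele.length()
    bounds: list[tuple[int, int]] = []
    start = 1
    for c in cuts:
        if start <= c < total:
            bounds.append((start, c))
            start = c + 1
    bounds.append((start, total))

    junction_positions = [j.derived_pos for j in allele.junctions]
    domains = []
    for s, e in bounds:
        iv = GenomicInterval("derived", s, e)
        members = tuple(p for p in projections
                        if p.source.kind != "boundary"
                        and s <= p.derived_midpoint <= e)
        # a junction at derived position jp sits between bases jp and jp+1
        has_junction = any(s <= jp and jp + 1 <= e for jp in junction_positions)
        domains.append(PredictedDomain(derived_interval=iv, contained=members,
                                       contains_junction=has_junction))
    return domains


def _contact_pairs(domains: list[PredictedDomain], promoter_name: str,
                   enhancer_kind: str) -> list[tuple[ProjectedFeature,
                                                     ProjectedFeature]]:
    pairs = []
    for dom in domains:
        promoters = [p for p in dom.contained
                     if p.source.name == promoter_name and not p.truncated]
        enhancers = [p for p in dom.contained
                     if p.source.kind == enhancer_kind and not p.truncated]
        pairs.extend((pm, en) for pm in promoters for en in enhancers)
    return pairs


def assess_ectopic_contact(model: LocusModel, sv: Optional[ComplexSV],
                           promoter_name: str = "GDPD1_promoter",
                           enhancer_kind: str = "enhancer",
                           ) -> ContactAssessment:
    """Compare predicted domains of the wild-type and derived alleles and
    decide whether the SV creates a promoter-enhancer contact absent from
    the reference. Any intact promoter copy paired with any intact
    enhancer copy in one domain counts (existential semantics)."""
    model.by_name(promoter_name)  # raises if absent/ambiguous

    ref_allele = identity_allele(model.locus)
    ref_domains = partition_domains(project_features(model, ref_allele),
                                    ref_allele)
    reference_contact = bool(_contact_pairs(ref_domains, promoter_name,
                                            enhancer_kind))

    allele = build_derived_allele(sv, model.locus)
    domains = partition_domains(project_features(model, allele), allele)
    pairs = _contact_pairs(domains, promoter_name, enhancer_kind)
    derived_contact = bool(pairs)

    return ContactAssessment(
        sv_id=(sv.id if sv is not None and sv.id else "identity"),
        domains=tuple(domains),
        reference_contact=reference_contact,
        derived_contact=derived_contact,
        ectopic_contact=derived_contact and not reference_contact,
        neo_tad=any(d.contains_junction for d in domains),
        contacting_pairs=tuple(pairs),
    )


def predict_rp17_pathogenicity(assessment: ContactAssessment) -> str:
    """Dichotomous RP17 verdict: a rearrangement enabling ectopic
    enhancer-promoter contact is a candidate pathogenic allele (this feeds
    PP3 computational evidence); anything else — including large gains
    with no breakpoint inside the locus — is likely benign."""
    return CANDIDATE_PATHOGENIC if assessment.ectopic_contact else LIKELY_BENIGN
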