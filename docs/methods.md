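# Methods

## Scope and coordinate conventions

The package models a single reference window, chr17:59,100,000–59,700,000
(GRCh38), chosen to contain every breakpoint of the catalogued RP17-SVs
with margin; the window is configurable and the chromosome is implicit in
the SV notation (the catalogue strings omit it). All core coordinates are
1-based inclusive, the HGVS `g.` convention of the catalogue; conversion
to 0-based half-open happens only at BED boundaries. The parser accepts
exactly the catalogue dialect (dup / ins / delins with bracketed element
lists, `inv` suffixes, ACGT linkers, tolerated whitespace after `;`, and
a linker fused directly to a following segment); everything else —
breakends, transcript-level HGVS, chromosome-qualified forms — is
rejected rather than guessed at.

## Derived-allele reconstruction

A dup becomes `[window.start..b] [a..b] [b+1..window.end]`; an ins at
`a_(a+1)` splices its elements between `a` and `a+1`; a delins removes
`[a..b]` and splices the elements in its place. Segments carry an affine
(possibly reflecting) map between reference and derived coordinates.
Novel linkers are kept as their own tiles so the segments tile the
derived allele contiguously from position 1; each linker simultaneously
belongs to the single junction joining its flanking reference segments.
A junction is recorded at every adjacency of consecutive reference
segments that is not reference-contiguous in matching orientation.
Reference-adjacent same-orientation adjacencies are never junctions.

Copy counts use a difference array over interval endpoints:
`c(x) = 1 − [x ∈ delins anchor] + [x ∈ dup anchor] + Σ segments covering x`,
merged maximally so adjacent partitions always differ. The delins
semantics deliberately let an inserted inversion restore the deleted
interval to net count 1 (as in the US delins-inversion allele): the
replaced interval loses its single reference copy and each inserted
segment independently adds coverage. Counts are per derived allele; the
diploid view (`+1` everywhere) is an explicit transformation, keeping the
allele algebra exact and the measurement model separate.

Correctness of the interval arithmetic is established against a
brute-force oracle that enumerates every reference base of the derived
allele directly from the rearrangement rules and counts occurrences; the
two routes are compared exactly on 200 random SVs over a 10-kb toy locus
and on the catalogue mapped onto it (an affine, containment-preserving
coordinate map; ins anchors are re-adjacent-ified after rounding).

## Locus annotation fixture

The true enhancer/boundary coordinates live in epigenomic resources not
packaged here; the shipped locus model uses documented approximations,
kept in `data/rp17_locus_model.json` as configuration, not code:

- *GDPD1* promoter at the 5' end of *GDPD1*, chr17:59,220,450–59,220,750;
- one CTCF-enriched boundary element at chr17:59,279,500–59,280,500,
  strictly between the promoter and the enhancer cluster;
- three retinal enhancer elements inside the minimal shared interval
  chr17:59,421,853–59,433,393 (*LINC01476* intron 2);
- gene bodies for *GDPD1*, *YPEL2*, *LINC01476* spanning the printed
  anchors.

The boundary placement is an assumption, not a result: any position in
the open interval (promoter end, 59,288,296) yields the catalogue-wide
verdicts below, whereas a placement right of 59,336,282 would wrongly
insulate the German allele's promoter copy from the enhancers. Replace
the JSON coordinates if precise boundary calls are available.

## TAD repartitioning and the contact verdict

Chromatin contact is modeled as co-membership in a predicted domain — a
deliberate simplification (the interpretive framework for these alleles
is itself schematic); distance decay, loop extrusion and Hi-C matrices
are out of scope. The derived allele is cut at the midpoint of every
boundary projection with `truncated = false`; a truncated boundary
(breakpoint inside the element) is disrupted and imposes no cut; an
intact boundary copy inside an inserted segment still cuts (duplicated
boundaries still insulate). Features are assigned to domains by midpoint
containment, ties going to the left domain. Contact is existential: any
intact promoter copy sharing a domain with any intact enhancer copy
counts. `ectopic_contact = derived_contact AND NOT reference_contact`;
`neo_tad` is true when a predicted domain spans a novel junction.
Removing a boundary from the model can only merge domains, so the
contact set is monotone in boundary removal (property-tested).

A large duplication whose breakpoints both lie outside the modeled
window leaves the window unrearranged and is assessed as the identity
allele: no junction, boundary intact, no ectopic contact — the
likely-benign control logic for gains that do not disturb the local TAD
landscape.

## ACMG/AMP evidence combination

The strict published combining table is implemented and tested
exhaustively against an independently written enumeration over all
subsets of a 10-code universe. Strength overrides (e.g. PP1 at strong for
extensive cosegregation) are explicit. Under the strict table
PP1_strong + PM2 + PM5 + PP3 (1 strong + 2 moderate + 1 supporting) is
likely pathogenic; because this exact combination has been reported as
pathogenic for an RP17 allele, the classifier attaches a note when the
input matches it instead of silently resolving the discrepancy either
way. Benign-direction codes are supported but unused by the RP17
fixtures.

## Measurement models and thresholds

**qPCR (ΔΔCt).** `ΔCt = mean Ct(target) − mean Ct(reference amplicon)`;
`ΔΔCt = ΔCt(sample) − ΔCt(calibrator)`; `fold = 2^(−ΔΔCt)` (efficiency 2
assumed; no melt-curve or efficiency correction). Copy-state bands — the
assay itself publishes none — are midpoints between the theoretical
diploid ratios 1.0 / 1.5 / 2.0 with guard bands: normal [0.8, 1.25),
duplication [1.25, 1.75), triplication [1.75, 2.3], else no_call; all
configurable. The synthetic generator draws replicate Ct values as
`baseline − log2(diploid CN / 2) + N(0, σ_Ct)` with σ_Ct = 0.05 cycles
and duplicate reactions by default; the reference amplicon is unaffected
by locus copy number. Amplicon positions (GDPD1 exon3/intron3 at
~59,225,1xx; LINC01476 intron 2 at ~59,428,2xx) are approximate
placements inside the published qPCR design window
chr17:59,220,511–59,526,851, stored as configuration.

**smMIPs CNV prescreen.** Calls overlapping the locus pass with Bayes
factor ≥ 100 and internal cohort frequency ≤ 10%; the filter is
idempotent and order-preserving. The CNV caller itself is not
reimplemented — the package consumes its call table. The synthetic
generator's Bayes factor is a Gaussian log-marginal-likelihood ratio
between the carrier and diploid copy-number hypotheses over simulated
probe log2 ratios (probe pitch 2 kb, σ = 0.25), a documented stand-in
whose evidence grows monotonically with probe count; the negative-control
cohort appears only through the internal-frequency field.

**SNP-array signature matching.** Profiles (probe pitch 1 kb,
σ_log2 = 0.1 by default) are segmented in fixed 10-kb windows by mean
log2 ratio with cuts at 0.32 and 0.70 (midpoints of log2(3/2) and
log2(4/2)); the expected signature of each catalogued SV is generated at
the *same* probe positions and passed through the *same* segmentation,
so breakpoint quantization affects both sides alike and a noise-free
carrier self-matches at exactly 1.0. Similarity is the mean of the
Jaccard indices of the CN=3 and CN=4 window sets (two empty strata score
1); rankings below 0.8 are labeled novel/no-match. Real array breakpoints
are rough estimates; the windowed Jaccard absorbs that fuzziness.

**SNV prioritization.** MAF caps 0.005 (AR) / 0.001 (AD); tier 1
stop-gain/stop-loss/frameshift/start-loss/canonical-splice, tier 2
in-frame indels, tier 3 missense with CADD-PHRED ≥ 15 or REVEL ≥ 0.3 and
any variant with SpliceAI ≥ 0.2 (one tool suffices). Missing scores never
qualify. Ranking is stable within tiers and per-record (no cross-record
coupling).

## Randomness and problem sizes

Every generator is a pure function of (config, inputs, seed); one seed
feeds a named substream per generator (qPCR / array / smMIPs / toy), so
adding a generator never perturbs existing fixtures. Property tests use
200 random SVs for the copy-number oracle and 500 serializer round trips
(hypothesis, derandomized); the toy locus is 10 kb so per-base oracles
stay exact and cheap. The full suite runs in a few seconds on one CPU.

## What the synthetic data does and does not show

The generators emulate Gaussian measurement noise on Ct and log2 scales
and copy-number signal exactly consistent with a chosen SV. They do not
emulate PCR efficiency drift, probe GC bias, array waviness, mosaicism,
or breakpoint-calling error; passing tests therefore demonstrate the
correctness of the decision rules and the allele algebra under the
stated noise model, not the field performance of the assays. Cohort-level
detection rates depend on private patient data and are out of scope.

## Known limitations

- Single-locus tool: generalization to other loci is configuration (a
  locus model JSON), not new code; no genome-wide scanning.
- No haplotype phasing, read-level evidence, microhomology detection, or
  primer thermodynamics; junction sequences support primer design but are
  not primer predictions.
- The TAD model is qualitative; it predicts domain co-membership, not
  expression levels of *GDPD1*.
- The shared-interval intersection returns the longest piece if the
  intersection is fragmented; for the packaged catalogue it is a single
  interval.
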