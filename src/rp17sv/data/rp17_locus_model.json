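{
  "comment": "Approximate regulatory annotation of the RP17 locus (chr17q22). Feature coordinates are documented approximations chosen to reproduce the locus architecture: GDPD1 with its promoter, a CTCF-enriched boundary element separating GDPD1 from the retinal enhancer cluster, and three retinal enhancer elements inside LINC01476 intron 2 within the minimal shared amplified interval chr17:59,421,853-59,433,393. All coordinates are configuration, not code.",
  "build": "GRCh38",
  "locus": {"chrom": "chr17", "start": 59100000, "end": 59700000},
  "features": [
    {"name": "GDPD1", "kind": "gene", "start": 59220600, "end": 59276000, "strand": "+"},
    {"name": "YPEL2", "kind": "gene", "start": 59300000, "end": 59363000, "strand": "-"},
    {"name": "LINC01476", "kind": "gene", "start": 59400000, "end": 59530000, "strand": "+"},
    {"name": "GDPD1_promoter", "kind": "promoter", "start": 59220450, "end": 59220750, "strand": "."},
    {"name": "CTCF_boundary", "kind": "boundary", "start": 59279500, "end": 59280500, "strand": "."},
    {"name": "retinal_enhancer_1", "kind": "enhancer", "start": 59423000, "end": 59423600, "strand": "."},
    {"name": "retinal_enhancer_2", "kind": "enhancer", "start": 59427200, "end": 59427800, "strand": "."},
    {"name": "retinal_enhancer_3", "kind": "enhancer", "start": 59431500, "end": 59432100, "strand": "."}
  ],
  "qpcr_amplicons": {
    "GDPD1_ex3int3": {"start": 59225050, "end": 59225170},
    "LINC01476_int2": {"start": 59428200, "end": 59428320},
    "reference_label": "RPPH1"
  }
}
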