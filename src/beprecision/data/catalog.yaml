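# Built-in knowledge base: Cas9 variant PAM specificities, cytosine base
# editor profiles (activity windows / preferred positions, PAM-relative,
# -1 = PAM-adjacent), and the editor-selection decision table.
#
# provenance of a window: paper-stated (quantified in the study's text),
# figure-informed-default (read off figure-level evidence; override freely),
# external-citation (editor recommended by name only, no window profile).

pam_specs:
  - cas_variant: SpCas9
    motifs: [NGG]
  - cas_variant: VQR-Cas9
    motifs: [NGA]
  - cas_variant: VRER-Cas9
    motifs: [NGCG]
  - cas_variant: xCas9
    motifs: [NG, GAA, GAT]
  - cas_variant: SpCas9-NG
    motifs: [NG]

editors:
  - name: BE3
    family: APOBEC1
    pams: [SpCas9]
    window: [-17, -13]
    preferred: [-15]
    provenance: external-citation

  - name: nCDA1-BE3
    family: CDA1
    pams: [SpCas9]
    window: [-20, -14]
    preferred: [-18, -17]
    provenance: paper-stated

  - name: cCDA1-BE3
    family: CDA1
    pams: [SpCas9]
    window: [-19, -16]
    preferred: [-18]
    provenance: figure-informed-default

  # Mildest CDA1 truncation: recommended across every distance bucket from
  # <-19 to -15, so its window spans the full distal range.
  - name: "nCDA1Δ198-BE3"
    family: CDA1
    pams: [SpCas9]
    window: [-20, -14]
    preferred: [-18]
    provenance: figure-informed-default

  # Collective name used by the decision table for the C-terminal CDA1
  # truncation series (Δ194..Δ188); constructs exist for every tested Cas9
  # PAM variant, hence the full PAM list.
  - name: "nCDA1Δ(194-188)-BE3"
    family: CDA1
    pams: [SpCas9, VQR-Cas9, VRER-Cas9, xCas9, SpCas9-NG]
    window: [-19, -17]
    preferred: [-18, -17]
    provenance: paper-stated

  - name: A3A-BE3
    family: A3A
    pams: [SpCas9]
    window: [-19, -11]
    preferred: [-16, -15]
    provenance: paper-stated

  - name: A3A-NL-BE3
    family: A3A
    pams: [SpCas9]
    window: [-20, -11]
    preferred: [-18]
    provenance: figure-informed-default

  - name: "A3AΔ194-BE3"
    family: A3A
    pams: [SpCas9]
    window: [-19, -11]
    preferred: [-16, -15]
    provenance: figure-informed-default

  - name: "A3AΔ190-BE3"
    family: A3A
    pams: [SpCas9]
    window: [-17, -14]
    preferred: [-16, -15]
    provenance: figure-informed-default

  - name: "A3AΔ186-BE3"
    family: A3A
    pams: [SpCas9]
    window: [-17, -14]
    preferred: [-16, -15]
    provenance: figure-informed-default

  - name: "A3AΔ182-BE3"
    family: A3A
    pams: [SpCas9]
    window: [-17, -14]
    preferred: [-16, -15]
    provenance: paper-stated

  - name: "A3A(Y130F)Δ186-BE3"
    family: A3A
    pams: [SpCas9]
    window: [-17, -14]
    preferred: [-16, -15]
    provenance: paper-stated

  - name: eA3A-BE3
    family: A3A
    pams: [SpCas9]
    window: [-17, -14]
    preferred: [-16, -15]
    sequence_preference: TCR
    provenance: paper-stated

  # Recommendable by name only; their windows were characterized elsewhere
  # and are deliberately not profiled here.
  - name: YEE-BE3
    family: APOBEC1
    pams: [SpCas9]
    provenance: external-citation
  - name: BE-PAPAPAP
    family: APOBEC1
    pams: [SpCas9]
    provenance: external-citation

# Individual CDA1-truncation constructs (each Cas9 scaffold x each retained
# C-terminal residue) are expanded programmatically by the loader from this
# block; all inherit the truncation-series window.
cda1_truncation_series:
  residues: [195, 194, 193, 192, 190, 188]
  window: [-19, -17]
  preferred: [-18, -17]
  provenance: figure-informed-default
  scaffolds:
    - {suffix: BE3, pams: [SpCas9]}
    - {suffix: VQRBE3, pams: [VQR-Cas9]}
    - {suffix: VRERBE3, pams: [VRER-Cas9]}
    - {suffix: xBE3, pams: [xCas9]}
    - {suffix: NGBE3, pams: [SpCas9-NG]}

# Editor-selection decision table: one entry per (distance bucket, bystander
# context) cell.  "no-bystander" means no C other than the target within the
# activity window of the listed editor (evaluated per editor).  For pattern
# cells, target_offset is the 0-based index of the target C within the
# pattern; the anchoring follows the prose description of each cell since a
# plain-text table cannot carry the underlined target C.  Order within a
# cell is preserved from the source and is not a ranking.
rules:
  - {distance: "<-19", bystander: no-bystander,
     editors: ["nCDA1-BE3", "nCDA1Δ198-BE3", "A3A-NL-BE3"]}
  - {distance: "-19", bystander: no-bystander,
     editors: ["nCDA1-BE3", "nCDA1Δ198-BE3", "A3A-NL-BE3"]}
  - {distance: "-19", bystander: CCDDD, target_offset: 1,
     editors: ["cCDA1-BE3"]}
  - {distance: "-18", bystander: no-bystander,
     editors: ["nCDA1Δ198-BE3", "nCDA1-BE3", "cCDA1-BE3", "A3A-NL-BE3"]}
  - {distance: "-18", bystander: NCN, target_offset: 1,
     editors: ["nCDA1Δ(194-188)-BE3"]}
  - {distance: "-17", bystander: no-bystander,
     editors: ["nCDA1Δ198-BE3", "cCDA1-BE3", "A3A-BE3", "nCDA1-BE3", "BE3"]}
  - {distance: "-17", bystander: DCN, target_offset: 1,
     editors: ["nCDA1Δ(194-188)-BE3"]}
  - {distance: "-17", bystander: CCDDDD, target_offset: 1,
     editors: ["BE3"]}
  - {distance: "-16", bystander: no-bystander,
     editors: ["BE3", "nCDA1Δ198-BE3", "A3A-BE3"]}
  - {distance: "-16", bystander: DDDCC, target_offset: 3,
     editors: ["cCDA1-BE3"]}
  - {distance: "-16", bystander: TCC, target_offset: 1,
     editors: ["cCDA1-BE3", "YEE-BE3", "BE-PAPAPAP"]}
  - {distance: "-16", bystander: NCD, target_offset: 1,
     editors: ["A3AΔ182-BE3", "A3A(Y130F)Δ186-BE3"]}
  - {distance: "-15", bystander: no-bystander,
     editors: ["BE3", "nCDA1Δ198-BE3", "A3A-BE3"]}
  - {distance: "-15", bystander: CDCD, target_offset: 2,
     editors: ["BE-PAPAPAP", "A3AΔ182-BE3", "A3A(Y130F)Δ186-BE3", "YEE-BE3"]}
  - {distance: "-15", bystander: DCN, target_offset: 1,
     editors: ["A3AΔ182-BE3", "A3A(Y130F)Δ186-BE3"]}
  - {distance: "-15", bystander: RCCD, target_offset: 2,
     editors: ["BE-PAPAPAP"]}
  - {distance: "-14", bystander: no-bystander,
     editors: ["BE3", "A3A-BE3", "nCDA1-BE3"]}
  - {distance: "-14", bystander: DDCC, target_offset: 2,
     editors: ["BE-PAPAPAP"]}
  - {distance: ">-14", bystander: no-bystander,
     editors: ["A3A-BE3", "nCDA1-BE3", "BE3"]}

# Position priority used by the pathogenic-variant scanner: the stated
# priority triple for the CDA1 precision editors, extended by the positions
# selectively edited by the A3A truncation editors.
scan_position_ranking: [-18, -17, -19, -16, -15]

# Full-length deaminase sizes (aa); a construct name like "A3AΔ182" retains
# residues 1..182, i.e. removes length-182 C-terminal residues.
deaminase_lengths:
  CDA1: 208
  A3A: 199
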