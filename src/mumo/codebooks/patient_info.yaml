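# codebook for the parameterless patient-information encoder
version: 1
name: patient_info
fields:
  - name: age
    kind: continuous
    range: [18, 100]
  - name: sex
    kind: categorical
    vocab: [male, female]
  - name: tumor_site
    kind: categorical
    vocab: [GEJ, nonGEJ]
  - name: differentiation
    kind: categorical
    vocab: [poor, moderate, well]
  - name: lauren
    kind: categorical
    vocab: [intestinal, diffuse, mixed]
    na: NA
  - name: treatment_line
    kind: continuous
    range: [1, 5]
  - name: days_to_treatment
    kind: continuous
    range: [0, 365]
  - name: pdl1
    kind: categorical
    vocab: [pos, neg]
    na: NA
  - name: mmr
    kind: categorical
    vocab: [pMMR, dMMR]
    na: NA
  - name: ebv
    kind: categorical
    vocab: [pos, neg]
    na: NA
  - name: tnm_stage
    kind: categorical
    vocab: [III, IV]
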