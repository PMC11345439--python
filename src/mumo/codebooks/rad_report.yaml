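# codebook for the parameterless radiology-report encoder
version: 1
name: rad_report
fields:
  - name: post_gastrectomy
    kind: binary
  - name: n_met_lymph_nodes
    kind: continuous
    range: [0, 20]
  - name: ln_locations
    kind: set
    vocab: [perigastric, celiac, hepatoduodenal, retroperitoneal, mediastinal, supraclavicular]
  - name: liver_met
    kind: binary
  - name: lung_met
    kind: binary
  - name: peritoneal_met
    kind: binary
  - name: ln_type_diversity
    kind: continuous
    range: [0, 6]
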