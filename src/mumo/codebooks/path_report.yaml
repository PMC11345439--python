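# codebook for the parameterless pathology-report encoder
version: 1
name: path_report
fields:
  - name: tumor_proportion
    kind: continuous
    range: [0, 1]
  - name: til_level
    kind: continuous
    range: [0, 1]
  - name: her2_heterogeneity
    kind: set
    vocab: ["0", "1+", "2+", "3+"]
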