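# Default taurine-reduction pathway grammars.
# Each step lists alternative gene requirements; an alternative is an AND-set of
# catalog symbols (multi-subunit complexes require every subunit). The variant
# set of a pathway is the Cartesian product over steps. Edit this file to add
# further alternatives; the grammar is data, not code.
version: "1.0"
pathways:
  - name: taurine_reduction_3step
    steps:
      - label: taurine deamination
        alternatives:
          - [tpa]
          - [toa]
      - label: sulfoacetaldehyde acetyl transfer
        alternatives:
          - [xsc]
      - label: terminal sulfite reduction
        alternatives:
          - [dsrA, dsrB]
          - [asrA, asrB, asrC]
    excluded_genes: []
  - name: taurine_reduction_4step
    steps:
      - label: taurine deamination
        alternatives:
          - [tpa]
          - [toa]
      - label: sulfoacetaldehyde reduction
        alternatives:
          - [isfD]
      - label: isethionate cleavage
        alternatives:
          - [islA, islB]
      - label: terminal sulfite reduction
        alternatives:
          - [dsrA, dsrB]
          - [asrA, asrB, asrC]
    excluded_genes: []
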