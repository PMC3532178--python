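schema: 1
volume: 100.0
species:
- name: P
  class: slow
  initial: 200.0
- name: M
  class: fast
  initial: 0.1
reactions:
- reactants: {}
  products:
    M: 1
  rate_constant: 1.0
  name: transcription
- reactants:
    M: 1
  products: {}
  rate_constant: 10.0
  name: mrna_decay
- reactants:
    M: 1
  products:
    M: 1
    P: 1
  rate_constant: 200.0
  name: translation
- reactants:
    P: 1
  products: {}
  rate_constant: 0.1
  name: protein_decay
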