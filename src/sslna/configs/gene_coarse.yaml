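schema: 1
volume: 100.0
species:
- name: M
  class: slow
  initial: 0.903704373311081
- name: P
  class: slow
  initial: 103.23156355309116
reactions:
- reactants: {}
  products:
    M: 1
  rate: 100.0*0.01*100000.0/(100000.0 + P**2)
  name: txn
- reactants:
    M: 1
  products: {}
  rate_constant: 1.0
  name: mrna_decay
- reactants:
    M: 1
  products:
    M: 1
    P: 1
  rate_constant: 1.0
  name: translation
- reactants:
    P: 1
  products: {}
  rate: 1.0*1.0*P/(11.0 + P)
  name: degrade
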