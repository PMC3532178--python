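schema: 1
volume: 100.0
species:
- name: S
  class: slow
  initial: 4516.806814831878
reactions:
- reactants: {}
  products:
    S: 1
  rate_constant: 0.5
  name: input
- reactants:
    S: 1
  products: {}
  rate: S*(1.0*(1.0/202000000.0 + 1.0*S/(202000000.0*0.101))/(1 + S/202000000.0 +
    S**2/(202000000.0*0.101)))
  name: catalysis
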