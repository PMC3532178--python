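schema: 1
volume: 100.0
species:
- name: S
  class: slow
  initial: 4516.806814831878
- name: EE
  class: fast
  initial: 0.5000000000000001
- name: EES
  class: fast
  initial: 1.118021488819772e-05
- name: SEES
  class: fast
  initial: 0.4999888197851117
reactions:
- reactants: {}
  products:
    S: 1
  rate_constant: 0.5
  name: input
- reactants:
    S: 1
    EE: 1
  products:
    EES: 1
  rate_constant: 5.0e-07
  name: bind1
- reactants:
    EES: 1
  products:
    S: 1
    EE: 1
  rate_constant: 100.0
  name: unbind1
- reactants:
    EES: 1
  products:
    EE: 1
  rate_constant: 1.0
  name: cat1
- reactants:
    S: 1
    EES: 1
  products:
    SEES: 1
  rate_constant: 1000.0
  name: bind2
- reactants:
    SEES: 1
  products:
    S: 1
    EES: 1
  rate_constant: 100.0
  name: unbind2
- reactants:
    SEES: 1
  products:
    EES: 1
  rate_constant: 1.0
  name: cat2
conservation_laws:
- coefficients:
    EE: 1.0
    EES: 1.0
    SEES: 1.0
  total: 1.0
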