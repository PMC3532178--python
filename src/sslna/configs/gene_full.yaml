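schema: 1
volume: 100.0
species:
- name: M
  class: slow
  initial: 0.903704373311081
- name: P
  class: slow
  initial: 103.23156355309116
- name: G
  class: fast
  initial: 0.00903611092125197
- name: GP
  class: fast
  initial: 9.32811858840004e-07
- name: GP2
  class: fast
  initial: 0.0009629562668891896
- name: E
  class: fast
  initial: 0.09629562668891907
- name: EP
  class: fast
  initial: 0.9037043733110809
reactions:
- reactants:
    G: 1
  products:
    G: 1
    M: 1
  rate_constant: 100.0
  name: txn_G
- reactants:
    GP: 1
  products:
    GP: 1
    M: 1
  rate_constant: 100.0
  name: txn_GP
- reactants:
    P: 1
    G: 1
  products:
    GP: 1
  rate_constant: 1.0e-05
  name: bindP1
- reactants:
    GP: 1
  products:
    P: 1
    G: 1
  rate_constant: 10.0
  name: unbindP1
- reactants:
    P: 1
    GP: 1
  products:
    GP2: 1
  rate_constant: 100.0
  name: bindP2
- reactants:
    GP2: 1
  products:
    P: 1
    GP: 1
  rate_constant: 10.0
  name: unbindP2
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
    E: 1
  products:
    EP: 1
  rate_constant: 1.0
  name: bindE
- reactants:
    EP: 1
  products:
    P: 1
    E: 1
  rate_constant: 10.0
  name: unbindE
- reactants:
    EP: 1
  products:
    E: 1
  rate_constant: 1.0
  name: degrade
conservation_laws:
- coefficients:
    G: 1.0
    GP: 1.0
    GP2: 1.0
  total: 0.01
- coefficients:
    E: 1.0
    EP: 1.0
  total: 1.0
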