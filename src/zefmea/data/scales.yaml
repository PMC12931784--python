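scales:
- name: importance
  terms:
  - label: EI
    l: 1
    m: 1
    u: 1
    ci: 3.0
  - label: WI
    l: 0.6666666666666666
    m: 1
    u: 1.5
    ci: 3.8
  - label: FI
    l: 1.5
    m: 2
    u: 2.5
    ci: 5.29
  - label: I
    l: 2.5
    m: 3
    u: 3.5
    ci: 6.69
  - label: VI
    l: 3.5
    m: 4
    u: 4.5
    ci: 8.04
  - label: AI
    l: 4.5
    m: 5
    u: 5.5
    ci: 9.35
- name: reliability
  terms:
  - label: VL
    l: 0
    m: 0
    u: 0.3
  - label: L
    l: 0.1
    m: 0.3
    u: 0.5
  - label: M
    l: 0.3
    m: 0.5
    u: 0.7
  - label: H
    l: 0.5
    m: 0.7
    u: 0.9
  - label: VH
    l: 0.7
    m: 1.0
    u: 1.0
- name: rating
  terms:
  - label: VL
    l: 0
    m: 1
    u: 2
  - label: L
    l: 1
    m: 2
    u: 3
  - label: ML
    l: 2
    m: 3.5
    u: 5
  - label: M
    l: 4
    m: 5
    u: 6
  - label: MH
    l: 5
    m: 6.5
    u: 8
  - label: H
    l: 7
    m: 8
    u: 9
  - label: VH
    l: 8
    m: 9
    u: 10
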