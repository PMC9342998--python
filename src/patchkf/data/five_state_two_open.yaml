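# 5-state model with two open states: C1 <-> C2 <-> C3 binding chain,
# O4 branching off the singly liganded C2 and O5 off the doubly liganded C3.
name: five_state_two_open
n_states: 5
edges:
  - [1, 2, k12, 1]
  - [2, 1, k21, 0]
  - [2, 3, k23, 1]
  - [3, 2, k32, 0]
  - [2, 4, k24, 0]
  - [4, 2, k42, 0]
  - [3, 5, k35, 0]
  - [5, 3, k53, 0]
conducting:
  4: 1.0
  5: 1.0
bound_ligands:
  1: 0
  2: 1
  3: 2
  4: 1
  5: 2
loops: []
default_rates:
  k12: 10.0
  k21: 10.0
  k23: 10.0
  k32: 20.0
  k24: 20.0
  k42: 100.0
  k35: 100.0
  k53: 50.0
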