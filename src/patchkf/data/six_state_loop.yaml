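# 6-state model with one cycle, for the microscopic-reversibility prior.
# Binding chain C1 <-> C2 <-> C3 with opening C3 <-> O4, plus a second
# conformation C5 (singly liganded) that binds to C6 (doubly liganded) and
# reconnects to C3, closing the cycle 2 -> 5 -> 6 -> 3 -> 2.  Each direction
# of the cycle carries exactly one binding step, so ligand factors cancel in
# the loop product.  default_rates satisfy detailed balance around the loop
# exactly (k25*k56*k63*k32 == k23*k36*k65*k52).
name: six_state_loop
n_states: 6
edges:
  - [1, 2, k12, 1]
  - [2, 1, k21, 0]
  - [2, 3, k23, 1]
  - [3, 2, k32, 0]
  - [3, 4, k34, 0]
  - [4, 3, k43, 0]
  - [2, 5, k25, 0]
  - [5, 2, k52, 0]
  - [5, 6, k56, 1]
  - [6, 5, k65, 0]
  - [6, 3, k63, 0]
  - [3, 6, k36, 0]
conducting:
  4: 1.0
bound_ligands:
  1: 0
  2: 1
  3: 2
  4: 2
  5: 1
  6: 2
loops:
  - [2, 5, 6, 3]
default_rates:
  k12: 10.0
  k21: 10.0
  k23: 10.0
  k32: 20.0
  k34: 100.0
  k43: 50.0
  k25: 5.0
  k52: 15.0
  k56: 8.0
  k65: 40.0
  k63: 30.0
  k36: 4.0
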