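# 4-state CCCO scheme: C1 <-> C2 <-> C3 <-> O4
# Two sequential ligand-binding steps (on-rates in uM^-1 s^-1, scaled by the
# ligand concentration) followed by one opening step.  The shipped
# default_rates are the repository's canonical parametrization for all
# simulation benchmarks; they are of the physiological order of magnitude for
# cyclic-nucleotide-gated-type channels (EC50 ~ 1 uM, gating ~ 100 s^-1).
name: ccco
n_states: 4
edges:
  - [1, 2, k12, 1]   # binding of the first ligand
  - [2, 1, k21, 0]
  - [2, 3, k23, 1]   # binding of the second ligand
  - [3, 2, k32, 0]
  - [3, 4, k34, 0]   # opening
  - [4, 3, k43, 0]
conducting:
  4: 1.0
bound_ligands:
  1: 0
  2: 1
  3: 2
  4: 2
loops: []
default_rates:
  k12: 10.0
  k21: 10.0
  k23: 10.0
  k32: 20.0
  k34: 100.0
  k43: 50.0
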