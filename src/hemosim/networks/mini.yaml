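# Toy reversible-binding network for unit tests; the steady state has a
# closed-form solution via the dissociation constant koff/kon = 10 nM.
name: mini
constants:
  kon: 1.0e-3
  koff: 1.0e-2
species:
  - {id: A, initial: 100.0, diffusion: 5.0e-11}
  - {id: B, initial: 50.0, diffusion: 5.0e-11}
  - {id: AB, initial: 0.0, diffusion: 5.0e-11}
reactions:
  - {id: bind, eq: "A + B -> AB", k: kon, kr: koff}
observables:
  complex: {AB: 1.0}
scaffolds:
  a_total: {A: 1, AB: 1}
  b_total: {B: 1, AB: 1}
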