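# Simulation scenario 1: unidirectional model (no trait2 -> trait1 effect).
kind: umr
n: 1000
n_reps: 1000
maf: 0.3
blocks:
  - label: "Strong IV (1)"
    strength: strong
    n_instruments: 1
    beta: 1.0
    gammas: [[-1.9, 0.0], [-0.9, 0.0], [0.9, 0.0], [1.9, 0.0]]
  - label: "Strong IVs (20)"
    strength: strong
    n_instruments: 20
    beta: 2.0
    gammas: [[-1.9, 0.0], [-0.9, 0.0], [0.9, 0.0], [1.9, 0.0]]
  - label: "Weak IVs (20)"
    strength: weak
    n_instruments: 20
    beta: 0.02
    gammas: [[-1.9, 0.0], [-0.9, 0.0], [0.9, 0.0], [1.9, 0.0]]
  - label: "Weak IVs (100)"
    strength: weak
    n_instruments: 100
    beta: 0.05
    gammas: [[-1.9, 0.0], [-0.9, 0.0], [0.9, 0.0], [1.9, 0.0]]
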