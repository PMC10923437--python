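# Simulation scenario 3: bidirectional model with weak instruments.
kind: bmr
n: 1000
n_reps: 1000
maf: 0.3
blocks:
  - label: "Weak IV (1)"
    strength: weak
    n_instruments: 1
    beta: 0.02
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
  - label: "Weak IVs (5)"
    strength: weak
    n_instruments: 5
    beta: 0.02
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
  - label: "Weak IVs (10)"
    strength: weak
    n_instruments: 10
    beta: 0.02
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
  - label: "Weak IVs (20)"
    strength: weak
    n_instruments: 20
    beta: 0.02
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
  - label: "Weak IVs (100)"
    strength: weak
    n_instruments: 100
    beta: 0.05
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
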