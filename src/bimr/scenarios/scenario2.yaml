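# Simulation scenario 2: bidirectional model with strong instruments.
kind: bmr
n: 1000
n_reps: 1000
maf: 0.3
blocks:
  - label: "Strong IV (1)"
    strength: strong
    n_instruments: 1
    beta: 1.0
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
  - label: "Strong IVs (5)"
    strength: strong
    n_instruments: 5
    beta: 2.0
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
  - label: "Strong IVs (10)"
    strength: strong
    n_instruments: 10
    beta: 2.0
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
  - label: "Strong IVs (20)"
    strength: strong
    n_instruments: 20
    beta: 2.0
    gammas: [[-1.9, -0.5], [-1.9, 0.5], [-0.9, 0.9], [0.9, -0.9]]
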