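name: h2es-h2
geometry: h2_h2.xyz
basis: dz
fragments: [0, 0, 1, 1]
monomer_a: {active_electrons: 2, active_orbitals: 2, n_states: 2, target_state: 1}
monomer_b: {active_electrons: 2, active_orbitals: 2}
tags: [ES]
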