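name: h2-h2
basis: dz
fragments: [0, 0, 1, 1]
monomer_a: {active_electrons: 2, active_orbitals: 2}
monomer_b: {active_electrons: 2, active_orbitals: 2}
tags: [GS, negative-dispersion]
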