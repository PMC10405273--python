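name: h2o-h2o-cas
geometry: h2o_h2o.xyz
basis: sto-3g
fragments: [0, 0, 0, 1, 1, 1]
monomer_a: {active_electrons: 4, active_orbitals: 4}
monomer_b: {active_electrons: 4, active_orbitals: 4}
tags: [GS, negative-dispersion]
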