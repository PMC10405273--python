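2
helium dimer near the van der Waals minimum
He  0.000000   0.000000   0.000000
He  3.000000   0.000000   0.000000
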