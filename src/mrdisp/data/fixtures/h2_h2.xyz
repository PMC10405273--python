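4
parallel hydrogen dimer, 3.5 A inter-axis separation
H   0.000000   0.000000   0.000000
H   0.000000   0.000000   0.741400
H   3.500000   0.000000   0.000000
H   3.500000   0.000000   0.741400
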