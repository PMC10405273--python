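complex,casscf,cas_plus_disp,sapt,td_lc_bop_lrd,reference
Benzene-Cyclopentane,2.77,-3.31,-3.42,-3.11,-3.45
Benzene-Neopentane,2.06,-2.71,-2.80,-2.79,-2.86
AcOH-Pentane,2.27,-2.78,-2.85,-2.67,-3.03
AcNH2-Pentane,3.11,-2.74,-2.90,-2.48,-2.76
Peptide-Pentane,3.18,-4.05,-3.97,-3.52,-4.07
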