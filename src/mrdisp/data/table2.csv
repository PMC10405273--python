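complex,casscf,cas_plus_disp,sapt,td_lc_bop_lrd,reference
Benzene-Cyclopentane,2.75,-3.51,-3.63,-3.04,-3.51
Benzene-Neopentane,2.06,-2.86,-2.95,-2.72,-2.85
AcOH-Pentane,2.18,-2.86,-2.82,-2.49,-2.91
AcNH2-Pentane,2.32,-3.48,-3.61,-2.96,-3.53
Peptide-Pentane,2.95,-4.23,-4.26,-3.47,-4.26
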