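complex,state,e_elst,e_exch,e_ind,e_exch_ind,e_disp,e_exch_disp,delta,sapt
Benzene-Cyclopentane,GS,-2.05,5.33,-1.45,1.28,-7.13,0.87,-0.48,-3.63
Benzene-Neopentane,GS,-1.58,4.08,-1.00,0.83,-5.58,0.65,-0.35,-2.95
AcOH-Pentane,GS,-1.54,4.20,-1.05,0.83,-5.55,0.57,-0.28,-2.82
AcNH2-Pentane,GS,-2.09,5.24,-1.57,1.01,-6.51,0.71,-0.39,-3.61
Peptide-Pentane,GS,-2.31,6.07,-1.57,1.15,-8.03,0.85,-0.43,-4.26
Benzene-Cyclopentane,ES,-1.92,5.15,-1.42,1.30,-6.89,0.82,-0.47,-3.42
Benzene-Neopentane,ES,-1.43,3.87,-0.97,0.85,-5.38,0.61,-0.34,-2.80
AcOH-Pentane,ES,-1.53,4.12,-1.03,0.91,-5.61,0.56,-0.27,-2.85
AcNH2-Pentane,ES,-2.19,5.69,-2.05,2.01,-6.66,0.81,-0.52,-2.90
Peptide-Pentane,ES,-2.27,6.11,-1.54,1.36,-8.10,0.88,-0.42,-3.97
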