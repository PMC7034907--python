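element,atomic_mass_g_mol
H,1.008
C,12.011
N,14.007
O,15.999
Na,22.98976928
Mg,24.305
Al,26.9815385
P,30.973762
S,32.06
Cl,35.45
Ca,40.078
Fe,55.845
Cu,63.546
Ga,69.723
Mo,95.95
Gd,157.25
Lu,174.967
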