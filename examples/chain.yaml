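# Six-rotor chain at the defect-punctuated drift peak (SI units).
N: 6
D: 1.01
h: 50.0e-6          # height above the wall (m)
lambda_: 4.5e-6     # radial trap stiffness (N/m)
t_end: 2000.0
seed: 1
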