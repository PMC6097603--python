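# Coarse (h, lambda) phase-diagram sweep; heights in metres, stiffness in N/m.
N: 6
D: 1.01
t_end: 600.0
t_burn: 200.0
h_values: [5.0e-6, 20.0e-6, 80.0e-6, 300.0e-6]
lambda_values: [2.0e-6, 4.5e-6, 8.0e-6]
master_seed: 0
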