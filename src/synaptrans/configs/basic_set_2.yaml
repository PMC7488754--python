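# Basic reference parameter set of the local-translation circuit.
# K_x and k_x0 are not part of the reference set; the package defaults
# (K_x = 1.0, k_x0 = 0.0) are stated here explicitly.
k_a0: 0.0
k_a: 1.0
K_a: 1.0
h_a: 1.0
y0: 1.0
k_b0: 1.0
k_b: 200.0
K_b: 3.0
h_b: 15.0
h_x: 3.0
k_x: 40.0
k_x0: 0.0
K_x: 1.0
k_dx: 0.1
k_rx: 0.9
k_dz: 0.8
k_rz: 0.2
tau_a: 1.0
tau_b: 1.0
tau_r: 10.0
tau_e: 15.0
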