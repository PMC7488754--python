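# K_a = 3, k_rz = 0 on the "maximum" set: the zero stationary solution.
mode: simulate
parameters: {h_x: 3, h_b: 20, k_x: 40, k_b: 200, K_a: 3, k_rz: 0.0, k_dz: 1.0}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 3}
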