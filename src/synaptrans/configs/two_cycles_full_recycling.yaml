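# K_a = 3, k_rz = 1 on the "maximum" set (h_b = 20): two coexisting
# cyclic attractors; neither intersects the x = 2 plane.
mode: census
parameters: {h_x: 3, h_b: 20, k_x: 40, k_b: 200, K_a: 3, k_rz: 1.0, k_dz: 0.0}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 3}
census: {n_starts: 12}
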