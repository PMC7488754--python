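# Regime table at h_x = 3 over (h_b, k_x) x K_a x k_rz (k_dz = 1 - k_rz).
mode: table
parameters: {k_b: 100}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 3}
table: {h_x: 3, n_starts: 12}
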