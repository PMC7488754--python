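# Chaotic reference trajectory: k_rz = 0.25, tau_e = 5.
mode: simulate
parameters: {k_rz: 0.25, k_dz: 0.75}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 5}
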