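# Full recycling k_rz = 1: the single cyclic attractor.
mode: census
parameters: {k_rz: 1.0, k_dz: 0.0}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 5}
census: {n_starts: 12}
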