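# k_rz sweep on the maximum varying-parameter set with K_a = 3: zero
# stationary solutions at low k_rz, periodic solutions appearing on the
# diagram above ~0.80/0.82.
mode: scan
parameters: {h_x: 3, h_b: 15, k_x: 40, k_b: 200, K_a: 3}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 3}
section: {variable: x, level: 2.0, direction: increasing}
scan: {parameter: k_rz, start: 0.0, stop: 1.0, step: 0.01,
       couple_kdz: true, n_starts: 1}
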