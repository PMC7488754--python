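# k_rz sweep on the minimum varying-parameter set: periodic solutions at
# low k_rz give way to diagram-stationary columns above ~0.55/0.56.
mode: scan
parameters: {h_x: 1, h_b: 5, k_x: 10, k_b: 100, K_a: 1}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 3}
section: {variable: x, level: 2.0, direction: increasing}
scan: {parameter: k_rz, start: 0.0, stop: 1.0, step: 0.01,
       couple_kdz: true, n_starts: 1}
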