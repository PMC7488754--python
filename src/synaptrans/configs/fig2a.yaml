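# tau_e sweep at k_rz = 0.25: multiplicity of attractors, simple cycle up
# to tau_e ~ 4.47, period-doubling route to chaos on the second branch.
mode: scan
parameters: {k_rz: 0.25, k_dz: 0.75}
delays: {tau_a: 1, tau_b: 2, tau_r: 3, tau_e: 3}
section: {variable: x, level: 2.0, direction: increasing}
scan: {parameter: tau_e, start: 3.0, stop: 5.0, step: 0.02,
       couple_kdz: false, n_starts: 12}
seed: 0
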