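# Size-structured cell fission reducing to the Monod chemostat pair.
name: monod_fission
params: {a: 1.0, b: 1.0, D: 0.5, beta_c: 0.5}
istate: {x_min: 3.0517578125e-05, x_max: 32768.0}
rates:
  g: "(a*S/(b+S))*x"
  mu: "beta_c + D"
birth_kernel:
  form: fission
  beta0: "beta_c"
environment:
  mode: feedback
  S0: 1.0
chemostat: {D: 0.5, S_ext: 2.0, gamma: 1.0, a: 1.0, b: 1.0}
initial: {shape: point, state: 1.0, total_mass: 0.2}
run: {horizon: 20.0, dt: 0.005, merge_dx: 0.002}
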