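# Strict physiological-age model: mass-conserving fission with a
# Michaelis-Menten common factor; the biomass weight is the dominant
# eigenfunction with eigenvalue 1.
params: {bhat: 0.9}
istate: {x_min: 7.62939453125e-06, x_max: 131072.0}
theta: "S/(1+S)"
g0: "x"
mu0: "bhat"
kernel: {form: fission, beta0: "bhat"}
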