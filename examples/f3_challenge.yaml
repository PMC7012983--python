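# Generalised von Bertalanffy family member whose growth rate is the
# trigonometric expression v1 (1+cos x) + v2 sin x + v3 (1-cos x):
# v0 = 1 + cos x turns the rescaled state into tan(x/2).
istate: {x_min: -3.0415926535897933, x_max: 3.0415926535897933, birth_state: 0.0}
catalogue:
  family: F3
  k: 2
  v0: "1 + cos(x)"
  v1: "0.7"
  v2: "-0.3"
  v3: "0.5"
  mu0: "0.0"
  x_b: 0.0
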