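# Surviving-regime continuous culture: monod(S_ext) = 2/3 > D.
chemostat: {D: 0.5, S_ext: 2.0, gamma: 1.0, a: 1.0, b: 1.0}
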