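# Unamended deep-borehole fluid scenario: a sustained ~100 nW biological
# plateau (the only unamended site with replicable signal), no growth, noise
# 2 nW (ampule-level detection floor is 1.2 nW/mL x 2 mL = 2.4 nW).
# The insertion artifact decays fast enough that the record flattens within
# tens of hours, emulating "equilibration" of the signal.
duration_h: 150.0
dt_h: 0.05
artifact: {shape: power, a: 1.0e-05, b: -2.0, c: 0.0}
peaks: []
plateau_W: 1.0e-07
noise_sd_W: 2.0e-09
growth: {N0: 4.03e+05, K: 4.03e+05, r: 0.0}
coupling: {reaction: h2_sulfate, substrate: H2, S0_mol: 2.06e-06}
seed: 0
volume_mL: 2.0
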