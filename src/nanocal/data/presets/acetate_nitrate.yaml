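# 10 mM acetate + 10 mM nitrate co-amendment scenario: a slow rise to a
# ~175 nW signal sustained past 100 h; cells grow from 4.74e4 toward ~1.2e6
# cells/mL by ~216 h. Heat is coupled to acetate oxidation with nitrate.
duration_h: 216.0
dt_h: 0.1
artifact: {shape: power, a: 1.0e-05, b: -2.0, c: 0.0}
peaks:
  - {shape: logistic_burst, amplitude_W: 7.5e-08, center_h: 60.0, width_h: 40.0}
plateau_W: 1.0e-07
noise_sd_W: 5.0e-09
growth: {N0: 4.74e+04, K: 1.20e+06, r: 0.04}
coupling: {reaction: acetate_nitrate, substrate: acetate, S0_mol: 2.0e-05}
seed: 0
volume_mL: 2.0
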