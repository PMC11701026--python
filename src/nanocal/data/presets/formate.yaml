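# 10 mM formate amendment scenario: heat flow rises to ~450 nW near 20 h,
# then tapers toward a ~100 nW sustained level; cells grow ~3.99e4 -> 4.18e5
# cells/mL in the first ~46 h. Heat is coupled to aerobic formate oxidation.
duration_h: 150.0
dt_h: 0.05
artifact: {shape: power, a: 1.0e-05, b: -2.0, c: 0.0}
peaks:
  - {shape: logistic_burst, amplitude_W: 3.5e-07, center_h: 20.0, width_h: 8.0}
plateau_W: 1.0e-07
noise_sd_W: 5.0e-09
growth: {N0: 3.99e+04, K: 4.18e+05, r: 0.15}
coupling: {reaction: formate_o2, substrate: formate, S0_mol: 2.0e-05}
seed: 0
volume_mL: 2.0
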