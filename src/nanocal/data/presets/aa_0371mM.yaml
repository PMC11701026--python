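# 0.371 mM casamino-acid amendment scenario.
# Main biological burst: 2.25 uW peaking at 32.5 h; a small early burst near
# 12 h; total analytic biological heat 0.0433 J (the main peak width is solved
# from the closed-form Gaussian integral so the two bursts sum to 0.0433 J).
# Noise 20 nW; insertion artifact is a decaying power law plus a 30 nW
# instrument offset. Growth: ~1.16e5 -> 1.41e8 cells/mL within 70 h.
duration_h: 70.0
dt_h: 0.02
artifact: {shape: power, a: 2.0e-06, b: -1.0, c: 3.0e-08}
peaks:
  - {shape: gaussian, amplitude_W: 2.0e-07, center_h: 12.0, width_h: 1.2}
  - {shape: gaussian, amplitude_W: 2.25e-06, center_h: 32.5, width_h: 2.02596}
plateau_W: 0.0
noise_sd_W: 2.0e-08
growth: {N0: 1.16e+05, K: 1.41e+08, r: 0.25}
# chemistry tie-in: sulfate reduction with H2 drawing on the ampule's initial
# dissolved H2 (1.03e-6 mol/mL x 2 mL)
coupling: {reaction: h2_sulfate, substrate: H2, S0_mol: 2.06e-06}
seed: 0
volume_mL: 2.0
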