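# Methods

## Reaction enthalpies

Standard-state enthalpies of reaction are computed as ΔH°ᵣ = Σ νᵢ ΔH°f,i
from a bundled table of formation enthalpies at 25 °C, 1 bar
(`nanocal/data/formation_enthalpies.csv`), under the usual aqueous
conventions ΔH°f(H⁺) = 0 and ΔH°f(e⁻) = 0.  Inorganic ions and liquid water
use CODATA-consistent values; dissolved gases (O₂, H₂, N₂, CO₂) use
geochemical (SUPCRT slop-file) values for the aqueous species; the 20
amino acids carry aqueous values assembled from crystal formation
enthalpies plus enthalpies of dissolution.  An optional constant-heat-
capacity term Σ νᵢ cp,ᵢ·(T − 25 °C) corrects to the 28 °C incubation
temperature for the species that carry cp data; over a 3 K span this
correction is below 1.5 kJ/mol for every bundled reaction — far smaller
than the spread between thermodynamic data sources, which is the true
accuracy limit of any re-derivation from independent data.

CO₂ is modeled as the neutral aqueous species CO₂(aq); carbonate speciation
is deliberately not modeled, matching how the candidate reactions are
written.  Activity coefficients, ionic strength, and pressure dependence
are out of scope (heat, unlike Gibbs energy, is compared at standard state
throughout).

## Half reactions and the nominal amino acid

Electron donors are oxidized by a generic CHNOS half-reaction builder:
carbon goes fully to CO₂ while nitrogen leaves as NH₄⁺ and sulfur as HS⁻
(only carbon is oxidized); O and H are balanced with H₂O and H⁺, and the
electron count follows from charge balance.  Reduction halves are
O₂ + 4H⁺ + 4e⁻ → 2H₂O, SO₄²⁻ + 9H⁺ + 8e⁻ → HS⁻ + 4H₂O, and
NO₃⁻ + 6H⁺ + 5e⁻ → ½N₂ + 3H₂O.  Halves are normalized per electron before
combination (so non-integer electron counts combine cleanly) and the full
reaction is rescaled so the acceptor appears with its conventional
coefficient; Hess's law (combined ΔH = electron-weighted sum of half ΔHs)
holds to 1e-9 relative and is property-tested.

Casamino-acid amendments have unknown composition, so oxidation enthalpies
use a nominal mean amino acid: each amino acid's oxidation half is weighted
by its mole fraction in E. coli protein (bundled composition, 20 amino
acids summing to 1; tryptophan is retained in the weighting even though
acid-hydrolyzed casein lacks it, since the mixture's actual proportions are
unknown and the protein composition is the declared approximation).  The
mean reaction is normalized **per mole of electron acceptor**; the
alternative per-mole-of-amino-acid normalization changes only the printed
scale of the reaction, not any predicted species turnover.

## Heat-to-moles budgets and screening

Given total corrected heat Q (J) and a reaction with enthalpy ΔH (kJ/mol as
written), species turnover is nₛ = |νₛ|·Q/(|ΔH|·1000).  Budgets are exact
in Q (linear, round-trippable) and keep species in exact stoichiometric
ratio.  Screening compares predicted vs measured changes: ratios at or
beyond a factor of 10 either way are inconsistent (the order-of-magnitude
criterion; configurable), measurements below their detection floor leave
the verdict indeterminate, and a prediction above an undetected species'
floor is flagged rather than excluded — low-level O₂ consumption, for
example, cannot be ruled out by a gas chromatograph that never saw O₂.
Observed chemistry is supplied in moles per ampule; per-mL measurements
are converted by the 2 mL sample volume upstream.

### What a 25 °C bundled dataset reproduces — and what it cannot

At Q = 0.0433 J the package reproduces the printed H₂-reaction budgets
within ~1–6 % (knallgas 1.57e-7 vs 1.59e-7 mol; nitrate 1.68e-7 vs 1.70e-7;
sulfate 7.46e-7 vs 7.91e-7), the Stickland CO₂ within ~3 % of the
discussion value (3.64e-7 vs 3.53e-7 mol; the corresponding summary-table
row prints 4.27e-7, which is arithmetically incompatible with the
discussion value for the same heat — we report our computed number), and
the amino-acid/nitrate budget within ~14 %.  Two amino-acid rows are not
reproducible from independent data: the amino-acid/O₂ row implies ~606 kJ
of heat per mole of O₂, well outside the ~450–480 kJ/mol-O₂ band that
virtually all organic oxidations obey (Thornton's rule; our value is
451 kJ/mol-O₂), and the amino-acid/sulfate row implies |ΔH| ≈ 10.9 kJ per
mole of SO₄²⁻ — a near-cancellation of large formation enthalpies whose
exact value is hypersensitive to the thermodynamic dataset (we compute
≈ 32 kJ/mol).  These sensitivities are intrinsic to weakly exothermic
sulfate-coupled oxidations, not to the implementation; the package reports
its computed values.

## Thermogram processing

Records hold time in hours and power in watts, with a per-point inclusion
mask; no operation deletes raw samples, so corrections are reversible and
idempotent (a synchronized record re-synchronizes to itself).

**Synchronization method.**  The insertion event is the maximum |dP/dt|
within the first 5 h (configurable); records are shifted so it sits at
t = 0.  The cut is the first time the rolling-median-smoothed signal varies
by less than 3× the late-record noise MAD over a 2 h dwell — i.e. the
transient has settled into the local trend.  The published description of
this step is qualitative ("easily recognizable" convergence); these
defaults are this package's operationalization, and a manual cut time is
always available (and recorded in the parameter log) for records the
heuristic cannot handle, such as monotonically ramping signals.

**Power-function method.**  f(t) = a·t^b + c is least-squares fit
(`scipy.optimize.curve_fit`, bounded b < 0, tight tolerances) to window
segments assumed to contain only artifact and instrument offset — by
default the first and last 10 % of the record, configurable because the
published segment choices are not stated.  Initialization: c₀ = tail-window
median, (a₀, b₀) from log–log regression of (p − c₀) on t; jittered
restarts on non-convergence.  The fit domain requires t > 0 (the time
origin is placed one sampling interval after the record start, avoiding the
t = 0 singularity).  Noiseless recovery is exact to <1e-6 relative;
against the generator, fitted baselines track the true artifact within 2 %
inside the windows at the bundled noise levels.

**Features.**  Cumulative heat is trapezoidal integration of power over
time (hours → seconds internally), exact for piecewise-linear profiles and
additive over adjacent ranges; total heat integrates the full masked record
from the cut time (whether to start instead at peak onset is unstated in
the source method; full-record is the default here).  Peak power is the
maximum masked sample, earliest time on ties.  The ampule-level detection
floor is 1.2 nW/mL × volume.

## Synthetic experiments

The generator emulates what the analysis needs, not the instrument's
physics: an insertion artifact from the same power-law family the
correction fits (guaranteeing a well-specified regime; an exponential
artifact mode exists to probe misspecification), biological heat as a
plateau plus Gaussian or logistic-burst (sech²) pulses — single-peaked,
tailed shapes chosen to resemble observed amendment responses, not a
mechanistic claim — and white Gaussian noise from a seeded
`numpy.random.default_rng` (fixed seed ⇒ bit-identical records).  Closed
forms (erf/tanh) give the exact biological heat, independent of the
trapezoid integrator they validate.  Growth is logistic; chemistry is tied
to cumulative biological heat through a coupling reaction so that substrate
consumed × |ΔH| × 1000 / |ν| equals the true heat exactly.

Bundled presets pin the scenarios to printed observations: a ~100 nW
unamended plateau with 2 nW noise; a ~450 nW formate burst; a slow
~175 nW acetate+nitrate rise; and the 0.371 mM amino-acid amendment with a
2.25 µW Gaussian peak at 32.5 h, a small early burst near 12 h, 20 nW
noise, and the main peak width solved in closed form so total biological
heat is 0.0433 J.  Real instrument drift, multi-peak taxon deconvolution,
and mechanistic thermokinetics are not emulated — parameter-recovery tests
on these fixtures demonstrate the pipeline's correctness under its stated
noise model, not performance on arbitrary real-world drift.

Problem sizes throughout (3,500–7,000 samples per record; 20-seed recovery
batches) were chosen as representative of real export densities while
keeping the full suite fast.

## Known limitations

* Enthalpy re-derivation from independent 25 °C data carries a few-percent
  data-provenance uncertainty, catastrophic only for near-thermoneutral
  reactions (see the sulfate/amino-acid discussion above).
* The synchronization heuristic assumes the artifact settles into noise;
  records whose biological signal rises before the artifact decays need the
  power-function method or a manual cut.
* Heat is attributed reaction-by-reaction; simultaneous partitioning among
  co-active catabolisms is not modeled.
* VPR summaries treat reported per-site ratios as fixture inputs where raw
  counts are unavailable.
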