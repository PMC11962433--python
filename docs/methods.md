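# Methods

## Degradation from CO₂ evolution

Aerobic marine biodegradation is quantified from cumulative CO₂ in closed
flasks. The degradation fraction of sample *i* at time *t* is

    Deg_i(t) = (m_CO2,i(t) − m_CO2,blank(t)) / ThCO2_i,
    ThCO2_i = m0,i · C_tot · 44/12,

where m0 is the initial polymer mass, C_tot the total carbon mass fraction
(packaged defaults: PCL 0.454, PLA 0.493, PBSA 0.52) and 44/12 converts
carbon to CO₂ mass. Assumptions carried by this reduction:

- **Aerobic conditions**: methane production is excluded from the balance.
- **Biomass carbon neglected**: carbon fixed in microbial biomass does not
  appear as CO₂; the resulting underestimate of degradation is typically
  below 5–10 % and is documented, not corrected.
- **Blank convention**: the *mean* of the seawater-only blank flasks at each
  time point is subtracted (a paired-blank convention would also be
  defensible; the mean is less noisy with triplicate blanks). When sample
  and blank grids differ the blank is linearly interpolated onto the sample
  grid — exact for a linear blank drift and mild at biweekly sampling.
- **Negative corrected signals** (sample below blank within noise) are
  clamped to 0 and flagged with a warning, because the fractions feed a
  root of (1 − Δm/m0) downstream and must lie in [0, 1).
- The abiotic (poisoned) control is a QC channel only — it verifies the
  absence of non-microbial CO₂ sources and is never subtracted into samples.

Triplicates are summarised by the arithmetic mean and sample standard
deviation per time point; per-replicate fractions are retained so rate
uncertainty can be propagated instead of being re-derived from the mean.

## Shrinking-particle surface degradation rate

Under surface (not bulk) erosion, a particle's characteristic length d0
shrinks at a constant front velocity v_d on each exposed face, giving

    Δm/m0 = 1 − (1 − 2·v_d·t/d0)^a,     v_d = ½·(d0/t)·(1 − (1 − Δm/m0)^(1/a)),

with shape exponent a = 3 (sphere), 2 (fiber, radial recession), 1 (film,
thickness recession; the factor ½ covers the two faces). v_d is evaluated
with t in years and d0 in µm so rates are natively µm/yr; a converter to
µm/day feeds the fate model. Complete degradation (Δm/m0 ≥ 1) makes v_d a
lower bound only and raises an error rather than returning a number.

Per-replicate rates are estimated first and then averaged (default); an
alternative mode inverts the triplicate-mean fraction, which differs
slightly because the inversion is convex in Δm/m0. Multi-condition rates
for one polymer are aggregated by geometric mean, appropriate for rates
spanning orders of magnitude across particle sizes and temperatures.

The macro→micro correction f_corr = (d_s/d_l)^(2/3), Δm/m0|corr =
f_corr·Δm/m0|large is exposed as an explicit opt-in transform. It is a
conservative device for reusing macro-scale literature mass losses at micro
scale — not a mass balance — and has only been validated for one material,
so the pipeline never applies it silently.

## Two-compartment fate model

Water column (including surface water, which has no separate rates here —
a deliberate collapse) and surficial sediment exchange and lose mass by
first-order processes: degradation in each compartment, sedimentation
(water→sediment), resuspension (sediment→water) and deep burial
(sediment→permanent loss). With

    K = [[k_deg,w + k_sed,        −k_resusp],
         [−k_sed,   k_deg,s + k_resusp + k_burial]],   dX/dt = −K·X + e,

the fate factors are the steady-state residence times τ = K⁻¹·e (days per
unit emission rate into water), identical to the time-integrated mass of a
unit pulse. An independent transient oracle integrates the pulse decay
(LSODA, rtol 1e-9, horizon 50 times the slowest eigen-timescale) and agrees
with the matrix solution to well within 0.5 % across random parameter
draws. A singular K (a compartment or loop without any loss pathway) raises
an error that names the closed loop; the limit with no sedimentation and
water-only emission is handled as a single-compartment model.

The SSDR→rate-constant map is the initial-rate equivalent of the shrinking
particle: d(ln m)/dt at t = 0 gives k_deg = 2·a·v_d/d0 (6 v_d/d0 spheres,
4 v_d/d0 fibers, 2 v_d/d0 films). This first-order surrogate conserves the
initial mass-loss rate but decays exponentially rather than in finite time;
it is the standard simplification for multimedia fate matrices. Sediment
degradation defaults to the water-column rate (no sediment-specific data)
but is independently overridable for sensitivity analysis.

Numeric sedimentation/resuspension/burial rates are density- and
site-specific and not fixed by this package. `DEMO_FATE_PARAMETERS`
(k_sed = 0.4 /day, k_resusp = 1e-3 /day, k_burial = 2e-3 /day) encode the
qualitative regime of a high-density settling polymer — sedimentation fast,
return and burial two to three orders slower — for demonstration and
testing only.

## Characterization factors

    midpoint CF  = FF_w·EEF_w + FF_sed·EEF_sed      [PAF·m³·day/kg]
    endpoint CF  = midpoint · SF / depth / 365      [PDF·m²·yr/kg]
    species·yr/kg = endpoint · 3.46e-12 species/m³ · 100 m

The day→yr division is written out explicitly because the endpoint unit is
per year while fate factors are in days. EEFs and the severity factor SF
are not public. Only the product SF/depth is identifiable from the packaged
CF table, whose endpoint/midpoint ratio is constant (≈ 2.72e-5 across all
45 rows); the defaults SF = 0.993, depth = 100 m are *calibrated* to that
ratio and labelled as such. Demo EEFs (1000 / 100 PAF·m³/kg/day for water /
sediment) express that exposure-effect is stronger in the water column.

The canonical 45-row dataset (PCL, PLA, PBSA × sphere, fiber, film × 1, 10,
100, 1000, 5000 µm; both levels) ships as versioned text exactly as
tabulated; computed CF tables use the same schema with `source=computed`
and are never merged with canonical rows. A validator asserts the dataset's
structural regularities: CF strictly increasing with size, film ≥ fiber ≥
sphere at fixed size (surface-to-volume ordering), PLA ≥ PBSA ≥ PCL at
fixed geometry (degradability ordering), and the constant endpoint/midpoint
ratio within ±1 %. Comparative metrics (size, shape and degradability
effects) are ratios, so they are invariant to the unknown EEF/SF/depth
scale — which is exactly why they are meaningful without the unpublished
parameters. Reported percentages are rounded half away from zero at the
printed precision.

## Scenario study

Emission records (stage, polymer, shape, size, mass per functional unit,
compartment) are characterized only for the marine compartment. The seven
scenarios combine: emission set (guideline-based vs worst-case complete
end-of-life fragmentation), CF size class (medium = each record's own size;
low/high force 1 µm / 5000 µm), and polymer CF set (PLA vs PCL). Impact is
Σ mass × endpoint CF, converted to species·yr; the contribution analysis
reports PEB/(PEB + Σ background). Background damages per impact category
would require a full LCI database and are an input table; the packaged
background and inventories are synthetic demonstration fixtures
(`synthetic_demo_*.csv`), so the demo shares illustrate the computation,
not a real product's footprint.

## Synthetic incubation generator

The generator emulates a six-month, biweekly-sampled campaign: triplicate
sample flasks, triplicate seawater blanks, one poisoned abiotic flask.
Signal model per sample flask: blank drift (linear, 0.1 mg/day — the
functional form of the inoculum's intrinsic activity is not constrained by
data, so the simplest form is used) plus Deg(t)·ThCO2 from the forward
shrinking-particle model, plus Gaussian read-out noise (sd 5 mg vs a
ThCO2 of ≈1665 mg at the 1 g default load). Replicate variability is a
lognormal multiplier (mean 1, CV 0.35) on each flask's SSDR rather than on
the CO₂ readings: observed triplicate spreads of tens of percentage points
in final degradation are biological process variability, and a single rate
multiplier reproduces a ≈39–65 % spread. Temperature enters as one
multiplicative rate scaling (0.04 emulates the ≈96 % slowdown at 4 °C); an
Arrhenius law would be over-fitting a single cold observation.

What the generator does *not* emulate: headspace CO₂ partitioning and
alkalinity chemistry, residual-monomer contributions, priming of the
inoculum, autocorrelated drift, fragmentation. Passing recovery tests
therefore demonstrates correctness of the estimator chain under the stated
noise model, not robustness to every artefact of real respirometry.

Default problem sizes keep everything desk-scale: 14 time points × 7 flasks
per condition, 200 replicated experiments for the recovery statistics, 100
random draws for the fate-oracle agreement; all chosen as the smallest
sizes at which the checked statistics are stable.

## Known limitations

- First-order degradation is an initial-rate surrogate of finite-time
  particle consumption; residence times of fast-degrading large particles
  are mildly overestimated.
- No windage, Langmuir circulation, biofouling, or regionalization; no
  time-horizon-specific (transient) fate factors — steady state only.
- Bulk (hydrolytic) degradation is outside the surface-erosion model; for
  polymers with substantial bulk degradation the SSDR conflates mechanisms,
  which is the motivation for the conservative downscaling correction.
- Additive and degradation-product toxicity are out of scope; the CFs
  cover physical effects only.
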