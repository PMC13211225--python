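# Methods

## Kinetic model

Degradation is described by the truncated Šesták–Berggren rate law,
dα/dt = k(T)·(1−α)^n·α^m with Arrhenius rate constant
k(T) = A·exp(−Ea/(R·T)), R = 8.314 J/(mol·K), time in months and
temperature stored in Kelvin (inputs in °C are converted as K = °C +
273.15).  The exponent n is the reaction order of the decaying factor and
m the autocatalytic order; m > 0 produces a lag phase whose length grows
with m, followed by acceleration — the phenomenology of nucleation-driven
protein aggregation.  Special cases: n=0 linear, n=1 first-order, and
n=1, m=1 the Prout–Tompkins equation with logistic solution.

A model comprises one or two sub-reactions.  We read the multi-step
construction as *parallel independent* sub-reactions — each step carries
its own progress variable α_i, rate parameters and orders, and the steps
are combined only in the observable.  The alternative (step 1's product
feeding step 2) would require a mechanistic coupling the phenomenological
rate law does not define; the parallel reading keeps each step within the
same one-dimensional family and matches the additive construction of the
model.  Two-step models fix m₁ = 0 so the lag-free step is identified as
step 1.

**Observable mapping.**  Assays report signals, not conversions, and the
mapping is treated as affine: y(t) = y0 + Σ_i dY_i·α_i(t), with baseline
y0 and signed amplitudes dY_i fitted alongside the kinetics.  The sign
freedom lets the same machinery fit decreasing responses (SE-HPLC purity,
acetate content) and increasing ones (hydrodynamic radius, turbidity,
barycentric mean).

**Autocatalytic seeding.**  α = 0 is a fixed point when m > 0, so
autocatalytic steps start from a small seed conversion α₀ (default 1e−6,
optionally fitted on a log scale within [1e−9, 1e−2]) — standard
Prout–Tompkins practice.  Steps with m = 0 always integrate from α = 0;
their trajectories are independent of α₀ by construction.

**Integration.**  Temperature programs are piecewise-constant; within a
segment the rate constant is frozen and the step advances from its
carried-over conversion, which makes both isothermal storage and
temperature-cycling (e.g. 8↔25 °C) exact compositions of isothermal
solves.  In scaled time τ = k·t the isothermal problem is
parameter-free per (n, m, α₀), so one solution serves every temperature;
closed forms are used for all m = 0 orders and for n=1, m=1, and an
adaptive stiff-capable solver (LSODA, rtol 1e−8, atol scaled to
min(1e−12, 1e−8·α₀)) handles the rest.  The absolute tolerance must sit
below the seed conversion: during the lag phase α ≈ α₀ ≈ 1e−6, and a
looser floor would destroy relative accuracy exactly where the lag length
is decided.  Trajectories are clipped to [0, 1] and forced non-decreasing
to remove solver-level wiggles.

## Global fitting

All temperatures are fitted simultaneously: one (A_i, Ea_i) per step for
the entire dataset, so the temperature dependence is constrained to be
Arrhenius rather than estimated per condition.  To avoid the extreme
A–Ea correlation of the naive parameterization the optimizer works in
(ln k_ref, Ea) with k_ref the rate constant at T_ref = 298.15 K;
A = k_ref·exp(Ea/(R·T_ref)) is recovered afterwards.  Replicates enter as
independent residuals (no pre-averaging), and the loss is unweighted
least squares — assay noise is treated as homoscedastic within an assay.

Optimization uses trust-region-reflective least squares with a fixed
multi-start schedule: activation energies {30, 60, 90, 120} kJ/mol with a
data-scaled rate guess (the hottest arm converting ~63% over the study),
plus a ten-fold-slower fifth start.  The schedule is deterministic; a
seed only enters if more starts are requested than the schedule provides.
Reaction orders are frozen at candidate-grid values by default (the grid
is n ∈ {0, 0.5, 1, 2} × m ∈ {0, 0.5, 1}, one- and two-step); a
continuous mode bounded [0, 3] exists for order refinement.  RMSE is
defined as sqrt(RSS/n) — the degrees-of-freedom correction enters the
prediction-width formula through the t-quantile instead.  Fits with
n_params + 1 ≥ n_points are refused.

## Model selection

Candidates are compared with the Gaussian least-squares information
criteria AIC = n·ln(RSS/n) + 2p and BIC = n·ln(RSS/n) + p·ln(n), where p
counts all fitted parameters *plus one* for the implicit error variance
(a constant offset across candidates on the same data, but the
conventional count).  Criteria become Akaike weights
w_i ∝ exp(−Δ_i/2), normalized over the candidate set; models are ranked
by the selected weight (wAIC by default), with ties broken by fewer
parameters, then grid order.  Headline predictions use the rank-1 model;
weight-averaged prediction is a deliberate non-feature pending a use
case.  AICc is available as an option but off by default.

## Uncertainty

Prediction intervals come from a noise bootstrap: the selected model is
refitted to B−1 = 199 copies of the dataset perturbed with i.i.d.
Gaussian noise, giving a 200-member ensemble together with the base fit.
The noise SD defaults to the base fit's RMSE (a built-in estimate of
assay variability; an assay-specific SD can be supplied instead).
Replicate refits warm-start at the base estimate, falling back to the
full multi-start schedule on failure; more than 20% failures aborts the
ensemble.  At each prediction time the 2.5th/97.5th empirical percentiles
(linear interpolation between order statistics) of the ensemble
predictions form the 95% confidence band, and each side is inflated
separately to a prediction band:

    pred_width = sqrt(conf_width² + (t_{α/2, n−p} · RMSE)²)

with dof = n − p, p the fitted model parameters.  Because the two sides
use their own percentile distances the interval is asymmetric whenever
the bootstrap distribution is skewed.  The prediction band contains the
confidence band by construction, and both widen monotonically with the
level.

## HTS readouts

* **Scatter correction** — the protein-free window 350–500 nm is fitted
  with s(λ) = a + b·λ^c (internally scaled to λ/400 nm for conditioning;
  start c = −4, the Rayleigh exponent, with c free in sign), then
  extrapolated and subtracted over the full 250–500 nm range.
* **Turbidity** — apparent absorbance at 350 nm interpolated from the
  *uncorrected* spectrum, since the scattering signal is the quantity of
  interest.
* **Fluorescence** — trapezoidal AUC and the barycentric mean
  BCM = Σλ_i·I_i / ΣI_i over 300–450 nm, computed on raw emission by
  default (scatter correction of emission spectra is optional); small
  negative noise excursions are tolerated, a non-positive total intensity
  is an error.
* **DLS** — second-order cumulant fit in the squared (Frisken) form
  g₂(τ) = 1 + β·e^{−2Γτ}(1 + (μ₂/2)τ²)², PDI = μ₂/Γ²; radius via
  q = (4π·n_ri/λ)·sin(θ/2), D = Γ/q², R_h = k_B·T/(6π·η·D).  Instrument
  defaults (θ = 158°, λ = 830 nm, n_ri = 1.33, η = 0.89 mPa·s, 25 °C) are
  typical of plate-reader DLS and configurable.

## Synthetic data: what it emulates and what it does not

The generators emulate a short accelerated stability study on a
refrigerated biologic: 5/25/40/45 °C, eight time points over 0–3 months,
triplicate measurements (the usual plate layout), homoscedastic Gaussian
noise at 2% CV.  Two stock truths:

* **first_order** — purity-like decay, one step, n=1, m=0, Ea = 80
  kJ/mol, k(45 °C) = 1.0/month.  The hottest arm runs to ~95% conversion,
  deliberately far enough through the curve that order structures are
  distinguishable; storage at 5 °C loses ~37% over 36 months.
* **aggregation** — radius-like growth, two steps: a small gradual drift
  (n=1, m=0, Ea = 60 kJ/mol) plus an autocatalytic term (n=1, m=1,
  Ea = 100 kJ/mol, α₀ = 1e−6, k(45 °C) = 8/month) whose logistic midpoint
  falls at ~1.7 months at 45 °C and far beyond the study at 5/25 °C —
  flat cold arms, accelerating hot arms.

Spectral generators produce Gaussian emission bands with red-drifting
centers and decaying amplitudes, absorbance spectra as an analyte band
plus a growing a + b·λ^c scatter baseline, and single- or
multi-exponential correlograms from known radii.

Passing the simulation studies therefore shows *internal* correctness and
calibration under a correctly specified, homoscedastic-Gaussian,
isothermal-arm world.  Real stability data add model misspecification,
heteroscedastic and non-Gaussian assay error, batch effects, and
deviations from Arrhenius behaviour (e.g. near phase transitions) — the
studies say nothing about those, and prediction intervals on real data
should be read as lower bounds on uncertainty.

## Simulation-study sizes and seeds

The calibration studies are sized for desk-scale runs: coverage uses 100
datasets × 200 bootstraps (the held-out point is 5 °C/12 months);
parameter and structure recovery use 50 replicates each.  Structure
recovery fits the 12-model one-step grid with 3 optimizer starts per
model — the starts schedule is a numerics knob, not a study condition,
and 3 starts reproduce the 5-start optima on this family while keeping
the grid sweep proportionate.  All studies derive their per-replicate
seeds from a single root seed via `numpy` seed sequences.

## Known limitations

* Two-step models are parallel, not sequential; truly consecutive
  mechanisms are approximated at best.
* No weighted or heteroscedastic regression; responses with
  signal-dependent noise should be transformed first.
* The late-stage slowdown of S-shaped aggregation (approach to a plateau
  below α = 1) is only captured insofar as the amplitude dY absorbs it.
* The bootstrap treats the selected structure as fixed; model-selection
  uncertainty is not propagated into the bands.
* DLS cumulant analysis reports a mean radius and PDI only; no
  distribution inversion (CONTIN-style) is attempted.
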