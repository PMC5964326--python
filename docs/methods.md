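# Methods

## Model

The regulatory core is the canonical sequestration architecture of the
yeast GAL switch: Gal80p represses Gal4p by stoichiometric binding
(`kf84`/`kr84`, Kd = 0.2 nM in the defaults), and inducer-activated
sensor removes Gal80p into a second complex (`kf83`/`kr83`). Sensor–sugar
binding is not modelled explicitly; instead the inducer concentration
gates the forward rate of the lumped sensor–repressor interaction as

    kf_eff(s) = kf83 · s / (Ks + s)

with half-saturation `Ks` in % w/v. A linear mode (`kf83·s/s_ref`) is
selectable through the parameter file for sensitivity analysis. Promoter
activities are Hill functions of *free* Gal4p. The right-hand side of
the six-species system is

    dG3/dt  = P3(G4) [+ PG1(G4) if dual | const. rate if constitutive]
              − kf_eff(s)·G3·G80 + kr83·C83 − γ·G3
    dG80/dt = P80(G4) − kf_eff(s)·G3·G80 + kr83·C83
              − kf84·G80·G4 + kr84·C84 − γ·G80
    dG4/dt  = α4 − kf84·G80·G4 + kr84·C84 − γ·G4
    dC83/dt = kf_eff(s)·G3·G80 − kr83·C83 − γ·C83
    dC84/dt = kf84·G80·G4 − kr84·C84 − γ·C84
    dGFP/dt = βGFP · G4^n1/(K1^n1 + G4^n1)

where `P_x(G4) = α_x + β_x·G4^n_x/(K_x^n_x + G4^n_x)`. GFP carries no
decay term, so fluorescence readouts are always accumulated GFP at a
fixed readout time T (default 1080 min = 18 h, matching the plate-reader
incubation). Gal1p's galactokinase activity is outside the model: the
strains the model describes have it deleted, and the dual feedback is
created by expressing the *sensor* from both the GAL3 and GAL1
promoters.

Integration uses `scipy.integrate.solve_ivp` with BDF, rtol 1e-8 /
atol 1e-10 by default (configurable). Sub-tolerance negative excursions
are clipped to zero; an excursion beyond −1e-6 nM is treated as solver
failure. Steady states of the five regulatory species are obtained by
long-time integration (default 2×10⁵ min) followed by `scipy.optimize.root`
polishing, and labelled "induced"/"uninduced" by comparing free Gal4p to
K1.

## Default parameters

The defaults (`src/xylreg/data/default_params.yaml`) are package data,
not code. Scales: total Gal4p pool 40 nM; basal Gal80p pool ~80 nM in
excess of it; sensor basal pool ~30 nM; dilution γ = 0.01 /min (~70 min
doubling). The GAL3 promoter is weak with substantial basal activity
(α3 = 0.3, β3 = 1.2 nM/min); the GAL1 promoter term of the dual design
is low-basal (αG1 = 0.005) with a sharper activation curve (n1 = 3,
K1 = 0.65 nM — free Gal4p is scarce under repression, so half-activation
sits far below the total pool). The lumped binding defaults
(kf83 = 0.25 /nM/min, kr83 = 0.35 /min) put the default design inside
the dose window of the printed xylose series; the five-decade sweep
replaces kf83 anyway. `constitutive_rate` = 1.536 nM/min makes the
constitutive-sensor strain express, without induction, the same total
sensor pool as the fully induced dual-feedback strain.

The set was chosen by iterating against the package's own property
suite (dose-response ordering of the designs, sensitivity-factor
dominance and regime structure across the sweep, hysteresis of the dual
design with a monostable weak-binding control) and then frozen. Two
behaviours deserve explicit mention:

* **Hysteresis is kinetic.** At infinite time the default system has a
  unique steady state at every inducer level; the history dependence the
  hysteresis protocol measures comes from slow relaxation across the
  experimental window (24 h pre-incubation + 18 h readout), during which
  pre-induced cells keep an active regulatory state while naive cells
  are still switching on. The protocol-level gap (up to ~15% of the peak
  readout, nonnegative at every dose) is what the package asserts; a
  strict saddle-node pair is not claimed.
* **Low-kf83 similarity is not reproduced by the shipped defaults.**
  Across the printed sweep range the dual design is at least as
  sensitive as the single design at *every* defined point, the
  architecture gap has a single interior maximum, and both curves
  saturate in the strongest decade. However, at the weakest printed
  binding strengths the gap is ~25–45% rather than <10%: with these
  defaults the two designs converge only below kf83 = 0.1. Parameter
  exploration showed a structural trade-off in this model family:
  parameterizations whose weak-binding decade is graded (and therefore
  similar) systematically put the dual design's half-rise a few percent
  *above* the single design's there — the dual's extra sensor production
  engages late in the dose axis and inflates the top of its curve —
  breaking the dominance ordering instead. The shipped defaults
  prioritise the ordering result.

## Dose-response quantities

The sensitivity factor is extracted at the half-RISE level
(min + 0.5·span over the tested grid) by piecewise-linear interpolation
in log10 concentration; s = 0 points enter the extrema but not the
interpolation. For curves induced from a dark baseline this equals the
half-maximum, and on an analytic Hill curve it returns K for any
cooperativity; using the raw 0.5·max level instead would pin shallow
curves' midpoints at the grid floor once basal GFP accumulation exceeds
half the span. Curves whose total rise is below 1.2-fold are reported as
having an undefined sensitivity factor (kept, flagged, never dropped).
The saturated flag marks curves whose top two readings differ by <5%.
Multiple half-rise crossings resolve to the smallest concentration with
a warning.

Dose-response simulations start from the uninduced regulatory steady
state (cells pre-grown without inducer) with GFP zeroed at the media
shift. Starting from an all-zero state instead would grant every
simulation a spurious burst of free Gal4p while Gal80p accumulates. The
hysteresis protocol equilibrates 24 h with and without saturating
inducer (4%), zeroes GFP, and reruns the dose response from both states;
the weak-binding control (kf83 = 0.01) erases the memory to <1% of peak.

The kf83 sweep covers 25 log-spaced points over 0.1–10⁴ (5 per decade),
holding kr83 fixed (a Kd-preserving co-varying mode is available). Its
per-point dose grid is a wide dilution ladder (10⁻⁶ to 8%) so that
curves stay defined even where the half-rise falls below the
experimentally printed concentrations. Regime classification labels the
leading run of points with relative gap < 0.1 "low", the trailing run
with per-decade change < 0.05 in both curves "high", and the remainder
"intermediate"; fewer than 3 points in any regime attaches an
instability warning.

## Hill fitting

`fit_hill` minimises squared residuals of `F0 + Fmax·sⁿ/(Kⁿ+sⁿ)` in
linear response space (optional weights) using lmfit, multi-started over
4 log-spaced K guesses × n ∈ {0.5, 1, 2, 4}, with bounds n ∈ [0.2, 10]
and K within [min positive s/10, max s×10]. Zero-concentration points
constrain F0. A response span below 3× the pooled replicate standard
deviation raises a no-induction signal rather than returning a fit.
Under the generator's own conditions (5% multiplicative noise,
triplicates, 8 concentrations) the median relative error of K and n is
a few percent.

## Cytometry statistics

ON/OFF decomposition fits a two-component Gaussian mixture to log10
fluorescence (scikit-learn EM, deterministic median-split
initialisation, 100 iterations max, tolerance 1e-8). The threshold is
the equal-posterior boundary between the components; events at or below
it count OFF. Samples whose components are closer than 2 pooled log-sds,
or where one component holds <1% of the weight, are unimodal: they are
assigned wholly ON or OFF by comparing the sample median to a supplied
OFF reference level plus a margin of max(3 pooled log-sds, 0.3 dex). CV
is the n−1 sample standard deviation over the mean of the *linear*
events, the standard cytometry definition.

## Synthetic data

The plate-reader generator draws triplicate readings `F(s)·exp(ε)`,
ε ~ N(0, σ) with σ = sqrt(ln(1+cv²)) and cv = 0.05 by default
(an additive-Gaussian mode exists for robustness checks), over the
published concentration ladders (galactose 2–2×10⁻⁶%, xylose 8–2×10⁻³%
in 10-fold steps; the 4…0% xylose series). The cytometry generator
draws 10,000 events per sample from a two-component log-normal mixture
(OFF at 1 a.u., ON at 100 a.u., log-sd 0.2) whose ON fraction follows a
Hill function of concentration (K = 0.5%, n = 2 — the minimal consistent
choice; the underlying experiments show population shifts but no
functional form). A per-architecture noise multiplier (dual 0.5× single
in the pipeline defaults) emulates the lower expression noise of dual
feedback; the CV ordering the pipeline reports on synthetic data is
therefore by construction, and validates the statistics, not the
mechanism. Generators are byte-deterministic given a seed, and ground
truth is serialised to sidecar files the analysis never reads.

What the synthetic data does not emulate: growth/OD dynamics, instrument
gating and compensation, autofluorescence, and any mechanistic link
between the ODE model and single-cell noise (no stochastic simulation).
Passing tests on synthetic data demonstrate correctness of the
estimators under the stated noise model, not performance on real
cytometry files.

## Problem sizes

Default test and pipeline sizes: 25-point sweeps with an 11-point dose
ladder per point, 18 h readouts, 10,000-event cytometry samples, 50–100
seeded replicates for fit-recovery statistics. These match the assay
scales the package emulates and keep a full run on one core in the
minutes range.
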