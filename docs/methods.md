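# Methods

This note documents the models, numerical choices and limitations of
`meropk` — what is computed, under which assumptions, and what the tests do
and do not demonstrate.

## Structural kinetics (`model_core`)

Disposition is a linear two-compartment mammillary model with elimination
from the central compartment and zero-order (constant-rate) infusion input.
With micro constants `k10 = CL/V1`, `k12 = Q/V1`, `k21 = Q/V2`, the hybrid
rates λ1 ≥ λ2 are the roots of `s² − (k10+k12+k21)s + k10·k21 = 0`, and the
central concentration after a unit bolus is `c1·e^(−λ1 t) + c2·e^(−λ2 t)`
with `c1 = (λ1−k21)/(V1(λ1−λ2))`, `c2 = (k21−λ2)/(V1(λ1−λ2))`.  Infusions
integrate this kernel in closed form; multiple doses superpose; steady
state multiplies each exponential term by its accumulation factor
`1/(1 − e^(−λτ))` rather than simulating many doses, so steady-state
profiles are exact and cheap enough for 10,000-patient simulation runs.
A 50-dose explicit superposition and a high-accuracy `solve_ivp`
integration of the mass-balance ODEs are kept as independent test oracles
(closed form agrees with the ODE to < 1e−6 relative, with the 50-dose sum
to < 1e−8).

Numerical guards:

- The repeated-root case λ1 = λ2 (unreachable for physiological
  parameters) is handled by a relative nudge of 1e−9 on k21 instead of a
  separate limit formula.
- Q = 0 is accepted as the one-compartment limit; the vanished β mode has
  zero amplitude and is masked out of all divisions.
- Dose enters every concentration expression as a single terminal
  multiplication.  Concentrations are therefore exactly linear in dose,
  and because IEEE-754 scaling by powers of two is exact, PTA for an
  fT>4MIC target at dose 4·D is *bit-identical* to PTA for fT>MIC at dose
  D under a shared population — the mechanism behind the overlap of those
  published curves.

Units are hours, mg, L and mg/L throughout.

## Population model and virtual patients (`population`)

The fixed/random-effect constants default to the published healthy-adult
estimates (see README).  Choices the source left open:

- ω and σ values printed as percentages are interpreted as SDs of the
  log-scale random effects (the standard convention for log-normal CV%).
- Virtual-patient creatinine is log-normal with *arithmetic* mean
  0.863 mg/dL and CV 19.0 %; the distribution family was stated but not its
  moments, so the printed mean/CV are matched (`lognormal_mean_cv` solves
  μ, σ of ln CR accordingly).  Only creatinine is sampled for PTA;
  demographics are added to synthetic-study records for per-kg reporting
  but never enter the kinetics.
- The fixed-ω variability terms on Q (14.4 %) and V2 (17.9 %) *are*
  sampled by default; `include_fixed_iiv=False` zeroes them for
  sensitivity analyses, since whether fixed terms were simulated was not
  stated.
- Residual (proportional) error is applied only to synthetic-study
  observations, never in PTA simulation — PTA is a property of the true
  individual concentration profile, per standard practice.

The renal-function suite implements Cockcroft–Gault in its standard form
`(140−Age)·weight/(72·CR)` (×0.85 for women), du Bois BSA, MDRD, and the
CKD-EPI creatinine (2021 race-free coefficients), cystatin C and
creatinine–cystatin equations with their min/max kernels as tabulated in
the source study, including its 0.7 mg/L knot for the cystatin-only
equation.  Cystatin-dependent outputs are returned as `None` when cystatin
C is absent.  These equations feed reporting only; clearance in the
kinetic model depends on serum creatinine alone.

## Target attainment (`pta`)

`fT>MIC` is evaluated over one steady-state dosing interval, which at
steady state equals the fraction of any 24-h window (verified by a tiling
test).  The free profile `f·C(t)` (f = 0.98) is screened on a uniform grid
(default 0.005 h) and every bracketed threshold crossing is refined by
bisection to 1e−4 h; intervals entirely above or below contribute their
full width.  A profile entirely above threshold reports exactly 1.0 so the
100 % targets are never lost to rounding.  Ties `f·C = threshold` count as
non-attainment (measure-zero under the continuous model).  Halving the
grid step moves any fraction by < 0.5 percentage points of the window.

PTA at a MIC is the share of patients whose fraction meets the target
threshold (≥).  One population is shared across all regimens, targets and
MICs of a campaign to maximize comparability, and the per-regimen
concentration matrix is computed once and reused across thresholds.
Continuous infusions use the exact plateau rule, independent of the grid.
Distribution-weighted attainment supports both the expectation form
Σ p(MIC)·PTA(MIC) and per-patient random MIC assignment; the two agree
within Monte Carlo error.  The EUCAST *P. aeruginosa* ladder spans
0.06–16 mg/L; its published weights cover 94.95 % of isolates (the ladder
is truncated) and are renormalized to sum to one.

Default campaign sizes follow the published design: 10,000 virtual
patients; dose grid 500/1000/1500/2000 mg; infusion durations 0.5 and 3 h;
intervals 6, 8 and 12 h; continuous daily doses 2/4/6/8 g; targets
40 %/100 % fT>MIC and fT>4MIC.

## Noncompartmental analysis (`nca`)

AUC/AUMC use the linear-up/log-down trapezoid: rising or equal segments
linear; falling segments with positive endpoints use
`Δt·(C1−C2)/ln(C1/C2)` and the moment analogue
`(t1C1−t2C2)/k + (C1−C2)/k²`, exact for mono-exponential decline; a fall
to zero reverts to linear.  λz comes from log-linear regression over
contiguous terminal windows of ≥ 3 positive post-peak points, selected by
best adjusted R² with ties going to the longer window (a fixed `last_n`
rule is available for reproducibility studies).  Extrapolation:
`AUCinf = AUClast + Clast/λz`,
`AUMCinf = AUMClast + Tlast·Clast/λz + Clast/λz²`,
`MRTinf = AUMCinf/AUCinf − Tinf/2`, `CL = dose/AUCinf`, `Vz = CL/λz`,
`Vss = MRT·CL`, `t½ = ln2/λz`.  Cmax, Tlast and Clast are observed values
only; Tlast/Clast refer to the last strictly positive observation, and
pre-dose or embedded zeros are excluded from all log operations.  A
non-negative terminal slope or < 3 usable points flags failure and
withholds every extrapolated quantity.

Note that accurate absolute AUC requires the profile to start at the
(zero) pre-dose sample: dropping the rising limb's first segment biases CL
upward by the missing early area.

## Synthetic study (`synthetic_study`)

The generator replicates the single-dose trial design: n = 12 subjects,
500 mg over 0.5 h, samples at 0, 0.5, 0.75, 1, 2, 3, 6 h, observations
`y = C·(1+ε)`, ε ~ N(0, 0.109²), truncated at zero (truncation is
negligible at this σ and leaves the pre-dose zero exact).  Output is a
NONMEM-style CSV (ID, TIME, AMT, RATE, DV, EVID, MDV + covariates; EVID 1
dosing rows with MDV 1).  Demographics are sampled independently
log-normal from the study's mean/CV table with an 8:4 male:female ratio.
What the generator does *not* emulate: assay quantification limits,
sampling-time deviations, covariate correlations (e.g. weight–height), or
any model misspecification — passing recovery tests therefore demonstrate
correctness of the pipeline under the generative model, not robustness to
real-data pathologies.

## Parameter recovery (`estimation`)

Per-subject {CL, V1, Q, V2} are estimated by nonlinear least squares on
log parameters, residuals weighted by the observed concentration (floored
at 1e−6 mg/L), multi-start (5 log-normally jittered starts, SD 0.3)
keeping the best objective.  Two design points were settled empirically:

- Weighting by *predicted* concentration lets residuals saturate at −1 as
  predictions grow, creating a spurious unbounded optimum; observation
  weighting removes it.
- An unconstrained log-parameterization admits a degenerate ridge for the
  sparse 7-point design: clearance collapses toward zero while a huge,
  slowly-equilibrating peripheral volume (V2 of thousands of liters)
  drains drug quasi-irreversibly and mimics elimination — and for some
  noise realizations that ridge is the global optimum, reachable even from
  a truth start.  Fits are therefore constrained to a wide physiological
  box (CL, V1 ∈ [0.5, 100] L/h or L; Q ∈ [0.05, 100] L/h;
  V2 ∈ [0.1, 200] L) via bounded trust-region least squares.  Within the
  box, noise-free dense profiles recover all four parameters to < 0.1 %,
  and across 100 noisy 12-subject replicates the fitted geometric-mean CL
  falls within 10 % of the replicate's true geometric-mean CL in ≥ 90 % of
  replicates.

The recovery criterion deliberately compares estimated to *sample-true*
geometric means: with ω_CL = 26.2 % the sampling SD of a 12-subject
geometric-mean CL is ≈ 8 %, so a comparison against the population typical
value would fail ~1 replicate in 4 from sampling variability alone and
would measure the design, not the estimator.  Q and V2 remain weakly
identified per subject under the 7-point schedule; pooled summaries
therefore report CL and Vss alongside the raw parameters.

This is a deliberate per-subject harness, not a mixed-effects estimator:
no pooling, shrinkage, covariate search or likelihood-ratio machinery.

## Configuration, outputs, problem sizes

Campaigns are driven by a pydantic-validated YAML config (`RunConfig`)
carrying the model constants, covariate distribution, regimen grid,
targets, MIC ladder, n, seed and grid step; outputs are tidy CSVs in which
every row carries regimen, target, MIC, PTA, n and seed, plus a JSON
provenance log (config hash, versions).  All randomness flows through
`numpy.random.default_rng` seeds.  Default problem sizes — 10,000 patients
per campaign, 100 replicates for recovery studies, 0.005-h PTA grid — are
the package's standard operating points; each PTA curve evaluates in
seconds on a single core.

## Known limitations

- Healthy-adult model: no renal impairment, augmented renal clearance,
  CRRT/ECMO or pediatric extrapolation; extrapolating the creatinine power
  law far outside ~0.5–1.5 mg/dL is unsupported.
- No between-occasion variability, no covariate effects beyond creatinine
  on CL, no nonlinear elimination, no three-compartment option.
- PTA addresses efficacy targets only; toxicity thresholds and
  bacterial-kill dynamics are out of scope.
- The MIC distribution is a fixed surveillance snapshot; local
  susceptibility patterns will shift weighted-attainment results.
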