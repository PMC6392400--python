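# Methods

## The model

A Type II functional response describes a consumer whose intake saturates
because every gram eaten costs handling time. For a feeding trial in which
the resource is *not* replaced as it is consumed, the appropriate form is
Rogers' random-predator equation, the integral of Holling's disc equation
over a depleting resource:

    Ne = N · (1 − exp(a · (Ne · h − T)))                     (implicit)

where `N` is the initial biomass offered (g), `Ne` the biomass consumed over
the trial, `T` the trial duration (hours), `a` the attack (cropping) rate
(per hour) and `h` the handling (chewing and digestion) time (hours per
gram). The equation is implicit in `Ne`; its explicit solution uses the
principal branch of the Lambert W function:

    Ne = N − W(a·h·N · exp(−a·(T − h·N))) / (a·h)

The maximum feeding rate is `1/h` (g per hour); total intake saturates at
`T/h` as `N → ∞`. The limits `a → 0` (no consumption) and `h → 0`
(exponential depletion, `Ne = N(1 − e^{−aT})`) are handled in closed form.
For `h·N ≫ T` the W argument overflows in double precision, so the solver
switches to the asymptotic expansion `W(e^L) ≈ L − log L` refined by fixed
iteration; a unit test sweeps 1,000 random parameter draws and checks the
implicit-equation residual is below 1e−10 everywhere.

## Experimental design and data correction

The emulated experiment is a split-plot: five tanks, each held at one
temperature (26–34 °C in 2 °C steps), are the whole plots; boxes within a
tank — one of ten plant species at one of seven biomass levels (1, 2, 4, 6,
8, 10, 12 g wet weight) with a single snail — are the subplots; the whole
layout is repeated in three temporal blocks (3 × 5 × 10 × 7 = 1,050 units).
Five species share the herbivore's South American origin ("familiar"), five
do not ("novel").

Plants change weight over 60 h even without herbivory (imbibition,
air-drying). A matching no-herbivore control (10 species × 7 levels × 3
replicates = 210 units) measures this; net consumption is gross consumption
(initial − final weight) minus the species' mean control change. The
packaged control table carries the measured per-species means ± SD (e.g.
alligator weed −0.076 ± 0.15 g, pennywort 0.014 ± 0.072 g). The correction
is applied per species, pooled across biomass levels. Corrected values are
clamped into `[0, N]` — Rogers' equation is undefined outside it — and every
record carries a flag saying whether clamping changed it, so a run can
report how much of the data sat outside the physical range.

## Synthetic data generator

The generator exists so that the full chain (correction → NLS fitting →
bootstrap → mixed models → PGLS) can be exercised and calibrated without
the original raw data. It emulates:

* the full split-plot layout above, enumerated in a fixed block-major order;
* a truth surface in which `log a` and `log h` are linear in temperature
  with origin-specific intercepts and slopes. Defaults mirror the study's
  reported effect structure: attack rate constant in temperature, lower for
  familiar plants (0.05 vs 0.10 hr⁻¹); `log h` falling with temperature for
  familiar plants (−0.129 per °C) and flat for novel ones (+0.004), with
  `h = 20` vs `8` hr/g at 30 °C (maximum feeding rate 0.05 vs 0.125 g/hr —
  realistic totals of 3–7.5 g per 60 h trial for a ~13 g snail). Attack
  rates are set high enough that low-biomass rations are nearly fully
  consumed, so every species × temperature cell saturates inside the 1–12 g
  range and `h` is identifiable — a property the real data evidently had;
* mean-zero species random offsets (SD 0.1) on both log scales, and an
  optional phylogenetic effect on familiar `log h` (+11 per unit cophenetic
  distance, the sign and magnitude of the reported slope), applied centered
  on the familiar-species mean distance so group-level magnitudes are
  unchanged;
* measurement noise: the species' natural weight change drawn
  `Normal(mean, SD)` from the control table plus weighing error
  (SD 0.05 g) on the final weight, truncated so final weight stays in
  `[0, N]`; simulated records are then control-corrected and clamped
  exactly as real data would be.

A single global seed feeds named substreams (`species_offsets`, `trials`,
`controls`, …), so adding a stage never perturbs earlier draws and every
dataset is reproducible from (config, seed).

What the generator does **not** emulate: within-trial satiation dynamics,
snail body-mass variation, realized-temperature jitter around the nominal
tank targets, non-Normal measurement error, and any plant chemistry.
Passing recovery tests therefore demonstrate that the estimation chain is
correct and calibrated under its own assumptions, not that those
assumptions hold for any particular real dataset.

## Fitting and bootstrap

`(a, h)` are estimated per species × temperature by nonlinear least squares
on the log-parameter scale (positivity enforced by construction),
Levenberg–Marquardt, with a heuristic start (`a₀` from the low-biomass
regression of `Ne/T` on `N`; `h₀ = T / max(Ne)`) and five deterministic
log-scale jitters before a fit is declared non-converged. All-zero
consumption is reported as a boundary fit (`a` at a 1e−12 floor, flagged)
rather than an error. `T` defaults to the study's 60 h, so `a` and `h` are
reported per hour; the unit convention is configurable.

Group-mean curves (five familiar or five novel species pooled at one
temperature) get pointwise 95% percentile bootstrap bands: individual trial
records are resampled with replacement within group × temperature (a
species-block bootstrap is available behind `by_species=True`), the model
refit per resample starting from the point estimate, and curves evaluated
on a biomass grid; resamples that fail to fit are redrawn up to a capped
retry count. Default 2,000 resamples, seeded. A calibration simulation
(300 datasets, 500 resamples, evaluated at N = 6 g with species offsets
off and symmetric noise of control SD 0.15 g / weighing SD 0.05 g) measures
91.7% coverage of the true curve — the familiar mild undercoverage of
percentile intervals around nonlinear refits, inside the ±4-point band the
acceptance check allows.

## Comparative models

Log-transformed parameters (natural log; the base only shifts intercepts)
enter two frameworks. Because `log max = −log h` exactly, the handling-time
and maximum-feeding-rate tests are numerically equivalent up to sign — the
code asserts this rather than treating them as independent results.

**Split-plot LMM.** `y = β₀ + β_temp·x_temp + β_g·x_g + β_int·x_temp·x_g +
b_tank + ε` with REML and a random tank intercept (statsmodels `MixedLM`),
where `x_g` is a novel-origin 0/1 indicator (novel = 1) or, in the
familiar-only model, the species' mean cophenetic distance to the five
novel plants. Temperature enters as an uncentered numeric covariate in °C.
Per-term Wald F tests (1 numerator df) are referred to the stratum the term
lives in: temperature varies only between tanks, so its denominator df is
`n_tanks − 1 − 1 = 3`; origin/phylo and the interaction vary within tanks,
giving `N − n_tanks − 2` = 43 (50 rows) or 18 (25 rows). These dfs are a
pure function of the design shape and are asserted as such. If REML lands
on (or fails at) the zero-variance boundary the fit falls back to the OLS
estimate with a `boundary_fit` flag instead of raising. Per-origin
temperature slopes and per-temperature phylogeny slopes are reported as
linear-combination contrasts with subplot-stratum t tests. No
multiple-testing correction is applied; p values are reported raw.
Satterthwaite/Kenward–Roger approximations are out of scope.

**PGLS.** Generalized least squares with error covariance `σ²V`, `V(i,j)`
the shared root-to-MRCA path length under Brownian motion. Implemented
directly: `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y`, residual variance on `n − p` df,
t tests from the GLS covariance. Estimates and t statistics are invariant
to rescaling `V` (so branch-length units don't matter), and the model
reduces exactly to OLS on a star phylogeny — both are asserted. Because one
observation per tip is required, the regression runs at each temperature
level and once on per-species temperature-averaged values. A null
simulation (pure Brownian traits, no origin effect, 2,000 replicates)
checks the t test's type-I error is 5% within Monte-Carlo tolerance.
Pagel's λ and Ornstein–Uhlenbeck covariances are out of scope.

## The packaged tree

Only five cophenetic distances were published (sweet potato to each novel
species: 0.236, 0.386, 0.012, 0.236, 0.236; mean 0.22). The packaged
Newick is a synthetic ultrametric reconstruction (ingroup depth 0.193,
arbitrary units) with an APG-consistent topology — monocots
(water lettuce + taro, then water hyacinth), a caryophyllid/Haloragaceae
eudicot clade (alligator weed + parrot feather), and asterids with the two
*Ipomoea* species sister to the celery/pennywort/lettuce clade — built so
those five distances are reproduced exactly. All other pairwise distances
are fixture values; tests pin only the published ones. The gymnosperm
out-group is dropped before any distance or covariance computation.

## Problem sizes and numerical choices

The packaged analysis and the acceptance checks run at the study's own
dimensions (1,050 trials, 50 fits). Simulation-based calibrations use 200
replicates for parameter- and slope-recovery checks, 300 datasets × 500
resamples for bootstrap coverage, and 2,000 replicates for the PGLS null —
sizes at which the Monte-Carlo standard errors are comfortably below the
tolerances being tested. Ties and degenerate inputs: fits require ≥ 3
distinct biomass levels; a Lambert-W argument below −1/e + 1e−12 (reachable
only by round-off at extreme draws) is clipped; zero-length root-to-tip
paths make the Brownian covariance singular and raise with the offending
taxa named.

## Known limitations

* The split-plot temperature test has only 3 denominator df — the design
  confounds tank and temperature, so the whole-plot stratum is tiny; this
  is a property of the emulated experiment, not of the implementation.
* Handling time is unidentifiable when consumption does not saturate within
  the biomass range; the fitter then returns boundary-adjacent estimates
  with finite SSE rather than refusing, and downstream log-transforms will
  amplify such cells. The generator's defaults avoid this regime.
* The control SD printed per species is stored as-is; whether it was taken
  across the 7 biomass levels or all 21 control units is not re-derived.
* Percentile bootstrap bands undercover slightly (see above); a
  bias-corrected variant is not implemented.
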