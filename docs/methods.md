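# Methods

## What the toolkit does

`dynia-mc` is a Monte-Carlo multi-run harness for batch-executable dynamic
models, with two analysis methods built on top of the harvested ensemble:

* **DYNIA** (Dynamic Identifiability Analysis) — time-resolved parameter
  sensitivity: at every time step, the runs that best fit the observations
  inside a moving window condition each parameter's marginal distribution,
  and the departure of that conditional distribution from the uniform prior
  is summarised as an Identifiability Index.
* **GLUE** (Generalized Likelihood Uncertainty Estimation) — behavioural
  filtering: every run whose NRMSE against observations is at or below a
  threshold is treated as equally probable, and prediction bounds are
  percentiles over that behavioural set.

The harness generalises the write/run/harvest pattern used to drive
closed-source simulators: text templates with `{{name}}` placeholders are
materialised into one folder per treatment, treatments execute strictly one
at a time with completion verified (process exit plus sentinel-file polling
for detached executables) before the next launch, and outputs are collected
into a runs × time × variables ensemble. A bundled surrogate crop model
(`minicrop`) exercises the whole pipeline in-process and as a genuine
external executable (`minicrop` CLI), so no proprietary simulator is needed.

## DYNIA, precisely

Given an ensemble of N runs over T steps and an observed series:

1. **Windowed objective.** Entry (r, t) is the MAE (or RMSE) of run r's
   residuals over `[t−w, t+w]`, truncated at the record's ends (never
   padded — no data are fabricated outside the record). Default w = 10.
2. **Support set.** The `ceil(q·N)` smallest-objective runs at each step,
   q = 0.10 by default; ties break by ascending run index so results are
   deterministic. Rounding up means q > 0 never yields an empty set.
3. **Container density.** Each parameter's support values are binned into
   M = 20 equal-width containers over its prior bounds (half-open bins, the
   last closed). For *integer* parameters the container count is capped at
   the number of distinct integer values: with more containers than values,
   the structurally empty bins would register as spurious identifiability.
4. **Identifiability Index.** `IDI = [½ Σ|p_m − 1/M|] · M/(M−1)` — the
   total-variation distance from uniform, rescaled so a point mass scores 1
   and the uniform density scores 0. The per-container gradient
   `G_m = p_m · M` (density ratio against the prior) is what the
   time-parameter heatmaps shade.
5. **Confidence limits and information content.** The 5th/95th percentiles
   of the support values give 90% confidence limits;
   `IC = 1 − (CL width)/(prior width)`. A uniform (uninformative) support
   has IC ≈ 0.10 at this level, which is why IC is best read against the
   permutation null band provided by `ic_noise_band` (random support sets
   of the same size).

Multi-output conditioning is supported: with a mapping of observed series,
each variable's windowed objective is normalised by its observed mean
magnitude and averaged, so a support run must fit all outputs at once. Only
marginal distributions are examined; parameter interactions are outside the
method's reach by construction.

Finite-sample behaviour matters when comparing parameters: with 50 support
points over 20 containers, a completely uninformative parameter has a
time-averaged IDI around 0.25 purely from multinomial noise (smaller for
integer parameters with fewer containers). The closed-loop experiment
(below) therefore always reports the negative controls' values alongside
the sensitive parameters'.

## GLUE

NRMSE is `100 · RMSE / mean(obs)` in percent (range normalisation is
available); a zero normaliser is an error, never a silent 0 or ∞. The
behavioural filter accepts runs with NRMSE ≤ threshold (inclusive; default
10%), assigns equal weights 1/k, and prediction bounds are central
percentiles per time step (level 1.0 is the min/max envelope). Because
equal-weight GLUE is known to over-widen bounds, the uncertainty summary
reports observed containment next to relative band width instead of
claiming calibrated coverage. The pipeline's default scoring variable is
biomass: a running-yield record is identically zero before flowering, where
mean-normalised NRMSE is undefined.

## The minicrop surrogate

A daily-step, water-driven crop model, deliberately the simplest structure
consistent with the mechanism list of canopy-based water-driven models. It
is a surrogate for testing the analysis machinery, not a reimplementation
of any production model.

* **Thermal time**: `ΔGDD = max(0, min(Tupper, Tavg) − Tbase)`,
  Tavg = (Tmin+Tmax)/2; emergence, senescence, maturity, flowering and the
  harvest-index build-up are GDD milestones (X39, X41, X42, X43, X47).
* **Canopy cover**: seeded at `CC0 = X26·X28/10⁸` at emergence; logistic
  growth `ΔCC = CGC·Ks_exp·CC·(1 − CC/CCx)` before the senescence
  milestone; exponential decline at `CDC·ΔGDD` after; an extra relative
  loss of up to 5%/day under senescence-level water stress; clipped to
  `[0, CCx]`.
* **Stress**: relative depletion D between a process's upper threshold
  (D = 0) and lower threshold (D = 1) maps to
  `Ks = 1 − (e^{fD} − 1)/(e^f − 1)` (straight line at f = 0). Canopy
  expansion uses X4/X5/X6, stomatal closure X7/X8 (lower threshold 1),
  early senescence X9/X10.
* **Water**: a single bucket of fixed depth (the maximum rooting depth of
  the default soil, 1.5 m) with uniform volumetric content.
  `Tr = Ks_sto·KcTr·CC·ETo` capped by root-zone water above wilting point;
  `E = 1.1·(1−CC)·ETo` capped by a 0.15 m evaporation layer above half the
  wilting point. Rain (and irrigation, if enabled) enters first; excess
  above field capacity drains. The fixed bucket depth is what makes the
  daily balance `Δstorage = rain + irrigation − E − Tr − drainage` close
  exactly (machine precision; the tests require < 10⁻⁶ mm per season) —
  current root depth enters only through the transpiration cap.
* **Root depth**: `Zr = Zmin + (Zmax−Zmin)·min(1, GDD/X40)^(X22/15)` — the
  exponent is normalised so the registry's typical shape value (15) gives a
  linear profile.
* **Production**: `ΔB = WP*·(Tr/ETo)` up to maturity; HI ramps linearly
  over X47 GDD after flowering up to HIo; yield = HI·B. Under permanent
  field capacity this reduces exactly to `B = WP*·Σ(Tr/ETo)`, which the
  tests assert.
* **Negative controls**: 21 registry parameters (salinity, pollination
  temperatures, aeration, CO₂ response, and others listed in
  `INERT_PARAMETERS`) are accepted and ignored, so sensitivity analyses
  have ground-truth inert parameters. Cold/heat pollination stress is off
  by default. All state updates are numpy ufuncs, so passing parameter
  arrays simulates a whole ensemble in one vectorised sweep over days; a
  test pins the vectorised sweep to row-by-row scalar simulation.

### Synthetic weather

`generate_weather` emulates an autumn-sown semi-arid wheat season: a
sinusoidal annual temperature course (sowing ≈ mid November, cool winter,
warm late spring) with daily noise, ETo increasing with temperature
(≈1.5 mm/d winter to ≈7 mm/d early summer), and sparse winter/spring rain
(~250 mm/season in `semi_arid`; `no_rain` and `wet` variants exist). Under
the default season the mid-bound reference crop emerges around day 27,
flowers around day 171, senesces around day 197 and matures around day 220
of 240. What it does *not* emulate: multi-year sequences, dew/snow,
within-day dynamics, spatial variability, or correlated forcing errors —
so passing closed-loop tests demonstrate method behaviour under clean,
stationary forcing, not performance on real meteorological records.

## The closed-loop recovery experiment

`dynia_mc.experiments.ground_truth_recovery` is the package's standing
end-to-end check: 20 seeded replicates, each with a fresh 240-day season,
observations generated at the registry mid-bounds truth with 5%
multiplicative Gaussian noise per channel, and N = 500 Monte-Carlo runs.
DYNIA runs once conditioned jointly on all five channels and once on the
running-yield channel alone (the only output that carries information about
harvest-index parameters). Reported per replicate: time-averaged IDI per
parameter, IDI peak days, time-averaged IC with its permutation null band,
and the fraction of steps where the 90% CLs bracket the truth.

What the experiment shows — and honestly does not show: the canopy growth
coefficient's identifiability is real and localised in the canopy-growth
phase (its median peak day sits ~115 days before senescence), harvest-index
parameters peak after flowering, negative controls stay inside their IC
null bands, and CLs of the sensitive parameters cover the truth. But with
47 simultaneously free parameters and 500 runs, the *marginal* support
distribution of the water-productivity parameter barely narrows (its
support-set sd stays near the prior sd even under whole-record, all-channel
conditioning), so its time-averaged IDI does not consistently clear the
maximum over seven null parameters. That is an equifinality property of the
sampling size and dimensionality, and it is surfaced — not hidden — by the
acceptance suite.

## Numerical and design choices

* Independent uniform priors over the registry bounds by default; truncated
  normals available. Integer parameters sample continuously, round half-up
  and clamp, so both bounds stay reachable.
* The bundled wheat registry transcribes the 47-parameter table (names,
  order, integer flags); the numeric bounds are plausible wheat values from
  the broader crop-modelling literature, chosen once as fixture values —
  the source table publishes no bounds.
* Windowed objectives truncate at record boundaries rather than pad.
* Support-set ties break by run index (stable sort) — degenerate ensembles
  give deterministic, documented behaviour.
* Sample matrices, ensembles and analysis tables persist as CSV with
  full-precision `repr` floats plus JSON sidecars; reruns of a fixed
  configuration are byte-identical, and the pipeline manifest hashes every
  artifact (`dynia-mc verify`).
* Sequential execution is the default and the contract (no overlapping run
  intervals, verified by an instrumented mock); a 12 s inter-launch pause
  is conventional for heavyweight external executables, 0 for in-process
  backends.
* Problem sizes used by the test suite and acceptance script (ensembles of
  50–500 runs, 80–240-day seasons, 20 replicates) are chosen so the whole
  closed loop stays fast while keeping the support set at a statistically
  meaningful 50 runs at defaults.

## Known limitations

* DYNIA here evaluates global *marginal* distributions only; interacting
  parameters can appear jointly unidentifiable.
* Raw IDI values carry finite-sample bias that depends on the container
  count; compare parameters at equal M, or against the permutation null.
* GLUE equal-weight bounds are conservative; containment is reported, not
  calibrated coverage.
* The surrogate's single-bucket soil and constant-coefficient evaporation
  are intentionally crude; they keep the evaporation channel active without
  a soil profile model.
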