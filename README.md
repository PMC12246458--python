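# dynia-mc

Monte-Carlo multi-run, time-resolved identifiability (DYNIA) and GLUE
uncertainty analysis for batch-executable dynamic models — with a bundled
water-driven surrogate crop simulator so the whole pipeline runs with no
external model installed.

## Who this is for

Modellers who need to run a simulator hundreds or thousands of times under
sampled parameters — including closed-source executables that can only be
driven through input files — and then ask two questions of the ensemble:

* **When does each parameter matter?** DYNIA conditions each parameter's
  marginal distribution on the best-fitting runs inside a moving time
  window. At step *t*, the `⌈qN⌉` runs with the smallest windowed error
  (MAE or RMSE over `[t−w, t+w]`) form the support set; their values are
  binned into M equal-width containers over the prior `[a, b]`, and the
  Identifiability Index

  `IDI(t) = [½ Σₘ |pₘ(t) − 1/M|] · M/(M−1)`

  measures how far that conditional density departs from the uniform prior
  (0 = unconstrained, 1 = a single container). 90% confidence limits of the
  support values give the information content
  `IC(t) = 1 − (CL width)/(b − a)`.
* **How uncertain are the predictions?** GLUE accepts every run whose
  NRMSE (`100·RMSE/mean(obs)`, %) is at or below a threshold (10% by
  default) as equally probable, and takes per-step percentiles over the
  behavioural set as prediction bounds.

The execution layer materialises one folder per treatment from plain-text
templates (`{{name}}` placeholders), runs treatments strictly one at a time
with completion verified before the next launch (process exit plus
sentinel-file polling for detached executables), and harvests the outputs
into a runs × time × variables ensemble. The surrogate (`minicrop`) is a
daily-step wheat-like model with a 47-parameter registry in which 21
parameters are deliberately inert — known negative controls for the
sensitivity machinery.

## Worked example

```python
import numpy as np
from dynia_mc import wheat_registry, sample_parameters
from dynia_mc.minicrop import (generate_weather, simulate,
                               reference_parameters, simulate_ensemble)
from dynia_mc.treatment_runner import STUDY_CHANNELS, Ensemble
from dynia_mc.dynia import DyniaConfig, run_dynia
from dynia_mc.glue import (nrmse_report, behavioural_filter,
                           prediction_bounds, uncertainty_summary)

registry = wheat_registry()                      # 47 wheat parameters X1..X47
weather = generate_weather(240, seed=11)         # one semi-arid season
truth = reference_parameters(registry)
ref = simulate(truth, weather)
rng = np.random.default_rng(11)
observed = {c: ref.channels[c] * (1 + 0.05 * rng.standard_normal(240))
            for c in STUDY_CHANNELS}             # synthetic noisy observations

samples = sample_parameters(registry, n=500, seed=11)
ensemble = Ensemble(values=simulate_ensemble(samples, weather),
                    run_ids=list(range(1, 501)),
                    time=np.arange(1.0, 241.0),
                    channel_names=list(STUDY_CHANNELS))

# DYNIA, conditioned jointly on all five observed channels
result = run_dynia(ensemble, observed, samples, registry, DyniaConfig())
for name in ("X29", "X31", "X16"):
    idi = result.parameters[name].idi
    print(f"{name}: mean IDI {idi.mean():.3f}, "
          f"peak {idi.max():.3f} on day {np.argmax(idi) + 1}")

# GLUE at the 10% NRMSE criterion on biomass
report = nrmse_report(ensemble, observed)
bset = behavioural_filter(report, "biomass", threshold=10.0)
print(f"behavioural runs: {len(bset)}/500 ({100*bset.acceptance_rate:.1f}%)")
bounds = {v: prediction_bounds(ensemble, bset, v, 0.9) for v in STUDY_CHANNELS}
print(uncertainty_summary(bounds, observed).to_string(index=False))
```

Output:

```
X29: mean IDI 0.285, peak 0.400 on day 41
X31: mean IDI 0.282, peak 0.400 on day 95
X16: mean IDI 0.225, peak 0.360 on day 122
behavioural runs: 42/500 (8.4%)
          variable  relative_width  containment  rank
           biomass        0.150757     0.829167     1
evapotranspiration        0.319844     0.679167     2
  soil_evaporation        0.608251     0.862500     3
     transpiration        0.678174     1.000000     4
             yield        1.288434     1.000000     5
```

Reading it: the canopy growth coefficient (X29) peaks on day 41 — during
canopy expansion, well before senescence — while the salinity threshold
X16, inert by construction, stays near the finite-sample noise floor
(~0.2–0.25 at these settings; compare against `ic_noise_band` for a proper
null). 42 of 500 runs pass the 10% NRMSE criterion on biomass; ranking the
90% prediction bands by width normalised to the observed mean shows biomass
as the most reliable output and yield as the most uncertain.

## Command line

```bash
dynia-mc all --config run.yaml        # sample → run → observe → dynia → glue
dynia-mc dynia --config run.yaml --force
dynia-mc report --workdir out -p X29 --images
dynia-mc verify --workdir out         # re-hash every artifact
minicrop --params p.json --weather w.csv --out run.csv
```

A minimal `run.yaml` (`registry: wheat`, `n_samples: 500`, `seed: 1`)
gets the study defaults: ±10-step window, 20 containers, support fraction
0.10, 10% NRMSE threshold, 90% bounds. Every stage persists CSV/JSON
artifacts and resumes from them; reruns of a fixed configuration are
byte-identical, and `manifest.json` hashes every file.

Driving an external executable instead of the surrogate goes through
`treatment_runner.ExecutableBackend` with a JSON output schema (sentinel
file name, channel columns) — the test suite demonstrates the full
template → subprocess → harvest path using the `minicrop` CLI as the
"closed-source" model.

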