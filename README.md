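# carryover

Carry-over effects in a migratory seabird: does what a bird did last year —
its breeding phenology and its winter at-sea behaviour — predict whether it
raises a chick, fails, or skips breeding this year?

The package is an end-to-end, reproducible reimplementation of that
analysis for researchers working with geolocator/immersion-logger data and
multi-year breeding records. Because the original field data are not
deposited, a first-class synthetic-data module generates the three inputs
(immersion series, phenology tables, encounter histories) with the study's
statistical structure, so every stage is testable from a clean checkout.

## What it computes

Reproductive performance (RP) of a bird-season is SUCCESS (raised a
chick), FAIL (failed during incubation) or SKIP (did not lay).

1. **Activity budgets** (`carryover.activity`) — per-block saltwater
   immersion wet fractions are classified (dry ⇒ flight, wet ⇒ resting,
   intermediate ⇒ foraging) and aggregated into daily daytime proportions.
2. **Breakpoints** (`carryover.segmented`) — piecewise-linear regression of
   flight proportion on winter date, y = a + bx + Σⱼ dⱼ(x − τⱼ)₊, fitted by
   iterative linearisation with bootstrap restarting; the breakpoint count
   is chosen by BIC.
3. **RP classifier** (`carryover.boost`) — from-scratch SAMME multi-class
   AdaBoost over phenology features: αₘ = ln((1−errₘ)/errₘ) + ln(K−1),
   stratified 10-fold cross-validation, within-sex label-permutation
   significance, greedy correlated-feature elimination and cumulative
   importance ranking.
4. **Winter trend contrasts** (`carryover.trends`) — additive decomposition
   (observed = trend + seasonal + remainder, exactly), RP-group mean
   trends, ECDF summaries, and pairwise two-sample Kolmogorov–Smirnov
   tests Bonferroni-corrected over all group pairs × activities.
5. **Multi-event capture–mark–recapture** (`carryover.mecmr`) — a
   hidden-Markov likelihood over encounter histories with survival φ,
   transition matrix ψ, detection p, state-uncertain events and
   finite-mixture heterogeneity; ML fitting on the link scale, AIC model
   comparison, and long-run probabilities of breeding success per current
   state (one-step and stationary modes) with bootstrap CIs.

The model-like stages follow scikit-learn conventions
(`SammeClassifier`, `SegmentedRegression`, `MecmrModel`: constructor
parameters, `fit`, fitted attributes with trailing underscores), with
module-level functions as thin wrappers.

## Worked example

```python
from carryover import (SimulationConfig, simulate_phenology,
                       simulate_encounter_histories, fit_mecmr, longrun_success)
from carryover.boost import cv_error

cfg = SimulationConfig(seed=42)          # default study: 111 bird-seasons, 64/29/18
phen = simulate_phenology(cfg)
rep = cv_error(phen, seed=0)
print(f"10-fold CV error {rep.error_percent:.2f}%  success {rep.success_percent:.2f}%")

hists, _ = simulate_encounter_histories(cfg)   # 199 birds incl. history-only
fit = fit_mecmr(hists, n_starts=5, seed=0)
print(longrun_success(fit, "next_year", n_boot=1000, seed=0))
```

prints

```
10-fold CV error 22.52%  success 77.48%
from_state  prob_success    ci_lo    ci_hi      mode
   SUCCESS      0.578871 0.526205 0.624490 next_year
      FAIL      0.418489 0.336577 0.507243 next_year
      SKIP      0.860907 0.772982 0.914048 next_year
```

The classifier beats 3-class chance (≈ 66.7% error) because prior-season
lay/hatch dates carry RP signal in the generator, and the fitted transition
matrix reproduces the generating carry-over pattern: a bird that skipped
breeding has the highest probability of breeding successfully the following
year, with percentile-bootstrap 95% intervals from the MLE sampling
distribution.

The same run is available from a shell:

```bash
carryover all --outdir out --seed 42        # writes CSVs + manifest.json
carryover validate --encounters out/encounters.csv
```

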