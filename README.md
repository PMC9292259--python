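# audiomaze

Bayesian models of human navigation in invisible, audio-feedback mazes.

Blindfolded navigators exploring a real-sized maze they can only sense
through sparse "wall touch" beeps face a classic spatial-cognition
problem: do they act on momentary feedback alone, or do they build and
reuse a mental map? This package implements three competing models of
such behaviour and everything needed to compare them on synthetic
cohorts with known ground truth:

* **FB** — feedback-only: a wall is "ahead" iff the previous step
  produced a hand beep within ±45° of the heading, or a head beep.
* **MBr** — map-resetting: wall-ahead judgements come from a learned
  Gaussian-mixture mental map, rebuilt from scratch every trial.
* **MBu** — map-updating: the same map criterion, but the map is carried
  across the three repeated trials of a maze.

All models share the same state machinery: per 500 ms motion vector
(step size *d*, turning angle *θ*), a noisy motion estimate
V = V\* + |V\*|ε with ε ~ N(0, Σ), dead-reckoned position (a random walk
in the error), and a mental map holding wall / no-wall evidence as
isotropic Gaussian components (FWHM ≈ 10 cm) added at the estimated
hand/body position each step. Each model's wall/no-wall step labels feed
per-class maximum-likelihood fits — step sizes d ~ Gamma(α, β), turns
θ ~ von Mises(μ, κ), eight free parameters — and models are scored by
the per-step (normalized) log-likelihood, compared across models with a
Friedman test and Bonferroni-corrected Wilcoxon signed-rank post-hocs,
overall and within egocentric/allocentric navigator-style subgroups.

Because the original motion-capture recordings are not redistributable,
the package ships a first-class simulator: corridor mazes in the 8 × 9 m
room and blindfolded walker agents that dead-reckon, build mental maps in
estimated coordinates, alternate walking bouts with wall-examination
dwells, and emit beeps from true contact geometry. Ground-truth
parameters and regime labels are recorded for every synthetic cohort, so
estimator recovery and model-comparison power are testable end to end.

## Worked example

```python
from audiomaze import (
    build_maze, simulate_cohort, fit_trial_models, compare_models,
)

maze = build_maze("Z")
records, manifest = simulate_cohort(
    n_participants=16, mazes=[maze], trials_per_maze=3,
    style_split=0.5, seed=7, step_cap=400,
)
fits = fit_trial_models(records, seed=7)
print(fits.groupby("model_kind")[["wall_fraction", "L_step_norm"]].mean())

for block in compare_models(fits, metric="step"):
    print(block.trial_index, round(block.friedman_stat, 2),
          [(pw.pair, pw.skipped or round(pw.corrected_p, 4))
           for pw in block.pairwise])
```

which prints (seed 7):

```
            wall_fraction  L_step_norm
model_kind
FB               0.083073     1.985771
MBr              0.094010     1.986723
MBu              0.117344     1.988441
1 2.0 [(('FB', 'MBr'), 0.6936), (('FB', 'MBu'), 0.6936), (('MBr', 'MBu'), 'identical by definition')]
2 9.88 [(('FB', 'MBr'), 1.0), (('FB', 'MBu'), 0.0155), (('MBr', 'MBu'), 0.005)]
3 1.5 [(('FB', 'MBr'), 1.0), (('FB', 'MBu'), 0.8936), (('MBr', 'MBu'), 0.3892)]
```

Reading this: the feedback-only model labels ~8% of steps as "wall
ahead" while the map models label more (the map remembers walls the hand
is not currently touching), the map models' per-step step-size
log-likelihood is higher (they predict the walker's slow
wall-examination steps better), and the Friedman statistic per trial
(df = 2) gates the pairwise Wilcoxon p-values; the MBr–MBu contrast is
skipped on trial 1 where the two models are identical by construction.
On this seed the map-updating model's advantage reaches Bonferroni
significance in trial 2.

A command-line pipeline wraps the same functions:

```bash
audiomaze simulate --participants 16 --mazes Z --trials 3 --seed 7 --out runs/sim
audiomaze fit      --manifest runs/sim/manifest.tsv --seed 7 --out runs/fit
audiomaze compare  --fits runs/fit/fits.tsv --styles runs/sim/manifest.tsv --out runs/cmp
```

Every output directory gets the effective configuration
(`config.echo.json`), logs, and SHA-256 checksums for bit-exact
reproduction.

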