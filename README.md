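# crowdasym

Simulation and Bayesian multilevel analysis of the **in-out asymmetry (IOA)
in visual crowding**.

## The scientific problem

A letter presented in the visual periphery becomes hard to identify when a
second letter — a *flanker* — sits next to it. This interference, visual
crowding, shows a striking spatial signature: a flanker placed *outward* of
the target (farther from fixation) interferes more than one placed *inward*
(closer to fixation), even though the inward flanker falls on retina with
better acuity. The ratio of the size threshold with an outward flanker to the
threshold with an inward flanker — the **in-out asymmetry, IOA** — has been
proposed as a diagnostic marker distinguishing crowding from other forms of
flanker interference such as contrast masking. Whether the asymmetry survives
away from the horizontal meridian, under target-location uncertainty, and
across ordinary (non-expert) observers determines whether it can actually
serve as that marker.

`crowdasym` implements, as a tested and reusable pipeline, the computational
chain behind such a study:

1. **Factorial design** (`design_core`): 3 designs (blocked / pre-cued /
   random target location) x 4 locations (up, down, left, right at 7.5 deg
   eccentricity) x 3 flanker conditions (none, inward, outward) = 36 cells;
   8 blocks of 120 trials per design, 2880 trials per observer.
2. **Synthetic observers** (`observer_sim`): ground-truth thresholds drawn
   from a lognormal population with configurable unflanked acuity, inward
   crowding factor and IOA; 9AFC responses from the Watson–Pelli Weibull
   psychometric function (guess rate 1/9, slope 3.5, lapse 0.05, threshold
   criterion 0.5).
3. **QUEST staircase** (`quest_engine`): a gridded Bayesian posterior over
   log10 threshold (prior: 1.1 deg +/- 3 log10 units), trial placement at the
   posterior mean clamped to [0.1, 3.0] deg, two 40-trial runs per cell whose
   pooled 80 trials are re-evaluated from the fresh prior to give one
   threshold and its posterior SD.
4. **Exclusion** (`preprocess`): thresholds with staircase SD > 0.2 log10
   units are flagged as unreliable.
5. **Multilevel lognormal regression** (`bayes_model`): thresholds
   `y ~ LogNormal(eta, sigma)` with `eta = x(cell)'beta + z(cell)'b_p`, all
   interactions in the fixed effects, per-observer varying main effects, and
   informed conservative priors — N(1, 2) location intercepts, N(1, 0.5)
   flanker effects, N(0, 1) everything else, half-Cauchy(0, 10) varying-effect
   SDs, half-Cauchy(0, 1) residual SD. Fit by a partially collapsed Gibbs
   sampler (see `docs/methods.md`).
6. **Asymmetry analysis** (`posterior_analysis`): per-draw crowding factors,
   IOA ratios, 53%/97% highest-density intervals, exceedance probabilities
   p(IOA > 1) and p(IOA > 1.5), meridian and design contrasts, and a
   simulated population of new observers quantifying individual differences.
7. **Recovery harness** (`recovery_harness`): one-command end-to-end
   ground-truth recovery experiments.

## Worked example

```python
import numpy as np
from crowdasym import *

# a 12-observer cohort with true inward crowding factor 2.0 and true IOA 2.5
population = PopulationConfig.uniform(n_participants=12)
observers = sample_population(population, rng_seed=1)
trials, thresholds = simulate_cohort(
    observers, StudyDesign(n_participants=12), QuestConfig(), rng_seed=1
)
thresholds = apply_exclusion(thresholds)
print(cohort_counts(thresholds))

data = build_design_matrix(thresholds)
draws = fit(data, mcmc="smoke", seed=1)
table = ioa_table(draws)
print(table[["design", "location", "median", "hdi97_lo", "hdi97_hi", "p_gt_1_5"]]
      .round(2).head(4).to_string(index=False))
```

prints

```
{'n_rows': 432, 'n_excluded': 9, 'pct_excluded': 2}
 design location  median  hdi97_lo  hdi97_hi  p_gt_1_5
blocked       up    2.53      2.31      2.79       1.0
blocked     down    2.45      2.22      2.69       1.0
blocked     left    2.52      2.29      2.81       1.0
blocked    right    2.36      2.11      2.60       1.0
```

Each row summarises the posterior of the IOA ratio for the average observer
in one (design, location) cell: the staircase-plus-model chain recovers the
generative IOA of 2.5 — the 97% HDIs bracket it — and assigns probability
1.0 to the asymmetry exceeding the conservative criterion of 1.5. Of the 432
simulated thresholds (12 observers x 36 cells), 9 (2%) were flagged as
unreliable by the SD > 0.2 rule.

The same pipeline is available from a shell:

```bash
crowdasym simulate --seed 1 --n-participants 12 --out-dir out
crowdasym fit out/thresholds.csv --seed 1 --mcmc-preset smoke --out-dir out
crowdasym analyze out/draws.npz --seed 1 --out-dir out
crowdasym recover --seed 1 --out-dir out
```

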