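# rankwarn

Single-sample early-warning detection of the **pre-disease state** from
gene-expression ranking change.

Complex diseases often progress through a sudden, bifurcation-like
transition: a stable normal state, a brief unstable *pre-disease* state
at its limit, then an (often irreversible) disease state. Dynamic
network biomarker (DNB) theory predicts that, near the transition, a
small gene module fluctuates strongly and coherently while its mean
expression barely moves — a signal that classical differential
expression misses, and that correlation-based DNB detection cannot see
when only **one sample per time point** is available, as in clinical
practice.

`rankwarn` implements a rank-amplified single-sample statistic for this
setting, for computational biologists analysing expression time courses
(e.g. infection challenge studies) or stage-grouped cohorts (e.g. tumor
stages).

## The statistic

Given `n` normal samples, the per-gene baseline is

    E_i^b = mean(E_i^1, ..., E_i^n)

with `R_i^b` the ascending fractional rank of `E_i^b` across genes
(ties averaged). A single sample at time `t` is scored per gene by its
expression change and its ranking change,

    dE_i^t = E_i^t - E_i^b,   dR_i^t = R_i^t - R_i^b,   S_i^t = dE_i^t * dR_i^t,

and the sample score aggregates the `m` largest local scores
(`m = 50` by default) over the `N` genes:

    S^t = (1/m) * sum_{top m} S_i^t / N.

The **ranking score** of a time course is `dS^t = S^t - S^0`, with
`S^0` the score at the first post-baseline time point. Under the normal
state `dS^t` hovers near zero; when a DNB module destabilizes, its genes
move in expression *and* leapfrog many other genes in rank, so their
products dominate the top-`m` sum and `dS^t` jumps.

Detection: the ranking scores of designated normal subjects are pooled,
z-scored, and the value at the upper-`alpha` standard-normal quantile
(default `alpha = 0.05`) is the threshold `theta`; a subject's earliest
strict exceedance `dS^t > theta` is the early-warning call. For
stage-averaged cohorts with too few reference samples to calibrate
`theta`, a sustained-increase rule calls the earliest stage with a
drastic, continued score rise. At the signal time point, the top-5%
local-score genes are candidate signaling genes; genes recurring in more
than four subjects form the common set for functional follow-up.

## Worked example

```python
import numpy as np
from rankwarn import (SimulationConfig, compute_baseline, compute_threshold,
                      detect_warning, score_series, simulate_factor_study,
                      simulate_null_study)

# calibrate theta from 30 null subjects' pooled ranking scores
pool = []
for i in range(30):
    null = simulate_null_study(SimulationConfig(seed=1000 + i))
    base = compute_baseline(null.normal_matrix)
    pool.append(score_series(null.course, base, m=50).ranking_scores)
theta = compute_threshold(np.concatenate(pool), alpha=0.05)

# a subject whose 20-gene DNB module destabilizes at time point 10 of 16
study = simulate_factor_study(SimulationConfig(seed=1))
series = score_series(study.course, compute_baseline(study.normal_matrix), m=50)
call = detect_warning(series, theta)
print(round(theta.theta, 4), call.signal_index, study.truth_transition_index)
```

prints

    0.0778 10 10

meaning: the calibrated threshold is `theta = 0.0778` on the
ranking-score scale; the subject's score first exceeds it at time point
10, exactly the planted transition. Before that point the trace stays
within the normal band (between `-0.11` and `+0.01`); at the transition
it rises to `0.195` and later to `1.67` — the rank change amplifies the
module's coordinated fluctuation well above the noise floor.

The `examples/` directory walks through each capability (single-sample
scoring, time-course warning, signaling genes, the network tipping-point
simulation, stage mode). A thin CLI mirrors the library:

```sh
rankwarn simulate --seed 1 --out study/
rankwarn run --matrix study/matrix.tsv --metadata study/metadata.tsv \
             --min-subjects 2 --truth study/truth.json --out study/results/
```

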