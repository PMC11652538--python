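# Methods

## Model and procedure

`rankwarn` scores a single expression sample against a normal baseline
and watches the score along a subject's time course for a calibrated
exceedance. The underlying picture is the dynamic-network-biomarker
(DNB) view of disease progression: approaching a bifurcation-like
critical transition, a small gene module shows sharply rising variance
and intra-module correlation (critical slowing down) while its
correlation with the rest of the system falls, and mean expression
changes remain small. Multi-sample DNB detection estimates those
variances and correlations directly; with one sample per time point
that is impossible, so this method uses ranking change as a
single-sample proxy for coordinated fluctuation.

Per gene, against a baseline built as the per-gene mean of the normal
samples (baseline rank = ascending fractional rank of the baseline
mean, average-tie convention):

* expression change `dE_i = E_i - E_i^b`;
* ranking change `dR_i = R_i - R_i^b`, with `R_i` the fractional rank
  of the sample's expression across all genes;
* local score `S_i = dE_i * dR_i`.

A gene scores high only when its expression moves *and* it overtakes
many other genes — a shift coordinated relative to the rest of the
transcriptome. The sample score is the mean of the `m` largest signed
local scores divided by the gene count `N`, and the ranking score of a
course is `dS^t = S^t - S^0` with `S^0` at the first post-baseline time
point, which removes subject-level offsets.

Detection pools the ranking scores of all time points of all designated
normal subjects, z-scores them with their sample mean and (n−1)
standard deviation, and takes the value at the upper-`alpha`
standard-normal quantile as the threshold `theta` on the original
scale: `theta = mean + z_(1-alpha) * sd` (for `alpha = 0.05`,
`z = 1.644854`). The earliest time point with `dS^t > theta` (strict)
is the warning. Thresholding in z-space at `z_(1-alpha)` and
back-transforming are equivalent; the original scale is used so that
`theta` is directly comparable across runs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `m` | 50 | top local scores aggregated per sample; the putative DNB is a small gene set, so `m << N` on genome-scale data |
| `alpha` | 0.05 | upper-tail mass of the normal-score distribution treated as warning territory |
| `fraction` | 0.05 | share of genes kept as candidate signaling genes at the signal time (ceiling rounding, so never empty) |
| `min_subjects` | 5 | recurrence cutoff for the common signaling-gene set ("more than four subjects") |
| `min_consecutive_increases`, `min_relative_jump` | 2, 1.0 | stage-mode rule knobs (below) |

Expression is taken as-is; the method is scale-covariant (scaling all
values by `c > 0` scales scores by `c`) and the pipeline offers an
optional `log2(x+1)` transform for raw counts. Missing values are
rejected at load time rather than imputed.

### Design choices where the procedure was open

* **Signed vs absolute top-`m`.** "Largest score" is read as largest
  *signed* product (coordinated shifts in either direction give
  positive products; discordant ones are negative and excluded). An
  `use_absolute` option exposes the other reading.
* **Ties.** Fractional (average) ranks; ties at the `m`-th score break
  lexicographically by gene id — this fixes the selected *set* but
  cannot change the score, since tied values contribute equally.
* **Boundary.** `dS = theta` exactly is not a signal (strict
  inequality).
* **`m > N`** is an error, not a clamp: on a panel smaller than `m` the
  user should choose `m` deliberately.
* **Gene-universe mismatch** between sample and baseline intersects the
  universes with a warning, re-ranks the baseline on the intersection,
  and errors below 2 shared genes.
* **Threshold pool** includes every ranking score of every normal
  subject's time point — including the identically zero first point,
  which is part of each subject's score series by definition.
* **Stage mode.** Stage-grouped cohorts (one pseudo-sample per stage =
  per-gene mean over the stage's samples, tumor-adjacent samples
  averaged separately as the baseline pool) rarely have enough
  reference samples for a trustworthy `theta`. The call is therefore a
  *heuristic*: the earliest stage (never the first) whose score has
  strictly risen for `min_consecutive_increases` consecutive stages
  with a cumulative rise of at least `min_relative_jump` times the
  spread (max − min) of the earlier stages. Both knobs are exposed and
  reported with the call; the rule is an operationalization of a
  "drastic increase on a continuous basis", not a calibrated test.

## Synthetic studies

The generators provide ground-truthed inputs with the statistical
structure the method assumes, so the whole pipeline is testable
offline.

**Factor model (primary test surface).** `n_genes = 200` genes with
base levels drawn uniformly on a log2-like `[4, 12]` scale and i.i.d.
Gaussian observation noise (`noise_sd = 1`). Each subject has an
8-sample normal pool (a typical asymptomatic-arm size in challenge
studies) and a 16-point course with the transition planted at index 10.
From the transition onward the `dnb_size = 20` module gains a shared
latent factor with loading `lambda_k = 0.9 * k * noise_sd` at the
`k`-th post-transition step plus a mean displacement of the same size,
so the module SD grows as `sqrt(1 + (0.9 k)^2)` — doubling by the
second post-transition step — while intra-module correlation rises
toward 1 and the rest of the genome stays stationary. Null studies are
the same process with the ramp at zero. These defaults are the package's
desk-scale study conditions and are deliberately small; the per-study
computation is the same as at genome scale.

What the factor model does **not** emulate: heteroskedastic per-gene
noise, correlated non-DNB background (housekeeping co-regulation),
heavy-tailed microarray noise, falling DNB-to-rest correlation as an
explicit control, or batch effects. Passing tests show the statistic
recovers a coherent variance-and-rank perturbation against an i.i.d.
background — not that it is robust to structured real-data artefacts.

**Michaelis–Menten network (secondary realism).** An 8-node
stand-in of the same model class as published tipping-point benchmark
systems (whose exact equations are not reproduced here): node 0 obeys
`dx/dt = a + q + 2 x^2/(1+x^2) - x`, with `a` solved from the
saddle-node conditions (`f = f' = 0`) so the low branch annihilates
exactly at the control parameter `q = 0`; downstream nodes form a
cascade of Hill activations/repressions with basal production 0.1 and
unit degradation. Euler–Maruyama integration (default `dt = 0.01`,
additive noise, non-negativity clip), quasi-static sweep of `q` over 16
values from −0.4 to 0.2 with 1,000 relaxation steps per value and the
`q = 0` index as ground truth; `dt >= 2` is rejected as unstable for
the explicit scheme and runaway states raise with advice to reduce the
step. Near `q = 0^-` the core node's restoring force vanishes, so its
variance and displacement grow — the critical-slowing-down signature
the score amplifies.

## Desk-scale experiment design and results caveat

The recovery/specificity/enrichment experiments (tests and
`scripts/acceptance.py`) calibrate one threshold from the pooled
ranking scores of 200 null subjects — mirroring the pooled normal-arm
calibration of the challenge-study design — then score 100 planted
studies against it. Problem sizes (200 genes, 16 points, 100 + 200
runs) keep a full experiment under ~10 s while using the same code
paths as genome-scale data.

One consequence of the method's own calibration is worth stating
plainly: with `alpha = 0.05`, each pre-transition time point of a
healthy course has ≈5% probability of a false exceedance. Over the
~8 scoreable pre-transition points of the default study layout, and
given the ≈0.5 correlation between a course's ranking scores induced by
the shared `-S^0` term, roughly one in five planted courses produces a
false *early* signal before the true transition — matching the false
signals observed in real asymptomatic subjects in this study design.
Early-warning accuracy measured as "signal within a tight window of the
truth" is therefore capped near 80% at these settings regardless of
signal strength; raising specificity (lower `alpha`) trades against
detection delay via the calibration, not the implementation.

## Numerical notes

* Fractional ranks via `scipy.stats.rankdata(method="average")`; rank
  sums always equal `N(N+1)/2` (property-tested).
* Top-`m` selection sorts by `(-score, gene_id)`; equal problem
  instances give bit-identical scores under gene permutation because
  the summed value sequence is unchanged.
* Normal quantile via `scipy.stats.norm.ppf`, accurate far beyond the
  6-decimal requirement of the procedure.
* Matrices round-trip through delimited text at 12 significant digits.
* All generators are `numpy.random.default_rng(seed)`-driven and
  byte-reproducible for a given configuration.

## Known limitations

* The score compares a sample only to the baseline, never between time
  points; abrupt baseline artefacts (e.g. a noisy baseline draw)
  propagate to every `dS^t` of that subject.
* The z-score calibration assumes the pooled normal ranking scores are
  approximately normal; on the factor-model null they are (excess
  kurtosis ≈ 0), but small calibration pools make `theta` noisy —
  pool as many normal subjects as available.
* Stage mode is a heuristic without error control; treat its calls as
  hypotheses to be checked against orthogonal evidence (e.g. survival
  separation between the called pre- and post-transition stages).
* The signaling-gene list is a ranking by a product statistic, not a
  significance-controlled set; downstream enrichment analysis is the
  intended consumer.
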