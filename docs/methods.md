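# Methods

## The classifier

The probabilistic neural network (PNN) implemented here is the classical
four-layer Parzen-window classifier. Given training vectors `w_i` with class
labels, a query `x` is scored per class by

```
f_c(x) = C_c * (1/n_c) * sum_{i in c} alpha_i * exp(-||x - w_i||^2 / (2 sigma^2))
         + lambda_b * b_c
```

and assigned to the argmax class. With `alpha = 1`, `b = 0` and unit costs
this is exactly the textbook PNN (a kernel density estimate per class,
normalized by the class count `n_c`). Three extensions make the model
tunable:

* **pattern weights** `alpha_i in [0, 1]` — per-training-sample kernel
  multipliers, letting the optimizer down-weight noisy or redundant patterns;
* **class biases** `b_c in [0, 1]` — additive per-class offsets in the
  summation layer. The bias enters after the cost-weighted kernel mean,
  scaled by `lambda_b` (default 1). This placement is one defensible reading
  of "biases in the summation layer"; driving `b_c -> 0` recovers the plain
  model, so the optimizer can neutralize the term when it does not help.
* **class costs** `C_c` — multiplicative prior/cost factors (default 1,
  not optimized).

`sigma` is a single shared Gaussian bandwidth, default **0.1** on min-max
scaled features. It is exposed as a parameter but deliberately never touched
by the optimizer: the search space is the weights and biases only.

Ties in the argmax go to the earliest class in the declared class order,
which makes predictions deterministic and independent of training-row order.

### Leave-one-out scoring

Training accuracy is the optimizer's objective. Scored naively, every
training point matches its own pattern unit (`phi = 1` at distance zero) and
accuracy saturates at 100%, flattening the fitness landscape. Fitness is
therefore computed in leave-one-out (LOO) mode: scoring training row `i`
excludes center `i`, and the excluded point's own class divides by
`n_c - 1` — the number of kernels actually summed — rather than `n_c`.
Plain (self-inclusive) scoring is retained for inference on new data.

## The optimizer

The Marine Predators Algorithm maintains a population of `N` candidate
vectors ("prey") in a bounded box, plus an elite memory holding the best
solution seen so far (the "top predator") and, per prey index, the best
position that index has ever held (marine memory saving). Each iteration
applies a phase update, re-evaluates, restores any prey whose memory was
better, refreshes the elite, then applies a FADs perturbation with a second
evaluate/memory/elite pass.

Phases by iteration fraction `t / t_max` (the thirds schedule of the
original algorithm):

1. **t < t_max/3, exploration** — Brownian prey steps:
   `S = R_B (Elite - R_B U)`, `U <- U + P R S` with `R_B` standard normal,
   `R` uniform, step constant `P = 0.5`.
2. **t_max/3 <= t < 2 t_max/3, transition** — the first half of the
   population takes Lévy prey steps (`S = R_L (Elite - R_L U)`,
   `U <- U + P R S`); the second half takes Brownian predator steps around
   the elite (`S = R_B (R_B Elite - U)`, `U <- Elite + P CF S`).
3. **t >= 2 t_max/3, exploitation** — Lévy predator steps:
   `S = R_L (R_L Elite - U)`, `U <- Elite + P CF S`.

`CF = (1 - t/t_max)^(2^(t/t_max))` is the adaptive step factor: 1 at the
start, 0 at the end, strictly decreasing (`CF(t_max/2) = 0.5^sqrt(2) ≈
0.3752`).

Lévy steps use the Mantegna construction `x = u / |v|^(1/beta)` with
`u ~ N(0, sigma_u^2)`, `v ~ N(0, 1)` and

```
sigma_u = [ Gamma(1+beta) sin(pi beta / 2)
            / (Gamma((1+beta)/2) beta 2^((beta-1)/2)) ]^(1/beta)
```

(`sigma_u(1.5) ≈ 0.6966`). The default tail exponent is `beta = 1.5`. Note
the construction degenerates at `beta = 2` (`sigma_u = 0`); the heavy-tail
regime of interest is `beta < 2`.

**FADs perturbation.** Per individual, with probability `FADs = 0.2` the
position takes a masked jump `U <- U + CF [L + R (Uˆ - L)] ⊗ W` toward a
random point of the box (`L`, `Uˆ` the bounds, `W` a binary mask); otherwise
it drifts along the difference of two distinct random prey,
`U <- U + [FADs (1 - r) + r] (U_r1 - U_r2)`. Two mask conventions are
implemented: `sparse` (default; mask entries are 1 with probability `FADs`,
as in the original algorithm) and `paper_literal` (the inverse, entries are
1 with probability `1 - FADs`), selectable via `fads_w_convention` for
fidelity experiments. With a single-individual population the drift branch
is unavailable and the masked jump is always applied.

**Numerical choices.** Positions are clamped to the nearest bound after
every update. One `numpy` generator per run, seeded from the configuration,
feeds all transient draws in a documented fixed order, so identical
(space, config, objective, seed) gives a bit-identical trace. Early stopping
is available via `patience` (iterations without elite improvement) but is
off by default so that runs with equal `t_max` are directly comparable.
Non-finite objective values raise immediately with the iteration context.

Default configuration: `N = 10`, `t_max = 100`, bounds `[0, 1]`,
`P = 0.5`, `FADs = 0.2`, `beta = 1.5` — the benchmark settings for PNN
weight/bias tuning.

## The hybrid trainer

Two encodings map a bounded vector `theta in [0, 1]^dim` to a PNN:

* `pattern_bias` (default): `theta = [alpha, b]`, dimension `n_tr + C`. The
  centers never move, so the LOO kernel matrix is theta-independent and is
  precomputed once; each fitness evaluation is then a single weighted
  matrix product. This is the encoding consistent with a parameter count
  "modest compared with O(n d)".
* `centers`: `theta = [vec(centers), b]`, dimension `n_tr * d + C`, for the
  alternative reading in which the pattern centers themselves are optimized
  (meaningful because features are min-max scaled to [0, 1]).

One individual of the initial population is planted at the **identity
encoding** (`alpha = 1`, `b = 0`, original centers). Combined with elite
memory this guarantees the trained model's LOO training fitness is never
below the vanilla PNN's — the hybrid cannot lose to its own baseline on the
training objective, making the improvement claim a testable invariant.

Fitness is the LOO fraction correct (for binary labels exactly
`(TP+TN)/(TP+TN+FP+FN)`). Budget accounting counts the initialization pass
plus both per-iteration evaluation passes: `N + 2 N t_max` evaluations per
run, so cross-optimizer comparisons can be made by evaluations rather than
iterations. The random-search baseline draws independent uniform vectors
from the same box (identity deliberately not planted) and keeps the best.

## Evaluation protocols

* **Stratified hold-out** (default 70/30): per class, membership is shuffled
  by the split seed and allocated by largest-remainder rounding of the
  global fraction, so per-class test shares are within one instance of the
  target. Classes need at least 2 members.
* **Repeated stratified k-fold** (default k=5, 30 repetitions, seeds 1..30):
  per repetition, each class is shuffled and dealt round-robin into folds
  (fold order itself shuffled per class), giving per-class fold sizes that
  differ by at most one; metrics are averaged over folds within a
  repetition.
* **Metrics**: accuracy, precision, recall, F1 on the percent scale; AUC via
  the Mann–Whitney rank statistic with midranks for ties. Zero-denominator
  precision/recall is reported as 0 with a warning so reports stay total.
  The positive label defaults to the lexicographically/numerically larger
  one; multiclass problems use macro (one-vs-rest) averaging.
* Features are min-max normalized with statistics from the training split
  only; test values are clipped to [0, 1] and constant training features map
  to 0.

## Statistical battery

* **Wilcoxon signed-rank**: zero differences dropped; for at most 25 nonzero
  pairs the two-sided p-value is exact (the full sign-assignment null,
  computed by dynamic programming over doubled midranks — identical to
  enumeration); beyond that, a normal approximation with continuity and tie
  corrections.
* **Holm–Bonferroni**: thresholds `alpha / (k - i + 1)` in ascending-p
  order, with strict step-down semantics — the first failure stops all later
  rejections, so the rejection set is always a prefix of the sorted order.
* **BCa bootstrap CI** (default 10,000 resamples): bias correction `z0` from
  the fraction of bootstrap replicates below the point estimate,
  acceleration `a` from the jackknife third-moment formula; seeded
  resampling; constant data yields a zero-width interval. A
  `force_percentile` switch pins `z0 = a = 0` for validation against plain
  percentile intervals.
* **Cohen's d** for paired designs: mean difference over the standard
  deviation of the differences (ddof 1).
* **Levene's test** with mean centering (the classical form), delegated to
  `scipy.stats.levene`.
* **Correlations**: Spearman (Pearson on midranks) and Pearson with
  t-approximation p-values, via `scipy.stats`.

## Synthetic data

The generators stand in for the 11 UCI benchmarks so that the whole pipeline
runs offline:

* `make_gaussian_classes` — per-class isotropic unit-variance Gaussian
  clouds whose means sit `separation` spreads apart (class 0 at the origin,
  other means along random unit directions), min-max scaled to [0, 1], with
  a `noise_rate` fraction of labels flipped.
* `make_interleaved_nonlinear` — two interlocking crescents in the first two
  features (not linearly separable by construction; a linear model scores
  well below a local one), jitter `0.3/separation` so the ~0.3 inter-crescent
  gap is `separation` within-class spreads, extra dimensions filled with
  uniform noise.
* `make_benchmark_suite(master_seed)` — eleven datasets with exactly the
  instance and feature counts of the benchmark tables (HSS 283×3 through
  Fourclass 797×2), imbalanced analogs where the originals are imbalanced,
  the Fourclass analog using the crescent structure, everything else
  Gaussian with separation 2.5 and 5% label noise — moderate overlap chosen
  so baseline accuracies land in a realistic 70–90% band with room for the
  optimizer to improve.

What the synthetic suite does **not** emulate: correlated or heterogeneous
feature scales, discrete/ordinal features, missing values, and the specific
class geometries of the real UCI tables. Tests passing on this suite
demonstrate the pipeline's correctness and the qualitative
optimizer-beats-baseline pattern, not the published per-dataset accuracy
levels, which depend on the real data.

## Problem sizes used in tests and the acceptance script

Property tests run the optimizer at population 25 and 300 iterations on a
5-dimensional sphere (success: best value below 1e-2, at least 9 of 10
seeds). The end-to-end benchmark reproduction runs the full 11-dataset suite
at a reduced budget — population 10, 30 iterations, 5 hold-out seeds — which
completes in well under a minute while preserving the qualitative pattern
(MPA-PNN at or above the vanilla PNN mean test accuracy on at least 9 of 11
datasets, and training fitness never below the vanilla LOO baseline, which
the identity seeding guarantees on every run).

## Known limitations

* PNN inference is O(n_tr · d) per query and fitness is O(n_tr² d); no
  prototype condensation, kernel approximation, or spatial indexing is
  implemented, so very large corpora are out of scope.
* The bandwidth `sigma` is global and fixed; per-class or adaptive
  bandwidths are not supported.
* The Mantegna sampler degenerates at `beta = 2` rather than reducing to an
  exact Gaussian.
* Calibration metrics (Brier, ECE), nested cross-validation, and Bayesian
  optimization baselines are not included.
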