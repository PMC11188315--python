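# Methods

## The model

The predictor is a Gaussian radial basis function network with K hidden
units over d standardized inputs:

    ŷ(x) = Σₛ wₛ · exp(−‖x − oₛ‖² / 2σₛ²) + b,

with centers oₛ ∈ ℝᵈ, widths σₛ > 0, output weights wₛ and a scalar output
bias (threshold) b.  `‖·‖` is the Euclidean norm.  Prediction targets are
plot-level soil nutrient contents (mg/kg) or yields (kg); inputs are
z-scored nutrient contents, so centers and widths live in standardized
units.

## Hybrid training

The grey wolf optimizer searches the flat parameter vector
`[centers | log σ | w | b]` (length K·d + 2K + 1) to minimize the mean
relative prediction error `mean(|y − ŷ|/|y|)` on the training split.  GWO
keeps the three best-so-far solutions (alpha/beta/delta, ties broken by
earliest evaluation); each wolf moves to the mean of three leader-guided
candidates `leader − M ⊙ |N ⊙ leader − w|` with per-component draws
M ∈ [−ω, ω], N ∈ [0, 2] and a convergence factor ω = 2(1 − k/k_max).
Positions leaving the search box are clipped.

Search box: centers in each feature's observed [min, max] widened by 0.5×
the range; log-widths in [log 0.05, log 5]; weights in ±10·sd(y); bias in
mean(y) ± 10·sd(y).  The bias box is centred on the target mean because
soil contents and yields are strictly positive at levels (≈20–300) far
above their spread — a zero-centred bias box would make the constant term
unreachable and the relative-error landscape needlessly hard.

Two numerical choices matter for search quality and are worth stating:

* **Unit canonicalization.** The network is invariant under permutation of
  its hidden units, so the same function appears at K! points of the search
  space and averaging leaders unit-wise across permutations produces
  meaningless candidates.  After every update each wolf is mapped to the
  representative with units sorted by first center coordinate.  The
  unit-wise boxes are identical, so sorting keeps positions feasible.
* **Gradient fine-tuning ("refine").** Optionally, after the search, each
  of the three leader wolves is fine-tuned by full-batch gradient descent
  on mean squared error over all parameters, and the candidate with the
  lowest training mean relative error is returned.  The step size starts at
  `refine_lr` and adapts (×1.2 on an accepted step, ×0.5 on a rejected
  one); the epoch-best parameters are returned, so refinement never makes
  the training loss worse.  Refinement is off by default — the headline
  training behaviour is the metaheuristic search — but the benchmark runs
  the full hybrid (search + refinement), which is how the method is
  described: backpropagation corrects the output when it deviates from the
  expected value.

Defaults: K = 10, 30 wolves, 100 iterations, `refine_lr` 1e-3,
`refine_epochs` 2000.  The benchmark and recovery experiments use larger
budgets (K = 15, 40 wolves, 400 iterations, 4000–12000 refine epochs),
chosen once as the configuration of those experiments; the trade-off is
pure compute time, a few seconds per fit.

Training fitness is measured on the training split by default.  A
validation-fitness mode exists (`fitness_split="validation"`) but changes
model selection and is off by default.

## Standardization

`H̄ᵢ = (Hᵢ − R)/αₕ` per attribute with R the mean.  The default scale αₕ is
the population (divide-by-n) standard deviation, which is the only reading
under which the standardized data have variance 1; a `variance` convention
(divide by the population variance) is retained as an explicit option
because the transform is sometimes stated that way.  Parameters are always
fitted on the training split and reused for validation and prediction to
avoid leakage.  MAPE and the relative-error fitness require |y| ≥ 1e-8;
soil contents and yields are strictly positive, so the guard never triggers
on well-formed data.

## Evaluation metrics

MAPE = 100·mean(|U − Û|/|U|), MAE = mean(|U − Û|), R² = 1 − SSE/SST with
SST about the mean of the **actual** values (the standard coefficient of
determination).  Comparison tables have one row per metric and one column
per model; a designated subject model gets relative-change columns —
reduction `100(ref − new)/ref` for the error metrics, increase
`100(new − ref)/ref` for R² — rounded half-up to two decimals for
presentation (raw values are returned by `relative_change`).

## Baselines

* **Plain RBF fit**: K centers by greedy farthest-point (maximin) sampling
  of training rows from a seeded random start; one shared width equal to
  the mean nearest-center distance; output layer by least squares
  (minimum-norm when underdetermined).  This is the conventional RBF recipe
  and a strong baseline on smooth targets.
* **BPNN**: one hidden layer of logistic-sigmoid units (default 10), linear
  output, mini-batch gradient descent (batch 6, 100 epochs, initial lr
  0.01) with the per-epoch schedule `lr_e = lr/(1 + decay·e)`, decay 0.001,
  seeded shuffling.  Targets are centred/scaled internally during training
  (predictions are returned in original units); without this the loss
  surface for targets near 170 kg and unit-scale weights makes SGD at
  lr 0.01 diverge.

The benchmark trains every model per seed on identical 7:3 splits with
identical training-split standardization, evaluates MAPE/MAE/R² on
validation in original units, and aggregates by the median across seeds.
Model failures are recorded per cell and the benchmark continues.

## Yield regression

Forward stepwise linear regression over candidate predictors (default: the
three nutrient contents).  Entry: the candidate with the smallest
partial-F p-value (equivalently the t-test on its coefficient) below
α_enter = 0.05, ties broken by column order; after each entry, any included
variable with p > α_remove = 0.10 is removed, worst first.  The loop stops
when no candidate can enter, or when the fit is numerically perfect
(R² > 1 − 1e-12), where partial F-tests degenerate to 0/0.  Zero-variance
candidates are excluded with a warning; the final design is checked for
full rank.

A note on expected recovery rates: entry tests one candidate at a time at
α = 0.05, so with m irrelevant candidates the familywise probability that
at least one enters is 1 − 0.95^m per replicate (~14% for m = 3, ~23% for
m = 5).  Recovery experiments therefore measure recovery of the *true
support* with coefficients near truth (≈100% in the shipped simulations)
and hold the exact-selected-set rate only to its binomial expectation; the
null experiment uses two candidates, where the intercept-only rate is
expected near 90%.

## Synthetic data generator

Emulates a plot-level orchard survey: three nutrient contents and three
fertilizer application rates drawn independently normal (truncated strictly
positive by resampling; bias < 1% at the preset coefficients of variation),
and a yield response plus additive Gaussian noise (default sd 5 kg),
re-drawn on the rare negative. Two calibration presets reflect two
inconsistent scales reported for the same plantation and are offered
side by side rather than silently reconciled:

* `plantation`: site-average assay moments — alk. N 21.5 ± 3.0, avail. P
  47.1 ± 0.6, avail. K 117.7 ± 20.9 mg/kg; application-rate moments from
  the published ten-plot table.
* `table1`: all moments estimated from the ten published plot rows
  (yields ≈ 162–185 kg).

Responses (all with planted ground truth returned to the caller):

* `smooth` (default): yield = 170 + 12·z_N + 6·z_P + 8·z_K +
  10·tanh(z_N·z_K/2), in standardized nutrient units — an affine trend with
  a bounded interaction, the kind of mild nonlinearity a nutrient→yield
  surface plausibly carries at moderate ranges.  With noise sd 5 the best
  achievable validation MAPE is ≈2.35% (mean absolute of a N(0,5) over a
  170 kg level), which anchors the benchmark numbers.
* `linear`: affine in raw nutrient contents.
* `rbf`: a planted K = 3 Gaussian RBF network over standardized nutrients
  (centers within ±1.5, widths 0.8–1.4, |weights| 15–35 around a 170 kg
  base), used for recovery experiments against a known generative model.

Nutrients are drawn independently (no covariance information is available
for the calibration site); a correlation-matrix hook exists for stress
tests.  What the generator does **not** emulate: spatial autocorrelation
between neighbouring plots, measurement error in the assays, covariance
between nutrients and applications, season/weather effects.  Passing tests
therefore demonstrate the correctness and relative behaviour of the
algorithms under the stated distributional assumptions, not field
performance.

## Experiment sizes and determinism

Shipped experiments use n = 500 (benchmark, 10 split seeds), n = 300
(planted recovery, 10 training seeds) and n = 5000 (split arithmetic);
stepwise simulations use n = 200 with 100 replicates.  These sizes give
stable medians and rates while keeping any single experiment in the
minutes range on one CPU.  Every stochastic component — generation,
splitting, initialization, mini-batch shuffling — is driven by an explicit
integer seed through `numpy.random.default_rng`, and equal seeds reproduce
results bit-for-bit.

## Known limitations

* The published headline accuracy of the hybrid on the original 5,000-plot
  survey cannot be checked here: that dataset is unpublished.  What the
  package reproduces is the self-contained arithmetic of the published
  comparison tables and the qualitative ordering (hybrid ≤ plain RBF and
  BPNN in median validation MAPE) on synthetic data.
* On very smooth targets the plain least-squares RBF baseline is near the
  noise floor, so the hybrid's margin over it is small (hundredths of a
  percentage point of MAPE); the ordering is stable across the shipped
  seeds but not a large effect.
* Relative-error fitness is undefined at zero targets; the package guards
  rather than redefines (no symmetric-MAPE variant).
* GWO convergence guarantees are empirical (monotone best-so-far trace by
  construction; no global-optimality claim).
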