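# Methods

## Model

`rvmgs` implements sparse Bayesian linear regression — the relevance
vector machine (RVM) — for quantitative-trait prediction from
genome-wide biallelic markers, and a bagged ensemble of such models for
marker ranking.

The observation model is

    t_i = y(x_i; w) + eps_i,      eps_i ~ N(0, sigma^2)
    y(x; w) = sum_m w_m rho_m(x)

with independent zero-mean Gaussian priors `w_m ~ N(0, 1/alpha_m)`.
Each weight owns its precision `alpha_m` (automatic relevance
determination); the precisions and the noise variance are chosen by
type-II maximum likelihood, i.e. by maximising the marginal likelihood
(evidence)

    p(t | alpha, sigma^2) = N(t | 0, C),
    C = sigma^2 I + Phi A^{-1} Phi^T,   A = diag(alpha).

The posterior over weights is Gaussian with

    Sigma = (Phi^T Phi / sigma^2 + A)^{-1},
    mu    = Sigma Phi^T t / sigma^2,

and the classical re-estimation updates are

    gamma_m     = 1 - alpha_m Sigma_mm            (well-determinedness)
    alpha_m     <- gamma_m / mu_m^2
    sigma^2     <- ||t - Phi mu||^2 / (N - sum_m gamma_m).

A precision reaching `alpha_prune_threshold` (default `1e12`) removes
its column permanently; the survivors are the relevance vectors (RVs).
The noise-variance update is written with the *squared* residual norm,
which is what the standard evidence derivation yields (printed
statements of this update occasionally omit the exponent).

Two design-matrix layouts give the two model families:

* **kernel RVM** — `Phi[i, j] = K(x_i, x_j)`, one column per training
  individual; RVs are individuals; prediction is
  `y* = sum_r w_r K(x*, x_r)`.  Kernels: linear `x.x'`, polynomial
  `(x.x' + c)^d`, Gaussian `exp(-gamma ||x - x'||^2)`.  Genotypes enter
  kernels as raw 0/1 values.  No intercept column by default
  (`include_kernel_intercept` opts in).
* **linear-basis RVM** — column 0 is an all-ones intercept and columns
  `1..M` are the markers themselves, so the sparsity falls on markers:
  the model is simultaneously a predictor and an embedded feature
  selector.

This is the *full-batch* algorithm: every sweep re-estimates all active
precisions from a complete posterior evaluation.  The greedy sequential
(fast marginal-likelihood) variant that grows the model from a single
basis function is deliberately out of scope.

## Noise handling: the design decision that matters most

Joint re-estimation of `sigma^2` alongside the precisions is
structurally unstable on marker designs with many more columns than
individuals (M >> N, the genomic-selection regime).  While the active
set can still interpolate the targets, the residual in the update above
collapses, its denominator `N - sum(gamma)` approaches zero, and
`sigma^2` free-falls; the fit then saturates with noise-fitting
columns.  This is a property of the full-batch updates, not of this
implementation: `sklearn.linear_model.ARDRegression`, which implements
the same updates, retains 35–100% of columns with `sigma^2 -> 0` and
held-out R^2 ~ 0 on the same synthetic data.

`rvmgs` therefore supports two noise schedules (`RVMConfig.noise`):

* `"fixed"` (default): `sigma^2` stays at
  `sigma2_init_fraction * var(t)` and only the precisions iterate.  The
  default fraction is 1.0 — until the evidence says otherwise, all
  target variance is treated as noise.  This is the recommended (and
  default) mode for M >> N marker data; on synthetic additive traits it
  tracks the Lasso within ~0.05 held-out R^2 while recovering all
  simulated causal markers.
* `"joint"`: a precision-only phase runs to convergence first; noise
  sweeps are then joined in until `alpha` *and* `sigma^2` reach a joint
  fixed point (re-applying the updates changes them by < 1e-4 relative
  in the test suite).  Appropriate for well-posed problems (fewer basis
  functions than observations), where it also estimates the residual
  variance honestly; used in the noiseless-recovery and fixed-point
  tests.

Stopping: the loop ends when the relative change of the log evidence
falls below `logml_rel_tolerance` (default 1e-6) — with one guard.  A
precision travelling towards the prune threshold moves by a roughly
constant log-factor per sweep while the evidence has long plateaued;
declaring convergence then would leave columns "mid-prune".
Convergence therefore additionally requires every `|Δ log alpha|` to be
below 0.05 in the final sweep.  The log evidence is non-decreasing
across sweeps in both modes (property-tested over 50 seeded problems).

Numerics: the posterior is computed by Cholesky factorisation of the
k×k precision `Phi^T Phi / sigma^2 + A` (never a generic inverse), with
one diagonal-jitter retry (`1e-10 · trace/k`) before declaring the
system ill-conditioned.  The evidence is evaluated through the same
factorisation via the Woodbury/determinant identities at `O(N k^2)`
cost; the N×N covariance `C` is never formed.  Targets are centred
before fitting (the mean is stored and restored at prediction);
`sigma^2` is floored at `1e-10 · var(t)` so noiseless inputs cannot
divide by zero.  Constant targets (including all-zero) yield an empty
model that predicts the training mean.  Gram statistics `Phi^T Phi` and
`Phi^T t` are computed once per fit and sliced as columns are pruned.

## Ensemble marker ranking

For ranking, 400 linear-basis RVMs (default) are each trained on a
random subsample of the individuals drawn *without replacement*, the
per-model fraction drawn uniformly from [0.50, 0.60].  Model `j` is
seeded `base_seed + j`, which makes the result identical whether the
members run serially or across worker processes (byte-identical output
is a test).  A marker's rank value is its selection count — the number
of members that kept it as an RV; its effect estimate is the mean of
its relevance weights over exactly those members, whose sign separates
trait-increasing from trait-decreasing alleles.  Markers never selected
are reported as unranked ("no effect").  The deterministic order is
count descending, then |mean weight| descending, then marker index.
"Influential" markers are those selected by at least
`threshold_fraction` (default one half) of the members.  Up to 10% of
members may fail numerically before the run errors; failures are logged
with their seeds.  The intercept never participates in ranking.

## Evaluation protocol

Prediction accuracy is the coefficient of determination on held-out
individuals, `R^2 = 1 - SS_res / SS_tot` (not a squared correlation; it
can be negative).  The default protocol is 10 repeats of 10-fold
cross-validation with freshly shuffled folds per repeat (`seed + r` for
repeat r); per-fold R^2 values are averaged within a repeat, and the
reported spread is the sample standard deviation across the repeat
means.  Model selection compares candidates — by default the linear
basis, the linear kernel, and Gaussian kernels at
`gamma in {1e-4, 2e-4, 3e-4}` — on identically seeded partitions and
takes the highest mean R^2, breaking exact ties towards the simpler
family (linear basis < linear kernel < polynomial < Gaussian), then the
smaller bandwidth.  `pearson_correlation` supports relating per-trait
accuracies to external heritability estimates.

Individuals with a missing value for the trait under study are dropped
before any fitting (alignment between genotype and phenotype tables is
by individual ID, in genotype-file order).

## Synthetic data generator

The generator emulates the shape of a haploid biparental cross:

* genotypes are 0/1 by parental origin, allele frequency 0.5 by default
  (balanced cross);
* local linkage is a first-order copy chain: marker `m` copies marker
  `m-1` with probability `ld_rho` (default 0.2), else is drawn fresh,
  giving geometrically decaying correlation along the chromosome.  This
  is deliberately not a genetic-map model — it is sufficient to produce
  the "nearby markers tag the same locus" behaviour without map files;
* `k_causal` markers (default 10) carry additive effects; the default
  effect distribution is fixed magnitude 1.0 with balanced random
  signs, so both trait-increasing and trait-decreasing alleles exist; a
  `normal(0, tau^2)` alternative is available;
* optional pairwise epistasis adds `effect * x_i * x_j` terms, which
  raises the broad-sense (total genetic) variance fraction above the
  narrow-sense one;
* the noise variance is set from the sampled genetic values so that
  `var(additive) / var(total)` equals the target narrow-sense
  heritability `h2` in expectation; the realized ratio is reported in
  `SimTruth` rather than enforced exactly, since exact enforcement
  would distort the noise distribution.  `h2 = 0` yields a pure-noise
  trait; `h2 = 1` (no epistasis) is noiseless.

Marker identifiers are synthetic `chr{c}:{pos}` strings spread over 16
chromosomes so the TSV/BED reporting path is exercised.

What the generator does **not** emulate: realistic recombination maps,
genotyping error, segregation distortion, population structure, or the
trait-specific noise of colony-size assays.  Passing tests on this
generator therefore demonstrate the mechanics of the method — recovery
of sparse signed effects under local LD and calibrated noise — not
performance on any particular real cross.

## Study-scale checks and problem sizes

The test suite runs two study-scale experiments chosen to finish in
minutes on one CPU: a 300 × 1,000 recovery study (10 causal markers,
five of each sign, h² = 0.8, 100-member ensemble) in which all ten
causal markers appear in the top 20 with perfectly matching signs, and
a 400 × 800 prediction study (h² = 0.5) with 5 repeats of 5-fold CV
over the default candidate grid.  `scripts/acceptance.py` recomputes
both from scratch.

## Known limitations

* Full-batch sparsity is real but milder than the sequential variant's:
  at the 400 × 800 / h² = 0.5 scenario the basis RVM keeps ~7–8% of
  markers and the Gaussian kernel RVM ~20% of training points as RVs;
  the sequential algorithm would keep several-fold fewer.  The ensemble
  ranking is insensitive to this (causal markers are selected by
  essentially all members, noise markers only sporadically).
* In `"fixed"` mode the reported `sigma2` is the assumed level, not an
  estimate; weights of strong effects are shrunk accordingly (a
  noiseless effect of 3.0 fits at ~2.9).  Use `"joint"` on well-posed
  problems when unbiased weights or an honest residual variance matter.
* The default Gaussian bandwidth grid (1e-4 … 3e-4) is calibrated for
  ~10⁴-marker panels; on much smaller simulated panels those kernels
  are nearly flat and the linear basis dominates model selection.
* Kernel-RVM training cost is O(N³) at the start (no pruning yet);
  basis-RVM cost is O(M³) per early sweep.  Both are fine at the
  biparental-cross scale (~10³ individuals, ~10⁴ markers per trait) but
  this is not a biobank-scale tool.
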