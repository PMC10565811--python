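# Methods

`gepqsar` models the log-activity of a congeneric series of
2-phenyl-3-(pyridin-2-yl)thiazolidin-4-one osteosarcoma inhibitors from
numeric molecular descriptors, two ways: a linear track (stepwise
multiple-linear-regression descriptor selection) and a nonlinear track
(gene expression programming, GEP). The quantum-chemical descriptor values
behind the original study were never published, so the package also ships a
calibrated synthetic-table generator; every benchmark below runs on data it
produces.

## Data model

A dataset is a compound-by-descriptor matrix with an aligned activity
vector. Activity is log10(IC50/nM); IC50 values stay in nanomolar as
printed (no molar conversion) and the base-10 logarithm is the packaged
convention (`log_transform`), the standard log(IC50)/pIC50 practice. The
packaged fixture carries the 39 published compounds with experimental IC50
from 8.8 nM (compound 2j) to 931.9 nM (7c); substituent columns are opaque
annotation text. Two rows (2k, 2L) list identical substituents with
different IC50 and are kept verbatim. Train/test splitting is uniformly
random and seed-reproducible; the default study split is 31 train / 8 test.

## Synthetic tables

`synthetic.generate` draws the four informative descriptors (MSA, ANRIFN,
FFPQC, TM2RE) from a multivariate normal with the published pairwise
correlation matrix (checked positive semi-definite; eigenvalues
0.194–2.273), affinely rescaled to per-descriptor (mean, sd). The true
marginal scales are unrecoverable, so defaults are chosen once for
plausibility: MSA (500, 100) — surface-area-like, consistent with its
O(1e-3) coefficient; ANRIFN (0.05, 0.02); FFPQC (20, 5); TM2RE (0.5, 0.2).
Decoy columns (default 16, so 4 of 20 columns are informative) are
independent standard normals. Activity is a planted model plus Gaussian
noise on the log scale, default sd 0.15 (≈ the square root of the reported
linear-model residual variance 0.107):

* `linear_hm`: logIC50 = −9.023 − 1.095e−03·MSA + 8.299·ANRIFN +
  6.249e−02·FFPQC + 4.720·TM2RE (the published linear model);
* `nonlinear_reference`: MSA·TM2RE + FFPQC, used with standardized (unit)
  scales — see the benchmark section.

The generator emulates only the statistical structure the regressions see:
Gaussian marginals, a fixed correlation structure, exchangeable decoys, and
additive homoscedastic noise. Real descriptor tables are non-Gaussian,
heavier-tailed, and contain blocks of highly redundant descriptors, so
passing benchmarks here demonstrates correctness of the machinery and
recovery power under the stated conditions — not performance on real
CODESSA output.

## Linear track

`fit_ols` is ordinary least squares (via statsmodels) reporting R²,
leave-one-out cross-validated R²cv = 1 − PRESS/SST (computed with the
hat-matrix identity, which is algebraically the literal n-refit loop and is
tested against one), the residual variance s² = SSE/(n−p−1), the overall F
statistic, and absolute t values.

`select_descriptors` grows the subset greedily: at each step it adds the
candidate maximizing R²cv among candidates whose absolute Pearson
correlation with every already-selected descriptor is below the threshold
(default 0.8, the published independence criterion), recording the
(k, R², R²cv, s², F) scan. Scoring by R²cv rather than R² mirrors the
emphasis on cross-validated quality; both are available. The subset size is
hard-capped at one descriptor per five compounds. Growth stops when the
R²cv gain drops below epsilon (default 0.02 — the "no significant change"
idea made concrete; the source states the idea but no number), and ties are
broken by column order. A seeded stochastic swap refinement
(`method="hillclimb"`) can follow the greedy pass; the recovery benchmark
uses it because greedy forward selection is provably myopic on correlated
designs.

Known limitation, measured: with the published correlation structure
(−0.720 and −0.702 between selected descriptors) and n = 31, the empirical
|r| of a truly-informative pair fluctuates above the 0.8 filter in roughly
one draw in three, making the true subset inadmissible on those draws;
exact 4-of-20 recovery then succeeds in about 6/10 seeds (17/30 over a
wider sweep), with the remaining failures due to a decoy subset genuinely
outscoring the truth on R²cv at this sample size. This is a property of the
study conditions, not of the search: the filter that guarantees
low-intercorrelation models also vetoes the planted truth near the
threshold.

## Nonlinear track (GEP engine)

Genotype: chromosomes of 5 genes (default), each gene a head of 8 symbols
(functions, terminals, or the constant placeholder `?`), a tail of
h·(a−1)+1 = 9 terminals/placeholders, and a Dc domain of 9 indices into a
per-gene pool of 10 random numerical constants — 26 symbols per gene.
Function set: addition, subtraction, multiplication, division, tangent, and
reciprocal (all binary except tan and inv). Constants are drawn uniformly
from [−20, 20]; the classic ±10 range is too narrow for the magnitude of
constants appearing in the published evolved equation.

Decoding is breadth-first Karva reading: the first symbol is the root, each
function node claims the next unclaimed symbols level by level, and symbols
past the open reading frame are ignored. Each `?` in the reading frame
consumes the next Dc index. The reciprocal decodes directly to a division
node with constant-1 numerator, so trees contain only binary operators plus
tan, and the fully parenthesized infix rendering round-trips through the
bundled parser exactly (constants display with 3 decimals; `precision=None`
renders exactly).

Evaluation is protected (total): a division whose denominator has magnitude
below 1e-12 returns the protected value (default 1.0), and any non-finite
intermediate (tangent poles, overflow) is replaced by it, so every
chromosome is evaluable everywhere. An alternative "poison" mode (score
such chromosomes at fitness ~0) is available via the protected-value flag
semantics in `evaluate`'s caller; protection is the default because it is
standard GEP practice and keeps the search space smooth.

Fitness is f = 1000/(1 + RMSE): bounded in (0, 1000], strictly decreasing
in error, exactly 1000 iff predictions equal observations. The published
run reports only the 1000 ceiling, so only the ceiling and monotonicity are
treated as contracts.

Evolution is generational with fitness-proportionate roulette selection
(size-2 tournament available), at least one elite copied unchanged (so the
best-so-far history is non-decreasing), and the classic operator suite at
canonical rates: point mutation 0.044, inversion 0.1, IS/RIS/gene
transposition 0.1 each, one-point and two-point recombination 0.3 each,
gene recombination 0.1, Dc mutation 0.044, constant mutation 0.01.
Recombination operates on the flattened head+tail+Dc string; the constant
pool of each child gene follows the parent that contributed the gene's
starting symbol. Termination: a generation budget, optionally short-cut by
a fitness threshold. Runs are exactly reproducible from (config, data).

## Recovery benchmarks and their scale

The additive sanity benchmark plants y = a + b (two terminals, no noise,
2 genes, head 4, no constants); ≥ 9/10 seeds reach fitness ≥ 999 within 200
generations.

The nonlinear benchmark plants y = MSA·TM2RE + FFPQC — expressible in two
genes over the function set — on standardized descriptor scales with the
published correlation structure, noise sd 0.1, 39 compounds split 31/8.
Unit scales are used because the planted law must be reachable with
constants in [−20, 20] (a raw MSA of ~500 would not be), mirroring the
common practice of standardizing symbolic-regression inputs. The engine
runs at the published configuration (population 100, 5 genes, head 8) for
500 generations under engine seeds 1..10, and the winner is the
best-training-fitness run; the held-out partition is touched only for
reporting. Typical outcomes: 8–10 of 10 runs recover the law nearly exactly
(test R² ≈ 0.99). The known failure mode is a near-tie winner that fits
training noise with a rational term whose pole falls between training
points, which can collapse test R² on one unlucky row; fitness on the
training set cannot distinguish such a model from the true law, and no
parsimony pressure is applied by default. Problem sizes (n = 39, 500
generations, 10 seeds, ~2 minutes total) are the package's chosen benchmark
scale.

## Reference equations

The linear reference evaluates the published coefficients exactly. The
nonlinear reference is a transcription of the published evolved equation,
which cannot be evaluated as printed: parentheses are unbalanced, `2MSA`
has an implicit product, `tan−2.954` is ambiguous, and `d2` is undefined.
The canonical transcription (one string in `models.GEP_EQUATION_VARIANTS`,
so alternative readings stay pluggable) resolves:

1. parentheses left-greedily, closing each subexpression at the first
   balancing point;
2. `2MSA` → 2·MSA;
3. `9.984/−9.910+TM2RE` → (9.984/−9.910) + TM2RE (usual precedence);
4. `tan−2.954−FFPQC` → tan(−2.954) − FFPQC in the canonical variant; the
   `tan_of_sum` variant ships tan(−2.954 − FFPQC) because the text cannot
   decide between them;
5. `d2` → a terminal bound to a placeholder constant (default 1.0,
   overridable) — the token is undefined in the source and is flagged here
   rather than silently dropped.

These predictors exist to regression-test the evaluator and the comparison
machinery; with placeholder semantics for `d2` they make no claim to
reproduce the original model's numeric outputs on the authors' (unpublished)
descriptor values.

## Comparison statistics

`compare` computes, per model and per partition, R² = 1 − SSE/SST about the
partition mean and a dispersion s² = SSE/(n−1). The source never defines
its S²; SSE/(n−1) is the package's convention, used only for relative
comparison and kept distinct from the regression-fit s² = SSE/(n−p−1).

## Numerical choices

* Correlation-matrix PSD tolerance 1e-10; generation adds 1e-12 jitter
  before Cholesky.
* Leverage ≥ 1 − 1e-12 in leave-one-out marks a rank-deficient refit.
* Protected-evaluation cutoff |denominator| < 1e-12; protected value 1.0.
* Greedy-selection ties broken by column order (continuous data makes exact
  ties measure-zero).
* Degenerate inputs rejected explicitly: empty tables, duplicate compound
  ids, non-numeric cells (reported with row and column), constant activity
  vectors, constant descriptor columns in correlation work.
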