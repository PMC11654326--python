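# Methods

## Model and scope

The package fits ordinary least-squares linear models y = β₀ + Σ β_j x_j + ε
in the n ≪ p regime, selecting the columns greedily rather than by
penalization. The association between predictors and outcome is assumed
linear; predictors must be numeric (categorical variables recoded as 0/1
indicators) with no missing values. Training-set p values are deliberately
not reported: the selection process is an implicit multiple-testing
procedure, so nominal per-coefficient p values on the training data would
be invalid. Inference about competing models happens on test data, via the
bootstrap machinery below.

## Selection procedure

Screening admits column j when |cor(x_j, y)| is **strictly** above the
threshold (default 0.1). The queue sorts by |r| descending — not signed
r, which would demote strong negative correlates — with ties broken by
ascending column index, so results are reproducible across platforms.
Zero-variance columns are assigned r = 0 and never enqueued.

The selection loop treats the first candidate exactly like all later
ones: the baseline "model" is intercept-only, with residuals y − ȳ and
adjusted R² = 0, so correlating a candidate with the baseline residuals
is the same as correlating it with the outcome. The residual-correlation
gate uses ≤ for rejection (a candidate must *exceed* the threshold to
justify a refit); the adjusted-R² gate uses ≥ (a gain exactly equal to
the threshold is accepted; a `strict_gt` switch flips this for users who
prefer the other convention). Rejected candidates are discarded
permanently — the flow is linear, with no active-set cycling.

Fits go through Householder QR on the design including the intercept
column. The design is flagged rank-deficient when the smallest absolute
diagonal of the triangular factor is below 1e−10 times the largest; such
candidate additions are *rejections*, not errors, because near-duplicate
columns are an expected feature of methylome data, not a user mistake.
When the current fit is numerically perfect (R² ≥ 1 − 1e−12) the
residuals are round-off dust and correlations against them are
meaningless, so remaining candidates short-circuit through the
residual-correlation rejection path. Selection halts early, with a logged
warning, if accepting another term would leave no error degrees of
freedom (n − k − 1 < 1).

Because the reported coefficients come from the final joint refit over
exactly the accepted columns, they coincide (to ≤ 1e−10 in the test
suite) with a direct least-squares refit on those columns — model files
can therefore be audited with any regression software.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `corr_threshold` | 0.1 | minimum \|r\| with the outcome to enter the queue (unitless correlation) |
| `resid_corr_threshold` | 0.1 | minimum \|r\| with current residuals to justify a QR refit |
| `delta_r2` | 0.01 | minimum adjusted-R² gain to accept (1% of outcome variance) |
| `workers` | 1 | screening threads; never changes output (fixed 8,192-column chunks, serial within-chunk reduction) |

Lowering the thresholds grows the model: on noise-only data the expected
number of admitted columns scales with p · P(|r| > t₁), so the defaults
are the parsimony dial.

## Model comparison

A predictor is calibrated by regressing the observed outcome on its
predictions; the calibration's adjusted R² (k = 1) is the accuracy
summary, and its residuals carry the remaining error in outcome units.
Competing predictors of the same outcome are compared by the ratio of
their calibration-residual variances. Because competing predictors are
strongly correlated with each other (and methylome features with one
another), the textbook F test's p value is not trusted; instead both
calibration regressions are bootstrapped **simultaneously** — each
replicate draws n case indices with replacement once and applies them to
both models — and F_b = var(resid_A)/var(resid_B) is recorded per
replicate (variances use the n − 1 denominator; the ratio is
convention-invariant). With F_lower and F_upper the central-F quantiles
at α and 1 − α (α = 0.05, B = 1000 by default) and n − 2 degrees of
freedom on both margins, the p value is

p = 1 − (#(F_b < F_lower) + #(F_b > F_upper)) / B.

Self-comparison yields every F_b = 1 and p = 1 exactly; swapping the two
predictors maps F_b → 1/F_b and leaves p unchanged because the band is
reciprocal-symmetric for equal dof. Replicates in which a resampled
predictor is constant have an undefined calibration slope; they are
redrawn (logged), with a hard cap of 10·B total draws. Degrees of
freedom always derive from the actual vector length supplied, never from
a stored constant.

Greedy reduction walks a fitted model's terms in acceptance order on
*test* data, keeping each term only if it raises raw R² by at least
`epsilon`. The improvement threshold is a design choice of this package;
the default 0.01 mirrors `delta_r2` and is configurable. Raw rather than
adjusted R² is used because the keep/drop rule itself bounds model size;
by construction the reduced model's test R² is within epsilon × (number
of dropped terms) of the full model's.

## Synthetic data

`generate_null(n, p, seed)` draws every matrix entry and the outcome iid
N(0, 1); the reference configuration (n = 1000, p = 500,000) is the
false-positive benchmark, where any accepted variable is spurious.
`generate_planted` adds y = X[:, support]·effects + N(0, noise_sd²), with
optional equicorrelated blocks built from a shared latent factor,
x = √ρ·z_block + √(1−ρ)·ε, which keeps each column marginally N(0, 1) —
so planting blocks does not perturb the null marginal the benchmark
relies on. Draw order (matrix, block factors, outcome noise) is fixed;
identical arguments and seed give bit-identical datasets.

The generator reproduces the statistical skeleton the selection assumes —
Gaussian marginals, linear effects, block redundancy — and deliberately
omits beta-distributed methylation marginals, cell-composition effects
and array batch structure. Tests passing on these data therefore
demonstrate the *algorithmic* contract (recovery, gating, false-positive
control under independence), not robustness to array artefacts.

Routine tests use a small preset (n = 200, p = 5,000); the full-scale
null experiment runs in the acceptance suite at its original size
(1,000 × 500,000, five seeds), which takes about two minutes and ~5 GB
and yields selected-variable counts in the low thirties.

## Numerical choices and edge cases

- Correlations are computed per column in float64 by centered dot
  products; chunk boundaries are fixed regardless of thread count, so
  screening is bit-reproducible across `workers` settings.
- A zero-variance vector in a correlation yields 0.0 plus a
  `DegenerateDataWarning` rather than NaN; a constant outcome therefore
  produces an empty queue and an intercept-only model whose intercept is
  the outcome mean.
- R² is defined as 0 for a zero-variance outcome (no variance to
  explain), and tiny negative round-off values (> −1e−12) are clamped to 0.
- Non-finite tokens (NaN/Inf) in input files are treated as missing
  values and rejected; files are structurally validated (header, field
  counts) before numeric parsing so ragged rows are reported as format
  errors with 1-based positions.
- Model files store estimates via `repr`, so write → read round-trips
  coefficients to full double precision.

## Known limitations

- Only linear main-effect models; no interactions, no non-linear terms.
- Greedy one-at-a-time admission can miss predictors whose value emerges
  only jointly (complex correlation structures among predictors).
- False-positive control is threshold-based, not FDR-calibrated: on pure
  noise at defaults the model still admits a few dozen columns out of
  500,000 and reports a substantially positive adjusted R² — exactly the
  overfitting the null benchmark quantifies. Guard against it by
  evaluating on held-out data.
- The whole matrix is held in memory (float64); the 500,000 × 1,000
  benchmark needs ~4 GB plus scratch.
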