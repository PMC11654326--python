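# minlinmo

Minimalist variable selection and linear prediction for **n ≪ p** datasets —
the regime of genome-wide DNA methylation arrays, where a few hundred to a
few thousand samples face hundreds of thousands of predictor columns (CpG
beta values). Penalized methods like the lasso produce accurate but large
models (hundreds of CpGs); this package instead builds deliberately small
ordinary-least-squares models — typically a dozen terms — that remain
interpretable while keeping acceptable accuracy, which is what you want when
the goal is an epigenetic clock whose CpGs you can actually read off and
assay.

## The algorithm

Given an n × p design matrix X and outcome y:

1. **Screening.** Compute the Pearson correlation r_j = cor(x_j, y) for
   every column; the indices with |r_j| > t₁ (default 0.1) enter a priority
   queue sorted by |r_j| descending.
2. **Greedy forward selection.** Starting from the intercept-only model
   (residuals y − ȳ, adjusted R² = 0), pop candidates in queue order. For
   each candidate x_j:
   - *Residual-correlation gate:* if |cor(x_j, current residuals)| ≤ t₂
     (default 0.1), discard without refitting — this is where the speed
     comes from.
   - *Adjusted-R² gate:* otherwise refit the model with x_j added
     (Householder-QR least squares, intercept always included) and keep it
     only if

     adj R² = 1 − (1 − R²)(n − 1)/(n − k − 1)

     improves by at least ΔR² (default 0.01). Rank-deficient additions are
     rejected; rejected candidates never re-enter.
3. **Output.** The final coefficients come from one joint refit on the
   accepted columns, so they are *exactly* what `lm(y ~ X[, selected])`
   would estimate.

Companion machinery for evaluating competing predictors on a test set:
calibration regressions (observed outcome on predicted outcome, putting
every predictor on the outcome's scale), a **paired-bootstrap F test** —
resample cases, apply the same indices to both predictors, refit both
calibrations and record F = var(resid_A)/var(resid_B); the p value is
1 − (#(F < F_lower) + #(F > F_upper))/B with the band from central-F
quantiles at n − 2 degrees of freedom — and greedy model reduction on test
data. A seed-reproducible synthetic-data module generates pure-noise nulls,
planted sparse signals, and equicorrelated column blocks that mimic
methylome redundancy.

## Worked example

```python
import minlinmo as mm

truth = mm.SyntheticTruth(support=[3, 17], effects=[1.5, -1.0], noise_sd=0.5)
m, y, _ = mm.generate_planted(500, 2000, truth, seed=42)
trace = mm.run_selection(m, y)
```

Running `python examples/planted_selection.py` prints:

```
queue held 68 candidates (of 2000 screened)
      x3  |r|=0.814  accepted
     x17  |r|=0.511  accepted
    x642  |r|=0.194  rejected_resid_corr
    ...
final model: intercept -0.0219
      x3  slope +1.4944
     x17  slope -0.9964
adjusted R2 0.9350
```

Of 2,000 columns, 68 cleared marginal screening; only the two planted
columns survived both gates, with slopes within sampling error of the true
(1.5, −1.0). The other examples cover the pure-noise false-positive
benchmark (`null_false_positives.py`), predictor comparison with the
bootstrap F test (`compare_two_predictors.py`), and test-set model
reduction (`reduce_on_test_data.py`).

The same workflows are available from a shell:

```bash
minlinmo simulate planted --n 500 --p 2000 --seed 42 \
    --support 3,17 --effects 1.5,-1.0 --x-out X.csv --y-out y.csv
minlinmo select --x X.csv --y y.csv --out model.csv
minlinmo predict --model model.csv --x X.csv --out pred.csv
```

Input files are plain CSV with a header row, no row names and no missing
values; model files are two-column `term,estimate` CSV with the intercept
first.

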