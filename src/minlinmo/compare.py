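"""Model-comparison statistics: calibration, paired bootstrap F, reduction.

Two prediction models of the same outcome are compared on a common test
set in three moves:

* each model's predictions are put on the outcome's scale by a calibration
  regression (observed outcome on predicted outcome);
* the residual variances of the two calibration fits are compared with an
  F ratio, bootstrapped by resampling CASES — the same resampled indices
  are applied to both models in every replicate, which respects the strong
  correlation between competing predictors and the dependence structure in
  methylation data that invalidates the textbook F test's p value;
* a fitted model can be greedily reduced on test data, keeping each term
  (in acceptance order) only while it still buys R2.

The bootstrap p value is ``1 - (#(F < F_lower) + #(F > F_upper)) / B``
where the band is the pair of central-F quantiles at ``alpha`` and
``1 - alpha`` with n - 2 degrees of freedom on both margins (a calibration
regression has a single predictor).  Large p means the band contains the
bulk of the bootstrap F ratios, i.e. no detectable accuracy difference.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ModelSpec, OutcomeVector, PredictorMatrix, ValidationError
from .selection import adjusted_r2, fit_ols

__all__ = [
    "CalibrationFit",
    "ComparisonResult",
    "calibration_fit",
    "f_bounds",
    "paired_bootstrap_f",
    "reduce_model",
    "write_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationFit:
    """Simple regression of observed outcome on a model's predictions."""

    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    residuals: np.ndarray


@dataclass
class ComparisonResult:
    """Paired-bootstrap F comparison of two predictors' residual variances."""

    f_stats: np.ndarray
    mean_f: float
    p_value: float
    f_lower: float
    f_upper: float
    dof: tuple[int, int]
    n_replicates: int
    alpha: float
    n_redrawn: int = 0


def _as_vector(v: OutcomeVector | np.ndarray) -> np.ndarray:
    if isinstance(v, OutcomeVector):
        return v.values
    return np.asarray(v, dtype=np.float64).reshape(-1)


def _simple_fit_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of y on x (with intercept), closed form."""
    xc = x - x.mean()
    slope = (xc @ y) / (xc @ xc)
    return y - y.mean() - slope * xc


def calibration_fit(
    observed: OutcomeVector | np.ndarray,
    predicted: OutcomeVector | np.ndarray,
) -> CalibrationFit:
    """Regress observed outcome on predicted outcome (one predictor).

    This normalizes any predictor to the outcome's own scale, so models
    reporting on different scales become comparable; its adjusted R2 (k=1)
    is the headline accuracy figure and its residuals feed the variance
    comparison.
    """
    yo = _as_vector(observed)
    yp = _as_vector(predicted)
    if yo.shape[0] != yp.shape[0]:
        raise ValidationError(
            f"length mismatch: observed {yo.shape[0]}, predicted {yp.shape[0]}"
        )
    n = yo.shape[0]
    if n < 4:
        raise ValidationError(f"need at least 4 points, got {n}")
    if np.ptp(yp) == 0.0:
        raise ValidationError("predicted values are constant; slope undefined")
    fit = fit_ols(yp[:, None], yo)
    return CalibrationFit(
        slope=float(fit.slopes[0]),
        intercept=fit.intercept,
        r2=fit.r2,
        adjusted_r2=adjusted_r2(fit.r2, n, 1),
        residuals=fit.residuals,
    )


def f_bounds(alpha: float, dof1: int, dof2: int) -> tuple[float, float]:
    """Central-F quantiles at alpha and 1 - alpha (the bootstrap band)."""
    if not (0.0 < alpha < 0.5):
        raise ValidationError(f"alpha must be in (0, 0.5), got {alpha}")
    if dof1 < 1 or dof2 < 1:
        raise ValidationError(f"degrees of freedom must be >= 1, got {dof1}, {dof2}")
    return (
        float(stats.f.ppf(alpha, dof1, dof2)),
        float(stats.f.ppf(1.0 - alpha, dof1, dof2)),
    )


def paired_bootstrap_f(
    observed: OutcomeVector | np.ndarray,
    predicted_a: OutcomeVector | np.ndarray,
    predicted_b: OutcomeVector | np.ndarray,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ComparisonResult:
    """Compare two predictors' calibration-residual variances by bootstrap.

    Per replicate, n case indices are drawn with replacement ONCE and the
    same indices are applied to both (observed, predicted) pairs; both
    calibration regressions are refit and F = var(resid_a)/var(resid_b)
    recorded (variances with the n-1 denominator; the ratio is
    denominator-convention-invariant).  A replicate in which either
    resampled predictor is constant is redrawn (logged), up to 10*B draws.

    Degrees of freedom are n - 2 on both margins.
    """
    yo = _as_vector(observed)
    ya = _as_vector(predicted_a)
    yb = _as_vector(predicted_b)
    n = yo.shape[0]
    if ya.shape[0] != n or yb.shape[0] != n:
        raise ValidationError("all three vectors must have the same length")
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    dof = n - 2
    f_lower, f_upper = f_bounds(alpha, dof, dof)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f_stats = np.empty(B, dtype=np.float64)
    draws = 0
    redrawn = 0
    b = 0
    while b < B:
        if draws >= 10 * B:
            raise RuntimeError(
                f"exceeded {10 * B} bootstrap draws with degenerate replicates"
            )
        idx = rng.integers(0, n, size=n)
        draws += 1
        ya_s, yb_s = ya[idx], yb[idx]
        if np.ptp(ya_s) == 0.0 or np.ptp(yb_s) == 0.0:
            redrawn += 1
            logger.info("redrawing bootstrap replicate with constant predictor")
            continue
        yo_s = yo[idx]
        ra = _simple_fit_residuals(yo_s, ya_s)
        rb = _simple_fit_residuals(yo_s, yb_s)
        f_stats[b] = ra.var(ddof=1) / rb.var(ddof=1)
        b += 1
    outside = int(np.count_nonzero(f_stats < f_lower)
                  + np.count_nonzero(f_stats > f_upper))
    return ComparisonResult(
        f_stats=f_stats,
        mean_f=float(f_stats.mean()),
        p_value=1.0 - outside / B,
        f_lower=f_lower,
        f_upper=f_upper,
        dof=(dof, dof),
        n_replicates=B,
        alpha=alpha,
        n_redrawn=redrawn,
    )


def reduce_model(
    model: ModelSpec,
    test_m: PredictorMatrix,
    test_y: OutcomeVector,
    epsilon: float = 0.01,
) -> ModelSpec:
    """Greedily prune a fitted model on TEST data, in acceptance order.

    Terms are scanned first-to-last; each is kept iff adding it to the
    kept set raises the test-data R2 by at least ``epsilon`` (raw R2 —
    model size is judged by the gain threshold, not a dof penalty).  The
    returned model is refit on the test data over the kept terms, so its
    coefficients are the test-set least-squares estimates.
    """
    missing = [t for t in model.term_names if t not in test_m.column_names]
    if missing:
        raise ValidationError(
            "model terms absent from the matrix: " + ", ".join(missing)
        )
    yv = test_y.values
    n = test_m.n_samples
    kept: list[int] = []
    r2_prev = 0.0
    fit_prev = fit_ols(np.empty((n, 0)), yv)
    for name in model.term_names:
        j = test_m.column_names.index(name)
        fit = fit_ols(test_m.values[:, kept + [j]], yv)
        if fit.rank_deficient:
            continue
        if fit.r2 - r2_prev >= epsilon:
            kept.append(j)
            r2_prev = fit.r2
            fit_prev = fit
    return ModelSpec(
        intercept=fit_prev.intercept,
        terms=[(test_m.column_names[j], float(b))
               for j, b in zip(kept, fit_prev.slopes)],
        adjusted_r2_final=adjusted_r2(fit_prev.r2, n, len(kept)),
        provenance=model.provenance,
    )


def write_comparison(
    results: dict[str, ComparisonResult] | ComparisonResult,
    path: str,
    dump_f: str | None = None,
) -> None:
    """Write comparison rows as CSV; optionally dump per-replicate F stats."""
    if isinstance(results, ComparisonResult):
        results = {"comparison": results}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "mean_f", "p_value", "f_lower", "f_upper",
                    "B", "dof1", "dof2", "alpha"])
        for label, r in results.items():
            w.writerow([label, repr(r.mean_f), repr(r.p_value),
                        repr(r.f_lower), repr(r.f_upper),
                        r.n_replicates, r.dof[0], r.dof[1], r.alpha])
    if dump_f is not None:
        with open(dump_f, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "replicate", "f"])
            for label, r in results.items():
                for i, f in enumerate(r.f_stats):
                    w.writerow([label, i, repr(float(f))])
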