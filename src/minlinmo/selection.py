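"""Greedy forward selection with residual-correlation and adjusted-R2 gates.

The loop pops candidates from the screening queue in order of decreasing
marginal |r|.  Each candidate faces two gates:

1. a cheap residual-correlation gate — if the candidate's absolute Pearson
   correlation with the current model's residuals is at or below a
   threshold (default 0.1) it is discarded without any refit, which is
   where most of the algorithm's speed comes from; and
2. the adjusted-R2 gate — otherwise the model is refit (QR least squares)
   with the candidate added, and the candidate is kept only if adjusted R2
   improves by at least ``delta_r2`` (default 0.01, i.e. one percentage
   point of variance explained, net of the degrees-of-freedom penalty).

Rejected candidates never re-enter.  Because the final coefficients come
from a single joint least-squares fit on the accepted set, they are exactly
what an ordinary regression of the outcome on the selected columns yields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .io import (
    ModelSpec,
    OutcomeVector,
    PredictorMatrix,
    ValidationError,
    validate_pair,
)
from .screening import CandidateQueue, _corr_one, screen

__all__ = [
    "SelectionConfig",
    "OlsFit",
    "SelectionStep",
    "SelectionTrace",
    "fit_ols",
    "adjusted_r2",
    "run_selection",
]

logger = logging.getLogger(__name__)

# relative tolerance on the triangular factor's diagonal for rank decisions
RANK_RTOL = 1e-10

ACCEPTED = "accepted"
REJECTED_RESID_CORR = "rejected_resid_corr"
REJECTED_DELTA_R2 = "rejected_delta_r2"
REJECTED_RANK = "rejected_rank"


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the selection loop (all user-adjustable).

    corr_threshold: minimum |r| with the outcome to enter the queue.
    resid_corr_threshold: minimum |r| with current residuals to justify a refit.
    delta_r2: minimum adjusted-R2 gain to accept a refit candidate.
    strict_gt: use a strict > on the adjusted-R2 gate instead of >=.
    """

    corr_threshold: float = 0.1
    resid_corr_threshold: float = 0.1
    delta_r2: float = 0.01
    strict_gt: bool = False

    def __post_init__(self) -> None:
        for name in ("corr_threshold", "resid_corr_threshold", "delta_r2"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if self.delta_r2 <= 0.0:
            raise ValidationError("delta_r2 must be positive")


@dataclass
class OlsFit:
    """A least-squares fit with an intercept always included."""

    intercept: float
    slopes: np.ndarray
    residuals: np.ndarray
    r2: float
    adjusted_r2: float
    rank_deficient: bool


@dataclass
class SelectionStep:
    """One popped candidate and what happened to it."""

    column_index: int
    column_name: str
    abs_corr_outcome: float
    abs_corr_resid: float | None
    adjusted_r2_before: float
    adjusted_r2_after: float | None
    decision: str


@dataclass
class SelectionTrace:
    """Full audit of a selection run: one step per popped candidate."""

    steps: list[SelectionStep]
    final_model: ModelSpec
    final_fit: OlsFit
    queue: CandidateQueue
    accepted_indices: list[int] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted_indices)

    def format_log(self) -> str:
        lines = []
        for s in self.steps:
            rc = "-" if s.abs_corr_resid is None else f"{s.abs_corr_resid:.4f}"
            after = "-" if s.adjusted_r2_after is None else f"{s.adjusted_r2_after:.5f}"
            lines.append(
                f"{s.column_index}\t{s.column_name}\t|r|={s.abs_corr_outcome:.4f}"
                f"\t|r_resid|={rc}\tadjR2 {s.adjusted_r2_before:.5f} -> {after}"
                f"\t{s.decision}"
            )
        return "\n".join(lines)


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Degrees-of-freedom-penalized R2: 1 - (1-R2)(n-1)/(n-k-1).

    k counts non-intercept terms; with k = 0 this is R2 itself.
    """
    if n - k - 1 < 1:
        raise ValidationError(
            f"adjusted R2 undefined: n - k - 1 = {n - k - 1} < 1"
        )
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def fit_ols(X: np.ndarray, y: np.ndarray | OutcomeVector) -> OlsFit:
    """Least squares of y on X plus an intercept, via Householder QR.

    X is the n x k submatrix of selected columns (k may be 0 for the
    intercept-only model).  The design including the intercept is flagged
    rank-deficient when the smallest |diagonal| of the triangular factor
    falls below RANK_RTOL times the largest; coefficients then come from a
    minimum-norm solve and the caller is expected to reject the candidate.
    """
    yv = y.values if isinstance(y, OutcomeVector) else np.asarray(y, np.float64)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if yv.shape[0] != n:
        raise ValidationError(f"outcome length {yv.shape[0]} != rows {n}")
    if n <= k + 1:
        raise ValidationError(
            f"more terms than supportable by n: n={n}, terms={k}"
        )
    A = np.empty((n, k + 1), dtype=np.float64)
    A[:, 0] = 1.0
    A[:, 1:] = X
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    rank_deficient = bool(diag.min() < RANK_RTOL * diag.max())
    if rank_deficient:
        beta = np.linalg.lstsq(A, yv, rcond=None)[0]
    else:
        beta = solve_triangular(R, Q.T @ yv)
    resid = yv - A @ beta
    tss = float(((yv - yv.mean()) ** 2).sum())
    rss = float(resid @ resid)
    if tss == 0.0:
        r2 = 0.0
    else:
        r2 = 1.0 - rss / tss
        if -1e-12 < r2 < 0.0:  # round-off from an essentially perfect null fit
            r2 = 0.0
    return OlsFit(
        intercept=float(beta[0]),
        slopes=beta[1:].copy(),
        residuals=resid,
        r2=r2,
        adjusted_r2=adjusted_r2(r2, n, k),
        rank_deficient=rank_deficient,
    )


def run_selection(
    m: PredictorMatrix,
    y: OutcomeVector,
    config: SelectionConfig | None = None,
    workers: int = 1,
) -> SelectionTrace:
    """Run the full selection: screen, then gate candidates one by one.

    The baseline is the intercept-only model (adjusted R2 = 0, residuals
    y - mean(y)); the first popped candidate passes through exactly the
    same two gates as every later one.  Selection halts early, with a
    warning, if accepting another term would exhaust the error degrees of
    freedom (n - k - 1 >= 1 must survive the addition).
    """
    config = config or SelectionConfig()
    report = validate_pair(m, y)
    report.raise_if_invalid()
    yv = y.values
    n = m.n_samples

    queue = screen(m, y, config.corr_threshold, workers=workers)
    if len(queue) == 0:
        logger.info("empty candidate queue: returning intercept-only model")

    baseline = fit_ols(np.empty((n, 0)), yv)
    accepted: list[int] = []
    current = baseline
    adj = 0.0
    steps: list[SelectionStep] = []

    for j, absr in queue.entries:
        if n - (len(accepted) + 1) - 1 < 1:
            logger.warning(
                "halting selection early: accepting another term would "
                "leave no error degrees of freedom (n=%d, k=%d)",
                n, len(accepted),
            )
            break
        if current.r2 >= 1.0 - 1e-12:
            # perfect fit: residuals are round-off dust, correlations
            # against them are meaningless — treat as zero
            c = 0.0
        else:
            c, _ = _corr_one(m.values[:, j], current.residuals)
            c = abs(c)
        if c <= config.resid_corr_threshold:
            steps.append(SelectionStep(j, m.column_names[j], absr, c,
                                       adj, None, REJECTED_RESID_CORR))
            continue
        fit = fit_ols(m.values[:, accepted + [j]], yv)
        if fit.rank_deficient:
            steps.append(SelectionStep(j, m.column_names[j], absr, c,
                                       adj, fit.adjusted_r2, REJECTED_RANK))
            continue
        gain = fit.adjusted_r2 - adj
        passed = gain > config.delta_r2 if config.strict_gt else gain >= config.delta_r2
        if passed:
            accepted.append(j)
            current = fit
            steps.append(SelectionStep(j, m.column_names[j], absr, c,
                                       adj, fit.adjusted_r2, ACCEPTED))
            adj = fit.adjusted_r2
        else:
            steps.append(SelectionStep(j, m.column_names[j], absr, c,
                                       adj, fit.adjusted_r2, REJECTED_DELTA_R2))

    # final coefficients are the last joint refit over exactly the accepted
    # set, hence identical to a direct OLS on those columns
    model = ModelSpec(
        intercept=current.intercept,
        terms=[(m.column_names[j], float(b))
               for j, b in zip(accepted, current.slopes)],
        adjusted_r2_final=adj,
        provenance=config,
    )
    return SelectionTrace(
        steps=steps,
        final_model=model,
        final_fit=current,
        queue=queue,
        accepted_indices=accepted,
    )
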