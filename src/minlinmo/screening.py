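"""Marginal correlation screening and the descending candidate queue.

Every predictor column is Pearson-correlated with the outcome; the indices
whose absolute correlation exceeds a threshold (0.1 by default) form the
candidate queue, sorted by |r| descending.  Only queue members are ever
considered by the forward-selection loop, which is what makes the method
tractable at p in the hundreds of thousands.

Columns are processed in fixed-size chunks whose boundaries do not depend
on the worker count, and each chunk reduces serially, so the queue is
bit-for-bit reproducible whether screening runs on 1 or 8 threads.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .io import OutcomeVector, PredictorMatrix, ValidationError

__all__ = ["DegenerateDataWarning", "CandidateQueue", "pearson", "screen"]

# columns per screening chunk; fixed so results never depend on `workers`
CHUNK = 8192


class DegenerateDataWarning(UserWarning):
    """A correlation was requested against a zero-variance vector."""


@dataclass
class CandidateQueue:
    """Predictor indices ranked by |Pearson r| with the outcome.

    entries: (column_index, abs_corr) with abs_corr non-increasing and all
    strictly above ``threshold_used``; ties broken by ascending index.
    """

    entries: list[tuple[int, float]]
    threshold_used: float
    n_degenerate: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def indices(self) -> list[int]:
        return [i for i, _ in self.entries]


def _corr_one(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Product-moment correlation plus a zero-variance flag (no warning)."""
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = float(xc @ xc)
    ssy = float(yc @ yc)
    if ssx == 0.0 or ssy == 0.0:
        return 0.0, True
    return float(xc @ yc) / np.sqrt(ssx * ssy), False


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Standard product-moment correlation of two length-n vectors, n >= 3.

    A zero-variance input yields 0.0 with a :class:`DegenerateDataWarning`
    (the undefined case is mapped to "no linear association" so that
    screening can simply never enqueue such a column).
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if x.shape[0] != y.shape[0]:
        raise ValidationError(
            f"length mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 observations for a correlation")
    r, degenerate = _corr_one(x, y)
    if degenerate:
        warnings.warn(
            "zero-variance vector in correlation; returning 0",
            DegenerateDataWarning,
            stacklevel=2,
        )
    return r


def _chunk_corrs(X: np.ndarray, a: int, b: int, yc: np.ndarray, ssy: float,
                 out: np.ndarray, degen: np.ndarray) -> None:
    """Correlations of columns [a, b) with centered outcome, into out[a:b]."""
    block = X[:, a:b]
    bc = block - block.mean(axis=0)
    ssx = np.einsum("ij,ij->j", bc, bc)
    zero = ssx == 0.0
    degen[a:b] = zero
    denom = np.sqrt(ssx * ssy, out=np.empty_like(ssx), where=~zero)
    denom[zero] = 1.0
    r = (bc.T @ yc) / denom
    r[zero] = 0.0
    out[a:b] = r


def screen(
    m: PredictorMatrix,
    y: OutcomeVector | np.ndarray,
    threshold: float = 0.1,
    workers: int = 1,
) -> CandidateQueue:
    """Build the candidate queue: columns with |r| strictly above threshold.

    The queue is sorted by |r| descending, ties broken by ascending column
    index.  Zero-variance columns get r = 0, are never enqueued, and are
    counted in ``n_degenerate``.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")
    yv = y.values if isinstance(y, OutcomeVector) else np.asarray(y, np.float64)
    if yv.shape[0] != m.n_samples:
        raise ValidationError(
            f"outcome length {yv.shape[0]} != matrix rows {m.n_samples}"
        )
    X = m.values
    p = m.n_predictors
    yc = yv - yv.mean()
    ssy = float(yc @ yc)
    corrs = np.empty(p, dtype=np.float64)
    degen = np.zeros(p, dtype=bool)
    if ssy == 0.0:
        # constant outcome: nothing can correlate with it
        corrs[:] = 0.0
        degen[:] = True
    else:
        spans = [(a, min(a + CHUNK, p)) for a in range(0, p, CHUNK)]
        if workers <= 1 or len(spans) == 1:
            for a, b in spans:
                _chunk_corrs(X, a, b, yc, ssy, corrs, degen)
        else:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futures = [
                    pool.submit(_chunk_corrs, X, a, b, yc, ssy, corrs, degen)
                    for a, b in spans
                ]
                for f in futures:
                    f.result()
    absr = np.abs(corrs)
    keep = np.flatnonzero(absr > threshold)
    # sort by |r| descending, ascending index on ties
    order = keep[np.lexsort((keep, -absr[keep]))]
    entries = [(int(j), float(absr[j])) for j in order]
    return CandidateQueue(
        entries=entries,
        threshold_used=float(threshold),
        n_degenerate=int(degen.sum()),
    )
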