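"""Synthetic n << p datasets for nulls, planted signals and decoy blocks.

Three kinds of structure are generated, all seed-reproducible:

* pure-noise nulls — every predictor and the outcome iid N(0, 1), the
  design used to measure how many false positives the selection admits at
  its default thresholds (the reference configuration is 500,000 columns
  by 1,000 rows);
* planted sparse linear signals — a handful of support columns carry known
  effects, everything else is noise, enabling exact parameter-recovery
  checks against the generating truth;
* equicorrelated column blocks — groups of columns sharing a latent factor
  (x = sqrt(rho) z + sqrt(1 - rho) eps, so every column stays marginally
  N(0, 1)), mimicking the heavy redundancy of methylome arrays where many
  CpGs track each other.

Beta-distributed methylation marginals, cell-composition and batch effects
are deliberately not modelled; the generator tests the algorithm's linear
machinery, not array artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import OutcomeVector, PredictorMatrix, ValidationError

__all__ = [
    "SyntheticTruth",
    "generate_null",
    "generate_planted",
    "write_truth",
    "FIXTURE_N",
    "FIXTURE_P",
]

# small preset for routine testing; the full-scale null is 1000 x 500000
FIXTURE_N = 200
FIXTURE_P = 5000


@dataclass
class SyntheticTruth:
    """Ground truth of a planted dataset.

    support: column indices carrying signal; effects: their slopes;
    noise_sd: sd of the additive Gaussian noise on the outcome;
    blocks: optional (member_indices, rho) groups of equicorrelated columns.
    """

    support: list[int]
    effects: np.ndarray
    noise_sd: float = 0.5
    blocks: list[tuple[list[int], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.support = [int(i) for i in self.support]
        self.effects = np.asarray(self.effects, dtype=np.float64).reshape(-1)
        if len(set(self.support)) != len(self.support):
            raise ValidationError("support indices must be unique")
        if self.effects.shape[0] != len(self.support):
            raise ValidationError(
                f"{self.effects.shape[0]} effects for {len(self.support)} support columns"
            )
        if not np.isfinite(self.effects).all():
            raise ValidationError("effects must be finite")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for members, rho in self.blocks:
            if not (0.0 <= rho < 1.0):
                raise ValidationError(f"block rho must be in [0, 1), got {rho}")


def _column_names(p: int) -> list[str]:
    return [f"x{j}" for j in range(p)]


def generate_null(n: int, p: int, seed: int | None = None
                  ) -> tuple[PredictorMatrix, OutcomeVector]:
    """Pure-noise dataset: every entry and the outcome iid N(0, 1).

    At (n=1000, p=500000) this reproduces the false-positive benchmark
    design; any variable the selection picks is by construction spurious.
    """
    if n < 3 or p < 1:
        raise ValidationError(f"need n >= 3 and p >= 1, got n={n}, p={p}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    return PredictorMatrix(X, _column_names(p)), OutcomeVector(y, "y")


def generate_planted(
    n: int,
    p: int,
    truth: SyntheticTruth,
    seed: int | None = None,
) -> tuple[PredictorMatrix, OutcomeVector, SyntheticTruth]:
    """Sparse linear signal in noise: y = X[:, support] @ effects + N(0, sd^2).

    Columns are iid N(0, 1) except block members, which share a latent
    factor at within-block correlation rho while keeping the N(0, 1)
    marginal.  Draw order (matrix, block factors, outcome noise) is fixed,
    so a seed pins the dataset exactly.
    """
    if n < 3 or p < 1:
        raise ValidationError(f"need n >= 3 and p >= 1, got n={n}, p={p}")
    if truth.support and (min(truth.support) < 0 or max(truth.support) >= p):
        raise ValidationError("support indices out of range")
    if len(truth.support) >= n - 1:
        raise ValidationError("support larger than n - 1 is not identifiable")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    for members, rho in truth.blocks:
        if members and (min(members) < 0 or max(members) >= p):
            raise ValidationError("block member index out of range")
        z = rng.standard_normal(n)
        X[:, members] = (
            np.sqrt(rho) * z[:, None]
            + np.sqrt(1.0 - rho) * rng.standard_normal((n, len(members)))
        )
    y = X[:, truth.support] @ truth.effects if truth.support else np.zeros(n)
    y = y + truth.noise_sd * rng.standard_normal(n)
    return (
        PredictorMatrix(X, _column_names(p)),
        OutcomeVector(y, "y"),
        truth,
    )


def write_truth(truth: SyntheticTruth, path: str) -> None:
    """Sidecar CSV of the planted truth: one row per support column."""
    import csv

    block_of: dict[int, tuple[int, float]] = {}
    for bi, (members, rho) in enumerate(truth.blocks):
        for j in members:
            block_of[j] = (bi, rho)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["column_index", "column_name", "effect", "noise_sd",
                    "block", "block_rho"])
        for j, b in zip(truth.support, truth.effects):
            blk = block_of.get(j)
            w.writerow([j, f"x{j}", repr(float(b)), repr(truth.noise_sd),
                        "" if blk is None else blk[0],
                        "" if blk is None else blk[1]])
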