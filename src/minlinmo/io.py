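"""CSV input/output contract: design matrices, outcome vectors and fitted models.

The on-disk contract is deliberately strict: comma-separated, a header row,
no row names, no missing values, every cell a finite real.  Categorical
variables must be recoded as 0/1 indicators before loading.  Error messages
report 1-based row/column positions as they appear in the file (the header
is row 1).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "PredictorMatrix",
    "OutcomeVector",
    "ModelSpec",
    "ValidationReport",
    "read_design_matrix",
    "read_outcome",
    "write_design_matrix",
    "write_outcome",
    "validate_pair",
    "write_model",
    "read_model",
    "predict",
]

INTERCEPT_LABEL = "(Intercept)"


class FormatError(ValueError):
    """A file does not follow the expected CSV layout."""


class ValidationError(ValueError):
    """Data violate the input contract (missing values, shape mismatch...)."""


@dataclass
class PredictorMatrix:
    """An n_samples x n_predictors numeric design matrix with column names.

    Structural invariants (2-D values, matching and unique column names) are
    enforced at construction; value-level invariants (finiteness, n >= 3)
    are checked by :func:`validate_pair` so that a report can enumerate
    every violation instead of failing on the first.
    """

    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("predictor matrix must be 2-dimensional")
        self.column_names = [str(c) for c in self.column_names]
        if len(self.column_names) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.column_names)} column names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.column_names)) != len(self.column_names):
            dupes = sorted({c for c in self.column_names if self.column_names.count(c) > 1})
            raise ValidationError(f"duplicate column names: {', '.join(dupes)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]


@dataclass
class OutcomeVector:
    """A length-n outcome with a label, in the outcome's own units."""

    values: np.ndarray
    name: str = "y"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class ModelSpec:
    """A fitted linear model: intercept plus named slopes in acceptance order."""

    intercept: float
    terms: list[tuple[str, float]]
    adjusted_r2_final: float | None = None
    provenance: Any = None

    def __post_init__(self) -> None:
        names = [t[0] for t in self.terms]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate term names in model")
        for name, slope in self.terms:
            if not math.isfinite(slope):
                raise ValidationError(f"non-finite slope for term {name!r}")
        if not math.isfinite(self.intercept):
            raise ValidationError("non-finite intercept")

    @property
    def term_names(self) -> list[str]:
        return [t[0] for t in self.terms]

    @property
    def slopes(self) -> np.ndarray:
        return np.array([t[1] for t in self.terms], dtype=np.float64)


@dataclass
class ValidationReport:
    """Outcome of validate_pair: every violation found, not just the first."""

    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def raise_if_invalid(self) -> None:
        if self.problems:
            raise ValidationError("; ".join(self.problems))


def _check_rectangular(path: str, expect_cols: int | None = None) -> int:
    """Stream the file once to verify all rows have the header's field count.

    Returns the header field count.  Raises FormatError on ragged rows,
    naming the 1-based row.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: file is empty") from None
        width = len(header)
        if expect_cols is not None and width != expect_cols:
            raise FormatError(
                f"{path}: expected {expect_cols} column(s), found {width}"
            )
        for i, row in enumerate(reader, start=2):
            if len(row) != width:
                raise FormatError(
                    f"{path}: row {i} has {len(row)} fields, "
                    f"header has {width} (ragged row)"
                )
    return width


def _first_bad_cell(df: pd.DataFrame) -> tuple[int, int, object] | None:
    """Locate the first cell that is missing or not a finite number.

    Returns (0-based data row, 0-based column, original value) or None.
    """
    for j, col in enumerate(df.columns):
        s = df[col]
        if s.dtype == object:
            for i, v in enumerate(s):
                try:
                    x = float(v)
                except (TypeError, ValueError):
                    return i, j, v
                if not math.isfinite(x):
                    return i, j, v
        else:
            arr = s.to_numpy(dtype=np.float64, copy=False)
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                return int(bad[0]), j, s.iloc[int(bad[0])]
    return None


def read_design_matrix(path: str) -> PredictorMatrix:
    """Read a comma-separated predictor matrix (header row, no row names).

    Every cell must parse as a finite real.  A non-numeric first column
    triggers a hint to drop row names; other non-numeric cells suggest 0/1
    indicator recoding of categorical variables.
    """
    _check_rectangular(path)
    try:
        df = pd.read_csv(path, header=0, skip_blank_lines=False)
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: {e}") from None
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no columns found")
    bad = _first_bad_cell(df)
    if bad is not None:
        i, j, v = bad
        pos = f"row {i + 2}, column {j + 1} ({df.columns[j]!r})"
        if v is None or (isinstance(v, float) and math.isnan(v)) or (
            isinstance(v, str) and v.strip() in ("", "NA", "NaN", "nan", "N/A")
        ):
            raise ValidationError(
                f"{path}: missing value at {pos}; there can be no missing values"
            )
        if j == 0:
            raise FormatError(
                f"{path}: non-numeric cell {v!r} at {pos}; if the first column "
                "holds row names, remove it (row names are not permitted)"
            )
        raise FormatError(
            f"{path}: non-numeric cell {v!r} at {pos}; categorical variables "
            "must be converted to 0/1 indicators"
        )
    values = df.to_numpy(dtype=np.float64)
    return PredictorMatrix(values, [str(c) for c in df.columns])


def read_outcome(path: str) -> OutcomeVector:
    """Read a single-column comma-separated outcome file with a header."""
    width = _check_rectangular(path)
    if width != 1:
        raise FormatError(
            f"{path}: outcome file must have exactly one column, found {width}"
        )
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))[0]
    try:
        float(header)
    except ValueError:
        pass
    else:
        raise FormatError(
            f"{path}: header {header!r} parses as a number; column names are "
            "required, also for the outcome file"
        )
    df = pd.read_csv(path, header=0, skip_blank_lines=False)
    bad = _first_bad_cell(df)
    if bad is not None:
        i, _, v = bad
        raise ValidationError(
            f"{path}: missing or non-numeric value {v!r} at row {i + 2}; "
            "there can be no missing values"
        )
    return OutcomeVector(df.iloc[:, 0].to_numpy(dtype=np.float64), str(df.columns[0]))


def write_design_matrix(m: PredictorMatrix, path: str) -> None:
    pd.DataFrame(m.values, columns=m.column_names).to_csv(path, index=False)


def write_outcome(y: OutcomeVector, path: str) -> None:
    pd.DataFrame({y.name: y.values}).to_csv(path, index=False)


def validate_pair(m: PredictorMatrix, y: OutcomeVector) -> ValidationReport:
    """Check a matrix/outcome pair against the input contract.

    All violations are collected in the report; nothing is raised here.
    """
    report = ValidationReport()
    if m.n_samples != len(y):
        report.problems.append(
            f"length mismatch: matrix has {m.n_samples} rows, "
            f"outcome has {len(y)} values"
        )
    if m.n_samples < 3:
        report.problems.append(f"need at least 3 samples, got {m.n_samples}")
    if not np.isfinite(m.values).all():
        n_bad = int((~np.isfinite(m.values)).sum())
        report.problems.append(
            f"predictor matrix contains {n_bad} missing/non-finite value(s)"
        )
    if not np.isfinite(y.values).all():
        n_bad = int((~np.isfinite(y.values)).sum())
        report.problems.append(
            f"outcome contains {n_bad} missing/non-finite value(s)"
        )
    return report


def write_model(model: ModelSpec, path: str) -> None:
    """Serialize a model as two-column CSV ``term,estimate``.

    The first data row is the intercept under the reserved name
    ``(Intercept)``; the remaining rows follow acceptance order.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "estimate"])
        writer.writerow([INTERCEPT_LABEL, repr(model.intercept)])
        for name, slope in model.terms:
            writer.writerow([name, repr(slope)])


def read_model(path: str) -> ModelSpec:
    """Read a model file written by :func:`write_model` (full precision)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty model file") from None
        if header != ["term", "estimate"]:
            raise FormatError(
                f"{path}: expected header 'term,estimate', got {','.join(header)!r}"
            )
        rows = [r for r in reader if r]
    if not rows or rows[0][0] != INTERCEPT_LABEL:
        raise FormatError(
            f"{path}: first data row must be the {INTERCEPT_LABEL} term"
        )
    terms: list[tuple[str, float]] = []
    for i, row in enumerate(rows, start=2):
        if len(row) != 2:
            raise FormatError(f"{path}: row {i} does not have 2 fields")
        name, est = row
        try:
            value = float(est)
        except ValueError:
            raise FormatError(
                f"{path}: malformed estimate {est!r} at row {i}"
            ) from None
        if not math.isfinite(value):
            raise FormatError(f"{path}: non-finite estimate at row {i}")
        terms.append((name, value))
    intercept = terms[0][1]
    slopes = terms[1:]
    names = [t[0] for t in slopes]
    if INTERCEPT_LABEL in names:
        raise FormatError(f"{path}: duplicate {INTERCEPT_LABEL} row")
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate term name in model file")
    return ModelSpec(intercept=intercept, terms=slopes)


def predict(model: ModelSpec, m: PredictorMatrix) -> OutcomeVector:
    """Apply a fitted model to new data, matching terms by column NAME.

    The join is name-based, so the prediction is invariant to any column
    permutation of ``m``.  Terms absent from ``m`` raise an error listing
    every missing name (partial predictions would be silently wrong).
    """
    missing = [name for name in model.term_names if name not in m.column_names]
    if missing:
        raise ValidationError(
            "model terms absent from the matrix: " + ", ".join(missing)
        )
    yhat = np.full(m.n_samples, model.intercept, dtype=np.float64)
    if model.terms:
        cols = [m.column_names.index(name) for name in model.term_names]
        yhat += m.values[:, cols] @ model.slopes
    return OutcomeVector(yhat, name="predicted")
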