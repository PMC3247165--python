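"""Array containers for the predictive factorization model.

The model couples five matrices: a sample-by-channel design matrix ``X``
(absorbance-like measurements), a ``{-1, +1}`` class membership matrix
``Y``, a per-class threshold vector ``b``, the class signal matrix ``S``
(one inferred source signal per class) and the mixing coefficient matrix
``A`` with ``X = A S``.  The containers below validate shapes and
finiteness once at construction so the numerical routines can operate on
bare arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SpectraMatrix",
    "ClassMatrix",
    "ThresholdVector",
    "SignalMatrix",
    "CoefficientMatrix",
    "MarginMatrix",
    "TargetMatrix",
    "LossValue",
    "FactorModel",
    "as_matrix",
    "as_vector",
]


def as_matrix(x: Any, name: str = "matrix") -> np.ndarray:
    """Coerce a container or array-like to a finite 2-D float array."""
    values = np.asarray(getattr(x, "values", x), dtype=float)
    if values.ndim == 1:
        values = values[np.newaxis, :]
    if values.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got ndim={values.ndim}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite entries")
    return values


def as_vector(x: Any, name: str = "vector") -> np.ndarray:
    """Coerce a container or array-like to a finite 1-D float array."""
    values = np.asarray(getattr(x, "values", getattr(x, "b", x)), dtype=float)
    values = np.atleast_1d(values.squeeze())
    if values.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite entries")
    return values


@dataclass
class SpectraMatrix:
    """n x d design matrix of spectra, one row per sample.

    ``wavenumbers`` (1/cm), when present, must be strictly monotone and
    match the number of channels; synthetic data uses an abstract grid on
    [0, 1] instead and leaves it unset.
    """

    values: np.ndarray
    sample_ids: list[str] | None = None
    wavenumbers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = as_matrix(self.values, "spectra")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("spectra matrix must be at least 1x1")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match number of rows")
        if self.wavenumbers is not None:
            self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
            if self.wavenumbers.shape != (d,):
                raise ValueError("wavenumbers length must equal number of channels")
            diffs = np.diff(self.wavenumbers)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError("wavenumbers must be strictly monotone")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class ClassMatrix:
    """n x k class membership matrix over {-1, +1}.

    For training data every row carries exactly one ``+1`` (single-label);
    predicted matrices may violate that, so the constraint is opt-in via
    ``require_single_label``.
    """

    values: np.ndarray
    class_names: list[str]
    require_single_label: bool = False

    def __post_init__(self) -> None:
        self.values = as_matrix(self.values, "class matrix")
        self.class_names = list(self.class_names)
        k = self.values.shape[1]
        if k < 1 or len(self.class_names) != k:
            raise ValueError("class_names must match the number of columns")
        if not np.all(np.isin(self.values, (-1.0, 1.0))):
            raise ValueError("class matrix entries must be -1 or +1")
        if self.require_single_label and not np.all((self.values > 0).sum(axis=1) == 1):
            raise ValueError("each training row must have exactly one +1")

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def labels(self) -> list[str]:
        """Recover one label per row (requires single-label rows)."""
        idx = np.argmax(self.values, axis=1)
        if not np.all((self.values > 0).sum(axis=1) == 1):
            raise ValueError("labels() requires exactly one +1 per row")
        return [self.class_names[j] for j in idx]


@dataclass
class ThresholdVector:
    """Per-class decision thresholds b; class j is predicted when a_ij >= b_j."""

    b: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.b = as_vector(self.b, "threshold vector")
        if self.class_names is not None and len(self.class_names) != self.b.size:
            raise ValueError("class_names must match threshold length")

    def __len__(self) -> int:
        return self.b.size


@dataclass
class SignalMatrix:
    """k x d matrix of inferred class signals, one row per class."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = as_matrix(self.values, "signal matrix")

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]


@dataclass
class CoefficientMatrix:
    """n x k mixing coefficients; entry (i, j) is the share of signal j in sample i."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = as_matrix(self.values, "coefficient matrix")


@dataclass
class MarginMatrix:
    """n x k signum arguments V = A - 1 b^T of the linear threshold rule."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = as_matrix(self.values, "margin matrix")

    @classmethod
    def from_coefficients(cls, A: Any, b: Any) -> "MarginMatrix":
        A = as_matrix(A, "coefficient matrix")
        b = as_vector(b, "threshold vector")
        if A.shape[1] != b.size:
            raise ValueError("coefficient columns must match threshold length")
        return cls(A - b[np.newaxis, :])


@dataclass
class TargetMatrix:
    """n x k regression target W = Y + 1 b^T of the closed-form solution."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = as_matrix(self.values, "target matrix")

    @classmethod
    def from_classes(cls, Y: Any, b: Any) -> "TargetMatrix":
        Y = as_matrix(Y, "class matrix")
        b = as_vector(b, "threshold vector")
        if Y.shape[1] != b.size:
            raise ValueError("class columns must match threshold length")
        return cls(Y + b[np.newaxis, :])


@dataclass(frozen=True)
class LossValue:
    """Joint loss L = F^2 + B with the Brier weight kappa = 1/(n k)."""

    frobenius: float
    brier: float
    kappa: float
    combined: float

    def __post_init__(self) -> None:
        if self.frobenius < 0 or self.brier < 0:
            raise ValueError("loss components must be non-negative")
        if not np.isclose(self.combined, self.frobenius**2 + self.brier):
            raise ValueError("combined loss must equal frobenius**2 + brier")


@dataclass
class FactorModel:
    """Trained model: thresholds plus the signal matrix derived from them.

    The entire predictive state is the k-vector ``b``; ``S`` is recomputed
    from the training data through the closed form and cached here so that
    prediction on new spectra needs only ``A* = X* S^+``.
    """

    thresholds: ThresholdVector
    signals: SignalMatrix
    class_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signals.n_classes != len(self.thresholds):
            raise ValueError("signal rows must match threshold length")
        if len(self.class_names) != len(self.thresholds):
            raise ValueError("class_names must match threshold length")

    @property
    def b(self) -> np.ndarray:
        return self.thresholds.b

    @property
    def S(self) -> np.ndarray:
        return self.signals.values
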