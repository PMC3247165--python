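"""Closed-form predictive factorization and its two loss functions.

Given spectra ``X`` (n x d), class memberships ``Y`` (n x k, entries in
{-1, +1}) and a threshold vector ``b`` (k), the model seeks ``X = A S``
with the linear decision rule ``y_ij = sign(a_ij - b_j)``.  Minimizing
the joint loss

    L(S, b) = ||X - X S^+ S||_F^2  +  kappa * ||Y o (X S^+ - 1 b^T) - 1||_F^2

with kappa = 1/(n k) admits the closed form

    S = (Y + 1 b^T)^+ X,

which reduces training to a k-dimensional search over ``b`` (module
:mod:`brierscoremf.train`).  Prediction for new spectra is
``A* = X* S^+`` thresholded against ``b``.
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np

from .types import ClassMatrix, LossValue, SignalMatrix, as_matrix, as_vector

__all__ = [
    "build_class_matrix",
    "pseudoinverse",
    "frobenius_loss",
    "brier_score_loss",
    "combined_loss",
    "closed_form_signals",
    "estimate_coefficients",
    "predict_classes",
]


def build_class_matrix(labels: Sequence[str], class_names: Sequence[str]) -> ClassMatrix:
    """Encode per-sample labels as an n x k matrix over {-1, +1}.

    Entry (i, j) is +1 iff ``labels[i] == class_names[j]`` and -1
    otherwise, so every row carries exactly one +1.
    """
    class_names = list(class_names)
    if not class_names:
        raise ValueError("class_names must not be empty")
    index = {c: j for j, c in enumerate(class_names)}
    if len(index) != len(class_names):
        raise ValueError("class_names must be unique")
    n, k = len(labels), len(class_names)
    values = -np.ones((n, k))
    for i, label in enumerate(labels):
        if label not in index:
            raise ValueError(f"unknown label {label!r}: not in class registry")
        values[i, index[label]] = 1.0
    return ClassMatrix(values, class_names, require_single_label=True)


def pseudoinverse(M: Any, tol: float | None = None) -> np.ndarray:
    """Moore-Penrose pseudoinverse of a real matrix.

    Singular values below ``tol * sigma_max`` are treated as zero; the
    default cutoff is ``max(p, q) * eps``.  The result satisfies the four
    defining identities M M+ M = M, M+ M M+ = M+, (M M+)^T = M M+,
    (M+ M)^T = M+ M to numerical accuracy for every shape and rank.
    """
    M = as_matrix(M, "matrix")
    if tol is None:
        return np.linalg.pinv(M)
    return np.linalg.pinv(M, rtol=tol)


def frobenius_loss(X: Any, A: Any, S: Any) -> float:
    """Reconstruction divergence F = ||X - A S||_F."""
    X = as_matrix(X, "spectra")
    A = as_matrix(A, "coefficient matrix")
    S = as_matrix(S, "signal matrix")
    if A.shape[0] != X.shape[0] or A.shape[1] != S.shape[0] or S.shape[1] != X.shape[1]:
        raise ValueError(
            f"shape mismatch: X {X.shape}, A {A.shape}, S {S.shape} do not conform"
        )
    return float(np.linalg.norm(X - A @ S))


def brier_score_loss(Y: Any, V: Any) -> float:
    """Matrix Brier score B(Y, V) = kappa * tr[(Y o V - 1)^T (Y o V - 1)].

    With kappa = 1/(n k) this is the mean over all cells of
    ``(y_ij * v_ij - 1)^2``, the squared-error classification loss for
    labels in {-1, +1} evaluated at margins ``v_ij = a_ij - b_j``.
    """
    Y = as_matrix(Y, "class matrix")
    V = as_matrix(V, "margin matrix")
    if Y.shape != V.shape:
        raise ValueError(f"shape mismatch: Y {Y.shape} vs V {V.shape}")
    resid = Y * V - 1.0
    return float(np.mean(resid * resid))


def combined_loss(X: Any, Y: Any, S: Any, b: Any) -> LossValue:
    """Joint loss L = F(X, X S^+ S)^2 + B(Y, X S^+ - 1 b^T).

    The coefficient matrix is substituted by its least-squares value
    ``A = X S^+`` so the loss depends on ``S`` and ``b`` alone.
    """
    X = as_matrix(X, "spectra")
    Y = as_matrix(Y, "class matrix")
    S = as_matrix(S, "signal matrix")
    b = as_vector(b, "threshold vector")
    n, d = X.shape
    k = Y.shape[1]
    if Y.shape[0] != n or S.shape != (k, d) or b.size != k:
        raise ValueError("shapes of X, Y, S, b do not conform")
    S_pinv = np.linalg.pinv(S)
    A = X @ S_pinv
    frob = float(np.linalg.norm(X - A @ S))
    brier = brier_score_loss(Y, A - b[np.newaxis, :])
    return LossValue(
        frobenius=frob,
        brier=brier,
        kappa=1.0 / (n * k),
        combined=frob**2 + brier,
    )


def closed_form_signals(X: Any, Y: Any, b: Any, tol: float | None = None) -> SignalMatrix:
    """Closed-form signal matrix S = (Y + 1 b^T)^+ X.

    This is the stationary point of the joint loss: setting the matrix
    differential to zero forces ``X S^+ = Y + 1 b^T = W`` and hence
    ``S = W^+ X``.  Rank-deficient ``W`` is handled by the pseudoinverse,
    which returns the minimum-norm least-squares solution.
    """
    X = as_matrix(X, "spectra")
    Y = as_matrix(Y, "class matrix")
    b = as_vector(b, "threshold vector")
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if b.size != Y.shape[1]:
        raise ValueError("threshold length must match class count")
    W = Y + b[np.newaxis, :]
    return SignalMatrix(pseudoinverse(W, tol) @ X)


def estimate_coefficients(Xstar: Any, S: Any, tol: float | None = None) -> np.ndarray:
    """Mixing coefficients A = X* S^+ for (possibly unseen) spectra.

    For consistent training data ``X = A0 S`` with ``S`` of full row
    rank this recovers ``A0`` exactly.
    """
    Xstar = as_matrix(Xstar, "spectra")
    S = as_matrix(S, "signal matrix")
    if Xstar.shape[1] != S.shape[1]:
        raise ValueError(
            f"channel mismatch: spectra have {Xstar.shape[1]} columns, signals {S.shape[1]}"
        )
    return Xstar @ pseudoinverse(S, tol)


def predict_classes(A: Any, b: Any) -> np.ndarray:
    """Threshold rule y_ij = sign(a_ij - b_j), ties (a_ij == b_j) map to +1.

    Returns an n x k array over {-1, +1}.  Rows may contain zero or
    several +1 entries: the rule is natively multi-label and downstream
    evaluation scores each class one-vs-rest.
    """
    A = as_matrix(A, "coefficient matrix")
    b = as_vector(b, "threshold vector")
    if A.shape[1] != b.size:
        raise ValueError("coefficient columns must match threshold length")
    return np.where(A >= b[np.newaxis, :], 1.0, -1.0)
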