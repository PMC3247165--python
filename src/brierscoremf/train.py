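"""Threshold training: the cross-validated objective O(b) and BFGS search.

Because the signal matrix has the closed form ``S = (Y + 1 b^T)^+ X``,
the only free parameter of the model is the threshold vector ``b``.  It
is chosen to maximize

    O(b) = (1 / r) * prod_i s_i * t_i

where ``s_i`` and ``t_i`` are per-class sensitivity and specificity
estimated by an inner stratified cross-validation (counts pooled over
folds) and ``r`` is the pooled held-out reconstruction error.  The
product couples classification quality across all classes while ``1/r``
rewards factorizations that generalize as signal models.  O is maximized
with BFGS over central-difference gradients.  Because O is zero wherever
any class is never recovered — and its gradient is zero there too — the
search refines every start by a self-consistent threshold iteration,
restarts from uniform and log-uniform draws on zero plateaus, and as a
last resort climbs a floored geometric mean of the per-class s_i * t_i,
which preserves the product's balance but stays informative on the
plateau (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Callable

import numpy as np
from scipy.optimize import minimize

from .core import closed_form_signals
from .types import FactorModel, SignalMatrix, ThresholdVector, as_matrix, as_vector

__all__ = [
    "TrainerConfig",
    "stratified_fold_assignment",
    "objective",
    "numerical_gradient",
    "fit",
]


@dataclass(frozen=True)
class TrainerConfig:
    """Knobs of the threshold search.

    inner_folds
        Folds of the inner cross-validation inside O(b) (default 5,
        mirroring the outer evaluation protocol).
    bfgs_max_iter
        Iteration cap per BFGS run; the objective is cheap but each
        gradient costs 2k evaluations.
    gradient_step
        Central-difference step h.  The classification part of O is
        piecewise constant in b, so h must be large enough to see counts
        change; 1e-2 on the natural (0, 1) threshold scale works well.
    b_init
        Optional explicit starting point; by default drawn uniformly
        from (0, 1)^k with ``rng_seed``.
    rng_seed
        Seeds fold assignment and starting points; fixing it makes
        training bit-reproducible.
    r_floor
        Lower clamp for the pooled reconstruction error before the
        division in O(b); on exactly factorizable data r underflows to
        rounding noise and the clamp keeps 1/r stable.
    max_restarts
        Fresh uniform restarts allowed when the search is stuck on an
        O = 0 plateau (zero gradient everywhere).
    pooling
        "micro": pool confusion counts over folds before computing
        s_i, t_i (default; robust for small classes).  "macro": average
        per-fold rates, skipping folds where a rate is undefined.
    """

    inner_folds: int = 5
    bfgs_max_iter: int = 15
    gradient_step: float = 1e-2
    b_init: Any = None
    rng_seed: int = 0
    r_floor: float = 1e-6
    max_restarts: int = 3
    pooling: str = "micro"

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.gradient_step <= 0:
            raise ValueError("gradient_step must be positive")
        if self.r_floor <= 0:
            raise ValueError("r_floor must be positive")
        if self.pooling not in ("micro", "macro"):
            raise ValueError("pooling must be 'micro' or 'macro'")


def stratified_fold_assignment(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign samples to folds, spreading every class as evenly as possible.

    Classes with fewer members than folds are placed in a subset of the
    folds (never dropped); globally the fold sizes stay balanced.  The
    assignment is a deterministic function of the generator state.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("need at least two folds")
    if n_folds > labels.size:
        raise ValueError("more folds than samples")
    fold = np.empty(labels.size, dtype=np.intp)
    counts = np.zeros(n_folds, dtype=np.intp)
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for i in idx:
            f = int(np.argmin(counts))  # least-filled fold, lowest index on ties
            fold[i] = f
            counts[f] += 1
    return fold


def _pool_objective(s: np.ndarray, t: np.ndarray, r: float, r_floor: float) -> float:
    """O = prod_i(s_i * t_i) / max(r, r_floor); undefined rates are skipped."""
    terms = s * t
    terms = terms[~np.isnan(terms)]
    if terms.size == 0:
        return 0.0
    prod = float(np.prod(terms))
    if prod == 0.0:
        return 0.0
    return prod / max(float(r), r_floor)


def _cv_rates(
    b: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    fold_ids: np.ndarray,
    pooling: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cross-validated (s_i, t_i, r) at threshold b with fixed folds."""
    k = Y.shape[1]
    n_folds = int(fold_ids.max()) + 1
    tp = np.zeros(k)
    fn = np.zeros(k)
    tn = np.zeros(k)
    fp = np.zeros(k)
    macro_s = []
    macro_t = []
    r_total = 0.0
    for f in range(n_folds):
        test = fold_ids == f
        train = ~test
        W = Y[train] + b[np.newaxis, :]
        S = np.linalg.pinv(W) @ X[train]
        S_pinv = np.linalg.pinv(S)
        A_test = X[test] @ S_pinv
        pred_pos = A_test >= b[np.newaxis, :]
        true_pos = Y[test] > 0
        f_tp = (pred_pos & true_pos).sum(axis=0)
        f_fn = (~pred_pos & true_pos).sum(axis=0)
        f_tn = (~pred_pos & ~true_pos).sum(axis=0)
        f_fp = (pred_pos & ~true_pos).sum(axis=0)
        tp += f_tp
        fn += f_fn
        tn += f_tn
        fp += f_fp
        if pooling == "macro":
            with np.errstate(invalid="ignore"):
                macro_s.append(f_tp / (f_tp + f_fn))
                macro_t.append(f_tn / (f_tn + f_fp))
        r_total += float(np.linalg.norm(X[test] - A_test @ S))
    if pooling == "macro":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            s = np.nanmean(np.vstack(macro_s), axis=0)
            t = np.nanmean(np.vstack(macro_t), axis=0)
    else:
        with np.errstate(invalid="ignore"):
            s = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
            t = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), np.nan)
    return s, t, r_total


def objective(
    b: Any,
    X: Any,
    Y: Any,
    cfg: TrainerConfig | None = None,
    fold_ids: np.ndarray | None = None,
) -> float:
    """Evaluate the cross-validated objective O(b).

    When ``fold_ids`` is not supplied, a stratified assignment is drawn
    from ``cfg.rng_seed`` — so repeated calls with the same inputs are
    identical.  During :func:`fit` the assignment is computed once and
    reused for every evaluation, keeping O a fixed function of b.
    """
    cfg = cfg or TrainerConfig()
    b = as_vector(b, "threshold vector")
    X = as_matrix(X, "spectra")
    Y = as_matrix(Y, "class matrix")
    if Y.shape[0] != X.shape[0] or Y.shape[1] != b.size:
        raise ValueError("shapes of b, X, Y do not conform")
    # A class without any member (possible in outer-CV training subsets of
    # heavily subsampled many-class data) has undefined sensitivity; it is
    # skipped in the product rather than raising, so the factorial design
    # with k approaching n/2 remains runnable.
    if fold_ids is None:
        labels = np.argmax(Y, axis=1)
        rng = np.random.default_rng(cfg.rng_seed)
        fold_ids = stratified_fold_assignment(labels, cfg.inner_folds, rng)
    s, t, r = _cv_rates(b, X, Y, fold_ids, cfg.pooling)
    return _pool_objective(s, t, r, cfg.r_floor)


def self_consistent_thresholds(
    X: np.ndarray, Y: np.ndarray, b0: np.ndarray, iters: int = 4
) -> np.ndarray:
    """Refine a threshold vector against the model's own coefficients.

    Alternates computing ``A = X S(b)^+`` with resetting each ``b_j`` to
    the midpoint between the smallest member and the largest non-member
    coefficient of class j.  If the factorization separates a class at
    all, the midpoint is a separating threshold, which places the start
    of the BFGS search inside the (often narrow) region where the
    product objective is non-zero.
    """
    b = np.array(b0, dtype=float, copy=True)
    k = Y.shape[1]
    for _ in range(iters):
        W = Y + b[np.newaxis, :]
        S = np.linalg.pinv(W) @ X
        A = X @ np.linalg.pinv(S)
        for j in range(k):
            pos = A[Y[:, j] > 0, j]
            neg = A[Y[:, j] < 0, j]
            if pos.size and neg.size:
                b[j] = 0.5 * (pos.min() + neg.max())
            elif pos.size:
                b[j] = float(pos.min())
    return b


def numerical_gradient(
    f: Callable[[np.ndarray], float], b: Any, h: float
) -> np.ndarray:
    """Central-difference gradient (f(b + h e_j) - f(b - h e_j)) / 2h."""
    b = as_vector(b, "point")
    if h <= 0:
        raise ValueError("step h must be positive")
    grad = np.empty(b.size)
    for j in range(b.size):
        e = np.zeros(b.size)
        e[j] = h
        hi = float(f(b + e))
        lo = float(f(b - e))
        if not (np.isfinite(hi) and np.isfinite(lo)):
            raise ValueError(f"objective is non-finite near coordinate {j}")
        grad[j] = (hi - lo) / (2.0 * h)
    return grad


def fit(X: Any, Y: Any, cfg: TrainerConfig | None = None) -> FactorModel:
    """Train a factor model by maximizing O(b) with BFGS.

    BFGS minimizes ``-O`` from a uniform random start; the best threshold
    vector seen across all evaluations (including gradient probes) is
    kept, so the returned model never scores below its starting point.
    If the search never leaves the O = 0 plateau it restarts from a
    fresh uniform point up to ``cfg.max_restarts`` times.  The final
    signal matrix is recomputed from all training data at the optimal b.
    """
    cfg = cfg or TrainerConfig()
    X = as_matrix(X, "spectra")
    Yc = Y  # keep the container for class names if present
    Y = as_matrix(Y, "class matrix")
    n, k = Y.shape
    class_names = list(getattr(Yc, "class_names", [f"c{j + 1}" for j in range(k)]))

    rng = np.random.default_rng(cfg.rng_seed)
    labels = np.argmax(Y, axis=1)
    fold_ids = stratified_fold_assignment(labels, cfg.inner_folds, rng)

    # best iterate: primary key O, tie-broken on the O = 0 plateau by the
    # mean per-class s_i * t_i so a stuck search still returns the most
    # discriminative threshold it visited
    best: dict[str, Any] = {"b": None, "O": -np.inf, "soft": -np.inf}

    def _scores(b: np.ndarray) -> tuple[float, float]:
        s, t, r = _cv_rates(b, X, Y, fold_ids, cfg.pooling)
        val = _pool_objective(s, t, r, cfg.r_floor)
        terms = (s * t)[~np.isnan(s * t)]
        # floored geometric mean: keeps the product's balance across
        # classes but stays informative when single terms hit zero
        soft = float(np.exp(np.mean(np.log(np.maximum(terms, 1e-4))))) if terms.size else 0.0
        if (val, soft) > (best["O"], best["soft"]):
            best["O"] = val
            best["soft"] = soft
            best["b"] = np.array(b, dtype=float, copy=True)
        return val, soft

    def O_tracked(b: np.ndarray) -> float:
        return _scores(b)[0]

    def neg_O(b: np.ndarray) -> float:
        return -O_tracked(b)

    def neg_grad(b: np.ndarray) -> np.ndarray:
        return numerical_gradient(neg_O, b, cfg.gradient_step)

    converged = False
    n_starts = 0
    for attempt in range(cfg.max_restarts + 1):
        if attempt == 0 and cfg.b_init is not None:
            b0 = as_vector(cfg.b_init, "b_init")
            if b0.size != k:
                raise ValueError("b_init length must equal the number of classes")
        elif attempt % 2 == 0:
            b0 = rng.uniform(size=k)
        else:
            # log-uniform draw: the non-zero region of O can be narrow in
            # coordinates whose true threshold is small
            b0 = np.exp(rng.uniform(np.log(1e-3), 0.0, size=k))
        n_starts += 1
        O_plain = O_tracked(b0)
        # refine the start against the model's own coefficient geometry
        b0_sc = self_consistent_thresholds(X, Y, b0)
        O_sc = O_tracked(b0_sc)
        start = b0_sc if O_sc >= O_plain else b0
        res = minimize(
            neg_O,
            start,
            jac=neg_grad,
            method="BFGS",
            options={"maxiter": cfg.bfgs_max_iter},
        )
        converged = converged or bool(res.success)
        if best["O"] > 0.0:
            break

    if best["O"] == 0.0:
        # the product objective is flat at zero here (some class is never
        # recovered); fall back to the smooth surrogate — the mean of the
        # per-class s_i * t_i — which still carries gradient information
        def neg_soft(b: np.ndarray) -> float:
            return -_scores(b)[1]

        minimize(
            neg_soft,
            best["b"],
            jac=lambda b: numerical_gradient(neg_soft, b, cfg.gradient_step),
            method="BFGS",
            options={"maxiter": cfg.bfgs_max_iter},
        )

    b_final = best["b"]
    S = closed_form_signals(X, Y, b_final)
    meta = {
        "objective": float(best["O"]),
        "converged": converged,
        "n_starts": n_starts,
        "rng_seed": cfg.rng_seed,
        "config": {
            "inner_folds": cfg.inner_folds,
            "bfgs_max_iter": cfg.bfgs_max_iter,
            "gradient_step": cfg.gradient_step,
            "r_floor": cfg.r_floor,
            "max_restarts": cfg.max_restarts,
            "pooling": cfg.pooling,
        },
    }
    if not converged:
        meta["warning"] = "BFGS did not report convergence; best iterate returned"
    return FactorModel(
        thresholds=ThresholdVector(b_final, class_names),
        signals=S if isinstance(S, SignalMatrix) else SignalMatrix(S),
        class_names=class_names,
        meta=meta,
    )
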