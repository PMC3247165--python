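"""Outer cross-validation, per-class metrics and the benchmark driver.

Every class is scored one-vs-rest from the {-1, +1} membership matrices:
sensitivity ``s_i = TP/(TP+FN)``, specificity ``t_i = TN/(TN+FP)`` and
the Matthews correlation coefficient.  Rates whose denominator is zero
are reported as NaN ("undefined"), never silently as 0, and are excluded
from aggregates.  The factorization quality is tracked as the
reconstruction error ``r = ||X - X S^+ S||_F`` with a per-entry variant
``r^2 / (n d)`` (the alternative ``r / (n d)`` is available behind a
flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import estimate_coefficients, predict_classes
from .train import TrainerConfig, fit, stratified_fold_assignment
from .types import as_matrix

__all__ = [
    "EvaluationReport",
    "confusion_counts",
    "sensitivity_specificity",
    "mcc",
    "reconstruction_error",
    "outer_cv",
    "run_benchmark",
    "aggregate_benchmark",
]


@dataclass
class EvaluationReport:
    """Pooled outer-CV result: per-class confusion counts, rates and r."""

    class_names: list[str]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    mcc: np.ndarray
    r: float
    r_per_entry: float
    fold_ids: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_names,
                "tp": self.tp.astype(int),
                "tn": self.tn.astype(int),
                "fp": self.fp.astype(int),
                "fn": self.fn.astype(int),
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "mcc": self.mcc,
            }
        )

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))


def confusion_counts(
    Y: Any, Yhat: Any
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One-vs-rest (TP, TN, FP, FN) per class column.

    For every class ``TP + TN + FP + FN = n``; predictions may be
    multi-label, each column is scored independently.
    """
    Y = as_matrix(Y, "class matrix")
    Yhat = as_matrix(Yhat, "predicted class matrix")
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: Y {Y.shape} vs Yhat {Yhat.shape}")
    true_pos = Y > 0
    pred_pos = Yhat > 0
    tp = (true_pos & pred_pos).sum(axis=0).astype(float)
    tn = (~true_pos & ~pred_pos).sum(axis=0).astype(float)
    fp = (~true_pos & pred_pos).sum(axis=0).astype(float)
    fn = (true_pos & ~pred_pos).sum(axis=0).astype(float)
    return tp, tn, fp, fn


def sensitivity_specificity(
    tp: np.ndarray, tn: np.ndarray, fp: np.ndarray, fn: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """s_i = TP/(TP+FN), t_i = TN/(TN+FP); zero denominators give NaN."""
    tp, tn, fp, fn = (np.asarray(v, dtype=float) for v in (tp, tn, fp, fn))
    with np.errstate(invalid="ignore"):
        s = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
        t = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), np.nan)
    return s, t


def mcc(tp: np.ndarray, tn: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> np.ndarray:
    """Matthews correlation coefficient per class; 0 when a marginal is zero."""
    tp, tn, fp, fn = (np.asarray(v, dtype=float) for v in (tp, tn, fp, fn))
    num = tp * tn - fp * fn
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out = np.zeros(np.broadcast(tp, tn, fp, fn).shape)
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return out


def reconstruction_error(
    X: Any, S: Any, per_entry: str = "squared"
) -> tuple[float, float]:
    """r = ||X - X S^+ S||_F plus a per-matrix-entry normalization.

    ``per_entry="squared"`` (default) returns ``r**2 / (n d)``, the mean
    squared residual per cell; ``per_entry="linear"`` returns
    ``r / (n d)``.
    """
    X = as_matrix(X, "spectra")
    S = as_matrix(S, "signal matrix")
    if S.shape[1] != X.shape[1]:
        raise ValueError("signal channels must match spectra channels")
    if per_entry not in ("squared", "linear"):
        raise ValueError("per_entry must be 'squared' or 'linear'")
    proj = X @ np.linalg.pinv(S) @ S
    r = float(np.linalg.norm(X - proj))
    n_cells = X.shape[0] * X.shape[1]
    per = r**2 / n_cells if per_entry == "squared" else r / n_cells
    return r, per


def _derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(x) for x in key))
    return int(ss.generate_state(1)[0] % np.uint32(2**31))


def outer_cv(
    X: Any,
    labels: Sequence[str],
    class_names: Sequence[str] | None = None,
    folds: int = 5,
    cfg: TrainerConfig | None = None,
    seed: int = 0,
    per_entry: str = "squared",
) -> EvaluationReport:
    """Stratified outer cross-validation of the full training procedure.

    Per fold a model is fitted on the training part only (with its own
    inner CV, seeded deterministically from ``seed``) and scored on the
    held-out part; confusion counts are pooled over folds and the
    held-out residuals combine into one Frobenius norm over all samples.
    """
    from .core import build_class_matrix  # local to avoid cycle at import time

    X = as_matrix(X, "spectra")
    labels = list(labels)
    if class_names is None:
        class_names = sorted(set(labels))
    class_names = list(class_names)
    Y = as_matrix(build_class_matrix(labels, class_names))
    n, k = Y.shape
    cfg = cfg or TrainerConfig()

    rng = np.random.default_rng(_derive_seed(seed, 0))
    label_idx = np.argmax(Y, axis=1)
    fold_ids = stratified_fold_assignment(label_idx, folds, rng)

    tp = np.zeros(k)
    tn = np.zeros(k)
    fp = np.zeros(k)
    fn = np.zeros(k)
    r_sq = 0.0
    for f in range(folds):
        test = fold_ids == f
        train = ~test
        fold_cfg = TrainerConfig(
            inner_folds=cfg.inner_folds,
            bfgs_max_iter=cfg.bfgs_max_iter,
            gradient_step=cfg.gradient_step,
            b_init=cfg.b_init,
            rng_seed=_derive_seed(seed, 1, f),
            r_floor=cfg.r_floor,
            max_restarts=cfg.max_restarts,
            pooling=cfg.pooling,
        )
        model = fit(X[train], _SubclassView(Y[train], class_names), fold_cfg)
        S = model.S
        A_test = estimate_coefficients(X[test], S)
        Yhat = predict_classes(A_test, model.b)
        f_tp, f_tn, f_fp, f_fn = confusion_counts(Y[test], Yhat)
        tp += f_tp
        tn += f_tn
        fp += f_fp
        fn += f_fn
        r_fold, _ = reconstruction_error(X[test], S)
        r_sq += r_fold**2
    r = float(np.sqrt(r_sq))
    n_cells = n * X.shape[1]
    per = r**2 / n_cells if per_entry == "squared" else r / n_cells
    s, t = sensitivity_specificity(tp, tn, fp, fn)
    return EvaluationReport(
        class_names=class_names,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        sensitivity=s,
        specificity=t,
        mcc=mcc(tp, tn, fp, fn),
        r=r,
        r_per_entry=float(per),
        fold_ids=fold_ids,
        seed=seed,
        config={"folds": folds, "per_entry": per_entry},
    )


class _SubclassView:
    """Minimal Y container carrying class names into :func:`fit`."""

    def __init__(self, values: np.ndarray, class_names: list[str]):
        self.values = values
        self.class_names = class_names


def _svm_fold_counts(
    X: np.ndarray,
    label_idx: np.ndarray,
    Y: np.ndarray,
    fold_ids: np.ndarray,
    folds: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled one-vs-rest counts for the linear SVM baseline (one-vs-one)."""
    from sklearn.svm import SVC

    k = Y.shape[1]
    tp = np.zeros(k)
    tn = np.zeros(k)
    fp = np.zeros(k)
    fn = np.zeros(k)
    for f in range(folds):
        test = fold_ids == f
        train = ~test
        clf = SVC(kernel="linear", random_state=seed)
        clf.fit(X[train], label_idx[train])
        pred = clf.predict(X[test])
        Yhat = -np.ones((int(test.sum()), k))
        Yhat[np.arange(Yhat.shape[0]), pred] = 1.0
        f_tp, f_tn, f_fp, f_fn = confusion_counts(Y[test], Yhat)
        tp += f_tp
        tn += f_tn
        fp += f_fp
        fn += f_fn
    return tp, tn, fp, fn


def run_benchmark(
    design: Iterable,
    methods: Sequence[str] = ("brierscoremf", "linear-svm"),
    cfg: TrainerConfig | None = None,
    folds: int = 5,
    master_seed: int = 0,
    out_path: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the factorial synthetic experiment; one tidy row per dataset x method.

    Each config is realized with its own seed, evaluated by outer CV, and
    summarized by the mean over classes of pooled sensitivity and
    specificity.  The SVM baseline (linear kernel, native one-vs-one
    decomposition) shares the dataset but runs its own plain CV without
    an inner loop.  The whole run is a pure function of
    ``(design, master_seed)``.
    """
    from .simulate import sample_dataset

    rows = []
    for cfg_i, syn_cfg in enumerate(design):
        ds = sample_dataset(syn_cfg)
        X = as_matrix(ds.X)
        Y = as_matrix(ds.Y)
        label_idx = np.argmax(Y, axis=1)
        eval_seed = _derive_seed(master_seed, syn_cfg.seed, syn_cfg.n, syn_cfg.k, syn_cfg.m)
        for method in methods:
            if method == "brierscoremf":
                report = outer_cv(
                    X, ds.labels, ds.class_names, folds=folds, cfg=cfg, seed=eval_seed
                )
                sens, spec = report.sensitivity, report.specificity
                r = report.r
            elif method in ("linear-svm", "svm"):
                rng = np.random.default_rng(_derive_seed(eval_seed, 0))
                fold_ids = stratified_fold_assignment(label_idx, folds, rng)
                tp, tn, fp, fn = _svm_fold_counts(
                    X, label_idx, Y, fold_ids, folds, eval_seed
                )
                sens, spec = sensitivity_specificity(tp, tn, fp, fn)
                r = np.nan
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(
                {
                    "method": method,
                    "seed": syn_cfg.seed,
                    "n": syn_cfg.n,
                    "k": syn_cfg.k,
                    "m": syn_cfg.m,
                    "mean_sensitivity": float(np.nanmean(sens)),
                    "mean_specificity": float(np.nanmean(spec)),
                    "r": float(r) if np.isfinite(r) else np.nan,
                }
            )
        if progress and (cfg_i + 1) % 10 == 0:
            print(f"  benchmark: {cfg_i + 1} datasets done", flush=True)
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def aggregate_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD across seeds per (method, n, k, m) cell.

    Cells with a single seed report an undefined (NaN) SD rather than 0.
    """
    grouped = results.groupby(["method", "n", "k", "m"], as_index=False).agg(
        n_seeds=("seed", "size"),
        sensitivity_mean=("mean_sensitivity", "mean"),
        sensitivity_sd=("mean_sensitivity", lambda v: v.std(ddof=1)),
        specificity_mean=("mean_specificity", "mean"),
        specificity_sd=("mean_specificity", lambda v: v.std(ddof=1)),
    )
    return grouped
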