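"""Synthetic smooth-spectra generator and the factorial benchmark design.

Infrared spectra of compound mixtures are smooth functions of the
spectral coordinate, so synthetic class signals are drawn from a Sobolev
space on [0, 1]: a signal is a finite Fourier expansion
``f(x) = sum_{j<=o} theta_j phi_j(x)`` whose order ``o`` caps the
frequency content.  Mixing coefficients are drawn uniformly and rescaled
to be exactly consistent with a threshold vector ``b`` (entries of class
members land in ``[b_j, 1]``, non-members in ``[0, b_j)``) and to sum to
one per sample, after which ``X = A S`` holds exactly.  Each dataset is a
pure function of ``(seed, n, k, m)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Any, Iterable, Iterator, Sequence

import numpy as np

from .core import build_class_matrix
from .types import (
    ClassMatrix,
    CoefficientMatrix,
    SignalMatrix,
    SpectraMatrix,
    ThresholdVector,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "fourier_basis",
    "evaluate_signal",
    "sample_dataset",
    "generate_design",
]

#: margin keeping rescaled non-member coefficients strictly below b_j
_CLIP_MARGIN = 1e-9


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset: (seed, n samples, k classes, m channels)."""

    seed: int
    n: int
    k: int
    m: int
    order_range: tuple[int, int] = (1, 100)

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1 or self.m < 1:
            raise ValueError("n, k and m must be positive")
        lo, hi = self.order_range
        if lo < 1 or hi < lo:
            raise ValueError("order_range must be a positive integer interval")


@dataclass
class SyntheticDataset:
    """A generated dataset together with its ground-truth factorization."""

    X: SpectraMatrix
    Y: ClassMatrix
    A_true: CoefficientMatrix
    S_true: SignalMatrix
    b_true: ThresholdVector
    theta: np.ndarray  # k x o Fourier coefficients
    order: int
    labels: list[str]
    config: SyntheticConfig

    @property
    def class_names(self) -> list[str]:
        return self.Y.class_names


def fourier_basis(j: int | np.ndarray, x: Any) -> np.ndarray | float:
    """Orthonormal Fourier basis on [0, 1].

    phi_1(x) = 1, phi_{2j}(x) = sqrt(2) cos(2 pi j x),
    phi_{2j+1}(x) = sqrt(2) sin(2 pi j x); with this normalization
    ``integral phi_a phi_b = delta_ab`` on the unit interval.
    """
    x = np.asarray(x, dtype=float)
    j = int(j)
    if j < 1:
        raise ValueError("basis index must be >= 1")
    if j == 1:
        out = np.ones_like(x)
    elif j % 2 == 0:
        out = np.sqrt(2.0) * np.cos(2.0 * np.pi * (j // 2) * x)
    else:
        out = np.sqrt(2.0) * np.sin(2.0 * np.pi * (j // 2) * x)
    return out if out.ndim else float(out)


def evaluate_signal(theta: Sequence[float], grid: Any) -> np.ndarray:
    """Evaluate f(x) = sum_j theta_j phi_j(x) on a grid in [0, 1]."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("theta must contain at least one coefficient")
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0.0) | (grid > 1.0)):
        raise ValueError("grid points must lie in [0, 1]")
    basis = np.stack([fourier_basis(j, grid) for j in range(1, theta.size + 1)])
    return theta @ basis


def _scale_row(row: np.ndarray, pos: int, b: np.ndarray) -> np.ndarray:
    """Rescale one coefficient row to be threshold-consistent with unit sum.

    The member entry is mapped into [b_pos, 1], non-members into
    [0, b_j); non-members are then scaled so the row sums to one.  When
    that scaling would push a non-member to or above its threshold, the
    offender is capped just below b_j, the remaining non-members absorb
    the residual, and any deficit that cannot be placed without breaking
    a threshold is absorbed by raising the member entry (which stays in
    [b_pos, 1] by construction), so both invariants always hold exactly.
    """
    k = row.size
    scaled = np.empty(k)
    neg = np.ones(k, dtype=bool)
    neg[pos] = False
    scaled[pos] = b[pos] + row[pos] * (1.0 - b[pos])
    scaled[neg] = row[neg] * b[neg]

    cap = b * (1.0 - _CLIP_MARGIN)
    target = 1.0 - scaled[pos]
    free = neg.copy()
    while True:
        free_sum = scaled[free].sum()
        if free_sum <= 0.0 or target <= 0.0:
            scaled[free] = 0.0
            break
        factor = target / free_sum
        rescaled = scaled[free] * factor
        over = rescaled > cap[free]
        if not over.any():
            scaled[free] = rescaled
            break
        # cap the offenders and retry with the remaining free entries
        idx = np.flatnonzero(free)
        clip_idx = idx[over]
        scaled[clip_idx] = cap[clip_idx]
        target -= cap[clip_idx].sum()
        free[clip_idx] = False
        if not free.any():
            break
    scaled[pos] = 1.0 - scaled[neg].sum()
    return scaled


def sample_dataset(cfg: SyntheticConfig, max_label_retries: int = 1000) -> SyntheticDataset:
    """Draw one synthetic dataset; the draw order is a stable contract.

    Per seed: thresholds ``b ~ U(0,1)^k``; ``n`` class labels with
    replacement (redrawn, consuming the stream, until every class
    appears); order ``o`` uniform on ``order_range``; Fourier
    coefficients ``T ~ U(0,1)^{k x o}``; raw coefficients
    ``A ~ U(0,1)^{n x k}``.  Signals are evaluated on ``m`` equispaced
    points spanning [0, 1] inclusive, coefficients are rescaled to the
    threshold-consistent unit-sum form, and ``X = A S`` exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n, k, m = cfg.n, cfg.k, cfg.m

    b = rng.uniform(size=k)
    for _ in range(max_label_retries):
        label_idx = rng.integers(0, k, size=n)
        if np.unique(label_idx).size == k:
            break
    else:
        raise RuntimeError(
            f"could not draw labels covering all {k} classes in "
            f"{max_label_retries} attempts (n={n}); increase n or retries"
        )
    lo, hi = cfg.order_range
    order = int(rng.integers(lo, hi + 1))
    theta = rng.uniform(size=(k, order))
    A_raw = rng.uniform(size=(n, k))

    grid = np.linspace(0.0, 1.0, m)
    S = np.vstack([evaluate_signal(theta[j], grid) for j in range(k)])

    class_names = [f"c{j + 1}" for j in range(k)]
    labels = [class_names[j] for j in label_idx]
    Y = build_class_matrix(labels, class_names)

    A = np.vstack([_scale_row(A_raw[i], label_idx[i], b) for i in range(n)])
    X = A @ S

    return SyntheticDataset(
        X=SpectraMatrix(X),
        Y=Y,
        A_true=CoefficientMatrix(A),
        S_true=SignalMatrix(S),
        b_true=ThresholdVector(b, class_names),
        theta=theta,
        order=order,
        labels=labels,
        config=cfg,
    )


def generate_design(
    seeds: Iterable[int],
    n_set: Iterable[int],
    k_set: Iterable[int],
    m_set: Iterable[int],
    order_range: tuple[int, int] = (1, 100),
) -> Iterator[SyntheticConfig]:
    """Yield the full factorial design seeds x n_set x k_set x m_set.

    Iteration order is the nested Cartesian product with ``seeds``
    outermost and ``m_set`` innermost; the benchmark of the reference
    experiment (100 seeds x n in {50,100,150} x k in
    {2,3,4,5,10,15,20,25} x m in {50,100}) enumerates 4800 configs.
    """
    seeds, n_set, k_set, m_set = map(list, (seeds, n_set, k_set, m_set))
    if not (seeds and n_set and k_set and m_set):
        raise ValueError("all design sets must be non-empty")
    for seed, n, k, m in itertools.product(seeds, n_set, k_set, m_set):
        yield SyntheticConfig(seed=seed, n=n, k=k, m=m, order_range=order_range)
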