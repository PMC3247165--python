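"""Clinical-style spectra preprocessing: replicate QC, averaging, smoothing.

Serum FTIR protocols measure every sample in replicate (typically three
acquisitions on different days).  The chain implemented here mirrors
standard chemometrics practice: replicate groups whose pairwise Pearson
correlation drops below 0.95 are discarded wholesale, surviving
replicates are averaged per channel, the averaged spectrum is smoothed
with a Savitzky-Golay filter of length 15, and known water-vapour
absorption windows (2200-2270 and 3200-3700 1/cm) can be masked out of
the wavenumber axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .types import SpectraMatrix

__all__ = [
    "ReplicateGroup",
    "QCResult",
    "DEFAULT_WATER_REGIONS",
    "pearson",
    "filter_replicates",
    "average_replicates",
    "savitzky_golay",
    "mask_water_regions",
    "preprocess_replicates",
]

DEFAULT_WATER_REGIONS: tuple[tuple[float, float], ...] = (
    (2200.0, 2270.0),
    (3200.0, 3700.0),
)


@dataclass
class ReplicateGroup:
    """Replicate spectra (r x d, r >= 2) of one sample on a shared axis."""

    sample_id: str
    spectra: np.ndarray
    wavenumbers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise ValueError("replicate spectra must form an r x d matrix")
        if self.spectra.shape[0] < 2:
            raise ValueError("a replicate group needs at least two spectra")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("replicate spectra contain non-finite entries")
        if self.wavenumbers is not None:
            self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
            if self.wavenumbers.shape != (self.spectra.shape[1],):
                raise ValueError("wavenumbers must match the channel count")

    @property
    def n_replicates(self) -> int:
        return self.spectra.shape[0]


@dataclass(frozen=True)
class QCResult:
    """Outcome of replicate QC: kept or rejected with the failing evidence."""

    sample_id: str
    passed: bool
    min_correlation: float | None = None
    failing_pair: tuple[int, int] | None = None
    reason: str | None = None
    group: ReplicateGroup | None = None


def pearson(u: Any, v: Any) -> float:
    """Pearson correlation of two spectra; undefined for constant input."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if u.size < 2:
        raise ValueError("need at least two channels")
    su, sv = np.std(u), np.std(v)
    if su == 0.0 or sv == 0.0:
        raise ValueError("correlation undefined for a constant spectrum")
    return float(np.corrcoef(u, v)[0, 1])


def filter_replicates(group: ReplicateGroup, rho_min: float = 0.95) -> QCResult:
    """Keep a group only if ALL pairwise replicate correlations reach rho_min.

    A single failing pair (or an undefined correlation from a constant
    replicate) rejects the whole group; the offending pair and the
    minimum correlation observed are recorded for the QC report.
    """
    r = group.n_replicates
    min_rho = np.inf
    worst: tuple[int, int] | None = None
    for i in range(r):
        for j in range(i + 1, r):
            try:
                rho = pearson(group.spectra[i], group.spectra[j])
            except ValueError:
                return QCResult(
                    sample_id=group.sample_id,
                    passed=False,
                    failing_pair=(i, j),
                    reason="undefined correlation (constant replicate)",
                )
            if rho < min_rho:
                min_rho = rho
                worst = (i, j)
    if min_rho < rho_min:
        return QCResult(
            sample_id=group.sample_id,
            passed=False,
            min_correlation=float(min_rho),
            failing_pair=worst,
            reason=f"pairwise correlation {min_rho:.4f} < {rho_min}",
        )
    return QCResult(
        sample_id=group.sample_id,
        passed=True,
        min_correlation=float(min_rho),
        group=group,
    )


def average_replicates(group: ReplicateGroup) -> np.ndarray:
    """Arithmetic mean across replicates per channel."""
    return group.spectra.mean(axis=0)


def savitzky_golay(spectrum: Any, window: int = 15, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Boundaries are handled by fitting a single degree-``polyorder``
    polynomial to the outermost window and evaluating it at the edge
    points; polynomials of degree <= polyorder pass through unchanged.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1:
        raise ValueError("spectrum must be a 1-D vector")
    if window % 2 == 0:
        raise ValueError("window length must be odd")
    if window > x.size:
        raise ValueError("window longer than the spectrum")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window length")
    return savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp")


def mask_water_regions(
    X: SpectraMatrix,
    regions: Sequence[tuple[float, float]] = DEFAULT_WATER_REGIONS,
) -> SpectraMatrix:
    """Drop channels whose wavenumber falls in any closed interval.

    Used to excise water-vapour absorption windows before training;
    channel order is otherwise preserved and repeated masking with the
    same regions is a no-op.
    """
    if X.wavenumbers is None:
        raise ValueError("masking requires a wavenumber axis")
    wn = X.wavenumbers
    keep = np.ones(wn.size, dtype=bool)
    for lo, hi in regions:
        keep &= ~((wn >= lo) & (wn <= hi))
    if not keep.any():
        raise ValueError("empty spectrum after masking: all channels removed")
    return SpectraMatrix(
        X.values[:, keep], sample_ids=list(X.sample_ids), wavenumbers=wn[keep]
    )


def preprocess_replicates(
    groups: Sequence[ReplicateGroup],
    rho_min: float = 0.95,
    window: int = 15,
    polyorder: int = 3,
    water_regions: Sequence[tuple[float, float]] | None = None,
) -> tuple[SpectraMatrix, list[QCResult]]:
    """Full chain: QC filter, average, smooth, optionally mask water regions.

    Returns the processed sample-by-channel matrix (one row per surviving
    sample) together with the per-group QC results.
    """
    results = [filter_replicates(g, rho_min) for g in groups]
    kept = [res.group for res in results if res.passed]
    if not kept:
        raise ValueError("no replicate group passed quality control")
    wn = kept[0].wavenumbers
    rows = [savitzky_golay(average_replicates(g), window, polyorder) for g in kept]
    X = SpectraMatrix(
        np.vstack(rows),
        sample_ids=[g.sample_id for g in kept],
        wavenumbers=wn,
    )
    if water_regions is not None:
        X = mask_water_regions(X, water_regions)
    return X, results
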