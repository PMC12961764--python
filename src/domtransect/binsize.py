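"""Bin-size optimization by the knee of the dissimilarity-vs-bins curve.

Binning trades chemical-shift robustness against spectral information:
coarse bins absorb shift fluctuations but blur differences between
samples, fine bins preserve information but fragment matching signals.
Sweeping the bin size and plotting the average pairwise Bray-Curtis
dissimilarity among samples against the resulting number of bins yields
a saturating, approximately logarithmic curve; its knee point is taken
as the best trade-off.

The knee is defined here as the exhaustive two-segment least-squares
breakpoint: for every interior candidate, a straight line is fitted to
the points left of (and including) the candidate and another to the
points right of (and including) it, and the candidate minimizing the
summed squared residuals is returned, ties broken toward smaller x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import average_dissimilarity, bray_curtis_matrix
from .nmr import Spectrum1D, SpectrumCOSY, assemble_data_matrix, bin_1d, bin_2d

__all__ = [
    "LogFit",
    "KneeResult",
    "SweepResult",
    "default_size_grid",
    "sweep_bin_sizes",
    "fit_log_model",
    "find_knee",
    "optimize_bin_size",
]


@dataclass(frozen=True)
class LogFit:
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


@dataclass(frozen=True)
class KneeResult:
    index: int
    x_value: float
    total_residuals: np.ndarray
    ambiguous: bool


@dataclass
class SweepResult:
    bin_sizes: np.ndarray
    n_bins: np.ndarray
    avg_dissimilarity: np.ndarray
    knee_index: int | None = None
    log_fit: LogFit | None = None

    @property
    def knee_bin_size(self) -> float | None:
        return None if self.knee_index is None else float(self.bin_sizes[self.knee_index])


def default_size_grid(lo: float = 0.01, hi: float = 1.0, n: int = 15) -> np.ndarray:
    """Geometrically spaced bin sizes spanning the sweep range (ppm)."""
    return np.geomspace(lo, hi, n)


def sweep_bin_sizes(spectra, sizes, mode: str, window=(0.0, 10.0)) -> SweepResult:
    """Bin all spectra at each size and record the mean Bray-Curtis value.

    ``mode`` is ``"1d"`` (Spectrum1D inputs) or ``"2d"`` (SpectrumCOSY).
    Matrices are total-sum normalized per sample before the dissimilarity
    computation, matching the downstream analysis.
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to form sample pairs")
    sizes = np.asarray(sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("bin sizes must be positive")
    mode = mode.lower()
    if mode not in ("1d", "2d"):
        raise ValueError("mode must be '1d' or '2d'")
    if mode == "1d" and not all(isinstance(s, Spectrum1D) for s in spectra):
        raise TypeError("1d mode expects Spectrum1D inputs")
    if mode == "2d" and not all(isinstance(s, SpectrumCOSY) for s in spectra):
        raise TypeError("2d mode expects SpectrumCOSY inputs")

    order = np.argsort(sizes)[::-1]  # coarse -> fine so n_bins is ascending
    sizes = sizes[order]
    n_bins, avg = [], []
    for size in sizes:
        if mode == "1d":
            vecs = [bin_1d(s, size, window) for s in spectra]
        else:
            vecs = [bin_2d(s, size, window) for s in spectra]
        n_bins.append(len(vecs[0].bin_definitions))
        matrix = assemble_data_matrix(vecs, normalize=True)
        dm = bray_curtis_matrix(matrix.values, matrix.sample_ids)
        avg.append(average_dissimilarity(dm))
    return SweepResult(
        bin_sizes=sizes,
        n_bins=np.asarray(n_bins, dtype=int),
        avg_dissimilarity=np.asarray(avg, dtype=float),
    )


def fit_log_model(n_bins, avg_dissimilarity) -> LogFit:
    """Least-squares fit of y = a ln(x) + b.

    R^2 is the squared Pearson correlation of fitted vs observed values.
    Constant inputs are flagged degenerate (slope 0, R^2 = 0).
    """
    x = np.asarray(n_bins, dtype=float)
    y = np.asarray(avg_dissimilarity, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three (n_bins, dissimilarity) points")
    if (x <= 0).any():
        raise ValueError("n_bins must be positive")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return LogFit(slope=0.0, intercept=float(np.mean(y)), r_squared=0.0, degenerate=True)
    A = np.column_stack([np.log(x), np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ np.array([a, b])
    if np.ptp(fitted) == 0:
        return LogFit(slope=float(a), intercept=float(b), r_squared=0.0, degenerate=True)
    r = np.corrcoef(fitted, y)[0, 1]
    return LogFit(slope=float(a), intercept=float(b), r_squared=float(r**2))


def _segment_sse(x: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([x, np.ones_like(x)])
    _, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if res.size:
        return float(res[0])
    fitted = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(((y - fitted) ** 2).sum())


def find_knee(x, y) -> KneeResult:
    """Exhaustive two-segment least-squares breakpoint search.

    Candidates are interior indices k (the knee point is shared by both
    segments, so each side keeps >= 2 points).  Near-equal residuals
    across all candidates (e.g. strictly linear data) are flagged
    ambiguous.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("knee detection needs at least four points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("x must be sorted strictly ascending")
    candidates = np.arange(1, x.size - 1)
    totals = np.empty(candidates.size)
    for pos, k in enumerate(candidates):
        totals[pos] = _segment_sse(x[: k + 1], y[: k + 1]) + _segment_sse(x[k:], y[k:])
    best = int(candidates[np.argmin(totals)])
    scale = max(float(np.ptp(y)) ** 2, 1e-300)
    ambiguous = bool(np.ptp(totals) <= 1e-9 * scale + 1e-12)
    return KneeResult(index=best, x_value=float(x[best]), total_residuals=totals,
                      ambiguous=ambiguous)


def optimize_bin_size(spectra, sizes=None, mode: str = "2d", window=(0.0, 10.0)) -> SweepResult:
    """Full sweep: dissimilarities, logarithmic fit and knee selection."""
    sizes = default_size_grid() if sizes is None else np.asarray(sizes, dtype=float)
    result = sweep_bin_sizes(spectra, sizes, mode, window)
    result.log_fit = fit_log_model(result.n_bins, result.avg_dissimilarity)
    knee = find_knee(result.n_bins.astype(float), result.avg_dissimilarity)
    result.knee_index = knee.index
    return result
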