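"""1D 1H and 2D COSY NMR spectral processing for DOM mixture analysis.

The processing chain mirrors standard environmental-metabolomics practice
for solid-phase-extracted dissolved organic matter: (1) resampling onto a
common chemical-shift grid, (2) excision of solvent regions (residual HDO
and CH3OH), (3) integration of structural-motif sections, (4) windowing
to 0-10 ppm, (5) equal-width binning, (6) per-sample normalization and
(7) assembly of a samples x bins data matrix.  COSY grids additionally
pass a signal-to-noise cutoff before binning, and bins intersecting the
F1=F2 diagonal are flagged so diagonal intensity (which dominates COSY
spectra of complex mixtures yet carries mostly 1D information) can be
excluded from diversity and dissimilarity analyses.

Bin membership is half-open ``[low, high)`` with the last bin closed, so
bin counts are exact (e.g. a 0.05 ppm bin size over 0-10 ppm yields
200 bins per axis and 40,000 COSY bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Spectrum1D",
    "SpectrumCOSY",
    "SectionScheme1D",
    "SectionScheme2D",
    "BinnedVector",
    "BinnedMatrix",
    "DEFAULT_SECTIONS_1D",
    "DEFAULT_SOLVENT_REGIONS",
    "DEFAULT_WINDOW",
    "load_default_cosy_scheme",
    "resample_to_grid",
    "excise_regions",
    "integrate_sections_1d",
    "bin_1d",
    "snr_filter_2d",
    "bin_2d",
    "strip_diagonal",
    "integrate_sections_2d",
    "assemble_data_matrix",
]

DEFAULT_WINDOW = (0.0, 10.0)

#: Residual-solvent chemical-shift regions excised from 1D spectra (ppm):
#: water and methanol.
DEFAULT_SOLVENT_REGIONS = ((4.70, 5.05), (3.20, 3.45))

#: Structural-motif sections of the 1D 1H spectrum (label, low, high in ppm).
DEFAULT_SECTIONS_1D = (
    ("aliphatic", 0.0, 1.9),
    ("acetyl", 1.9, 2.3),
    ("alpha_carbonyl", 2.3, 3.0),
    ("alpha_oxygen", 3.0, 5.3),
    ("olefinic", 5.3, 6.5),
    ("aromatic", 6.5, 10.0),
)


def _check_axis(shifts: np.ndarray, name: str) -> np.ndarray:
    shifts = np.asarray(shifts, dtype=float)
    if shifts.ndim != 1 or shifts.size == 0:
        raise ValueError(f"{name} must be a nonempty 1D array")
    if shifts.size > 1 and not np.all(np.diff(shifts) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return shifts


@dataclass
class Spectrum1D:
    """A 1D 1H spectrum: strictly increasing ppm axis plus intensities."""

    sample_id: str
    shifts: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.shifts = _check_axis(self.shifts, "shifts")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.shifts.shape:
            raise ValueError("shifts and intensities must have equal length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class SpectrumCOSY:
    """A 2D COSY spectrum: intensity grid indexed as (f1, f2)."""

    sample_id: str
    f2_shifts: np.ndarray
    f1_shifts: np.ndarray
    intensity_grid: np.ndarray

    def __post_init__(self) -> None:
        self.f2_shifts = _check_axis(self.f2_shifts, "f2_shifts")
        self.f1_shifts = _check_axis(self.f1_shifts, "f1_shifts")
        self.intensity_grid = np.asarray(self.intensity_grid, dtype=float)
        if self.intensity_grid.shape != (self.f1_shifts.size, self.f2_shifts.size):
            raise ValueError("grid shape must be (len(f1), len(f2))")


@dataclass(frozen=True)
class SectionScheme1D:
    """Ordered, contiguous, non-overlapping ppm sections of a 1D spectrum."""

    sections: tuple = DEFAULT_SECTIONS_1D

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.sections:
            if hi <= lo:
                raise ValueError(f"section {label!r} has nonpositive width")
            if prev_hi is not None and not np.isclose(lo, prev_hi):
                raise ValueError("sections must be contiguous and ordered")
            prev_hi = hi

    @property
    def labels(self) -> list:
        return [s[0] for s in self.sections]


@dataclass(frozen=True)
class SectionScheme2D:
    """Labelled axis-aligned rectangles (f2_low, f2_high, f1_low, f1_high)."""

    sections: dict

    def __post_init__(self) -> None:
        for label, rects in self.sections.items():
            for f2lo, f2hi, f1lo, f1hi in rects:
                if f2hi <= f2lo or f1hi <= f1lo:
                    raise ValueError(f"section {label!r} has a degenerate rectangle")
                if min(f2lo, f1lo) < 0 or max(f2hi, f1hi) > 10:
                    raise ValueError(f"section {label!r} outside the 0-10 ppm window")

    @property
    def labels(self) -> list:
        return list(self.sections)

    @classmethod
    def from_yaml(cls, path) -> "SectionScheme2D":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(sections={k: [tuple(r) for r in v] for k, v in doc["sections"].items()})


def load_default_cosy_scheme() -> SectionScheme2D:
    """The packaged 19-section (a-s) COSY structural-motif scheme."""
    ref = resources.files("domtransect").joinpath("data/cosy_sections.yaml")
    with resources.as_file(ref) as path:
        return SectionScheme2D.from_yaml(path)


@dataclass
class BinnedVector:
    """One sample's binned intensities plus the shared bin geometry.

    ``bin_definitions`` is a list of ppm intervals (1D) or ppm rectangles
    (2D, as (f2_low, f2_high, f1_low, f1_high)); ``diagonal_flags`` marks
    2D bins whose rectangle has a positive-length intersection with F1=F2.
    """

    sample_id: str
    values: np.ndarray
    bin_definitions: list
    diagonal_flags: np.ndarray | None = None


@dataclass
class BinnedMatrix:
    """Samples x bins intensity matrix with bin geometry."""

    sample_ids: list
    values: np.ndarray
    bin_definitions: list
    normalized: bool = False
    diagonal_flags: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin{i}" for i in range(len(self.bin_definitions))]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


# ---------------------------------------------------------------------------
# 1D operations
# ---------------------------------------------------------------------------

def resample_to_grid(spectrum: Spectrum1D, target_grid: np.ndarray) -> Spectrum1D:
    """Linear interpolation of a spectrum onto a new ppm grid.

    The target grid must lie inside the source shift range.
    """
    target = _check_axis(np.asarray(target_grid, dtype=float), "target_grid")
    if target[0] < spectrum.shifts[0] - 1e-12 or target[-1] > spectrum.shifts[-1] + 1e-12:
        raise ValueError("target grid extends outside the source shift range")
    interp = np.interp(target, spectrum.shifts, spectrum.intensities)
    return Spectrum1D(spectrum.sample_id, target, interp)


def excise_regions(spectrum: Spectrum1D, regions=DEFAULT_SOLVENT_REGIONS) -> Spectrum1D:
    """Drop data points whose shift falls inside any (lo, hi) ppm region."""
    if not regions:
        return Spectrum1D(spectrum.sample_id, spectrum.shifts.copy(),
                          spectrum.intensities.copy())
    keep = np.ones(spectrum.shifts.size, dtype=bool)
    for lo, hi in regions:
        if lo < 0 or hi > 10 or hi <= lo:
            raise ValueError(f"invalid excision region ({lo}, {hi})")
        keep &= ~((spectrum.shifts >= lo) & (spectrum.shifts <= hi))
    return Spectrum1D(spectrum.sample_id, spectrum.shifts[keep], spectrum.intensities[keep])


def integrate_sections_1d(
    spectrum: Spectrum1D, scheme: SectionScheme1D | None = None
) -> pd.Series:
    """Trapezoidal section integrals as percent of the total (sums to 100).

    Solvent regions should already be excised.  An all-zero spectrum has
    undefined fractions and raises ``ValueError``.
    """
    scheme = scheme or SectionScheme1D()
    raw = {}
    for label, lo, hi in scheme.sections:
        mask = (spectrum.shifts >= lo) & (spectrum.shifts <= hi)
        if mask.sum() >= 2:
            raw[label] = float(np.trapezoid(spectrum.intensities[mask], spectrum.shifts[mask]))
        else:
            raw[label] = 0.0
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("section fractions undefined: total integral is not positive")
    return pd.Series({k: 100.0 * v / total for k, v in raw.items()}, name=spectrum.sample_id)


def _bin_edges(window: tuple, bin_size: float) -> np.ndarray:
    lo, hi = window
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if hi <= lo:
        raise ValueError("window must have positive width")
    n = int(np.ceil((hi - lo) / bin_size - 1e-9))
    return lo + bin_size * np.arange(n + 1)


def _assign_bins(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bin index per point; -1 for points outside the window."""
    n = edges.size - 1
    idx = np.searchsorted(edges, x, side="right") - 1
    # points exactly at the upper window edge belong to the last (closed) bin
    idx[np.isclose(x, edges[-1])] = n - 1
    idx[(x < edges[0]) | (x > edges[-1])] = -1
    return idx


def bin_1d(
    spectrum: Spectrum1D, bin_size: float, window: tuple = DEFAULT_WINDOW
) -> BinnedVector:
    """Equal-width binning: bin value = sum of data-point intensities.

    Total in-window intensity is conserved exactly (the bins partition
    the window).
    """
    edges = _bin_edges(window, bin_size)
    n = edges.size - 1
    idx = _assign_bins(spectrum.shifts, edges)
    inside = idx >= 0
    values = np.bincount(idx[inside], weights=spectrum.intensities[inside], minlength=n)
    bin_defs = [(edges[i], edges[i + 1]) for i in range(n)]
    return BinnedVector(spectrum.sample_id, values, bin_defs)


# ---------------------------------------------------------------------------
# 2D operations
# ---------------------------------------------------------------------------

def estimate_noise_sigma(grid: np.ndarray) -> float:
    """Robust noise sigma: scaled median absolute deviation of the grid.

    DOM COSY grids are noise-dominated cell-wise, so the global MAD is a
    stable estimate of the additive-noise standard deviation.
    """
    grid = np.asarray(grid, dtype=float)
    mad = np.median(np.abs(grid - np.median(grid)))
    return float(1.4826 * mad)


def snr_filter_2d(
    cosy: SpectrumCOSY, cutoff: float = 3.0, noise_estimate="auto"
) -> SpectrumCOSY:
    """Zero all grid cells with intensity below ``cutoff`` x noise sigma."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if noise_estimate == "auto":
        sigma = estimate_noise_sigma(cosy.intensity_grid)
    else:
        sigma = float(noise_estimate)
    if sigma < 0:
        raise ValueError("noise estimate must be nonnegative")
    filtered = np.where(cosy.intensity_grid >= cutoff * sigma, cosy.intensity_grid, 0.0)
    return SpectrumCOSY(cosy.sample_id, cosy.f2_shifts.copy(), cosy.f1_shifts.copy(), filtered)


def bin_2d(
    cosy: SpectrumCOSY,
    bin_size: float,
    window: tuple = DEFAULT_WINDOW,
    diagonal_width_bins: int = 0,
) -> BinnedVector:
    """Square binning of a COSY grid over ``window x window``.

    Bin value = sum of grid-cell intensities whose (f2, f1) coordinates
    fall in the bin rectangle.  ``diagonal_flags`` marks bins within
    ``diagonal_width_bins`` of the F1=F2 diagonal (default: only bins the
    diagonal passes through).
    """
    edges = _bin_edges(window, bin_size)
    n = edges.size - 1
    i2 = _assign_bins(cosy.f2_shifts, edges)
    i1 = _assign_bins(cosy.f1_shifts, edges)
    in2, in1 = i2 >= 0, i1 >= 0
    sub = cosy.intensity_grid[np.ix_(in1, in2)]
    flat = i1[in1][:, None] * n + i2[None, in2]
    values = np.bincount(flat.ravel(), weights=sub.ravel(), minlength=n * n)
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))  # ii = f1 index, jj = f2 index
    flags = (np.abs(ii - jj) <= diagonal_width_bins).ravel()
    bin_defs = [
        (edges[j], edges[j + 1], edges[i], edges[i + 1])
        for i in range(n)
        for j in range(n)
    ]
    return BinnedVector(cosy.sample_id, values, bin_defs, diagonal_flags=flags)


def strip_diagonal(matrix: BinnedMatrix) -> BinnedMatrix:
    """Drop all diagonal-flagged bins from every sample (idempotent)."""
    if matrix.diagonal_flags is None:
        raise ValueError("strip_diagonal requires a 2D-binned matrix with diagonal flags")
    keep = ~np.asarray(matrix.diagonal_flags, dtype=bool)
    return BinnedMatrix(
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[:, keep],
        bin_definitions=[d for d, k in zip(matrix.bin_definitions, keep) if k],
        normalized=False,
        diagonal_flags=np.zeros(int(keep.sum()), dtype=bool),
    )


def _rect_centers(bin_definitions) -> np.ndarray:
    rects = np.asarray(bin_definitions, dtype=float)
    cf2 = 0.5 * (rects[:, 0] + rects[:, 1])
    cf1 = 0.5 * (rects[:, 2] + rects[:, 3])
    return np.column_stack([cf2, cf1])


def integrate_sections_2d(
    data,
    scheme: SectionScheme2D | None = None,
    exclude_diagonal: bool = False,
) -> pd.DataFrame:
    """Per-section intensity sums over a 2D binned matrix or raw COSY grid.

    A bin (or grid cell) belongs to a section when its center falls in any
    of the section's rectangles; intensity matching no section is reported
    under the explicit label ``"unassigned"``.
    """
    scheme = scheme or load_default_cosy_scheme()
    if isinstance(data, SpectrumCOSY):
        f2c, f1c = np.meshgrid(data.f2_shifts, data.f1_shifts)
        centers = np.column_stack([f2c.ravel(), f1c.ravel()])
        values = data.intensity_grid.reshape(1, -1)
        sample_ids = [data.sample_id]
        diag = None
    elif isinstance(data, BinnedMatrix):
        centers = _rect_centers(data.bin_definitions)
        values = data.values
        sample_ids = list(data.sample_ids)
        diag = data.diagonal_flags
    else:
        raise TypeError("expected a SpectrumCOSY or a 2D BinnedMatrix")

    if exclude_diagonal:
        if diag is None:
            raise ValueError("exclude_diagonal requires diagonal flags")
        keep = ~np.asarray(diag, dtype=bool)
        centers, values = centers[keep], values[:, keep]

    assigned = np.zeros(centers.shape[0], dtype=bool)
    out = {}
    for label, rects in scheme.sections.items():
        member = np.zeros(centers.shape[0], dtype=bool)
        for f2lo, f2hi, f1lo, f1hi in rects:
            member |= (
                (centers[:, 0] >= f2lo) & (centers[:, 0] < f2hi)
                & (centers[:, 1] >= f1lo) & (centers[:, 1] < f1hi)
            )
        assigned |= member
        out[label] = values[:, member].sum(axis=1)
    out["unassigned"] = values[:, ~assigned].sum(axis=1)
    return pd.DataFrame(out, index=sample_ids)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def assemble_data_matrix(binned, normalize: bool = True) -> BinnedMatrix:
    """Stack per-sample bin vectors; drop all-zero bins; optionally row-normalize.

    All vectors must share identical bin geometry.
    """
    binned = list(binned)
    if not binned:
        raise ValueError("no binned vectors supplied")
    ref = binned[0]
    for bv in binned[1:]:
        if len(bv.bin_definitions) != len(ref.bin_definitions) or not np.allclose(
            np.asarray(bv.bin_definitions, dtype=float),
            np.asarray(ref.bin_definitions, dtype=float),
        ):
            raise ValueError("mismatched bin geometries across samples")
    values = np.vstack([bv.values for bv in binned])
    nonzero = values.any(axis=0)
    values = values[:, nonzero]
    defs = [d for d, k in zip(ref.bin_definitions, nonzero) if k]
    flags = None
    if ref.diagonal_flags is not None:
        flags = np.asarray(ref.diagonal_flags, dtype=bool)[nonzero]
    if normalize:
        sums = values.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize a sample with zero total intensity")
        values = values / sums
    return BinnedMatrix(
        sample_ids=[bv.sample_id for bv in binned],
        values=values,
        bin_definitions=defs,
        normalized=normalize,
        diagonal_flags=flags,
    )
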