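"""Seeded synthetic river-to-coastal-ocean DOM transect datasets.

There is no public desk-scale benchmark coupling 1D 1H NMR, 2D COSY and
FT-ICR-MS observations of the same dissolved organic matter samples, so
this module generates one with the statistical structure the analysis
pipeline assumes:

* eight pooled samples (river RW, brackish BW1-BW4, coastal seawater SW,
  plus tidal-creek samples NT and ST) on a salinity gradient;
* 1D spectra whose aromatic section fraction decreases, and aliphatic
  fraction increases, monotonically with salinity;
* COSY grids whose intensity is dominated by the F1=F2 diagonal, with
  cross-peak richness increasing seaward and maximal in the tidal creek;
* a molecular-formula table with salinity-linked compound-group gradients
  and a sulfurized-aliphatic signal localized at a designated
  (mangrove-influenced) sample;
* per-sample metadata (salinity, DOC, d13C, BIX, HIX, I_SuP).

Every generator is deterministic for a fixed scenario seed, and the
bundle carries its ground truth (designed section fractions, group
multipliers, cross-peak counts) so downstream stages can be tested for
parameter recovery.

1D peaks are Lorentzian (the natural NMR lineshape).  2D COSY peaks are
compact Gaussians, emulating the apodized (sine-bell/Gaussian-windowed)
lineshapes of processed magnitude COSY spectra; compact 2D peaks are
what keeps diagonal intensity actually on the diagonal, as in real
processed spectra.  COSY peak centers are snapped to the centers of the
conventional 0.05 ppm bin grid so the designed diagonal/cross intensity
split is preserved by binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formulas import (
    FormulaTable,
    MolecularFormula,
    classify_compound_group,
    classify_sulfur_group,
    compute_descriptors,
)
from .nmr import DEFAULT_SOLVENT_REGIONS, Spectrum1D, SpectrumCOSY

__all__ = [
    "PeakSpec",
    "TransectScenario",
    "DatasetBundle",
    "default_grid_1d",
    "default_grid_cosy",
    "generate_formula_library",
    "generate_spectrum_1d",
    "generate_cosy",
    "generate_transect_bundle",
]

#: COSY bin size (ppm) whose bin-center grid peak positions are snapped to.
REFERENCE_BIN_SIZE_2D = 0.05


def default_grid_1d(spacing: float = 0.001) -> np.ndarray:
    """0-10 ppm at 0.001 ppm spacing by default."""
    return np.round(np.arange(0.0, 10.0 + spacing / 2, spacing), 6)


def default_grid_cosy(spacing: float = 0.02) -> np.ndarray:
    """0-10 ppm at 0.02 ppm spacing per COSY axis (desk-scale 2D grids)."""
    return np.round(np.arange(0.0, 10.0 + spacing / 2, spacing), 6)


@dataclass(frozen=True)
class PeakSpec:
    """One spectral peak: ppm center(s), half-width and integrated volume.

    For 1D peaks only ``center_f2`` is used; for COSY peaks ``center_f1``
    defaults to ``center_f2`` (a diagonal peak).
    """

    center_f2: float
    center_f1: float | None = None
    width: float = 0.01
    volume: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.volume < 0:
            raise ValueError("peak volume must be nonnegative")
        if self.center_f1 is None:
            object.__setattr__(self, "center_f1", self.center_f2)

    @property
    def is_diagonal(self) -> bool:
        return np.isclose(self.center_f1, self.center_f2)


@dataclass(frozen=True)
class TransectScenario:
    """Study conditions for one synthetic transect realization."""

    n_samples: int = 8
    sample_ids: tuple = ("RW", "BW1", "BW2", "BW3", "BW4", "SW", "NT", "ST")
    salinity_values: tuple = (0.0, 8.0, 16.0, 24.0, 30.0, 36.0, 20.0, 28.0)
    transect_indices: tuple = (0, 1, 2, 3, 4, 5)
    aromatic_fraction_endpoints: tuple = (0.09, 0.04)
    aliphatic_fraction_endpoints: tuple = (0.30, 0.37)
    olefinic_fraction_endpoints: tuple = (0.045, 0.022)
    sulfur_aliphatic_peak_sample: int = 6  # NT: mangrove tidal creek at low tide
    diagonal_intensity_fraction: float = 0.95
    noise_sd: float = 2.0
    #: per-sample chemical-shift variability (ppm, sd): the matrix/temperature
    #: effect that spectral binning is meant to compensate
    shift_jitter_sd: float = 0.003
    n_formulas: int = 1500
    grid_spacing_1d: float = 0.001
    grid_spacing_cosy: float = 0.02
    seed: int = 1

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if len(self.sample_ids) != self.n_samples or len(self.salinity_values) != self.n_samples:
            raise ValueError("sample_ids and salinity_values must match n_samples")
        for pair in (self.aromatic_fraction_endpoints, self.aliphatic_fraction_endpoints,
                     self.olefinic_fraction_endpoints):
            if not (0 <= pair[0] <= 1 and 0 <= pair[1] <= 1):
                raise ValueError("section fractions must lie in [0, 1]")
        if self.aromatic_fraction_endpoints[0] <= self.aromatic_fraction_endpoints[1]:
            raise ValueError("aromatic fraction must decrease river -> ocean")
        if self.aliphatic_fraction_endpoints[0] >= self.aliphatic_fraction_endpoints[1]:
            raise ValueError("aliphatic fraction must increase river -> ocean")
        sal = np.asarray(self.salinity_values)[list(self.transect_indices)]
        if not np.all(np.diff(sal) >= 0):
            raise ValueError("salinity must be nondecreasing along the transect subset")
        if not 0 < self.diagonal_intensity_fraction < 1:
            raise ValueError("diagonal_intensity_fraction must be in (0, 1)")
        if not 0 <= self.sulfur_aliphatic_peak_sample < self.n_samples:
            raise ValueError("sulfur_aliphatic_peak_sample out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_formulas < 1:
            raise ValueError("n_formulas must be positive")
        if self.grid_spacing_1d <= 0 or self.grid_spacing_cosy <= 0:
            raise ValueError("grid spacings must be positive")
        if self.shift_jitter_sd < 0:
            raise ValueError("shift_jitter_sd must be nonnegative")


@dataclass
class DatasetBundle:
    """All simulated data blocks plus the generator's ground truth."""

    spectra_1d: list
    spectra_cosy: list
    formula_table: FormulaTable
    metadata: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.spectra_1d]
        if [s.sample_id for s in self.spectra_cosy] != ids:
            raise ValueError("1D and COSY sample ids disagree")
        if self.formula_table.sample_ids != ids:
            raise ValueError("formula table sample ids disagree")
        if list(self.metadata.index) != ids:
            raise ValueError("metadata sample ids disagree")

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.spectra_1d]


# ---------------------------------------------------------------------------
# low-level peak synthesis
# ---------------------------------------------------------------------------

def generate_spectrum_1d(peaks, grid, noise_sd: float = 0.0, rng=None,
                         sample_id: str = "sim") -> Spectrum1D:
    """Sum of Lorentzian lineshapes plus optional Gaussian noise.

    Each peak integrates to its volume: V * (w/pi) / ((x-c)^2 + w^2).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > 10:
        raise ValueError("grid must lie within 0-10 ppm")
    intensity = np.zeros_like(grid)
    for pk in peaks:
        w = pk.width
        intensity += pk.volume * (w / np.pi) / ((grid - pk.center_f2) ** 2 + w**2)
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.shape)
    return Spectrum1D(sample_id, grid, intensity)


def _gauss(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def generate_cosy(peaks, grid, noise_sd: float = 0.0, rng=None,
                  sample_id: str = "sim") -> SpectrumCOSY:
    """2D Gaussian peaks on a square grid; off-diagonal peaks are mirrored.

    The noiseless grid is exactly symmetric under F1/F2 exchange.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    intensity = np.zeros((grid.size, grid.size))
    for pk in peaks:
        g2 = _gauss(grid, pk.center_f2, pk.width)
        g1 = _gauss(grid, pk.center_f1, pk.width)
        intensity += pk.volume * np.outer(g1, g2)
        if not pk.is_diagonal:
            intensity += pk.volume * np.outer(g2, g1)
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    return SpectrumCOSY(sample_id, grid, grid.copy(), intensity)


def _snap_to_bin_center(x: float, bin_size: float = REFERENCE_BIN_SIZE_2D) -> float:
    return float(np.floor(x / bin_size) * bin_size + bin_size / 2.0)


# ---------------------------------------------------------------------------
# molecular-formula library
# ---------------------------------------------------------------------------

_STRATA = {
    # stratum -> (target fraction of library, (hc_lo, hc_hi), (oc_lo, oc_hi), sulfur)
    "saturated": (0.02, None, None, False),
    "saccharide": (0.03, (1.72, 2.08), (0.72, 0.98), False),
    "unsaturated": (0.12, (1.52, 1.98), (0.05, 0.60), False),
    "highly_unsaturated": (0.43, (0.72, 1.44), (0.10, 0.65), False),
    "aromatic": (0.12, (0.50, 1.00), (0.02, 0.40), False),
    "PAC": (0.08, (0.30, 0.62), (0.00, 0.20), False),
    "dissolved_black_sulfur": (0.07, (0.32, 0.58), (0.02, 0.28), True),
    "highly_unsaturated_S": (0.07, (0.63, 0.97), (0.02, 0.28), True),
    "sulfurized_aliphatic": (0.06, (1.04, 1.46), (0.42, 0.68), True),
}

_SULFUR_STRATA = ("dissolved_black_sulfur", "highly_unsaturated_S", "sulfurized_aliphatic")


def _draw_formula(stratum: str, rng: np.random.Generator) -> MolecularFormula | None:
    _, hc_box, oc_box, wants_sulfur = _STRATA[stratum]
    if stratum == "saturated":
        c = int(rng.integers(10, 30))  # C >= 10 keeps H/C = 2 + 2/C within 2.2
        return MolecularFormula(c=c, h=2 * c + 2, o=int(rng.integers(0, 4)))
    c = int(rng.integers(8, 36))
    hc = rng.uniform(*hc_box)
    oc = rng.uniform(*oc_box)
    h = 2 * int(round(hc * c / 2.0))
    o = int(round(oc * c))
    s = int(rng.integers(1, 3)) if wants_sulfur else 0
    n = int(rng.integers(1, 3)) if (not wants_sulfur and rng.random() < 0.15) else 0
    p = 1 if (not wants_sulfur and rng.random() < 0.04) else 0
    if h < 1 or c < 1:
        return None
    f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
    d = compute_descriptors(f)
    if not (0.3 <= d.h_to_c <= 2.2 and 0.0 <= d.o_to_c <= 1.0):  # library span
        return None
    if wants_sulfur:
        return f if classify_sulfur_group(d) == stratum else None
    return f if classify_compound_group(d) == stratum else None


def generate_formula_library(n_formulas: int, seed: int) -> list[MolecularFormula]:
    """Stratified, seeded van Krevelen library covering every compound
    group and all three sulfur boxes."""
    if n_formulas < 1:
        raise ValueError("n_formulas must be positive")
    rng = np.random.default_rng(seed)
    strata = list(_STRATA)
    quotas = {s: max(1, int(round(_STRATA[s][0] * n_formulas))) for s in strata}
    # trim/extend to exactly n_formulas using the dominant stratum
    diff = n_formulas - sum(quotas.values())
    quotas["highly_unsaturated"] = max(1, quotas["highly_unsaturated"] + diff)
    if sum(quotas.values()) != n_formulas:  # n too small for all strata
        order = sorted(strata, key=lambda s: -_STRATA[s][0])
        quotas = {s: 0 for s in strata}
        for i in range(n_formulas):
            quotas[order[i % len(order)]] += 1
    library: list[MolecularFormula] = []
    seen: set = set()
    for stratum in strata:
        needed = quotas[stratum]
        attempts = 0
        while needed > 0:
            attempts += 1
            if attempts > 10000 * quotas[stratum] + 10000:
                raise RuntimeError(f"could not populate stratum {stratum!r}")
            f = _draw_formula(stratum, rng)
            if f is None or str(f) in seen:
                continue
            seen.add(str(f))
            library.append(f)
            needed -= 1
    return library


# ---------------------------------------------------------------------------
# transect bundle
# ---------------------------------------------------------------------------

#: Peak positions (ppm) per 1D section, placed away from section edges and
#: the solvent regions so Lorentzian tails stay (almost) within section.
_SECTION_PEAK_POSITIONS = {
    "aliphatic": (0.35, 0.70, 1.00, 1.30, 1.60),
    "acetyl": (2.05, 2.15),
    "alpha_carbonyl": (2.50, 2.70, 2.85),
    "alpha_oxygen": (3.60, 3.85, 4.10, 4.45),
    "olefinic": (5.70, 6.05),
    "aromatic": (6.90, 7.30, 7.80, 8.30),
}

#: COSY cross-peak candidate regions: (f2 interval, f1 interval) pairs of
#: plausible coupled-proton shifts (mirrors are added at generation time).
_CROSS_REGIONS = (
    ((0.6, 1.05), (1.05, 1.9)),
    ((1.05, 1.9), (1.9, 2.3)),
    ((1.05, 1.9), (2.3, 3.0)),
    ((0.6, 1.05), (2.3, 3.0)),
    ((0.6, 1.05), (3.0, 4.3)),
    ((1.05, 1.9), (3.0, 4.3)),
    ((3.0, 4.3), (4.3, 5.3)),
    ((1.05, 1.9), (5.3, 6.5)),
    ((3.0, 4.3), (3.0, 4.3)),
    ((5.3, 6.5), (6.5, 7.3)),
    ((6.5, 7.3), (7.3, 8.4)),
    ((7.3, 8.4), (8.4, 10.0)),
    ((1.9, 2.3), (6.5, 7.3)),
    ((2.3, 3.0), (6.5, 7.3)),
)

_GROUP_TREND = {
    # multiplier endpoints river -> ocean for compound groups
    "saturated": -0.60,
    "saccharide": -0.60,
    "unsaturated": +0.30,
    "highly_unsaturated": +0.20,
    "aromatic": -0.50,
    "PAC": -0.75,
    "other": 0.0,
}

_SULFUR_TREND = {
    "dissolved_black_sulfur": -0.90,  # ~90% decline river -> ocean
    "highly_unsaturated_S": +1.00,    # ~doubles river -> ocean
}


def _section_fractions(scenario: TransectScenario) -> pd.DataFrame:
    sal = np.asarray(scenario.salinity_values, dtype=float)
    tr = list(scenario.transect_indices)
    lo, hi = sal[tr[0]], sal[tr[-1]]
    t = np.clip((sal - lo) / (hi - lo), 0.0, 1.0)
    arom = np.interp(t, [0, 1], scenario.aromatic_fraction_endpoints)
    ali = np.interp(t, [0, 1], scenario.aliphatic_fraction_endpoints)
    olef = np.interp(t, [0, 1], scenario.olefinic_fraction_endpoints)
    remainder = 1.0 - (arom + ali + olef)
    w_acetyl = 0.17 + 0.02 * t
    w_carbonyl = 0.28 + 0.03 * t
    w_oxygen = 0.55 - 0.05 * t
    wsum = w_acetyl + w_carbonyl + w_oxygen
    frame = pd.DataFrame(
        {
            "aliphatic": ali,
            "acetyl": remainder * w_acetyl / wsum,
            "alpha_carbonyl": remainder * w_carbonyl / wsum,
            "alpha_oxygen": remainder * w_oxygen / wsum,
            "olefinic": olef,
            "aromatic": arom,
        },
        index=list(scenario.sample_ids),
    )
    return 100.0 * frame


def _cross_peak_counts(scenario: TransectScenario, t: np.ndarray) -> np.ndarray:
    counts = np.round(30 + 60 * t).astype(int)
    for idx in range(scenario.n_samples):
        if idx not in scenario.transect_indices:
            counts[idx] = 130 + 10 * (idx - min(
                i for i in range(scenario.n_samples) if i not in scenario.transect_indices
            ))
    return counts


#: Cross-peak abundance trends along the salinity gradient: terrestrial
#: motifs decline seaward, marine motifs increase, creek motifs are
#: enriched in the tidal-creek samples.
_CROSS_TRENDS = (("terrestrial", -0.6), ("marine", +0.6), ("creek", 0.0), ("neutral", 0.0))
_CROSS_TREND_P = (0.30, 0.30, 0.15, 0.25)


def _build_cross_library(rng: np.random.Generator, size: int = 200) -> list[dict]:
    """Candidate cross peaks: snapped position, base volume, trend type."""
    pts, seen = [], set()
    while len(pts) < size:
        f2box, f1box = _CROSS_REGIONS[int(rng.integers(0, len(_CROSS_REGIONS)))]
        c2 = _snap_to_bin_center(rng.uniform(*f2box))
        c1 = _snap_to_bin_center(rng.uniform(*f1box))
        if abs(c1 - c2) < 0.15 or (c2, c1) in seen:
            continue
        seen.add((c2, c1))
        trend = _CROSS_TRENDS[int(rng.choice(len(_CROSS_TRENDS), p=_CROSS_TREND_P))]
        pts.append(
            {
                "center_f2": c2,
                "center_f1": c1,
                "base_volume": float(rng.lognormal(mean=0.0, sigma=1.0)),
                "trend": trend[0],
                "slope": trend[1],
            }
        )
    return pts


def _cross_volume(peak: dict, t_sample: float, is_creek: bool) -> float:
    v = peak["base_volume"] * (1.0 + peak["slope"] * t_sample)
    if peak["trend"] == "creek":
        v *= 3.0 if is_creek else 1.0
    return max(v, 0.0)


def _metadata(scenario: TransectScenario, t: np.ndarray) -> pd.DataFrame:
    ids = list(scenario.sample_ids)
    creek = [i for i in range(scenario.n_samples) if i not in scenario.transect_indices]
    doc = 350.0 - 250.0 * t
    isup = 0.3 + 0.1 * t
    for rank, idx in enumerate(creek):
        doc[idx] += 60.0
        isup[idx] = 1.5 - 0.2 * rank
    return pd.DataFrame(
        {
            "salinity": np.asarray(scenario.salinity_values, dtype=float),
            "doc": doc,
            "d13c": -29.0 + 6.0 * t,
            "bix": 0.5 + 0.4 * t,
            "hix": 12.0 - 8.0 * t,
            "isup": isup,
        },
        index=ids,
    )


def generate_transect_bundle(scenario: TransectScenario | None = None) -> DatasetBundle:
    """Generate the full synthetic bundle for one scenario (seeded)."""
    scenario = scenario or TransectScenario()
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    ids = list(scenario.sample_ids)
    sal = np.asarray(scenario.salinity_values, dtype=float)
    tr = list(scenario.transect_indices)
    t = np.clip((sal - sal[tr[0]]) / (sal[tr[-1]] - sal[tr[0]]), 0.0, 1.0)

    fractions = _section_fractions(scenario)  # percent
    grid1d = default_grid_1d(scenario.grid_spacing_1d)
    grid2d = default_grid_cosy(scenario.grid_spacing_cosy)
    total_volume = 1000.0

    def jitter() -> float:
        # per-sample chemical-shift fluctuation, clipped to 2.5 sd so peaks
        # stay inside their reference 0.05 ppm bin
        if scenario.shift_jitter_sd == 0:
            return 0.0
        j = rng.normal(0.0, scenario.shift_jitter_sd)
        return float(np.clip(j, -2.5 * scenario.shift_jitter_sd, 2.5 * scenario.shift_jitter_sd))

    # --- 1D spectra -------------------------------------------------------
    spectra_1d = []
    for i, sid in enumerate(ids):
        peaks = []
        for section, positions in _SECTION_PEAK_POSITIONS.items():
            vol = total_volume * fractions.loc[sid, section] / 100.0 / len(positions)
            peaks.extend(
                PeakSpec(center_f2=c + jitter(), width=0.01, volume=vol) for c in positions
            )
        spectra_1d.append(
            generate_spectrum_1d(peaks, grid1d, scenario.noise_sd, rng, sample_id=sid)
        )

    # --- COSY spectra -----------------------------------------------------
    cross_library = _build_cross_library(rng)
    counts = _cross_peak_counts(scenario, t)
    sigma2d = 0.007
    diag_positions = [
        _snap_to_bin_center(c)
        for positions in _SECTION_PEAK_POSITIONS.values()
        for c in positions
    ]
    spectra_cosy = []
    f = scenario.diagonal_intensity_fraction
    for i, sid in enumerate(ids):
        diag_peaks = []
        for section, positions in _SECTION_PEAK_POSITIONS.items():
            vol = total_volume * f * fractions.loc[sid, section] / 100.0 / len(positions)
            # diagonal peaks jitter along the diagonal (same shift on both axes)
            diag_peaks.extend(
                PeakSpec(center_f2=_snap_to_bin_center(c) + jitter(), width=sigma2d, volume=vol)
                for c in positions
            )
        n_cross = int(counts[i])
        is_creek = i not in scenario.transect_indices
        cross_vols = np.array(
            [_cross_volume(pk, t[i], is_creek) for pk in cross_library[:n_cross]]
        )
        if scenario.noise_sd > 0:
            cross_vols = cross_vols * np.exp(0.10 * rng.normal(size=n_cross))
        cross_vols *= total_volume * (1.0 - f) / cross_vols.sum()
        cross_peaks = [
            PeakSpec(center_f2=pk["center_f2"] + jitter(),
                     center_f1=pk["center_f1"] + jitter(),
                     width=sigma2d, volume=v / 2.0)
            for pk, v in zip(cross_library[:n_cross], cross_vols)
        ]
        diag_grid = generate_cosy(diag_peaks, grid2d, 0.0, sample_id=sid)
        cross_grid = generate_cosy(cross_peaks, grid2d, 0.0, sample_id=sid)
        s_diag = diag_grid.intensity_grid.sum()
        s_cross = cross_grid.intensity_grid.sum()
        # rescale so the realized on-grid diagonal fraction equals the target
        if s_cross > 0:
            cross_grid.intensity_grid *= s_diag * (1.0 - f) / (f * s_cross)
        grid = diag_grid.intensity_grid + cross_grid.intensity_grid
        if scenario.noise_sd > 0:
            grid = grid + rng.normal(0.0, scenario.noise_sd, size=grid.shape)
        spectra_cosy.append(SpectrumCOSY(sid, grid2d.copy(), grid2d.copy(), grid))

    # --- formula table ----------------------------------------------------
    library = generate_formula_library(scenario.n_formulas, int(rng.integers(0, 2**31 - 1)))
    groups, sulfur_groups = [], []
    for fml in library:
        d = compute_descriptors(fml)
        groups.append(classify_compound_group(d))
        sulfur_groups.append(classify_sulfur_group(d))
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(library))

    mult = np.ones((len(library), scenario.n_samples))
    for j in range(scenario.n_samples):
        is_creek = j not in scenario.transect_indices
        for k, (g, sg) in enumerate(zip(groups, sulfur_groups)):
            m = 1.0 + _GROUP_TREND.get(g, 0.0) * t[j]
            if sg in _SULFUR_TREND:
                m *= 1.0 + _SULFUR_TREND[sg] * t[j]
            if sg == "sulfurized_aliphatic":
                # porewater sulfurization marks both tidal-creek samples,
                # strongest at the designated peak sample
                if j == scenario.sulfur_aliphatic_peak_sample:
                    m *= 3.0
                elif is_creek:
                    m *= 2.0
            mult[k, j] = m

    # presence by detection-limit censoring: each sample detects its top
    # fraction of formulas ranked by (abundance x detection variability), so
    # formula richness declines seaward in a gradient-correlated way rather
    # than by independent dropout
    detected_fraction = np.where(
        [i in scenario.transect_indices for i in range(scenario.n_samples)],
        0.95 - 0.30 * t,
        0.97,
    )
    intens = base[:, None] * mult
    if scenario.noise_sd > 0:
        intens = intens * np.exp(0.05 * rng.normal(size=intens.shape))
        detect_score = intens * np.exp(0.5 * rng.normal(size=intens.shape))
    else:
        detect_score = intens
    thresholds = np.quantile(detect_score, 1.0 - detected_fraction, axis=0).diagonal()
    intens = np.where(detect_score > thresholds[None, :], intens, 0.0)
    table = FormulaTable(library, pd.DataFrame(intens, columns=ids))

    metadata = _metadata(scenario, t)
    ground_truth = {
        "section_fractions": fractions,
        "cross_peak_counts": pd.Series(counts, index=ids),
        "group_multipliers": pd.DataFrame(mult, index=[str(f) for f in library], columns=ids),
        "diagonal_intensity_fraction": f,
        "transect_order": [ids[i] for i in tr],
        "solvent_regions": DEFAULT_SOLVENT_REGIONS,
    }
    return DatasetBundle(spectra_1d, spectra_cosy, table, metadata, ground_truth)
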