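# Methods

## Scope and data model

`domtransect` analyses three coupled observations of the same set of
solid-phase-extracted DOM samples: 1D ¹H NMR spectra (chemical shift δ_H in
ppm vs intensity), 2D ¹H,¹H COSY spectra (intensity grids over two ppm axes),
and FT-ICR-MS molecular-formula tables (CHNOSP formulas × per-sample relative
intensities), plus per-sample covariates (salinity, DOC, δ¹³C, fluorescence
indices BIX and HIX, and a porewater-sulfurization index I_SuP). Only the
0–10 ppm region of the spectra is analysed.

## NMR processing

1. **Resampling** (optional, `resample_to_grid`): linear interpolation onto a
   common grid; integrals of smooth spectra are preserved to well under 1%.
2. **Solvent excision**: data points inside 4.70–5.05 ppm (residual HDO) and
   3.20–3.45 ppm (CH₃OH) are removed from 1D spectra. COSY grids are not
   excised; they pass a signal-to-noise filter instead.
3. **Section integration**: trapezoidal integrals over six contiguous 1D
   sections — aliphatic 0.0–1.9, acetyl 1.9–2.3, α-carbonyl 2.3–3.0,
   α-oxygen 3.0–5.3, olefinic 5.3–6.5, aromatic 6.5–10.0 ppm — normalized to
   percent of their sum (sums to 100 by construction). An all-zero spectrum
   raises rather than returning undefined fractions.
4. **SNR filter (COSY)**: grid cells below `cutoff × σ` are zeroed
   (default cutoff 3). σ defaults to the scaled median absolute deviation of
   the whole grid (1.4826 × MAD), a robust estimate because DOM COSY grids
   are noise-dominated cell-wise.
5. **Binning**: equal-width bins covering the window; membership is half-open
   `[low, high)` with the last bin closed, so bin counts are exact
   (0.05 ppm ⇒ 200 bins per axis ⇒ 40,000 COSY bins) and total in-window
   intensity is conserved exactly. 2D bins carry a diagonal flag when their
   rectangle has a positive-length intersection with F1 = F2 (for equal
   square tilings: the bins with equal row and column index; an optional
   width parameter extends the flagged band by ±k bins, default 0).
6. **Matrix assembly**: bins with zero intensity in every sample are dropped;
   rows are total-sum normalized (the natural choice ahead of Bray–Curtis,
   which operates on compositions).

Diagonal handling: the ordinations use the full binned COSY matrix — the
diagonal carries the bulk (1D-like) composition. The diagonal-stripped matrix
feeds the Shannon-diversity computation and the dissimilarity reanalysis,
where the diagonal's dominance would otherwise mask cross-peak structure.

The 19-section COSY structural-motif scheme (labels a–s: cyclopropyl,
methyl, intra-aliphatic, heteroatom-adjacent alkyls, alkoxy and diol
motifs, anomeric and acetal protons, olefins, aromatic families and PACs)
ships as an editable YAML file of labelled rectangles
(`data/cosy_sections.yaml`). The shipped boundaries are approximate,
assembled from common ¹H shift ranges for those motifs; users with a
calibrated scheme should supply their own file. Bins whose centers fall in
no rectangle are reported under an explicit `unassigned` label, never
silently dropped.

## Bin-size optimization

For each candidate bin size, all spectra are binned, assembled and
normalized, and the mean of the n(n−1)/2 pairwise Bray–Curtis
dissimilarities is recorded against the resulting number of bins. The curve
is summarized by a least-squares fit of *y = a·ln(n_bins) + b* (R² = squared
Pearson correlation of fitted vs observed). The knee is the exhaustive
two-segment least-squares breakpoint: every interior candidate splits the
points into left and right subsets (the candidate belongs to both), each
side gets a straight-line fit, and the candidate with minimal summed squared
residuals wins; ties go to the smaller abscissa, and near-constant residual
profiles (e.g. exactly linear input) are flagged ambiguous. The default
sweep grid is geometric with 15 points. The generic utility spans
0.01–1 ppm; the pipeline floors the sweep at the COSY grid spacing
(0.02 ppm for synthetic grids) because bins finer than the digital
resolution are degenerate — one cell per bin — and only flatten the tail of
the curve.

## Molecular-formula classification

Descriptors: H/C, O/C, DBE = 1 + C − H/2 + N/2 + P/2, and the modified
aromaticity index AI_mod = (1 + C − O/2 − S − H/2)/(C − O/2 − S − N − P),
clamped to 0 when the numerator or denominator is ≤ 0 (such formulas cannot
be aromatic). Compound-group thresholds: saturated DBE = 0; saccharide
O/C ≥ 0.7 and 1.7 ≤ H/C < 2.2; unsaturated 1.5 ≤ H/C ≤ 2.0; highly
unsaturated AI_mod ≤ 0.50 and H/C < 1.5; aromatic 0.5 < AI_mod ≤ 0.67;
PAC AI_mod > 0.67. The rules overlap (glucose matches both the saccharide
and unsaturated rules), so evaluation order is explicit and configurable:
saturated → saccharide → unsaturated → PAC → aromatic → highly unsaturated
→ other. Sulfur groups use strict van Krevelen boxes — dissolved black
sulfur H/C < 0.6 and O/C < 0.3; highly unsaturated S 0.6 < H/C < 1.0 and
O/C < 0.3; sulfurized aliphatic 1.0 < H/C < 1.5 and 0.4 < O/C < 0.7 —
sulfur formulas on a boundary or outside all boxes go to `other_S` rather
than being forced into a box. Group abundances are percentages of total
per-sample intensity (summing to 100 with the residual label included), and
intensity-weighted parameters are Σwᵢdᵢ/Σwᵢ with intensities as weights.

## Diversity and dissimilarity

Richness counts strictly positive entries (any noise floor must be applied
upstream by the SNR filter). Shannon diversity is −Σ pᵢ log₂ pᵢ in bits over
relative intensities, with 0·log 0 := 0; an exclusion mask (used for the
COSY diagonal) removes entries before the proportions are formed.
Bray–Curtis dissimilarity BC = Σ|x−y|/Σ(x+y) is computed with scipy and
returned as a `skbio.DistanceMatrix`.

## Ordination and two-block integration

**PCoA** is classical scaling implemented directly: Gower centering of
−D²/2, symmetric eigendecomposition, scores = eigenvectors × √eigenvalue.
Proportions of explained variance are taken over positive eigenvalues only;
negative eigenvalues (possible for Bray–Curtis) are reported separately with
no Cailliez/Lingoes correction.

**Vector fitting** regresses each covariate on the centered first two score
columns; the fitted direction is the normalized coefficient vector and R²
the coefficient of determination. Significance comes from permuting the
covariate's values with a seeded generator and the add-one convention
p = (1 + #{r²_perm ≥ r²_obs})/(1 + N), N = 9,999 by default (floor 10⁻⁴).
Both r = √R² and the signed correlation of the covariate with the projection
onto the fitted direction are reported, along with display tiers at
p < 0.05 / 0.10 / 0.15 (report categories, not filters). Missing values are
excluded pairwise; constant covariates are flagged, not fitted.

**Spearman maps**: per formula, ρ of intensity vs covariate with midranks
for ties. For n ≤ 8 samples the two-sided p-value is exact — the proportion
of all n! covariate rank orders with |ρ| at least the observed — because
asymptotic approximations are invalid at pooled-transect sample sizes;
larger n falls back to the asymptotic p. Formulas above the threshold
(default p ≤ 0.1) are flagged, not removed, and every formula carries its
H/C–O/C coordinates and group labels for van Krevelen display.

**CCorA**: canonical correlations are the singular values of Qx′Qy, where
Qx, Qy are orthonormal bases of the column-centered blocks (rank-deficient
blocks are truncated with a warning); Pillai's trace is the sum of squared
canonical correlations, tested by permuting rows of the second block
(default 719 permutations, add-one p). The pipeline feeds in the first two
principal coordinates of the NMR- and MS-based ordinations.

## Synthetic transect generator

The generator emulates a pooled eight-sample mangrove-fringed
river-to-coastal-ocean data set: RW (river), BW1–BW4 (brackish), SW
(seawater) along a 0–36 PSU salinity gradient, plus NT and ST (tidal-creek,
mangrove porewater influenced). Designed structure:

* 1D section fractions interpolate linearly in salinity between river and
  ocean endpoints — aliphatic 30→37%, aromatic 9→4%, olefinic 4.5→2.2%,
  with the remainder split among acetyl/α-carbonyl/α-oxygen with mild
  counter-trends. Peaks are Lorentzian (HWHM 0.01 ppm) at fixed positions
  well inside their sections and away from the solvent regions, so the
  designed fractions are recoverable within 2 percentage points from
  noiseless data.
* COSY grids put a scenario-set fraction (default 0.95) of total intensity
  on the diagonal. 2D peaks are compact Gaussians (σ = 0.007 ppm), the
  realistic shape after sine-bell/Gaussian apodization of magnitude COSY —
  with Lorentzian tails a diagonal peak would leave a large share of its
  intensity in off-diagonal bins, which processed spectra do not show. Peak
  centers are snapped to the 0.05-ppm bin-center grid and the cross-peak
  component is rescaled so the realized on-grid diagonal fraction equals the
  scenario value exactly. Cross peaks come from a library of plausible
  coupled-shift pairs with terrestrial / marine / creek / neutral abundance
  trends; per-sample cross-peak counts grow seaward and are maximal in the
  tidal creek, giving the designed richness ordering.
* Every peak position receives a per-sample chemical-shift jitter
  (sd 0.003 ppm, clipped at 2.5 sd) — the temperature/matrix variability
  that binning exists to compensate. Without it the dissimilarity-vs-bins
  curve saturates; with it the sweep shows the expected logarithmic shape
  (R² ≈ 0.94) with a knee near 0.1 ppm. The clip keeps peaks inside their
  reference 0.05-ppm bins so the diagonal-fraction contract survives binning.
* The formula library is sampled stratified over van Krevelen boxes so every
  compound group and each sulfur box is populated. Per-sample intensities are
  lognormal base abundances times group trend multipliers (aromatic and PAC
  declining seaward, unsaturated/highly unsaturated increasing, dissolved
  black sulfur −90%, highly unsaturated S +100%, sulfurized aliphatics ×3 at
  the designated mangrove sample and ×2 at the other tidal-creek sample,
  mirroring the porewater-influence pattern of the I_SuP covariate).
  Presence/absence arises by detection-limit censoring: each sample retains
  its top fraction of formulas ranked by intensity times a lognormal
  detection factor (river 95%, seawater 65%, creek 97% of 1,500), so
  richness declines seaward in a gradient-correlated way — the mechanism by
  which formulas actually drop out of FT-ICR-MS spectra — rather than by
  independent dropout. Because group percentages are compositional, realized
  relative-abundance ratios are damped relative to the raw multipliers.
* Additive Gaussian noise (default sd 2.0 intensity units against cross-peak
  heights of order 10²–10³) exercises the SNR-3 filter meaningfully;
  `noise_sd = 0` gives exactly reproducible noiseless data for recovery
  tests. Everything is driven by one `numpy` generator seeded from the
  scenario, so identical scenarios are bit-identical.

What the generator does **not** emulate: FID acquisition, phasing or
apodization artifacts, J-coupling multiplet structure, isotopologue fine
structure, ionization bias, or peak-shape heterogeneity. Passing tests
therefore demonstrate that the statistical machinery recovers designed
compositional structure from data with the right gross geometry — not that
the pipeline is robust to every artifact of real spectrometers.

## Problem sizes and numerics

Default desk-scale sizes: 1D grids 0–10 ppm at 0.001 ppm (10,001 points),
COSY grids at 0.02 ppm (501 × 501), 8 samples, 1,500 formulas, sweep of 15
geometric bin sizes, 9,999 envfit and 719 CCorA permutations. The full
pipeline runs in well under a minute on one core. Numerical conventions:
eigenvalues below 10⁻¹⁰ × the spectral radius are treated as zero in PCoA;
permutation exceedance counts use a 10⁻¹² slack so ties at the observed
statistic count as exceeding; knee ambiguity uses a 10⁻⁹ relative residual
band; exact Spearman enumeration is chunked to bound memory at n = 8
(40,320 permutations). Degenerate inputs (all-zero spectra or samples,
constant covariates, rank-deficient CCorA blocks, single-sample sweeps) are
signalled explicitly rather than silently propagated.

## Known limitations

* The shipped COSY section rectangles are approximate; quantitative use of
  section labels requires a calibrated scheme.
* Exact Spearman p-values are limited to n ≤ 8 (factorial growth); the
  asymptotic fallback is poor for n = 9–12.
* PCoA applies no correction for negative eigenvalues; with strongly
  non-Euclidean dissimilarities the reported proportions refer to the
  positive part of the spectrum only.
* With n = 8 samples, permutation tests have a limited attainable floor
  (1/720 for 719 permutations) and modest power; this mirrors the design
  constraints of pooled-transect studies rather than a software limit.
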