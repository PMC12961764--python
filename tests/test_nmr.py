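import numpy as np
import pytest

from domtransect import nmr
from domtransect.nmr import (
    BinnedMatrix,
    SectionScheme2D,
    Spectrum1D,
    SpectrumCOSY,
    assemble_data_matrix,
    bin_1d,
    bin_2d,
    excise_regions,
    integrate_sections_1d,
    integrate_sections_2d,
    load_default_cosy_scheme,
    resample_to_grid,
    snr_filter_2d,
    strip_diagonal,
)
from domtransect.synthetic import PeakSpec, generate_spectrum_1d


def lorentzian_spectrum(center=5.0, width=0.01, volume=1.0, spacing=0.001):
    grid = np.arange(0.0, 10.0 + spacing / 2, spacing)
    return generate_spectrum_1d([PeakSpec(center, width=width, volume=volume)], grid)


class TestResample:
    def test_identity_grid(self):
        s = lorentzian_spectrum()
        out = resample_to_grid(s, s.shifts)
        assert np.array_equal(out.intensities, s.intensities)

    def test_linear_ramp_interpolates_exactly(self):
        grid = np.linspace(0, 10, 1001)
        s = Spectrum1D("ramp", grid, 3.0 * grid + 1.0)
        target = np.linspace(0.005, 9.995, 100)
        out = resample_to_grid(s, target)
        assert np.allclose(out.intensities, 3.0 * target + 1.0)

    def test_integral_preserved_on_coarser_grid(self):
        s = lorentzian_spectrum(center=5.0)
        coarse = resample_to_grid(s, s.shifts[::2])
        orig = np.trapezoid(s.intensities, s.shifts)
        new = np.trapezoid(coarse.intensities, coarse.shifts)
        assert new == pytest.approx(orig, rel=0.01)

    def test_target_outside_range_rejected(self):
        s = Spectrum1D("x", np.linspace(1, 9, 100), np.zeros(100))
        with pytest.raises(ValueError):
            resample_to_grid(s, np.linspace(0, 10, 50))


class TestExcise:
    def test_water_region_peak_removed(self):
        s = lorentzian_spectrum(center=4.9)
        out = excise_regions(s)
        mask = (out.shifts >= 4.70) & (out.shifts <= 5.05)
        assert mask.sum() == 0

    def test_peak_outside_regions_intact(self):
        s = lorentzian_spectrum(center=1.0)
        out = excise_regions(s)
        keep = (s.shifts < 3.20) | (s.shifts > 3.45)
        keep &= (s.shifts < 4.70) | (s.shifts > 5.05)
        assert np.array_equal(out.intensities, s.intensities[keep])
        assert out.intensities.max() == s.intensities.max()

    def test_empty_region_list_is_identity(self):
        s = lorentzian_spectrum()
        out = excise_regions(s, regions=())
        assert np.array_equal(out.shifts, s.shifts)
        assert np.array_equal(out.intensities, s.intensities)


class TestSectionIntegration1D:
    def test_single_peak_is_pure_aliphatic(self):
        fr = integrate_sections_1d(lorentzian_spectrum(center=1.0))
        assert fr["aliphatic"] == pytest.approx(100.0, abs=0.5)
        assert fr.drop("aliphatic").max() < 0.5

    def test_equal_peaks_split_fifty_fifty(self):
        grid = np.arange(0.0, 10.0005, 0.001)
        s = generate_spectrum_1d(
            [PeakSpec(1.0, width=0.01, volume=1.0), PeakSpec(7.0, width=0.01, volume=1.0)],
            grid,
        )
        fr = integrate_sections_1d(s)
        assert fr["aliphatic"] == pytest.approx(50.0, abs=0.5)
        assert fr["aromatic"] == pytest.approx(50.0, abs=0.5)

    def test_fractions_sum_to_hundred(self, bundle):
        for s in bundle.spectra_1d:
            fr = integrate_sections_1d(excise_regions(s))
            assert fr.sum() == pytest.approx(100.0, abs=0.1)

    def test_all_zero_spectrum_signalled(self):
        s = Spectrum1D("z", np.linspace(0, 10, 100), np.zeros(100))
        with pytest.raises(ValueError, match="undefined"):
            integrate_sections_1d(s)


class TestBin1D:
    def test_bin_count_for_default_size(self):
        bv = bin_1d(lorentzian_spectrum(), 0.10)
        assert len(bv.bin_definitions) == 100

    def test_total_intensity_conserved_exactly(self):
        s = lorentzian_spectrum(center=3.3)
        bv = bin_1d(s, 0.17)
        assert bv.values.sum() == pytest.approx(s.intensities.sum(), rel=1e-12)

    def test_point_mass_lands_in_first_bin(self):
        shifts = np.array([0.05, 5.0])
        s = Spectrum1D("pm", shifts, np.array([7.0, 0.0]))
        bv = bin_1d(s, 0.10)
        assert bv.values[0] == pytest.approx(7.0)
        assert bv.values[1:].sum() == 0.0

    def test_nonpositive_bin_size_rejected(self):
        with pytest.raises(ValueError):
            bin_1d(lorentzian_spectrum(), 0.0)


class TestSNRFilter:
    def test_pure_noise_mostly_zeroed(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(0, 10, 400)
        c = SpectrumCOSY("n", grid, grid, rng.normal(0, 1.0, (400, 400)))
        out = snr_filter_2d(c, cutoff=3.0)
        # one-sided Gaussian tail beyond 3 sigma is ~0.135%
        assert (out.intensity_grid == 0).mean() >= 0.99

    def test_strong_cell_survives(self):
        grid = np.linspace(0, 10, 50)
        g = np.zeros((50, 50))
        g[10, 20] = 10.0
        c = SpectrumCOSY("s", grid, grid, g)
        out = snr_filter_2d(c, cutoff=3.0, noise_estimate=1.0)
        assert out.intensity_grid[10, 20] == 10.0

    def test_vacuous_cutoff_keeps_positive_cells(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(0, 10, 100)
        g = np.abs(rng.normal(0, 1.0, (100, 100))) + 0.5
        c = SpectrumCOSY("v", grid, grid, g)
        out = snr_filter_2d(c, cutoff=1e-4)
        assert np.array_equal(out.intensity_grid, g)

    def test_nonpositive_cutoff_rejected(self):
        grid = np.linspace(0, 10, 10)
        c = SpectrumCOSY("x", grid, grid, np.ones((10, 10)))
        with pytest.raises(ValueError):
            snr_filter_2d(c, cutoff=0.0)


def square_cosy(n=101, fill=0.0):
    grid = np.linspace(0, 10, n)
    return SpectrumCOSY("sq", grid, grid, np.full((n, n), fill))


class TestBin2D:
    def test_bin_count_40000_at_0p05(self):
        bv = bin_2d(square_cosy(), 0.05)
        assert len(bv.bin_definitions) == 40_000

    def test_coarse_bins_and_diagonal_flags(self):
        bv = bin_2d(square_cosy(), 1.0)
        assert len(bv.bin_definitions) == 100
        assert bv.diagonal_flags.sum() == 10

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(0, 10, 97)
        g = rng.random((97, 97))
        c = SpectrumCOSY("r", grid, grid, g)
        bv = bin_2d(c, 0.37)
        assert bv.values.sum() == pytest.approx(g.sum(), rel=1e-12)

    def test_diagonal_width_extension(self):
        bv = bin_2d(square_cosy(), 1.0, diagonal_width_bins=1)
        assert bv.diagonal_flags.sum() == 10 + 2 * 9


class TestStripDiagonal:
    def _matrix(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0, 10, 51)
        vecs = []
        for sid in ("a", "b"):
            c = SpectrumCOSY(sid, grid, grid, rng.random((51, 51)))
            vecs.append(bin_2d(c, 1.0))
        return assemble_data_matrix(vecs, normalize=False)

    def test_off_diagonal_values_untouched(self):
        m = self._matrix()
        keep = ~m.diagonal_flags
        out = strip_diagonal(m)
        assert np.array_equal(out.values, m.values[:, keep])

    def test_idempotent(self):
        m = strip_diagonal(self._matrix())
        again = strip_diagonal(m)
        assert np.array_equal(again.values, m.values)

    def test_only_diagonal_intensity_leaves_zero_matrix(self):
        grid = np.linspace(0, 10, 51)
        g = np.zeros((51, 51))
        np.fill_diagonal(g, 1.0)
        vec = bin_2d(SpectrumCOSY("d", grid, grid, g), 1.0)
        m = assemble_data_matrix([vec], normalize=False)
        assert strip_diagonal(m).values.sum() == 0.0

    def test_rejects_matrix_without_flags(self):
        s = lorentzian_spectrum()
        m = assemble_data_matrix([bin_1d(s, 0.1)], normalize=False)
        with pytest.raises(ValueError):
            strip_diagonal(m)


class TestSectionIntegration2D:
    def test_point_mass_in_single_section(self):
        scheme = load_default_cosy_scheme()
        grid = np.linspace(0, 10, 501)
        g = np.zeros((501, 501))
        # intensity at (f2, f1) = (3.5, 3.5): inside the vicinal-diol box 'h'
        i = np.argmin(np.abs(grid - 3.5))
        g[i, i] = 5.0
        sums = integrate_sections_2d(SpectrumCOSY("p", grid, grid, g), scheme)
        assert sums.loc["p", "h"] == pytest.approx(5.0)
        assert sums.drop(columns="h").loc["p"].sum() == 0.0

    def test_unassigned_reported_not_dropped(self):
        scheme = SectionScheme2D(sections={"only": [(0.0, 1.0, 0.0, 1.0)]})
        grid = np.linspace(0, 10, 101)
        g = np.ones((101, 101))
        sums = integrate_sections_2d(SpectrumCOSY("u", grid, grid, g), scheme)
        assert sums.loc["u", "only"] + sums.loc["u", "unassigned"] == pytest.approx(g.sum())

    def test_exclude_diagonal_with_pure_diagonal_intensity(self):
        grid = np.linspace(0, 10, 101)
        g = np.zeros((101, 101))
        np.fill_diagonal(g, 1.0)
        vec = bin_2d(SpectrumCOSY("d", grid, grid, g), 0.5)
        m = assemble_data_matrix([vec], normalize=False)
        sums = integrate_sections_2d(m, exclude_diagonal=True)
        assert sums.loc["d"].sum() == 0.0

    def test_symmetric_scheme_invariant_under_axis_exchange(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 10, 201)
        sym = rng.random((201, 201))
        sym = sym + sym.T  # symmetric grid, mirrored cross peaks included
        c = SpectrumCOSY("s", grid, grid, sym)
        ct = SpectrumCOSY("s", grid, grid, sym.T)
        scheme = load_default_cosy_scheme()  # mirrored rectangles per label
        a = integrate_sections_2d(c, scheme)
        b = integrate_sections_2d(ct, scheme)
        assert np.allclose(a.values, b.values)


class TestAssemble:
    def test_all_zero_bin_removed(self):
        s1 = Spectrum1D("a", np.array([0.5, 1.5]), np.array([1.0, 0.0]))
        s2 = Spectrum1D("b", np.array([0.5, 1.5]), np.array([2.0, 0.0]))
        m = assemble_data_matrix([bin_1d(s1, 1.0), bin_1d(s2, 1.0)])
        assert m.values.shape[1] == 1

    def test_normalized_rows_sum_to_one(self, bundle):
        vecs = [bin_1d(s, 0.1) for s in bundle.spectra_1d[:3]]
        m = assemble_data_matrix(vecs, normalize=True)
        assert np.allclose(m.values.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_single_bin(self):
        s = Spectrum1D("a", np.array([0.5]), np.array([3.0]))
        m = assemble_data_matrix([bin_1d(s, 10.0)], normalize=True)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(1.0)

    def test_mismatched_geometry_rejected(self):
        s = lorentzian_spectrum()
        with pytest.raises(ValueError):
            assemble_data_matrix([bin_1d(s, 0.1), bin_1d(s, 0.2)])
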