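import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from domtransect.formulas import FormulaTable
from domtransect.multivariate import (
    ccora,
    fit_environmental_vectors,
    pcoa,
    spearman_correlation_map,
)


def euclidean_dm(points):
    return DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(len(points))])


class TestPCoA:
    def test_collinear_points_need_one_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        res = pcoa(euclidean_dm(pts), n_axes=1)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")), n_axes=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_classical_scaling_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(7, 2))
        res = pcoa(euclidean_dm(pts), n_axes=2)
        rebuilt = squareform(pdist(res.scores.to_numpy()))
        assert np.allclose(rebuilt, squareform(pdist(pts)), atol=1e-8)

    def test_agrees_with_skbio_reference(self, bundle):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        ft = bundle.formula_table.intensities.to_numpy().T
        ft = ft / ft.sum(axis=1, keepdims=True)
        dm = DistanceMatrix(squareform(pdist(ft, metric="braycurtis")),
                            ids=bundle.sample_ids)
        ours = pcoa(dm, n_axes=2)
        ref = skbio_pcoa(dm, number_of_dimensions=2)
        assert np.allclose(
            np.abs(ours.scores.to_numpy()), np.abs(ref.samples.to_numpy()), atol=1e-6
        )
        assert np.allclose(ours.eigenvalues[:2], ref.eigvals.to_numpy()[:2], atol=1e-8)

    def test_excess_axes_truncated_with_warning(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        with pytest.warns(UserWarning):
            res = pcoa(euclidean_dm(pts), n_axes=3)
        assert res.scores.shape[1] == 1


class TestVectorFitting:
    @staticmethod
    def _ordination(n=20, seed=13):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        return pcoa(euclidean_dm(pts), n_axes=2)

    def test_variable_equal_to_pc1_fits_perfectly(self):
        ordn = self._ordination()
        variables = pd.DataFrame({"v": ordn.scores["PC1"].to_numpy()})
        fit = fit_environmental_vectors(ordn, variables, n_permutations=499, seed=0)[0]
        assert fit.r_squared == pytest.approx(1.0)
        assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-8)
        assert abs(fit.direction[1]) == pytest.approx(0.0, abs=1e-6)

    def test_permutation_p_floor(self):
        ordn = self._ordination(n=30)
        variables = pd.DataFrame({"v": ordn.scores["PC1"].to_numpy()})
        fit = fit_environmental_vectors(ordn, variables, n_permutations=9999, seed=0)[0]
        assert fit.p_value == pytest.approx(1e-4)

    def test_constant_variable_flagged(self):
        ordn = self._ordination()
        fits = fit_environmental_vectors(
            ordn, pd.DataFrame({"c": np.ones(20)}), n_permutations=99, seed=0
        )
        assert fits[0].degenerate

    def test_seeded_reproducibility(self):
        ordn = self._ordination()
        rng = np.random.default_rng(5)
        variables = pd.DataFrame({"v": rng.normal(size=20)})
        p1 = fit_environmental_vectors(ordn, variables, 999, seed=7)[0].p_value
        p2 = fit_environmental_vectors(ordn, variables, 999, seed=7)[0].p_value
        assert p1 == p2


class TestSpearmanMap:
    @staticmethod
    def _table(intensities, samples):
        formulas = ["C16H10", "C6H12O6", "C10H13O5S"][: len(intensities)]
        return FormulaTable(formulas, pd.DataFrame(intensities, columns=samples))

    def test_monotone_increase_exact_p(self):
        samples = list("abcdef")
        t = self._table([[1, 2, 3, 4, 5, 6], [1, 1, 1, 2, 1, 1]], samples)
        cmap = spearman_correlation_map(t, np.arange(6.0))
        assert cmap.loc[0, "rho"] == pytest.approx(1.0)
        assert cmap.loc[0, "p_value"] == pytest.approx(2 / 720)
        assert cmap.loc[0, "significant"]

    def test_monotone_decrease(self):
        samples = list("abcdef")
        t = self._table([[6, 5, 4, 3, 2, 1]], samples)
        cmap = spearman_correlation_map(t, np.arange(6.0))
        assert cmap.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_intensity_flagged(self):
        samples = list("abcde")
        t = self._table([[1, 1, 1, 1, 1]], samples)
        cmap = spearman_correlation_map(t, np.arange(5.0))
        assert cmap.loc[0, "degenerate"]
        assert np.isnan(cmap.loc[0, "rho"])

    def test_nonsignificant_formulas_retained(self):
        rng = np.random.default_rng(3)
        samples = list("abcdef")
        t = self._table([rng.random(6), rng.random(6), rng.random(6)], samples)
        cmap = spearman_correlation_map(t, np.arange(6.0))
        assert len(cmap) == 3  # nothing dropped

    def test_too_few_samples_rejected(self):
        t = self._table([[1, 2, 3]], list("abc"))
        with pytest.raises(ValueError):
            spearman_correlation_map(t, np.arange(3.0))


class TestCCorA:
    def test_identical_blocks(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=(8, 2))
        res = ccora(x, x, n_permutations=99, seed=0)
        assert np.allclose(res.canonical_correlations, [1.0, 1.0])
        assert res.pillai_trace == pytest.approx(2.0)

    def test_column_swap_invariance(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=(8, 2))
        res = ccora(x, x[:, ::-1], n_permutations=99, seed=0)
        assert np.allclose(res.canonical_correlations, [1.0, 1.0])

    def test_invariance_to_invertible_transforms(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=(10, 2))
        y = rng.normal(size=(10, 2))
        a = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        b = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        r1 = ccora(x, y, n_permutations=49, seed=1)
        r2 = ccora(x @ a, y @ b, n_permutations=49, seed=1)
        assert np.allclose(r1.canonical_correlations, r2.canonical_correlations, atol=1e-8)

    def test_p_in_valid_range_and_reproducible(self):
        rng = np.random.default_rng(34)
        x, y = rng.normal(size=(8, 2)), rng.normal(size=(8, 2))
        r1 = ccora(x, y, n_permutations=719, seed=5)
        r2 = ccora(x, y, n_permutations=719, seed=5)
        assert r1.p_value == r2.p_value
        assert 1 / 720 <= r1.p_value <= 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ccora(np.zeros((3, 2)), np.zeros((3, 2)))


class TestTransectGeometry:
    def test_salinity_vector_strong_and_opposes_aromatic(self, report):
        fits = report.vector_fits["nmr"]
        assert fits.loc["salinity", "r"] > 0.5
        d_sal = fits.loc["salinity", ["dir_pc1", "dir_pc2"]].to_numpy(dtype=float)
        d_aro = fits.loc["aromatic", ["dir_pc1", "dir_pc2"]].to_numpy(dtype=float)
        assert float(d_sal @ d_aro) < 0
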