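"""Ordination and two-block integration of NMR and MS data.

Principal coordinate analysis (PCoA, classical scaling) embeds the
Bray-Curtis dissimilarity matrices; per-sample covariates (salinity,
DOC, d13C, fluorescence indices, section abundances, intensity-weighted
molecular parameters) are fitted post hoc to the first two axes with a
permutation test of the regression R^2 (envfit-style).  Spearman
correlation maps place every molecular formula in van Krevelen space
colored by its rank correlation with a covariate, with exact
enumeration p-values at the small sample sizes typical of pooled
transect studies (n <= 8).  Canonical correlation analysis (CCorA)
links the first two principal coordinates of the NMR- and MS-based
ordinations, with Pillai's trace tested by row permutation.

Permutation p-values use the add-one convention
p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations),
so the attainable floor is 1/(n_permutations + 1); exact-enumeration
Spearman p-values are exact proportions over all n! rank orders.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from skbio import DistanceMatrix

from .formulas import FormulaTable

__all__ = [
    "OrdinationResult",
    "VectorFit",
    "CCorAResult",
    "pcoa",
    "fit_environmental_vectors",
    "spearman_correlation_map",
    "ccora",
]

_EIG_TOL = 1e-10


@dataclass
class OrdinationResult:
    """PCoA scores with eigenvalues and proportions of explained variance."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def sample_ids(self) -> list:
        return list(self.scores.index)


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling of a dissimilarity matrix.

    Gower-centers -D^2/2, eigendecomposes it, and scales eigenvectors by
    the square root of their (positive) eigenvalues.  Proportions of
    explained variance are taken over the positive eigenvalues only;
    negative eigenvalues (possible for non-Euclidean dissimilarities such
    as Bray-Curtis) are reported separately and uncorrected.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least three samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > _EIG_TOL * scale
    negative = eigvals[eigvals < -_EIG_TOL * scale]
    pos_vals = eigvals[positive]
    if n_axes > pos_vals.size:
        warnings.warn(
            f"requested {n_axes} axes but only {pos_vals.size} positive eigenvalues; truncating"
        )
        n_axes = pos_vals.size
    scores = eigvecs[:, positive][:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=list(dm.ids), columns=cols),
        eigenvalues=pos_vals,
        proportion_explained=pos_vals / pos_vals.sum(),
        negative_eigenvalues=negative,
    )


@dataclass
class VectorFit:
    variable: str
    direction: np.ndarray
    r_squared: float
    r: float
    p_value: float
    n_permutations: int
    signed_correlation: float = float("nan")
    degenerate: bool = False


def _r2_of_permutations(v: np.ndarray, hat: np.ndarray, perms: np.ndarray) -> np.ndarray:
    vp = v[perms]  # (n_perm, n) permutations of the centered variable
    proj = vp @ hat
    return (proj * vp).sum(axis=1) / (vp * vp).sum(axis=1)


def fit_environmental_vectors(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> list[VectorFit]:
    """envfit-style post-hoc fitting of covariates to the first two axes.

    Each variable is regressed on the centered (PC1, PC2) scores; the fit
    direction is the normalized coefficient vector and R^2 the coefficient
    of determination.  Significance comes from permuting the variable's
    values.  Missing values are excluded pairwise; constant variables are
    flagged degenerate and receive no fit.
    """
    rng = np.random.default_rng(seed)
    scores_all = ordination.scores.iloc[:, :2].to_numpy(dtype=float)
    fits: list[VectorFit] = []
    for name in variables.columns:
        col = variables[name].to_numpy(dtype=float)
        mask = np.isfinite(col)
        if mask.sum() < 3:
            raise ValueError(f"variable {name!r} has fewer than 3 complete samples")
        v = col[mask]
        if np.ptp(v) == 0:
            fits.append(
                VectorFit(name, np.full(2, np.nan), np.nan, np.nan, np.nan,
                          n_permutations, degenerate=True)
            )
            continue
        s = scores_all[mask]
        sc = s - s.mean(axis=0)
        vc = v - v.mean()
        beta, *_ = np.linalg.lstsq(sc, vc, rcond=None)
        fitted = sc @ beta
        r2 = float(fitted @ fitted) / float(vc @ vc)
        direction = beta / np.linalg.norm(beta)
        # projection ("hat") matrix of the centered score plane
        hat = sc @ np.linalg.pinv(sc.T @ sc) @ sc.T
        n = vc.size
        perms = np.argsort(rng.random((n_permutations, n)), axis=1)
        r2_perm = _r2_of_permutations(vc, hat, perms)
        p = (1 + int((r2_perm >= r2 - 1e-12).sum())) / (1 + n_permutations)
        signed = float(np.corrcoef(v, s @ direction)[0, 1])
        fits.append(
            VectorFit(
                variable=name, direction=direction, r_squared=r2, r=math.sqrt(max(r2, 0.0)),
                p_value=p, n_permutations=n_permutations, signed_correlation=signed,
            )
        )
    return fits


def _exact_spearman_pvalues(cov_ranks: np.ndarray, feat_ranks: np.ndarray,
                            rho_obs: np.ndarray) -> np.ndarray:
    """Two-sided exact permutation p for Spearman rho via full enumeration.

    ``feat_ranks`` is (n, n_features) midranks; ties are preserved because
    rho is the Pearson correlation of the (mid)rank vectors and only the
    covariate ranks are permuted.
    """
    n = cov_ranks.size
    perm_matrix = np.array(list(iter_permutations(range(n))))
    pr = cov_ranks[perm_matrix]  # (n!, n)
    prc = pr - pr.mean(axis=1, keepdims=True)
    pr_norm = np.linalg.norm(prc, axis=1)
    fc = feat_ranks - feat_ranks.mean(axis=0, keepdims=True)
    f_norm = np.linalg.norm(fc, axis=0)
    n_feat = fc.shape[1]
    exceed = np.empty(n_feat)
    chunk = max(1, int(2**22 // perm_matrix.shape[0]))  # bound the (n!, chunk) buffer
    for start in range(0, n_feat, chunk):
        sl = slice(start, start + chunk)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_all = (prc @ fc[:, sl]) / (pr_norm[:, None] * f_norm[None, sl])
        exceed[sl] = (np.abs(rho_all) >= np.abs(rho_obs)[None, sl] - 1e-12).sum(axis=0)
    return exceed / perm_matrix.shape[0]


def spearman_correlation_map(
    table: FormulaTable,
    covariate,
    p_threshold: float = 0.1,
    sample_ids=None,
) -> pd.DataFrame:
    """Spearman rho of every formula's intensity with a covariate.

    Returns one row per formula with rho, p, a significance flag at
    ``p_threshold`` (non-significant formulas are retained, only flagged),
    and the H/C-O/C coordinates plus group labels for van Krevelen
    plotting.  Exact enumeration p-values are used for n <= 8; the
    asymptotic approximation otherwise.  Ties are midranked; constant
    intensity vectors are flagged degenerate with no rho.
    """
    if sample_ids is None:
        sample_ids = table.sample_ids
    cov = np.asarray(covariate, dtype=float)
    if cov.size != len(sample_ids):
        raise ValueError("covariate length must match the sample subset")
    if cov.size < 4:
        raise ValueError("need at least four paired observations")
    intens = table.intensities[list(sample_ids)].to_numpy(dtype=float)  # (F, n)
    desc = table.descriptor_frame()

    n = cov.size
    feat = intens.T  # (n, F)
    constant = np.ptp(feat, axis=0) == 0
    cov_ranks = rankdata(cov)
    feat_ranks = np.apply_along_axis(rankdata, 0, feat)
    crc = cov_ranks - cov_ranks.mean()
    frc = feat_ranks - feat_ranks.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(crc) * np.linalg.norm(frc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (crc @ frc) / denom
    rho[constant] = np.nan

    pvals = np.full(rho.shape, np.nan)
    ok = ~constant
    if n <= 8:
        pvals[ok] = _exact_spearman_pvalues(cov_ranks, feat_ranks[:, ok], rho[ok])
    else:
        for i in np.flatnonzero(ok):
            pvals[i] = spearmanr(cov, feat[:, i]).pvalue

    out = desc[["formula", "h_to_c", "o_to_c", "group", "sulfur_group"]].copy()
    out["rho"] = rho
    out["p_value"] = pvals
    out["significant"] = pvals <= p_threshold
    out["degenerate"] = constant
    return out


@dataclass
class CCorAResult:
    canonical_correlations: np.ndarray
    pillai_trace: float
    p_value: float
    n_permutations: int
    rank: int


def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scale = max(s[0], 1.0) if s.size else 1.0
    keep = s > 1e-10 * scale
    if keep.sum() < x.shape[1]:
        warnings.warn("rank-deficient block: truncating to available rank")
    return u[:, keep]


def ccora(X, Y, n_permutations: int = 719, seed: int | None = None) -> CCorAResult:
    """Canonical correlation analysis of two score blocks.

    Canonical correlations are the singular values of Qx' Qy where Qx, Qy
    are orthonormal bases of the column-centered blocks; Pillai's trace is
    the sum of their squares.  Significance comes from permuting the rows
    of Y (add-one permutation p on Pillai's trace).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2D with equal sample counts")
    n = X.shape[0]
    if n < 4:
        raise ValueError("CCorA needs at least four samples")
    qx = _orthonormal_basis(X)
    qy = _orthonormal_basis(Y)
    svals = np.clip(np.linalg.svd(qx.T @ qy, compute_uv=False), 0.0, 1.0)
    pillai = float((svals**2).sum())
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    qyp = qy[perms]  # (n_perm, n, k)
    cross = np.einsum("ni,pnj->pij", qx, qyp)
    pillai_perm = (cross**2).sum(axis=(1, 2))
    p = (1 + int((pillai_perm >= pillai - 1e-12).sum())) / (1 + n_permutations)
    return CCorAResult(
        canonical_correlations=np.sort(svals)[::-1],
        pillai_trace=pillai,
        p_value=p,
        n_permutations=n_permutations,
        rank=int(min(qx.shape[1], qy.shape[1])),
    )
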