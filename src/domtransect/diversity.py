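"""Richness, base-2 Shannon diversity and Bray-Curtis dissimilarity.

These operate identically on binned NMR intensity vectors and on
molecular-formula intensity vectors, so structural (NMR) and
compositional (MS) diversity can be compared on the same footing.
For COSY data the diagonal bins are typically excluded before the
Shannon computation, since most COSY intensity sits on the diagonal
and would otherwise swamp the evenness term.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "richness",
    "shannon_diversity",
    "bray_curtis_matrix",
    "average_dissimilarity",
]


def _as_vector(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1D intensity vector")
    if (v < 0).any():
        raise ValueError("intensities must be nonnegative")
    return v


def richness(vector) -> int:
    """Number of strictly positive entries."""
    return int(np.count_nonzero(_as_vector(vector) > 0))


def shannon_diversity(vector, exclude_flags=None) -> float:
    """Shannon index H = -sum p_i log2 p_i in bits.

    ``exclude_flags`` (boolean, True = drop) removes entries before the
    relative intensities are formed; zero entries contribute 0 by the
    0 log 0 := 0 convention.
    """
    v = _as_vector(vector)
    if exclude_flags is not None:
        flags = np.asarray(exclude_flags, dtype=bool)
        if flags.shape != v.shape:
            raise ValueError("exclude_flags must match the vector length")
        v = v[~flags]
    total = v.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined: no intensity after exclusion")
    p = v / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def bray_curtis_matrix(values, sample_ids=None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities of the rows of ``values``.

    BC(j, k) = sum|x_j - x_k| / sum(x_j + x_k), in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least two samples")
    if (values < 0).any():
        raise ValueError("intensities must be nonnegative")
    if (values.sum(axis=1) <= 0).any():
        raise ValueError("every sample needs at least one positive entry")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(values.shape[0])]
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(map(str, sample_ids)))


def average_dissimilarity(dm: DistanceMatrix) -> float:
    """Mean of the n(n-1)/2 upper-triangle dissimilarities."""
    if dm.shape[0] < 2:
        raise ValueError("need at least two samples")
    return float(dm.condensed_form().mean())
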