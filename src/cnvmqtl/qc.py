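"""Matrix QC utilities: quantile normalization and PCA stratification checks."""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .types import MethylationMatrix


def quantile_normalize(m: MethylationMatrix) -> MethylationMatrix:
    """Force every sample column onto a common empirical distribution.

    Each column's values are replaced by the rank-wise mean of the sorted
    columns (ties receive the average of their reference quantiles, the
    limma ``normalizeQuantiles`` convention), so within-sample rank order is
    preserved and all columns share an identical multiset of values.
    """
    beta = m.beta
    n_sites, n_samples = beta.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(beta, axis=0).mean(axis=1)
    out = np.empty_like(beta)
    for j in range(n_samples):
        # average-tie ranks map tied values to the mean reference quantile
        ranks = stats.rankdata(beta[:, j]) - 1.0  # 0-based, possibly fractional
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return MethylationMatrix(m.sites, m.samples, out)


def pca_qc(matrix: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` principal component scores for a samples × features matrix.

    Used as a stratification check before association: well-mixed cohorts
    show no cluster separation on the leading components.  Features are
    centred internally; returns ``(scores, explained_variance_fractions)``
    with a deterministic sign convention (the largest-magnitude loading of
    each component is positive).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D samples × features matrix")
    if k >= min(x.shape):
        raise ValueError(f"k={k} must be < min(n_samples, n_features)={min(x.shape)}")
    if np.allclose(x, x[0:1, :]):
        raise ValueError("constant matrix: no variance to decompose")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    # fix signs so results do not depend on the SVD implementation
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_.copy()
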