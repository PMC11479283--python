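"""Principal component analysis of one sensor's sample × channel matrix.

Deterministic SVD of the column-mean-centered matrix; explained variance
percentages are singular value² over the total centered sum of squares.
Component signs are fixed so the largest-magnitude loading element of each
component is positive, making results reproducible across platforms.
Correlation loadings (Pearson r of each original channel with each score)
are reported alongside, with channels crossing |r| ≥ 0.70 flagged as
influential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpectralDataset, ValidationError

INFLUENCE_THRESHOLD = 0.70


@dataclass
class PCAResult:
    mode: str
    column_means: np.ndarray
    loadings: np.ndarray                    # (n_channels, k), orthonormal columns
    scores: np.ndarray                      # (n_samples, k), zero column means
    explained_variance_percent: np.ndarray  # (k,), nonincreasing

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.column_means + self.scores @ self.loadings.T


def fit_pca(dataset: SpectralDataset, k: int) -> PCAResult:
    """Fit a k-component PCA by singular value decomposition."""
    X = dataset.values
    n, c = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if not 1 <= k <= min(n - 1, c):
        raise ValidationError(f"k must lie in [1, {min(n - 1, c)}], got {k}")
    means = X.mean(axis=0)
    Xc = X - means
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total_ss = float((Xc ** 2).sum())
    if total_ss == 0:
        raise ValidationError("data matrix is constant; PCA undefined")
    explained = 100.0 * s[:k] ** 2 / total_ss
    loadings = vt[:k].T.copy()
    scores = u[:, :k] * s[:k]
    # sign convention: largest-|.| element of each loading vector is positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        mode=dataset.mode,
        column_means=means,
        loadings=loadings,
        scores=scores,
        explained_variance_percent=explained,
    )


def correlation_loadings(result: PCAResult, dataset: SpectralDataset,
                         n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each channel with each of the first ``n_components`` scores.

    Returns ``(r, influential)`` where ``r`` has shape (n_channels, m) with
    NaN for zero-variance channels, and ``influential`` is the boolean mask
    of channels whose |r| reaches 0.70 on any of those components.
    """
    m = min(n_components, result.k)
    X = dataset.values
    if X.shape[0] != result.scores.shape[0]:
        raise ValidationError("dataset does not match the fitted result")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    constant = (X.max(axis=0) - X.min(axis=0)) == 0
    out = np.full((X.shape[1], m), np.nan)
    for j in range(m):
        t = result.scores[:, j]
        st = np.sqrt((t ** 2).sum())
        if st == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc * t[:, None]).sum(axis=0) / (sx * st)
        out[:, j] = np.where(constant | (sx == 0), np.nan, r)
    influential = np.nanmax(np.abs(np.where(np.isnan(out), 0.0, out)), axis=1) >= INFLUENCE_THRESHOLD
    return out, influential
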