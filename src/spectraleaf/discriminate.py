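"""Species-separation statistics and the trait cluster heatmap.

Per-channel one-way ANOVA F statistics locate the wavelengths (or time
points) where the two species differ most, summarized per spectral region
(UV-VIS 350–700, NIR 700–1300, SWIR1 1300–1800, SWIR2 1800–2500 nm,
half-open intervals). Cross-validated classification uses a two-class
linear discriminant on the first three principal-component scores of the
training folds, and reports accuracy and Cohen's kappa from the accumulated
out-of-fold confusion matrix. The Z-score trait heatmap uses agglomerative
Ward/Euclidean clustering on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

from .core import SpectralDataset, TraitTable, ValidationError, stratified_folds, zscore_traits
from .pca import fit_pca


@dataclass
class RegionScheme:
    """Named half-open wavelength intervals covering 350–2500 nm."""

    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "UV-VIS": (350.0, 700.0),
            "NIR": (700.0, 1300.0),
            "SWIR1": (1300.0, 1800.0),
            "SWIR2": (1800.0, 2500.0),
        }
    )

    def __post_init__(self) -> None:
        bounds = sorted(self.regions.values())
        for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
            if hi1 != lo2:
                raise ValidationError("regions must be ordered and non-overlapping")


@dataclass
class DiscriminationResult:
    mode: str
    f_series: np.ndarray
    axis: np.ndarray
    region_peaks: dict[str, float]
    accuracy: float
    kappa: float
    confusion: np.ndarray  # 2×2 counts, rows = true class, cols = predicted


@dataclass
class ClusterResult:
    trait_linkage: np.ndarray
    sample_linkage: np.ndarray
    trait_order: list[str]
    sample_order: list[str]
    zscores: np.ndarray   # samples × traits


def per_channel_f(dataset: SpectralDataset, labels: list[str] | None = None) -> np.ndarray:
    """Two-group one-way ANOVA F = MS_between / MS_within per channel.

    Channels where both groups have zero within-variance but different means
    are reported as +inf.
    """
    labels = np.asarray(labels if labels is not None else dataset.species)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups.size}")
    X = dataset.values
    n = X.shape[0]
    parts = [X[labels == g] for g in groups]
    if min(p.shape[0] for p in parts) < 2:
        raise ValidationError("each group needs at least 2 samples")
    grand = X.mean(axis=0)
    ssb = sum(p.shape[0] * (p.mean(axis=0) - grand) ** 2 for p in parts)
    ssw = sum(((p - p.mean(axis=0)) ** 2).sum(axis=0) for p in parts)
    msb = ssb / (groups.size - 1)
    msw = ssw / (n - groups.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0), np.inf)
    return np.where((msw == 0) & (msb == 0), 0.0, f)


def region_peaks(f_series: np.ndarray, axis: np.ndarray,
                 scheme: RegionScheme | None = None) -> dict[str, float]:
    """Channel with maximal F per region; ties resolve to the lowest value.

    Empty regions are omitted. The last region includes its upper bound so
    the final grid point is not orphaned.
    """
    scheme = scheme or RegionScheme()
    out: dict[str, float] = {}
    top = max(hi for _, hi in scheme.regions.values())
    for name, (lo, hi) in scheme.regions.items():
        mask = (axis >= lo) & ((axis <= hi) if hi == top else (axis < hi))
        if not mask.any():
            continue
        sub = np.where(np.isnan(f_series[mask]), -np.inf, f_series[mask])
        out[name] = float(axis[mask][int(np.argmax(sub))])
    return out


def cohen_kappa(confusion: np.ndarray) -> float:
    """(p_o − p_e) / (1 − p_e) from a square confusion-count matrix."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if (c < 0).any():
        raise ValidationError("confusion counts must be nonnegative")
    n = c.sum()
    if n < 1:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=0) * c.sum(axis=1)).sum()) / n ** 2
    if p_e >= 1.0:
        return float("nan")  # degenerate marginals: chance agreement is total
    return float((p_o - p_e) / (1.0 - p_e))


def _lda_two_class(scores: np.ndarray, y: np.ndarray):
    """Fisher discriminant for two classes: weight vector and midpoint threshold."""
    g0, g1 = scores[y == 0], scores[y == 1]
    mu0, mu1 = g0.mean(axis=0), g1.mean(axis=0)
    n0, n1 = g0.shape[0], g1.shape[0]
    pooled = (
        (g0 - mu0).T @ (g0 - mu0) + (g1 - mu1).T @ (g1 - mu1)
    ) / max(n0 + n1 - 2, 1)
    pooled = pooled + 1e-10 * np.eye(pooled.shape[0]) * max(np.trace(pooled), 1.0)
    w = np.linalg.solve(pooled, mu1 - mu0)
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return w, threshold


def classify_species(dataset: SpectralDataset, labels: list[str] | None = None,
                     n_components: int = 3, n_folds: int = 10,
                     seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Cross-validated LDA-on-PC-scores species classification.

    Returns ``(accuracy, kappa, confusion)`` accumulated over the
    out-of-fold predictions (rows of the confusion matrix are true classes).
    """
    labels = list(labels if labels is not None else dataset.species)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {len(classes)}")
    y = np.array([classes.index(l) for l in labels])
    n = y.size
    if n < 10:
        raise ValidationError("need at least 10 samples")
    folds = stratified_folds(labels, n_folds, seed)
    confusion = np.zeros((2, 2), dtype=int)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        train_ds = dataset.subset(np.flatnonzero(train))
        k = min(n_components, train_ds.n_samples - 1, train_ds.n_channels)
        res = fit_pca(train_ds, k)
        w, threshold = _lda_two_class(res.scores, y[train])
        proj = (dataset.values[test] - res.column_means) @ res.loadings @ w
        pred = (proj > threshold).astype(int)
        for truth, guess in zip(y[test], pred):
            confusion[truth, guess] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    return accuracy, cohen_kappa(confusion), confusion


def cluster_traits(traits: TraitTable) -> ClusterResult:
    """Ward/Euclidean agglomerative clustering of Z-scored traits, both axes."""
    if len(traits.data.columns) < 2 or len(traits.data) < 2:
        raise ValidationError("need at least 2 traits and 2 samples")
    z = zscore_traits(traits).to_numpy()
    trait_link = linkage(z.T, method="ward", metric="euclidean")
    sample_link = linkage(z, method="ward", metric="euclidean")
    trait_order = [traits.data.columns[i] for i in leaves_list(trait_link)]
    sample_order = [traits.sample_ids[i] for i in leaves_list(sample_link)]
    return ClusterResult(
        trait_linkage=trait_link, sample_linkage=sample_link,
        trait_order=trait_order, sample_order=sample_order, zscores=z,
    )


def linkage_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = node.get_left(), node.get_right()
        bl_l = node.dist - left.dist
        bl_r = node.dist - right.dist
        return f"({walk(left)}:{bl_l:.6g},{walk(right)}:{bl_r:.6g})"

    return walk(tree) + ";"


def discriminate_mode(dataset: SpectralDataset, seed: int = 0,
                      n_folds: int = 10) -> DiscriminationResult:
    """Full per-mode discrimination report: F series, region peaks, Acc/kappa."""
    f = per_channel_f(dataset)
    peaks = region_peaks(f, dataset.axis) if dataset.axis_unit == "nm" else {}
    acc, kappa, confusion = classify_species(dataset, seed=seed, n_folds=n_folds)
    return DiscriminationResult(
        mode=dataset.mode, f_series=f, axis=dataset.axis.copy(),
        region_peaks=peaks, accuracy=acc, kappa=kappa, confusion=confusion,
    )
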