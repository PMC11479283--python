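"""Exhaustive two-channel normalized-difference index optimization.

For every ordered pair of channels (wavelengths, or time points of a
fluorescence transient) the index

    NDI(c1, c2) = (v1 − v2) / (v1 + v2)

is computed per sample and correlated (Pearson) against a trait, yielding
an all-pairs r / r² matrix — the contour-map procedure used to pick the two
most responsive bands for a trait. Undefined cells (diagonal, zero
denominators in too many samples, zero index variance) are encoded as NaN,
never as 0, since 0 is a legitimate r².
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpectralDataset, ValidationError


@dataclass(frozen=True)
class BandPair:
    channel_1: float
    channel_2: float
    index_1: int
    index_2: int


@dataclass
class IndexMap:
    """All-pairs index-vs-trait correlation matrices for one trait."""

    trait: str
    mode: str
    axis: np.ndarray
    r_matrix: np.ndarray   # antisymmetric in sign under pair swap; NaN = undefined
    r2_matrix: np.ndarray  # symmetric; NaN = undefined
    n_samples: int

    @property
    def n_channels(self) -> int:
        return self.axis.size


def normalized_difference(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """(v1 − v2) / (v1 + v2) per sample; zero denominators become NaN."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValidationError("channel vectors are not aligned")
    denom = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (v1 - v2) / np.where(denom != 0, denom, 1.0), np.nan)
    if np.isnan(out).all():
        raise ValidationError("index undefined for every sample (all-zero channels)")
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over samples where x is defined; NaN if < 3 defined or constant."""
    ok = ~np.isnan(x)
    if ok.sum() < 3:
        return np.nan
    xs, ys = x[ok], y[ok]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float((xc * yc).sum() / (sx * sy))


def r2_map(dataset: SpectralDataset, trait: np.ndarray, trait_name: str = "trait") -> IndexMap:
    """Correlate the normalized-difference index of every channel pair with a trait."""
    y = np.asarray(trait, dtype=float)
    n, c = dataset.values.shape
    if y.shape != (n,):
        raise ValidationError("trait vector is not aligned with the dataset")
    if n < 3:
        raise ValidationError("need at least 3 samples")
    if y.std(ddof=1) == 0:
        raise ValidationError("trait has zero variance")
    X = dataset.values
    yc = y - y.mean()
    ss_y = float((yc ** 2).sum())
    r = np.full((c, c), np.nan)
    for i in range(c - 1):
        vi = X[:, i:i + 1]
        Vj = X[:, i + 1:]
        denom = vi + Vj
        bad = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            idx = (vi - Vj) / np.where(bad, 1.0, denom)
        if bad.any():
            idx = np.where(bad, np.nan, idx)
            row = np.array([_pearson(idx[:, j], y) for j in range(idx.shape[1])])
        else:
            ic = idx - idx.mean(axis=0)
            ss_i = (ic ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                row = (ic * yc[:, None]).sum(axis=0) / np.sqrt(ss_i * ss_y)
            row = np.where(ss_i == 0, np.nan, row)
        r[i, i + 1:] = row
        r[i + 1:, i] = -row  # swapping the pair negates the index, hence r
    r2 = r ** 2
    return IndexMap(trait=trait_name, mode=dataset.mode, axis=dataset.axis.copy(),
                    r_matrix=r, r2_matrix=r2, n_samples=n)


def best_pair(index_map: IndexMap) -> tuple[BandPair, float]:
    """Arg-max of r² over ordered pairs (i < j); ties broken by the smaller
    first channel, then the smaller second channel."""
    r2 = index_map.r2_matrix
    c = r2.shape[0]
    iu, ju = np.triu_indices(c, k=1)
    vals = r2[iu, ju]
    if np.isnan(vals).all():
        raise ValidationError("index map has no defined cell")
    best = np.nanmax(vals)
    tied = np.flatnonzero(vals == best)
    k = tied[0]  # triu_indices is ordered lexicographically by (i, j)
    i, j = int(iu[k]), int(ju[k])
    pair = BandPair(channel_1=float(index_map.axis[i]),
                    channel_2=float(index_map.axis[j]),
                    index_1=i, index_2=j)
    return pair, float(best)


def export_contour(index_map: IndexMap, csv_path, json_path=None) -> None:
    """Write the r² matrix as CSV (axis values as header row/column, NaN as
    empty cells) and optionally a best-pair JSON summary."""
    labels = [f"{v:.10g}" for v in index_map.axis]
    df = pd.DataFrame(index_map.r2_matrix, index=labels, columns=labels)
    df.to_csv(csv_path, float_format="%.12g", index_label="channel")
    if json_path is not None:
        pair, r2 = best_pair(index_map)
        payload = {
            "trait": index_map.trait,
            "mode": index_map.mode,
            "channel_1": pair.channel_1,
            "channel_2": pair.channel_2,
            "r": index_map.r_matrix[pair.index_1, pair.index_2],
            "r2": r2,
            "n": index_map.n_samples,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_contour(csv_path) -> tuple[np.ndarray, np.ndarray]:
    """Round-trip reader for :func:`export_contour` CSVs → (axis, r² matrix)."""
    df = pd.read_csv(csv_path, index_col=0)
    axis = np.array([float(c) for c in df.columns])
    return axis, df.to_numpy(dtype=float)
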