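"""Core data model and shared preprocessing for leaf optical spectra.

The central containers are :class:`SpectralDataset` — a sample × channel
matrix whose channel axis is either wavelength (nm, for reflectance R,
transmittance T and absorbance A) or time (s, for chlorophyll-fluorescence
transients) — and :class:`TraitTable`, the per-sample values of the eight
leaf structural/ultrastructural traits.

Conventions used throughout the package:

* absorbance is derived from the two optical measurements as A = 1 − (R + T);
* standard deviations use the n−1 denominator;
* the coefficient of variation is CV% = 100 · SD / mean;
* calibration/prediction splits are stratified by species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODES = ("fluorescence", "reflectance", "transmittance", "absorbance")

#: canonical trait column order (units embedded in the names)
TRAIT_COLUMNS = (
    "adaxial_epidermis_um",
    "adaxial_hypodermis_um",
    "parenchyma_um",
    "abaxial_hypodermis_um",
    "total_thickness_um",
    "chloroplast_count",
    "granum_height_nm",
    "thylakoid_layer_granum",
)

#: the four independently drawn leaf layers whose sum is the total thickness
LAYER_TRAITS = (
    "adaxial_epidermis_um",
    "adaxial_hypodermis_um",
    "parenchyma_um",
    "abaxial_hypodermis_um",
)


class AlignmentError(ValueError):
    """Axes, sample ids or sample order disagree between datasets."""


class ValidationError(ValueError):
    """A dataset violates a physical or structural constraint."""


@dataclass
class SpectralDataset:
    """Sample × channel matrix with an explicit, strictly increasing axis.

    Parameters
    ----------
    axis : array of channel positions (wavelength in nm or time in s).
    values : (n_samples, n_channels) matrix.
    mode : one of ``fluorescence | reflectance | transmittance | absorbance``.
    sample_ids, species : per-row identifiers and species labels.
    axis_unit : "nm" or "s".
    """

    axis: np.ndarray
    values: np.ndarray
    mode: str
    sample_ids: list[str]
    species: list[str]
    axis_unit: str = "nm"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.axis.ndim != 1 or np.any(np.diff(self.axis) <= 0):
            raise ValidationError("channel axis must be 1-D and strictly increasing")
        if self.values.ndim != 2 or self.values.shape[1] != self.axis.size:
            raise ValidationError(
                f"values shape {self.values.shape} does not match axis length {self.axis.size}"
            )
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValidationError("sample_ids length does not match row count")
        if len(self.species) != self.values.shape[0]:
            raise ValidationError("species length does not match row count")
        if np.isnan(self.values).any():
            raise ValidationError("missing values are not allowed")
        if self.mode != "fluorescence":
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValidationError(f"{self.mode} values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        """Row-subset (or reorder) by integer index array."""
        rows = np.asarray(rows)
        return SpectralDataset(
            axis=self.axis.copy(),
            values=self.values[rows].copy(),
            mode=self.mode,
            sample_ids=[self.sample_ids[i] for i in rows],
            species=[self.species[i] for i in rows],
            axis_unit=self.axis_unit,
        )


@dataclass
class TraitTable:
    """Per-sample table of the eight biophysical traits."""

    data: pd.DataFrame  # index = sample_id, columns ⊆ TRAIT_COLUMNS
    species: list[str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in trait table")
        unknown = set(self.data.columns) - set(TRAIT_COLUMNS)
        if unknown:
            raise ValidationError(f"unknown trait columns: {sorted(unknown)}")
        if len(self.species) != len(self.data):
            raise ValidationError("species length does not match trait rows")
        if (self.data.to_numpy() <= 0).any():
            raise ValidationError("trait values must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def trait(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class SplitPlan:
    """Disjoint calibration/prediction index sets over one sample roster."""

    calibration: np.ndarray
    prediction: np.ndarray
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration.tolist()), set(self.prediction.tolist())
        if cal & pred:
            raise ValidationError("calibration and prediction sets overlap")


def compute_absorbance(reflectance: SpectralDataset, transmittance: SpectralDataset) -> SpectralDataset:
    """Derive absorbance via A = 1 − (R + T).

    Inputs must share axis, sample ids and order. Any sample/channel where
    R + T exceeds 1 raises :class:`ValidationError` naming the offender.
    """
    r, t = reflectance, transmittance
    if r.mode != "reflectance" or t.mode != "transmittance":
        raise ValidationError("inputs must be reflectance and transmittance datasets")
    if r.axis.shape != t.axis.shape or not np.array_equal(r.axis, t.axis):
        raise AlignmentError("wavelength axes differ between R and T")
    if r.sample_ids != t.sample_ids:
        raise AlignmentError("sample ids / order differ between R and T")
    total = r.values + t.values
    bad = np.argwhere(total > 1 + 1e-9)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"R+T = {total[i, j]:.6f} > 1 for sample {r.sample_ids[i]!r} "
            f"at {r.axis[j]:g} {r.axis_unit}"
        )
    a = np.clip(1.0 - total, 0.0, 1.0)
    return SpectralDataset(
        axis=r.axis.copy(),
        values=a,
        mode="absorbance",
        sample_ids=list(r.sample_ids),
        species=list(r.species),
        axis_unit=r.axis_unit,
    )


def mean_center(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-mean-center a matrix; returns (centered, column_means)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValidationError("mean centering needs at least 2 rows")
    means = values.mean(axis=0)
    return values - means, means


def zscore_traits(traits: TraitTable) -> pd.DataFrame:
    """Standardize each trait column to mean 0, SD 1 (n−1 denominator)."""
    out = {}
    for col in traits.data.columns:
        x = traits.data[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"trait {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=traits.data.index)


def stratified_folds(labels: list[str], n_folds: int, seed: int) -> np.ndarray:
    """Assign each sample to a fold, stratified by label, seeded.

    Returns an integer fold id per sample. Shared by PLSR cross-validation
    and species classification so both see the same partitions.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n_folds < 2:
        raise ValidationError("need at least 2 folds")
    if n < n_folds:
        raise ValidationError("more folds than samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    start = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        folds[idx] = (np.arange(idx.size) + start) % n_folds
        start += idx.size  # stagger so small strata spread across folds
    return folds


def split_calibration_prediction(
    sample_ids: list[str],
    species: list[str],
    fraction: float = 0.75,
    seed: int = 0,
) -> SplitPlan:
    """Stratified calibration/prediction split (default 75/25 by species)."""
    n = len(sample_ids)
    if n < 8:
        raise ValidationError("need at least 8 samples to split")
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie strictly between 0 and 1")
    labels = np.asarray(species)
    rng = np.random.default_rng(seed)
    cal_idx: list[np.ndarray] = []
    pred_idx: list[np.ndarray] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            raise ValidationError(f"stratum {lab!r} has fewer than 2 samples")
        rng.shuffle(idx)
        n_cal = int(round(fraction * idx.size))
        n_cal = min(max(n_cal, 1), idx.size - 1)
        cal_idx.append(np.sort(idx[:n_cal]))
        pred_idx.append(np.sort(idx[n_cal:]))
    return SplitPlan(
        calibration=np.sort(np.concatenate(cal_idx)),
        prediction=np.sort(np.concatenate(pred_idx)),
        seed=seed,
    )


def describe(traits: TraitTable) -> pd.DataFrame:
    """Descriptive statistics per trait: count, mean, median, min, max, CV%."""
    if len(traits.data) < 2:
        raise ValidationError("need at least 2 samples to describe")
    rows = []
    for col in traits.data.columns:
        x = traits.data[col].to_numpy(dtype=float)
        rows.append(
            {
                "trait": col,
                "count": int(x.size),
                "mean": x.mean(),
                "median": float(np.median(x)),
                "minimum": x.min(),
                "maximum": x.max(),
                "cv_percent": 100.0 * x.std(ddof=1) / x.mean(),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# CSV I/O. Layout: sample_id, species, then one column per channel whose
# header is the axis value itself (plain decimal, >= 10 significant digits).
# ---------------------------------------------------------------------------

def write_dataset(dataset: SpectralDataset, path) -> None:
    cols = [f"{v:.10g}" for v in dataset.axis]
    df = pd.DataFrame(dataset.values, columns=cols)
    df.insert(0, "species", dataset.species)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path, mode: str, axis_unit: str = "nm") -> SpectralDataset:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns[:2]) != ["sample_id", "species"]:
        raise ValidationError(f"{path}: first columns must be sample_id, species")
    try:
        axis = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric channel header: {exc}") from exc
    if axis.size == 0 or np.any(np.diff(axis) <= 0):
        raise ValidationError(f"{path}: channel header must be strictly increasing")
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    nan_rows = np.flatnonzero(np.isnan(values).any(axis=1))
    if nan_rows.size:
        raise ValidationError(
            f"{path}: missing value in data row {nan_rows[0] + 1} "
            f"(sample {df['sample_id'].iloc[nan_rows[0]]!r})"
        )
    return SpectralDataset(
        axis=axis,
        values=values,
        mode=mode,
        sample_ids=[str(s) for s in df["sample_id"]],
        species=[str(s) for s in df["species"]],
        axis_unit=axis_unit,
    )


def write_traits(traits: TraitTable, path) -> None:
    df = traits.data.copy()
    df.insert(0, "species", traits.species)
    df.to_csv(path, index=True, index_label="sample_id", float_format="%.12g")


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, index_col="sample_id")
    if "species" not in df.columns:
        raise ValidationError(f"{path}: traits CSV must carry a species column")
    species = [str(s) for s in df.pop("species")]
    df.index = df.index.astype(str)
    return TraitTable(data=df.astype(float), species=species)
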