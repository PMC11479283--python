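"""NIPALS partial least squares regression and the chemometric metric suite.

Single-response PLSR in the classical NIPALS form: per factor, the weight
w ∝ Xᵀy (unit norm), score t = Xw, x-loading p = Xᵀt/(tᵀt), y-loading
q = yᵀt/(tᵀt), then deflation X ← X − t pᵀ, y ← y − q t. Both X and y are
mean-centered before extraction; the assembled coefficient vector B
satisfies predict(X_new) = (X_new − x̄)·B + ȳ.

Validation metrics follow the chemometric conventions under which a printed
SEP/RMSEP/bias triple is internally consistent:

* bias = mean(predicted − observed)
* RMSE with the n denominator (RMSEC / RMSECV / RMSEP by context)
* SEP  = bias-corrected SD of the residuals (n − 1 denominator)
* RPD  = SD(observed) / SEP
* identity: RMSE² = ((n−1)/n)·SEP² + bias², exact under these definitions.

The reported R² is the squared Pearson correlation between observed and
predicted; a 1 − SSres/SStot diagnostic (which can go negative on held-out
data) is carried alongside as ``r2_ss``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SpectralDataset, SplitPlan, TraitTable, ValidationError, stratified_folds

MAX_FACTORS_DEFAULT = 7


@dataclass
class PLSRModel:
    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (n_channels, A)
    x_loadings: np.ndarray   # (n_channels, A)
    y_loadings: np.ndarray   # (A,)
    x_scores: np.ndarray     # (n_cal, A), mutually orthogonal
    coefficients: np.ndarray  # (n_channels,), on centered X
    mode: str = ""
    trait: str = ""

    def coefficients_for(self, a: int) -> np.ndarray:
        """Regression vector using only the first ``a`` factors."""
        if not 1 <= a <= self.n_factors:
            raise ValidationError(f"factor count {a} outside [1, {self.n_factors}]")
        W = self.weights[:, :a]
        P = self.x_loadings[:, :a]
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)


@dataclass
class MetricSet:
    n: int
    r: float
    r2: float
    slope: float
    offset: float
    sep: float
    rmse: float
    rpd: float
    bias: float
    r2_ss: float  # 1 − SSres/SStot diagnostic (may be negative on held-out data)

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        d = {
            "n": self.n, "r": self.r, "r2": self.r2, "slope": self.slope,
            "offset": self.offset, "sep": self.sep, "rmse": self.rmse,
            "rpd": self.rpd, "bias": self.bias, "r2_ss": self.r2_ss,
        }
        return {f"{prefix}{k}": v for k, v in d.items()}


@dataclass
class FitReport:
    trait: str
    mode: str
    n_factors: int
    calibration: MetricSet
    cross_validation: MetricSet
    prediction: MetricSet


def fit_nipals(X: np.ndarray, y: np.ndarray, n_factors: int,
               mode: str = "", trait: str = "") -> PLSRModel:
    """Fit a single-response NIPALS PLSR with ``n_factors`` latent factors.

    Extraction stops early (with fewer factors) if the y-residual becomes
    orthogonal to the X-residual.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, c = X.shape
    if y.size != n:
        raise ValidationError("X and y are not aligned")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    max_a = min(n - 1, c)
    if not 1 <= n_factors <= max_a:
        raise ValidationError(f"n_factors must lie in [1, {max_a}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    W = np.zeros((c, n_factors))
    P = np.zeros((c, n_factors))
    q = np.zeros(n_factors)
    T = np.zeros((n, n_factors))
    a_done = 0
    for a in range(n_factors):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-12 * max(1.0, np.linalg.norm(y - y_mean)):
            break  # residual y orthogonal to residual X
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        p = Xr.T @ t / tt
        qa = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p)
        yr = yr - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
        a_done += 1
    if a_done == 0:
        raise ValidationError("y is orthogonal to X; no factor extractable")
    W, P, q, T = W[:, :a_done], P[:, :a_done], q[:a_done], T[:, :a_done]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        n_factors=a_done, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, x_scores=T,
        coefficients=coef, mode=mode, trait=trait,
    )


def predict(model: PLSRModel, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
    """Apply the stored centering and coefficients; row order preserved."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.x_mean.size:
        raise ValidationError(
            f"channel axis mismatch: model has {model.x_mean.size} channels, "
            f"input has {X_new.shape[-1]}"
        )
    coef = model.coefficients if n_factors is None else model.coefficients_for(n_factors)
    return (X_new - model.x_mean) @ coef + model.y_mean


def cross_validate(X: np.ndarray, y: np.ndarray, labels: list[str],
                   max_factors: int, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold predictions for factor counts 1..max_factors.

    Folds are seeded and stratified by species label; each sample is
    predicted exactly once per factor count by a model fit without its fold.
    Returns an (n_samples, max_factors) matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    folds = stratified_folds(labels, n_folds, seed)
    preds = np.full((n, max_factors), np.nan)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if train.sum() < 2:
            raise ValidationError(f"fold {f} leaves fewer than 2 training samples")
        a_max = min(max_factors, train.sum() - 1, X.shape[1])
        model = fit_nipals(X[train], y[train], a_max)
        for a in range(1, max_factors + 1):
            a_eff = min(a, model.n_factors)
            preds[test, a - 1] = predict(model, X[test], n_factors=a_eff)
    return preds


def select_factors(rmsecv: np.ndarray, cap: int = MAX_FACTORS_DEFAULT,
                   window: float = 0.02) -> int:
    """Parsimonious factor choice: the smallest count whose RMSECV is within
    ``window`` (relative) of the global minimum, never exceeding ``cap``."""
    rmsecv = np.asarray(rmsecv, dtype=float)
    if rmsecv.size == 0:
        raise ValidationError("empty RMSECV sequence")
    usable = rmsecv[: min(cap, rmsecv.size)]
    best = float(np.nanmin(usable))
    threshold = best * (1.0 + window)
    for a, v in enumerate(usable, start=1):
        if v <= threshold:
            return a
    return usable.size


def compute_metrics(observed: np.ndarray, predicted: np.ndarray) -> MetricSet:
    """The full r/R²/slope/offset/SEP/RMSE/RPD/bias suite (see module docs)."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValidationError("observed and predicted are not aligned")
    n = obs.size
    if n < 3:
        raise ValidationError("need at least 3 samples for metrics")
    sd_obs = obs.std(ddof=1)
    if sd_obs == 0:
        raise ValidationError("observed values have zero variance")
    err = pred - obs
    bias = float(err.mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    sep = float(err.std(ddof=1))
    rpd = float(sd_obs / sep) if sep > 0 else math.inf
    sd_pred = pred.std(ddof=1)
    if sd_pred == 0:
        r = 0.0
        slope, offset = 0.0, float(pred.mean())
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
        slope = float(np.cov(obs, pred, ddof=1)[0, 1] / obs.var(ddof=1))
        offset = float(pred.mean() - slope * obs.mean())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    r2_ss = float(1.0 - (err ** 2).sum() / ss_tot)
    return MetricSet(n=n, r=r, r2=r * r, slope=slope, offset=offset,
                     sep=sep, rmse=rmse, rpd=rpd, bias=bias, r2_ss=r2_ss)


def fit_and_report(X_cal: np.ndarray, y_cal: np.ndarray, labels_cal: list[str],
                   X_pred: np.ndarray, y_pred: np.ndarray,
                   max_factors: int = MAX_FACTORS_DEFAULT, n_folds: int = 10,
                   seed: int = 0, mode: str = "", trait: str = "") -> FitReport:
    """Calibrate, cross-validate, pick factors, and score the held-out set."""
    a_cap = min(max_factors, X_cal.shape[0] - 1, X_cal.shape[1])
    cv_preds = cross_validate(X_cal, y_cal, labels_cal, a_cap, n_folds=n_folds, seed=seed)
    rmsecv = np.sqrt(((cv_preds - y_cal[:, None]) ** 2).mean(axis=0))
    a = select_factors(rmsecv, cap=a_cap)
    model = fit_nipals(X_cal, y_cal, a, mode=mode, trait=trait)
    cal_metrics = compute_metrics(y_cal, predict(model, X_cal))
    cv_metrics = compute_metrics(y_cal, cv_preds[:, model.n_factors - 1])
    pred_metrics = compute_metrics(y_pred, predict(model, X_pred))
    return FitReport(trait=trait, mode=mode, n_factors=model.n_factors,
                     calibration=cal_metrics, cross_validation=cv_metrics,
                     prediction=pred_metrics)


def run_trait_models(datasets: dict[str, SpectralDataset], traits: TraitTable,
                     split: SplitPlan, max_factors: int = MAX_FACTORS_DEFAULT,
                     n_folds: int = 10, seed: int = 0,
                     trait_names: list[str] | None = None) -> pd.DataFrame:
    """One PLSR fit per mode × trait; returns the report table.

    Rows carry the chosen factor count plus the calibration, cross-validation
    and held-out prediction metric suites.
    """
    trait_names = list(trait_names or traits.data.columns)
    cal, pred = split.calibration, split.prediction
    rows = []
    for mode, ds in datasets.items():
        if ds.sample_ids != traits.sample_ids:
            raise ValidationError(f"{mode}: dataset and trait table are misaligned")
        labels_cal = [ds.species[i] for i in cal]
        X_cal, X_pred = ds.values[cal], ds.values[pred]
        for name in trait_names:
            y = traits.trait(name)
            report = fit_and_report(
                X_cal, y[cal], labels_cal, X_pred, y[pred],
                max_factors=max_factors, n_folds=n_folds, seed=seed,
                mode=mode, trait=name,
            )
            row = {"mode": mode, "trait": name, "n_factors": report.n_factors}
            row.update(report.calibration.as_dict("cal_"))
            row.update(report.cross_validation.as_dict("cv_"))
            row.update(report.prediction.as_dict("pred_"))
            rows.append(row)
    return pd.DataFrame(rows)
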