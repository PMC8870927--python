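"""Regression metrics (R^2, RMSE, MAE), model evaluation, and PCA.

Metrics follow the standard definitions

    R^2  = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RMSE = sqrt( (1/n) sum (y_i - yhat_i)^2 )
    MAE  = (1/n) sum |y_i - yhat_i|

computed internally on fraction labels and reported either on the
fraction or the percent scale (x100; R^2 is scale-invariant).

Stable-value models may be scored at row granularity (each of the 10
plateau seconds is an evaluation case) or per sample (the 10 row
predictions averaged first); CNN models predict one value per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .features import SV_POINTS, MultichannelInput, SVMatrix


class UndefinedMetricError(ValueError):
    """Raised when a metric is mathematically undefined (e.g. R^2 with
    zero label variance)."""


def _as_pair(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length and nonempty")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_hat))):
        raise ValueError("metrics require finite inputs")
    return y, y_hat


def r_squared(y, y_hat) -> float:
    y, y_hat = _as_pair(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: actual values have zero "
                                   "variance")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def rmse(y, y_hat) -> float:
    y, y_hat = _as_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mae(y, y_hat) -> float:
    y, y_hat = _as_pair(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


@dataclass
class MetricsReport:
    r2: float
    rmse: float
    mae: float
    scale: str = "fraction"      # "fraction" or "percent"
    granularity: str = "row"     # "row" or "per_sample"
    n: int = 0


def compute_metrics(y, y_hat, scale: str = "fraction",
                    granularity: str = "row") -> MetricsReport:
    """All three metrics on fraction-scale pairs; errors reported x100
    when ``scale="percent"`` (R^2 is unaffected by scaling)."""
    y, y_hat = _as_pair(y, y_hat)
    factor = 100.0 if scale == "percent" else 1.0
    return MetricsReport(
        r2=r_squared(y, y_hat),
        rmse=rmse(y, y_hat) * factor,
        mae=mae(y, y_hat) * factor,
        scale=scale,
        granularity=granularity,
        n=len(y),
    )


def evaluate_model(model, test_data: SVMatrix | MultichannelInput,
                   granularity: str = "row",
                   scale: str = "percent") -> MetricsReport:
    """Apply ``model.predict`` to the test representation and score it.

    For an :class:`SVMatrix`, ``granularity="row"`` scores every
    stable-value row; ``"per_sample"`` averages the 10 row predictions
    of each sample first. A :class:`MultichannelInput` is always scored
    per sample.
    """
    if isinstance(test_data, SVMatrix):
        pred = np.asarray(model.predict(test_data.rows), float)
        y = test_data.labels
        if granularity == "per_sample":
            pred = pred.reshape(-1, SV_POINTS).mean(axis=1)
            y = test_data.per_sample_labels()
    elif isinstance(test_data, MultichannelInput):
        pred = np.asarray(model.predict(test_data), float)
        y = test_data.labels
        granularity = "per_sample"
    else:
        raise TypeError(f"unsupported test data type {type(test_data)!r}")
    return compute_metrics(y, pred, scale=scale, granularity=granularity)


def pca_projection(
    sv: SVMatrix,
    n_components: int = 3,
    subset_seed: int | None = None,
    per_proportion: int | None = None,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of stable-value rows, optionally on a balanced random subset
    of samples (``per_proportion`` samples drawn per label, seeded).

    Features are mean-centered (and optionally scaled to unit variance);
    returns (component scores, explained variance ratios), components in
    descending-variance order. All of a selected sample's rows enter.
    """
    rows, labels = sv.rows, sv.labels
    if per_proportion is not None:
        rng = np.random.default_rng(subset_seed)
        samp_labels = sv.per_sample_labels()
        keep_samples: list[int] = []
        for p in np.unique(samp_labels):
            cand = np.flatnonzero(samp_labels == p)
            if len(cand) < per_proportion:
                raise ValueError(
                    f"only {len(cand)} samples at proportion {p}, need "
                    f"{per_proportion}"
                )
            keep_samples.extend(rng.choice(cand, per_proportion,
                                           replace=False))
        row_idx = np.concatenate([
            np.arange(s * SV_POINTS, (s + 1) * SV_POINTS)
            for s in sorted(keep_samples)
        ])
        rows = rows[row_idx]
    if n_components > rows.shape[1]:
        raise ValueError(
            f"n_components {n_components} exceeds feature count "
            f"{rows.shape[1]}"
        )
    X = rows - rows.mean(axis=0)
    if standardize:
        sd = rows.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
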