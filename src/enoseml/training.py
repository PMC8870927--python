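"""Training protocol: SGD/MSE CNN training with step-decayed learning
rate and periodic checkpoints, automated convergence-epoch selection,
3-fold grid search for the classical models, and hybrid assembly.

The CNN is trained with mini-batch SGD on MSE loss, initial learning
rate 0.001, and a fixed-step decay schedule (default: halve every 300
epochs). Batch size is 49 at the full training scale (147 samples) and
21 at the reduced scale (63 samples). Weights are checkpointed every 20
epochs plus the final epoch; a convergence epoch is then chosen as the
earliest epoch whose window-smoothed loss is within ``rel_tol`` of the
global minimum of the smoothed curve, and snapped to the nearest
checkpoint.

Grid search is exhaustive over the named grids with seeded 3-fold
cross-validation, stratified by the (discrete) adulteration proportion,
scored by mean CV MSE; ties break toward the earlier grid entry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold
from sklearn.svm import SVR as _SkSVR

from . import nn
from .features import MultichannelInput
from .models import (
    CNNRegressor,
    HybridModel,
    RFRParams,
    make_rfr,
)

# ---------------------------------------------------------------------------


@dataclass
class TrainHyper:
    """CNN training hyperparameters (MSE loss, momentum SGD)."""

    initial_lr: float = 0.001
    batch_size: int = 49
    n_epochs: int = 1100
    lr_step: int = 400
    lr_gamma: float = 0.6
    momentum: float = 0.99
    checkpoint_every: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be >= 1")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("lr_gamma must be in (0, 1]")


@dataclass
class TrainHistory:
    """Per-epoch losses plus a checkpoint registry (epoch -> weights)."""

    losses: np.ndarray
    checkpoints: dict[int, list[np.ndarray]]
    hyper: TrainHyper
    model: CNNRegressor | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.losses)

    def available_epochs(self) -> list[int]:
        return sorted(self.checkpoints)


def train_1dcnn(model: CNNRegressor, train_inputs: MultichannelInput,
                hyper: TrainHyper | None = None) -> TrainHistory:
    """Train the CNN regressor; deterministic given ``hyper.seed``.

    Labels are consumed as fractions. Raises on non-finite loss rather
    than silently diverging.
    """
    hyper = hyper or TrainHyper()
    X = np.asarray(train_inputs.tensor, float)
    y = np.asarray(train_inputs.labels, float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(hyper.seed)
    opt = nn.SGD(model.params(), hyper.initial_lr, hyper.momentum)
    losses = np.empty(hyper.n_epochs)
    checkpoints: dict[int, list[np.ndarray]] = {}
    n = X.shape[0]
    for epoch in range(1, hyper.n_epochs + 1):
        opt.lr = hyper.initial_lr * hyper.lr_gamma ** (
            (epoch - 1) // hyper.lr_step
        )
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            pred = model.forward(X[idx], training=True)
            loss, grad = nn.mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; the "
                    f"learning rate may be too high or the data degenerate"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            batch_losses.append(loss)
        losses[epoch - 1] = float(np.mean(batch_losses))
        if epoch % hyper.checkpoint_every == 0 or epoch == hyper.n_epochs:
            checkpoints[epoch] = model.state_dict()
    return TrainHistory(losses=losses, checkpoints=checkpoints, hyper=hyper,
                        model=model)


def smoothed_losses(losses: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average; entry e is the mean of losses[e-w+1 .. e]."""
    c = np.concatenate([[0.0], np.cumsum(losses)])
    out = np.full(len(losses), np.nan)
    out[window - 1:] = (c[window:] - c[:-window]) / window
    return out


def select_convergence_epoch(history: TrainHistory, window: int = 50,
                             rel_tol: float = 0.02) -> int:
    """Earliest (1-based) epoch whose smoothed loss is within ``rel_tol``
    of the smoothed-loss minimum.

    A run that plateaus early therefore reports the start of the
    plateau (up to window semantics), not the last epoch.
    """
    losses = np.asarray(history.losses, float)
    if not np.all(np.isfinite(losses)):
        raise ValueError("history contains non-finite losses")
    if len(losses) < window:
        raise ValueError(f"history shorter than window {window}")
    sm = smoothed_losses(losses, window)
    valid = sm[window - 1:]
    best = float(valid.min())
    thresh = best * (1.0 + rel_tol) if best > 0 else best + abs(rel_tol)
    first = int(np.argmax(valid <= thresh))
    return first + window  # convert index in `valid` to 1-based epoch


def nearest_checkpoint(history: TrainHistory, epoch: int) -> int:
    """Snap an epoch to the nearest checkpointed epoch (ties -> earlier)."""
    avail = history.available_epochs()
    if not avail:
        raise ValueError("history has no checkpoints")
    return min(avail, key=lambda e: (abs(e - epoch), e))


# ---------------------------------------------------------------------------
# grid search


#: Hyperparameter grids as printed in the study protocol.
SVR_GRID = {"C": (1, 5, 10, 20, 50, 100, 200, 500),
            "gamma": (0.01, 0.1, 1, 5, 10, 20)}
RFR_GRID = {"max_depth": (3, 5, 7, 9, 11, 13),
            "min_samples_split": (7, 14, 21, 28, 35, 42)}


@dataclass
class GridSpec:
    """A named parameter grid with the CV protocol attached."""

    grid: dict[str, Sequence]
    k_folds: int = 3
    seed: int = 0

    def combinations(self) -> list[dict]:
        keys = list(self.grid)
        if not keys:
            raise ValueError("empty grid")
        return [dict(zip(keys, vals))
                for vals in itertools.product(*(self.grid[k] for k in keys))]


@dataclass
class GridSearchResult:
    best_params: dict
    best_mse: float
    table: pd.DataFrame  # one row per combination: params, mean/std CV MSE


def _make_folds(y: np.ndarray, k: int, seed: int,
                groups: np.ndarray | None) -> list[tuple[np.ndarray, np.ndarray]]:
    if groups is not None:
        return list(GroupKFold(n_splits=k).split(y, groups=groups))
    # stratify by the discrete proportion label when possible
    strata = pd.factorize(np.round(np.asarray(y, float), 6))[0]
    if np.bincount(strata).min() >= k:
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros_like(strata), strata))
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(strata))


def grid_search_cv(
    model_family: str | Callable[[dict, np.ndarray], object],
    grid: GridSpec,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
) -> GridSearchResult:
    """Exhaustive seeded k-fold grid search minimizing mean CV MSE.

    ``model_family`` is ``"svr"``, ``"rfr"``, ``"bpnn"`` or a callable
    ``(params, X) -> unfitted sklearn estimator``. Folds are stratified
    by proportion (or blocked by ``groups`` if given). Ties break toward
    the earlier combination in grid-enumeration order.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if isinstance(model_family, str):
        fam = model_family.lower()
        if fam == "svr":
            def factory(p, X_):
                return _SkSVR(kernel="rbf", C=p["C"], gamma=p["gamma"],
                              epsilon=p.get("epsilon", 0.1))
        elif fam == "rfr":
            def factory(p, X_):
                return make_rfr(
                    RFRParams(max_depth=p["max_depth"],
                              min_samples_split=p["min_samples_split"],
                              seed=grid.seed),
                    X_.shape[1],
                )
        else:
            raise ValueError(f"unknown model family {model_family!r}")
    else:
        factory = model_family
    folds = _make_folds(y, grid.k_folds, grid.seed, groups)
    records = []
    best_i, best_mse = 0, np.inf
    combos = grid.combinations()
    for i, params in enumerate(combos):
        fold_mse = []
        for tr, te in folds:
            est = factory(params, X[tr])
            est.fit(X[tr], y[tr])
            resid = est.predict(X[te]) - y[te]
            fold_mse.append(float(np.mean(resid**2)))
        mean_mse = float(np.mean(fold_mse))
        records.append({**params, "mean_cv_mse": mean_mse,
                        "std_cv_mse": float(np.std(fold_mse))})
        if mean_mse < best_mse:  # strict: ties keep the earlier combo
            best_i, best_mse = i, mean_mse
    return GridSearchResult(best_params=combos[best_i], best_mse=best_mse,
                            table=pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# hybrid assembly


def assemble_hybrid(
    history: TrainHistory,
    epoch: int,
    rfr_grid: GridSpec,
    train_inputs: MultichannelInput,
) -> HybridModel:
    """Freeze the backbone at a checkpointed epoch and fit the forest.

    Restores the checkpoint into the trained model, extracts 128-dim
    inference-mode features for the training samples, grid-searches the
    forest on those features, and refits the winner on all of them.
    ``epoch`` must be exactly checkpointed; use
    :func:`nearest_checkpoint` to snap a convergence epoch first.
    """
    if history.model is None:
        raise ValueError("history carries no model reference")
    if epoch not in history.checkpoints:
        raise ValueError(
            f"epoch {epoch} not checkpointed; available: "
            f"{history.available_epochs()}"
        )
    model = history.model
    model.load_state_dict(history.checkpoints[epoch])
    feats = model.backbone.extract_features(train_inputs.tensor)
    y = np.asarray(train_inputs.labels, float)
    gs = grid_search_cv("rfr", rfr_grid, feats, y)
    params = RFRParams(max_depth=gs.best_params["max_depth"],
                       min_samples_split=gs.best_params["min_samples_split"],
                       seed=rfr_grid.seed)
    forest = make_rfr(params, feats.shape[1])
    forest.fit(feats, y)
    return HybridModel(backbone=model.backbone, forest=forest,
                       rfr_params=params)
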