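"""Brain-age regression on FNC features.

Three architectures behind one training contract:

* ``linear_baseline`` — closed-form ridge regression on (time-averaged)
  connectivity features; deterministic, used for fast calibration runs
  and as a transparent reference model.
* ``connectome_gcn`` — graph-convolution regressor over the static FNC
  matrix (see :mod:`dynbag.nets`).
* ``bilstm`` — bidirectional LSTM over the dynamic FNC window sequence.

Training follows the common brain-age recipe: grouped K-fold
cross-validation (scans of one subject never straddle train and
validation), Adam on mean absolute error, and selection of the epoch
with the best mean cross-validated MAE; the final model is refit on all
folds at the selected epoch budget. Out-of-fold predictions at the
selected epoch are kept so downstream brain-age gaps are out-of-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fnc import pearson
from .nets import Adam, BiLSTMRegressor, GCNRegressor, mae_loss

__all__ = [
    "ModelConfig",
    "desk_config",
    "fullscale_config",
    "TrainedBrainAgeModel",
    "train_brainage_cv",
    "predict_age",
    "evaluate_predictions",
    "ridge_closed_form",
]

ARCHITECTURES = ("linear_baseline", "connectome_gcn", "bilstm")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one brain-age regressor."""

    architecture: str = "linear_baseline"
    hidden_units: int = 128
    recurrent_layers: int = 3
    dropout: float = 0.1
    bidirectional: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    folds: int = 5
    ridge_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"valid: {list(ARCHITECTURES)}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def fullscale_config(architecture: str, seed: int = 0) -> ModelConfig:
    """Full-scale configuration: 3 recurrent layers of 128 hidden units,
    dropout 0.1, Adam(lr 1e-3), batch 64, 100 epochs, 5 folds."""
    return ModelConfig(architecture=architecture, seed=seed)


def desk_config(architecture: str, seed: int = 0) -> ModelConfig:
    """Desk-scale configuration for synthetic cohorts of a few hundred
    scans: 1 recurrent layer of 32 hidden units, 20 epochs, Adam(lr
    5e-3), batch 32. Small-sample training needs the larger step size
    and smaller batches to converge within the epoch budget."""
    return ModelConfig(architecture=architecture, hidden_units=32,
                       recurrent_layers=1, epochs=20, learning_rate=5e-3,
                       batch_size=32, seed=seed)


@dataclass
class TrainedBrainAgeModel:
    """Fitted brain-age regressor with its cross-validation report.

    ``cv_report`` is a (folds, epochs) array of validation MAE in years;
    ``selected_epoch`` (1-based) minimizes its mean over folds.
    ``oof_predictions`` are each scan's validation-fold predictions at
    the selected epoch, aligned with the training input order.
    """

    config: ModelConfig
    scope: str = "wide"
    modality: Optional[str] = None
    selected_epoch: int = 1
    cv_report: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    oof_predictions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fold_assignments: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    state: dict = field(default_factory=dict)

    @property
    def cv_mae(self) -> float:
        """Mean validation MAE (years) at the selected epoch."""
        return float(self.cv_report.mean(axis=0)[self.selected_epoch - 1])


# ---------------------------------------------------------------------------
# feature plumbing


def _prepare_features(features: np.ndarray, architecture: str) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x).reshape(x.shape[0], -1).all(axis=1))[0])
        raise ValueError(f"non-finite features in scan index {bad}")
    if architecture == "linear_baseline":
        if x.ndim == 3:  # dFNC window sequence -> time-averaged features
            x = x.mean(axis=1)
        if x.ndim != 2:
            raise ValueError("linear_baseline expects (N, F) or (N, W, F) features")
    elif architecture == "bilstm":
        if x.ndim != 3:
            raise ValueError("bilstm expects (N, W, F) window-sequence features")
    elif architecture == "connectome_gcn":
        if x.ndim != 3 or x.shape[1] != x.shape[2]:
            raise ValueError("connectome_gcn expects (N, C, C) connectivity matrices")
    return x


class _Scaler:
    """Column standardization with train-set statistics."""

    def __init__(self, x: np.ndarray):
        flat = x.reshape(-1, x.shape[-1]) if x.ndim == 3 else x
        self.mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


# ---------------------------------------------------------------------------
# ridge baseline


def ridge_closed_form(x: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Ridge solution on centered data: returns (coef, intercept)."""
    xm = x.mean(axis=0)
    ym = y.mean()
    xc = x - xm
    yc = y - ym
    a = xc.T @ xc + alpha * np.eye(x.shape[1])
    coef = np.linalg.solve(a, xc.T @ yc)
    return coef, float(ym - xm @ coef)


def _fit_linear(x: np.ndarray, y: np.ndarray, alpha: float) -> dict:
    scaler = _Scaler(x)
    coef, intercept = ridge_closed_form(scaler(x), y, alpha)
    return {"scaler": scaler, "coef": coef, "intercept": intercept,
            "n_features": x.shape[1]}


def _predict_linear(state: dict, x: np.ndarray) -> np.ndarray:
    return state["scaler"](x) @ state["coef"] + state["intercept"]


# ---------------------------------------------------------------------------
# gradient-trained nets


def _build_net(cfg: ModelConfig, x: np.ndarray, seed: int):
    if cfg.architecture == "bilstm":
        return BiLSTMRegressor(n_features=x.shape[2], hidden=cfg.hidden_units,
                               n_layers=cfg.recurrent_layers,
                               bidirectional=cfg.bidirectional,
                               dropout=cfg.dropout, seed=seed)
    return GCNRegressor(n_nodes=x.shape[1], hidden=cfg.hidden_units, seed=seed)


def _train_net(cfg: ModelConfig, x: np.ndarray, y: np.ndarray,
               x_val: Optional[np.ndarray], y_val: Optional[np.ndarray],
               epochs: int, seed: int):
    """Adam/MAE training loop; returns (state, per-epoch val MAE,
    per-epoch val predictions)."""
    standardize_x = cfg.architecture == "bilstm"
    scaler = _Scaler(x) if standardize_x else None
    xs = (scaler(x) if scaler else x).astype(np.float32)
    y_mean, y_sd = float(y.mean()), float(y.std())
    y_sd = y_sd if y_sd > 0 else 1.0
    ys = (y - y_mean) / y_sd
    net = _build_net(cfg, x, seed)
    # single-precision training: halves matmul cost; inference upcasts
    for name in net.params:
        net.params[name] = net.params[name].astype(np.float32)
    opt = Adam(net.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB47C]))
    n = xs.shape[0]
    val_mae = np.empty(epochs)
    val_preds = None
    if x_val is not None:
        xv = scaler(x_val) if scaler else x_val
        val_preds = np.empty((epochs, x_val.shape[0]))
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred, cache = net.forward(xs[idx], train=True, rng=rng)
            _, dpred = mae_loss(pred, ys[idx])
            grads = net.backward(cache, dpred)
            opt.step(grads)
        if x_val is not None:
            pv, _ = net.forward(xv, train=False)
            pv = pv * y_sd + y_mean
            val_preds[epoch] = pv
            val_mae[epoch] = float(np.mean(np.abs(pv - y_val)))
    state = {"net": net, "scaler": scaler, "y_mean": y_mean, "y_sd": y_sd,
             "input_shape": xs.shape[1:]}
    return state, val_mae, val_preds


def _predict_net(state: dict, x: np.ndarray) -> np.ndarray:
    xs = state["scaler"](x) if state["scaler"] else x
    pred, _ = state["net"].forward(xs, train=False)
    return pred * state["y_sd"] + state["y_mean"]


# ---------------------------------------------------------------------------
# public API


def _grouped_folds(groups: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold label per scan; all scans of a group share a fold."""
    uniq = np.unique(groups)
    if uniq.size < k:
        raise ValueError(f"need at least {k} distinct groups for {k}-fold CV, "
                         f"got {uniq.size}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF07D]))
    order = rng.permutation(uniq)
    fold_of_group = {g: f for f, chunk in enumerate(np.array_split(order, k)) for g in chunk}
    return np.array([fold_of_group[g] for g in groups], dtype=int)


def train_brainage_cv(
    features: np.ndarray,
    ages: np.ndarray,
    groups: Optional[np.ndarray] = None,
    cfg: ModelConfig = ModelConfig(),
    scope: str = "wide",
    modality: Optional[str] = None,
) -> TrainedBrainAgeModel:
    """Grouped K-fold cross-validated training of a brain-age regressor.

    One age per scan; ``groups`` carries subject ids when subjects have
    multiple scans (defaults to one group per scan). Deterministic given
    ``cfg.seed``.
    """
    x = _prepare_features(features, cfg.architecture)
    y = np.asarray(ages, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("need exactly one age per scan")
    if not np.all(np.isfinite(y)):
        raise ValueError("ages contain non-finite values")
    groups = np.asarray(groups) if groups is not None else np.arange(x.shape[0])
    if groups.shape[0] != x.shape[0]:
        raise ValueError("need exactly one group per scan")
    fold = _grouped_folds(groups, cfg.folds, cfg.seed)

    linear = cfg.architecture == "linear_baseline"
    n_epochs = 1 if linear else cfg.epochs
    cv_report = np.empty((cfg.folds, n_epochs))
    per_epoch_val: list[tuple[np.ndarray, np.ndarray]] = []
    for f in range(cfg.folds):
        tr, va = fold != f, fold == f
        if linear:
            state = _fit_linear(x[tr], y[tr], cfg.ridge_alpha)
            pv = _predict_linear(state, x[va])
            cv_report[f, 0] = float(np.mean(np.abs(pv - y[va])))
            per_epoch_val.append((np.flatnonzero(va), pv[None, :]))
        else:
            _, val_mae, val_preds = _train_net(
                cfg, x[tr], y[tr], x[va], y[va], n_epochs,
                seed=int(np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, 0xF17, f])).integers(2**31)),
            )
            cv_report[f] = val_mae
            per_epoch_val.append((np.flatnonzero(va), val_preds))

    selected = int(np.argmin(cv_report.mean(axis=0))) + 1
    oof = np.empty(x.shape[0])
    for idx, preds in per_epoch_val:
        oof[idx] = preds[selected - 1]

    refit_seed = int(np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x2EF17])).integers(2**31))
    if linear:
        state = _fit_linear(x, y, cfg.ridge_alpha)
    else:
        state, _, _ = _train_net(cfg, x, y, None, None, selected, seed=refit_seed)

    return TrainedBrainAgeModel(
        config=cfg, scope=scope, modality=modality, selected_epoch=selected,
        cv_report=cv_report, oof_predictions=oof, fold_assignments=fold,
        state=state,
    )


def predict_age(model: TrainedBrainAgeModel, features: np.ndarray) -> np.ndarray:
    """Deterministic inference: one predicted age (years) per scan."""
    x = _prepare_features(features, model.config.architecture)
    if model.config.architecture == "linear_baseline":
        expect = model.state["n_features"]
        if x.shape[1] != expect:
            raise ValueError(f"expected {expect} features, received {x.shape[1]}")
        return _predict_linear(model.state, x)
    expect = model.state["input_shape"]
    if x.shape[1:] != expect:
        raise ValueError(f"expected per-scan feature shape {expect}, "
                         f"received {x.shape[1:]}")
    return _predict_net(model.state, x)


def evaluate_predictions(pred: np.ndarray, chron: np.ndarray) -> dict[str, float]:
    """MAE (years) and Pearson r between predicted and chronological age."""
    pred = np.asarray(pred, dtype=float)
    chron = np.asarray(chron, dtype=float)
    if pred.shape != chron.shape:
        raise ValueError("prediction and age vectors must align")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(chron))):
        raise ValueError("non-finite values in predictions or ages")
    return {"mae": float(np.mean(np.abs(pred - chron))),
            "r": pearson(pred, chron)}
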