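"""Regression-residual PBRTQC: a covariate network feeds residuals to SPC.

Patient results vary mostly because patients vary.  A small
feed-forward network (inputs -> 20 -> 10 -> 1, tanh hidden units,
linear output) learns the mapping from patient covariates — age, sex,
department, diagnosis and a baseline feature — to the Box-Cox +
z-score transformed result.  The residual between the transformed
actual result and the prediction strips the explainable inter-patient
variation; substituting residuals for raw results as the SPC input
shrinks the monitored noise and speeds up error detection.

Training values are truncated to the [p1, p99] percentile band before
the Box-Cox fit (outlier removal); at monitoring time truncation is
NOT applied — biased values must reach the monitor.  All transform
parameters and encoder levels are frozen after training.  The training
set is split internally 70/15/15 into train/validation/test subsets;
optimization stops early when the validation MSE stalls.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.neural_network import MLPRegressor

from . import spc
from .datagen import AnalyteStream

__all__ = [
    "NNConfig",
    "PreprocessParams",
    "FeatureEncoder",
    "ResidualModel",
    "tanh_activation",
    "preprocess_train",
    "transform_values",
    "fit_residual_model",
    "residual_stream",
    "run_nn_monitor",
]

_CATEGORICAL = ["sex", "patient_category", "department", "diagnosis"]
_UNSEEN = "__unseen__"


def tanh_activation(z):
    """Hyperbolic tangent, (1 - e^{-2z}) / (1 + e^{-2z}).

    Evaluated as ``numpy.tanh`` (the same function in overflow-safe
    form); the hidden-unit nonlinearity of the regression network.
    """
    return np.tanh(z)


@dataclass(frozen=True)
class NNConfig:
    """Architecture and training settings of the residual network."""

    hidden_sizes: tuple = (20, 10)
    splits: tuple = (0.70, 0.15, 0.15)
    trunc_percentiles: tuple = (0.01, 0.99)
    max_epochs: int = 200
    patience: int = 20
    batch_size: int = 256
    learning_rate_init: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("internal split fractions must sum to 1")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass(frozen=True)
class PreprocessParams:
    """Frozen value transform: Box-Cox (MLE lambda) then z-score."""

    boxcox_lambda: float
    shift: float  # added before Box-Cox when non-positive values occur
    mean: float
    sd: float
    trunc_lo: float  # realized truncation bounds (training only)
    trunc_hi: float


def preprocess_train(
    values: np.ndarray, trunc_percentiles: tuple = (0.01, 0.99)
) -> tuple[np.ndarray, PreprocessParams]:
    """Fit the value transform on training data.

    Values outside the [p1, p99] percentile band are removed
    (truncation), the Box-Cox exponent is estimated by maximum
    likelihood on the remainder, and a z-score is fitted on the
    transformed values.  Returns the transformed kept values and the
    frozen parameters.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot preprocess an empty training set")
    lo, hi = np.quantile(x, trunc_percentiles)
    kept = x[(x >= lo) & (x <= hi)]
    shift = 0.0
    if kept.min() <= 0.0:
        shift = 1.0 - kept.min()
    transformed, lam = stats.boxcox(kept + shift)
    mean, sd = float(transformed.mean()), float(transformed.std())
    if sd <= 0.0:
        raise ValueError("degenerate training data: zero variance after transform")
    pp = PreprocessParams(
        boxcox_lambda=float(lam), shift=shift, mean=mean, sd=sd,
        trunc_lo=float(lo), trunc_hi=float(hi),
    )
    return (transformed - mean) / sd, pp


def transform_values(values, pp: PreprocessParams) -> np.ndarray:
    """Apply the frozen Box-Cox + z-score transform (no truncation)."""
    x = np.asarray(values, dtype=float) + pp.shift
    t = special.boxcox(x, pp.boxcox_lambda)
    return (t - pp.mean) / pp.sd


@dataclass
class FeatureEncoder:
    """Total covariate encoder: one-hot categoricals with a reserved
    unseen level, standardized age, and a constant baseline feature.

    The baseline input is the patient's most recent prior transformed
    result when a ``patient_id`` column links repeat visits; synthetic
    streams have no repeat visits, so it falls back to the training
    median (a constant) for every sample.
    """

    levels: dict = field(default_factory=dict)
    age_mean: float = 0.0
    age_sd: float = 1.0
    baseline_default: float = 0.0
    unseen_seen: list = field(default_factory=list)

    def fit(self, frame: pd.DataFrame, baseline_default: float) -> "FeatureEncoder":
        self.levels = {c: sorted(frame[c].astype(str).unique()) for c in _CATEGORICAL}
        age = frame["age"].to_numpy(dtype=float)
        self.age_mean = float(age.mean())
        self.age_sd = float(age.std()) or 1.0
        self.baseline_default = float(baseline_default)
        return self

    def encode(self, frame: pd.DataFrame) -> np.ndarray:
        cols = [((frame["age"].to_numpy(dtype=float) - self.age_mean) / self.age_sd)]
        for c in _CATEGORICAL:
            vals = frame[c].astype(str)
            known = set(self.levels[c])
            unseen_mask = ~vals.isin(known)
            if unseen_mask.any() and c not in self.unseen_seen:
                self.unseen_seen.append(c)
                warnings.warn(
                    f"unseen {c} categories mapped to the reserved level", stacklevel=2
                )
            for level in self.levels[c]:
                cols.append((vals == level).to_numpy(dtype=float))
            cols.append(unseen_mask.to_numpy(dtype=float))  # reserved level
        cols.append(np.full(len(frame), self.baseline_default))
        return np.column_stack(cols)


class _ZeroNet:
    """Degenerate predictor (constant 0): residuals equal the
    transformed values, so the residual monitor must reproduce an SPC
    run on transformed values exactly."""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.zeros(len(X))


@dataclass
class ResidualModel:
    """Fitted residual-regression model: encoder + transform + network."""

    preprocess: PreprocessParams
    encoder: FeatureEncoder
    net: object  # MLPRegressor or _ZeroNet
    cfg: NNConfig | None = None
    mse: dict = field(default_factory=dict)

    @classmethod
    def zero(cls, preprocess: PreprocessParams, encoder: FeatureEncoder) -> "ResidualModel":
        """Zero-weight degenerate model (oracle for equivalence tests)."""
        return cls(preprocess=preprocess, encoder=encoder, net=_ZeroNet())

    def residuals_from_transformed(
        self, transformed: np.ndarray, frame: pd.DataFrame
    ) -> np.ndarray:
        X = self.encoder.encode(frame)
        return np.asarray(transformed, dtype=float) - self.net.predict(X)


def fit_residual_model(train: AnalyteStream, cfg: NNConfig = NNConfig()) -> ResidualModel:
    """Train the covariate network on the training partition.

    The (truncated, transformed) training values are split 70/15/15 at
    random into internal train/validation/test subsets.  The network
    is optimized epoch by epoch with Adam; the weights with the best
    internal-validation MSE are kept, and optimization stops after
    ``cfg.patience`` epochs without improvement.  Deterministic for a
    fixed ``cfg.seed``.
    """
    frame = train.frame
    values = frame["value"].to_numpy(dtype=float)
    y_all, pp = preprocess_train(values, cfg.trunc_percentiles)
    keep = (values >= pp.trunc_lo) & (values <= pp.trunc_hi)
    kept_frame = frame.loc[keep].reset_index(drop=True)

    encoder = FeatureEncoder().fit(kept_frame, baseline_default=float(np.median(y_all)))
    X = encoder.encode(kept_frame)

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(X))
    n_tr = int(len(X) * cfg.splits[0])
    n_val = int(len(X) * cfg.splits[1])
    idx_tr, idx_val = order[:n_tr], order[n_tr : n_tr + n_val]
    idx_te = order[n_tr + n_val :]

    net = MLPRegressor(
        hidden_layer_sizes=cfg.hidden_sizes,
        activation="tanh",
        solver="adam",
        batch_size=min(cfg.batch_size, max(1, n_tr)),
        learning_rate_init=cfg.learning_rate_init,
        random_state=cfg.seed,
        max_iter=1,
    )
    best = None
    best_val = np.inf
    stale = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-epoch partial_fit convergence chatter
        for _ in range(cfg.max_epochs):
            net.partial_fit(X[idx_tr], y_all[idx_tr])
            val_mse = float(np.mean((net.predict(X[idx_val]) - y_all[idx_val]) ** 2))
            if val_mse < best_val - 1e-6:
                best_val = val_mse
                best = (copy.deepcopy(net.coefs_), copy.deepcopy(net.intercepts_))
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best is None:
        raise RuntimeError("residual network failed to complete a training epoch")
    net.coefs_, net.intercepts_ = best

    mse = {
        name: float(np.mean((net.predict(X[idx]) - y_all[idx]) ** 2))
        for name, idx in (("train", idx_tr), ("validation", idx_val), ("test", idx_te))
        if len(idx)
    }
    return ResidualModel(preprocess=pp, encoder=encoder, net=net, cfg=cfg, mse=mse)


def residual_stream(window: pd.DataFrame, model: ResidualModel) -> np.ndarray:
    """Residuals for a monitored window (frozen transform, no truncation)."""
    transformed = transform_values(window["value"].to_numpy(dtype=float), model.preprocess)
    return model.residuals_from_transformed(transformed, window)


def tune_nn_monitor(
    train: AnalyteStream,
    validation: AnalyteStream,
    model: ResidualModel,
    **grid_kwargs,
) -> spc.GridSearchResult:
    """Block-size search on the residual series (reuses the SPC search)."""
    return spc.grid_search(
        train, validation, monitor_input=lambda f: residual_stream(f, model), **grid_kwargs
    )


def run_nn_monitor(
    window: pd.DataFrame,
    model: ResidualModel,
    params: spc.EWMAParams,
    training_tail_residuals: np.ndarray,
) -> spc.ControlSeries:
    """Monitor one window's residual series against fitted EWMA limits."""
    return spc.run_monitor(residual_stream(window, model), params, training_tail_residuals)
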