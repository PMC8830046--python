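"""Committor regression with a multilayer perceptron trained by
likelihood maximization.

The network maps a feature vector X to a scalar reaction coordinate
q~(X); the predicted committor is obtained through the logistic link

    p_A(X) = 1 / (1 + exp(-q~))  =  (1 + tanh(q~/2)) / 2,

the two forms being the same function exactly.  Given shooting-point
counts (n_A^i, n_B^i), the weights minimize the negative log likelihood

    l = - sum_i [ n_A^i ln p_A(X_i) + n_B^i ln(1 - p_A(X_i)) ],

i.e. a binomial regression with a learned nonlinear predictor.  Training
follows the standard deep-regression recipe: feature standardization fit
on the training rows only, Adam, batch size 128, early stopping on the
validation loss (patience 10, best weights restored), and a refinement
stage with plateau-triggered learning-rate reduction (factor 5 down to
1e-5, plateau patience 7).

Implementation is plain NumPy: dense layers with ReLU or SELU
activations, Glorot-uniform or LeCun-normal initialization respectively,
and an optional dropout layer (standard for ReLU, alpha-dropout for
SELU) at a configurable position.  Dropout is inactive at inference, so
predictions are deterministic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.special import expit

from . import defaults
from .data import ShootingDataset

__all__ = [
    "MLPSpec",
    "CommittorModel",
    "link",
    "nll_loss",
    "saturated_loss",
    "predict_q",
    "train",
    "refine",
    "rms_committor_error",
]

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


@dataclasses.dataclass
class MLPSpec:
    """Architecture hyperparameters of the committor network."""

    n_hidden_layers: int = 2
    neurons_per_layer: int = 64
    activation: str = "relu"
    dropout_position: str = "none"
    dropout_rate: float = 0.0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if not 1 <= self.n_hidden_layers <= 6:
            raise ValueError("n_hidden_layers must be in 1..6")
        if not 32 <= self.neurons_per_layer <= 256:
            raise ValueError("neurons_per_layer must be in 32..256")
        if self.activation not in ("relu", "selu"):
            raise ValueError("activation must be 'relu' or 'selu'")
        if self.dropout_position not in (
            "none", "after_input", "middle", "before_output"
        ):
            raise ValueError(f"bad dropout_position {self.dropout_position!r}")
        if not 0.0 <= self.dropout_rate <= 0.40:
            raise ValueError("dropout_rate must be in [0, 0.40]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def link(q: np.ndarray | float) -> np.ndarray | float:
    """Logistic link p = 1/(1+exp(-q)) = (1+tanh(q/2))/2."""
    return expit(q)


def nll_loss(
    predictions: np.ndarray,
    n_A: np.ndarray,
    n_B: np.ndarray,
    eps: float = defaults.PROB_EPS,
) -> float:
    """Negative log likelihood l = -sum_i [n_A ln p_i + n_B ln(1-p_i)].

    Predicted probabilities are clipped to [eps, 1-eps] so that a
    saturated prediction cannot produce an infinite loss.
    """
    p = np.clip(np.asarray(predictions, dtype=float), eps, 1.0 - eps)
    n_A = np.asarray(n_A, dtype=float)
    n_B = np.asarray(n_B, dtype=float)
    if p.shape != n_A.shape or p.shape != n_B.shape:
        raise ValueError("predictions and counts must have matching shapes")
    return float(-(n_A * np.log(p) + n_B * np.log1p(-p)).sum())


def saturated_loss(n_A: np.ndarray, n_B: np.ndarray) -> float:
    """Loss of the saturated model p_i = n_A/(n_A+n_B); a lower bound on
    the loss attainable by any predictor."""
    n_A = np.asarray(n_A, dtype=float)
    n_B = np.asarray(n_B, dtype=float)
    tot = n_A + n_B
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, n_A / np.maximum(tot, 1), 0.5)
        terms = np.where(n_A > 0, n_A * np.log(p), 0.0) + np.where(
            n_B > 0, n_B * np.log(1 - p), 0.0
        )
    return float(-terms.sum())


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _init_params(
    spec: MLPSpec, n_features: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    sizes = [n_features] + [spec.neurons_per_layer] * spec.n_hidden_layers + [1]
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        if spec.activation == "relu":
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        else:
            W = rng.normal(0.0, math.sqrt(1.0 / fan_in), size=(fan_in, fan_out))
        params.append((W, np.zeros(fan_out)))
    return params


def _act(spec: MLPSpec, z: np.ndarray) -> np.ndarray:
    if spec.activation == "relu":
        return np.maximum(z, 0.0)
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))


def _act_grad(spec: MLPSpec, z: np.ndarray) -> np.ndarray:
    if spec.activation == "relu":
        return (z > 0).astype(float)
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


def _dropout_slot(spec: MLPSpec) -> int | None:
    """Index of the activation (0 = input) after which dropout applies."""
    if spec.dropout_position == "none" or spec.dropout_rate == 0.0:
        return None
    if spec.dropout_position == "after_input":
        return 0
    if spec.dropout_position == "middle":
        return (spec.n_hidden_layers + 1) // 2
    return spec.n_hidden_layers  # before_output


def _apply_dropout(
    spec: MLPSpec, a: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, tuple]:
    p = spec.dropout_rate
    mask = rng.random(a.shape) >= p
    if spec.activation == "relu":
        out = a * mask / (1.0 - p)
        return out, ("std", mask)
    # alpha dropout keeps the self-normalizing mean/variance
    ap = -_SELU_SCALE * _SELU_ALPHA
    q = 1.0 - p
    scale = (q + ap**2 * q * p) ** -0.5
    shift = -scale * p * ap
    out = scale * (np.where(mask, a, ap)) + shift
    return out, ("alpha", mask, scale)


def _forward(
    spec: MLPSpec,
    params: Sequence[tuple[np.ndarray, np.ndarray]],
    X: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list]:
    """Forward pass; when rng is given, dropout is active (training)."""
    slot = _dropout_slot(spec) if rng is not None else None
    cache: list = []
    a = X
    drop_meta = None
    if slot == 0 and rng is not None:
        a, drop_meta = _apply_dropout(spec, a, rng)
    cache.append(("input", X, a, drop_meta))
    n_layers = len(params)
    for li, (W, b) in enumerate(params):
        z = a @ W + b
        is_output = li == n_layers - 1
        if is_output:
            cache.append(("output", a, z, None))
            a = z
        else:
            h = _act(spec, z)
            drop_meta = None
            if slot == li + 1 and rng is not None:
                h, drop_meta = _apply_dropout(spec, h, rng)
            cache.append(("hidden", a, z, drop_meta))
            a = h
    return a[:, 0], cache


def _backward(
    spec: MLPSpec,
    params: Sequence[tuple[np.ndarray, np.ndarray]],
    cache: list,
    dq: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gradients of the batch loss w.r.t. every (W, b)."""
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params)  # type: ignore
    delta = dq[:, None]  # gradient w.r.t. the linear output
    for li in range(len(params) - 1, -1, -1):
        kind, a_in, z, drop_meta = cache[li + 1]
        W, _ = params[li]
        grads[li] = (a_in.T @ delta, delta.sum(axis=0))
        if li == 0:
            break
        delta = delta @ W.T
        # delta now sits after the activation (and dropout) of layer li-1
        _, a_prev_in, z_prev, drop_prev = cache[li]
        if drop_prev is not None:
            if drop_prev[0] == "std":
                _, mask = drop_prev
                delta = delta * mask / (1.0 - spec.dropout_rate)
            else:
                _, mask, scale = drop_prev
                delta = delta * mask * scale
        delta = delta * _act_grad(spec, z_prev)
    return grads


@dataclasses.dataclass
class CommittorModel:
    """A trained committor network with its normalization and history."""

    spec: MLPSpec
    params: list[tuple[np.ndarray, np.ndarray]]
    norm_mean: np.ndarray
    norm_std: np.ndarray
    training_history: dict
    feature_names: list[str] | None = None

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.norm_mean) / self.norm_std

    def predict_q(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.norm_mean.size:
            raise ValueError(
                f"expected {self.norm_mean.size} features, got {X.shape[1]}"
            )
        q, _ = _forward(self.spec, self.params, self._normalize(X), rng=None)
        return q

    def predict_p(self, X: np.ndarray) -> np.ndarray:
        return link(self.predict_q(X))

    @property
    def validation_loss(self) -> float:
        return self.training_history["best_val_loss"]


def predict_q(model: CommittorModel, features: np.ndarray) -> np.ndarray:
    """Deterministic forward pass to the scalar reaction coordinate."""
    return model.predict_q(features)


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        new = []
        for i, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
            mW, mb = self.m[i]
            vW, vb = self.v[i]
            mW = self.beta1 * mW + (1 - self.beta1) * gW
            mb = self.beta1 * mb + (1 - self.beta1) * gb
            vW = self.beta2 * vW + (1 - self.beta2) * gW**2
            vb = self.beta2 * vb + (1 - self.beta2) * gb**2
            self.m[i] = (mW, mb)
            self.v[i] = (vW, vb)
            W = W - self.lr * (mW / b1c) / (np.sqrt(vW / b2c) + self.eps)
            b = b - self.lr * (mb / b1c) / (np.sqrt(vb / b2c) + self.eps)
            new.append((W, b))
        return new


def _split_arrays(data: ShootingDataset, tag: str):
    mask = data.rows(tag)
    return data.features[mask], data.n_A[mask].astype(float), data.n_B[mask].astype(float)


def _epoch_loop(
    spec: MLPSpec,
    params,
    data: ShootingDataset,
    *,
    epochs: int,
    batch_size: int,
    patience: int,
    rng: np.random.Generator,
    norm: tuple[np.ndarray, np.ndarray],
    optimizer: _Adam,
    history: dict,
    plateau_patience: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shared optimization loop for train() and refine().

    Returns the best-validation-loss parameters.  When plateau_patience
    is set, the learning rate is divided by 5 (floor 1e-5) whenever the
    validation loss fails to improve for that many consecutive epochs.
    """
    mean, std = norm
    Xtr, nAtr, nBtr = _split_arrays(data, "train")
    Xva, nAva, nBva = _split_arrays(data, "validation")
    Xtr = (Xtr - mean) / std
    Xva = (Xva - mean) / std
    n_train = Xtr.shape[0]

    best_params = [(W.copy(), b.copy()) for W, b in params]
    best_val = history.get("best_val_loss", math.inf)
    wait = 0
    plateau_wait = 0
    for _ in range(epochs):
        order = rng.permutation(n_train)
        ep_loss = 0.0
        for start in range(0, n_train, batch_size):
            idx = order[start : start + batch_size]
            q, cache = _forward(spec, params, Xtr[idx], rng=rng)
            p = np.clip(expit(q), defaults.PROB_EPS, 1 - defaults.PROB_EPS)
            nA, nB = nAtr[idx], nBtr[idx]
            ep_loss += float(-(nA * np.log(p) + nB * np.log1p(-p)).sum())
            # d/dq of the per-batch mean loss
            dq = ((nA + nB) * p - nA) / idx.size
            grads = _backward(spec, params, cache, dq)
            params = optimizer.step(params, grads)
        qv, _ = _forward(spec, params, Xva, rng=None)
        val = nll_loss(expit(qv), nAva, nBva)
        history["train_loss"].append(ep_loss)
        history["val_loss"].append(val)
        history["lr"].append(optimizer.lr)
        if val < best_val:
            best_val = val
            best_params = [(W.copy(), b.copy()) for W, b in params]
            wait = 0
            plateau_wait = 0
        else:
            wait += 1
            plateau_wait += 1
            if plateau_patience is not None and plateau_wait >= plateau_patience:
                optimizer.lr = max(
                    optimizer.lr / defaults.LR_REDUCTION_FACTOR, defaults.LR_FLOOR
                )
                plateau_wait = 0
            if wait >= patience:
                break
    history["best_val_loss"] = best_val
    return best_params


def train(
    spec: MLPSpec,
    data: ShootingDataset,
    epochs: int = defaults.SEARCH_EPOCHS,
    batch_size: int = defaults.BATCH_SIZE,
    patience: int = defaults.EARLY_STOP_PATIENCE,
    rng_seed: int = 0,
) -> CommittorModel:
    """Fit the committor network by minimizing the likelihood loss.

    Features are standardized to mean 0 / sd 1 using the training rows
    only.  Training stops early when the validation loss fails to improve
    for ``patience`` epochs; the best-validation weights are returned.
    """
    if data.split_tags is None:
        raise ValueError("dataset needs split tags; call assign_split first")
    for tag in ("train", "validation"):
        if not np.any(data.rows(tag)):
            raise ValueError(f"empty {tag} split")
    rng = np.random.default_rng(rng_seed)
    Xtr = data.features[data.rows("train")]
    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0)
    std = np.where(std > 0, std, 1.0)

    params = _init_params(spec, data.n_features, rng)
    optimizer = _Adam(params, lr=spec.learning_rate)
    history = {"train_loss": [], "val_loss": [], "lr": [], "best_val_loss": math.inf}
    best = _epoch_loop(
        spec, params, data,
        epochs=epochs, batch_size=batch_size, patience=patience,
        rng=rng, norm=(mean, std), optimizer=optimizer, history=history,
    )
    return CommittorModel(
        spec=spec, params=best, norm_mean=mean, norm_std=std,
        training_history=history, feature_names=list(data.feature_names),
    )


def refine(
    model: CommittorModel,
    data: ShootingDataset,
    max_epochs: int = defaults.REFINE_EPOCHS,
    batch_size: int = defaults.BATCH_SIZE,
    patience: int = defaults.EARLY_STOP_PATIENCE,
    rng_seed: int = 1,
) -> CommittorModel:
    """Continue training with plateau-triggered learning-rate reduction.

    The learning rate is divided by 5 whenever the validation loss
    plateaus for 7 epochs, down to a floor of 1e-5; early stopping and
    best-weights restoration operate as in ``train``.
    """
    rng = np.random.default_rng(rng_seed)
    params = [(W.copy(), b.copy()) for W, b in model.params]
    optimizer = _Adam(params, lr=model.training_history["lr"][-1]
                      if model.training_history["lr"] else model.spec.learning_rate)
    history = {
        "train_loss": list(model.training_history["train_loss"]),
        "val_loss": list(model.training_history["val_loss"]),
        "lr": list(model.training_history["lr"]),
        "best_val_loss": model.training_history["best_val_loss"],
    }
    best = _epoch_loop(
        model.spec, params, data,
        epochs=max_epochs, batch_size=batch_size, patience=patience,
        rng=rng, norm=(model.norm_mean, model.norm_std),
        optimizer=optimizer, history=history,
        plateau_patience=defaults.LR_PLATEAU_PATIENCE,
    )
    return CommittorModel(
        spec=model.spec, params=best, norm_mean=model.norm_mean,
        norm_std=model.norm_std, training_history=history,
        feature_names=model.feature_names,
    )


def rms_committor_error(
    model: CommittorModel,
    data: ShootingDataset,
    tag: str = "test",
    reference: str = "empirical",
) -> float:
    """RMS deviation of predicted from reference committors (fractional
    units; multiply by 100 for percent).

    ``reference='empirical'`` compares against n_A/(n_A+n_B);
    ``'true'`` against the stored generating law (synthetic data only).
    """
    mask = data.rows(tag) if tag != "all" else np.ones(data.n_points, bool)
    pred = model.predict_p(data.features[mask])
    if reference == "true":
        if data.p_true is None:
            raise ValueError("dataset carries no generating committor law")
        ref = data.p_true[mask]
    else:
        ref = data.p_A[mask]
    ok = np.isfinite(ref)
    return float(np.sqrt(np.mean((pred[ok] - ref[ok]) ** 2)))
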