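"""Feed-forward regressor with a from-scratch Levenberg-Marquardt trainer.

The model is a fully connected multi-input multi-output network,
by default 5-12-10-8-4 (tanh hidden layers, identity output), mapping
the encoded subject vector to the encoded FITT prescription.

Training minimizes the L2-regularized loss

    L = MSE + alpha * sum_j w_j^2

where the MSE averages squared residuals over all samples and output
dimensions jointly and the penalty runs over weights only (biases are
excluded by default).  The LM update solves the damped normal equations

    delta_w = (J^T J + lambda I)^{-1} J^T e

on the stacked residual vector e = [r / sqrt(N*m); sqrt(alpha) * w],
whose squared norm is exactly L, so the penalty enters the step as extra
Gauss-Newton rows rather than as an ad-hoc gradient term.  The damping
factor shrinks (x0.1) after an accepted step and grows (x10) after a
rejected one, interpolating between Gauss-Newton and gradient descent;
accepted steps never increase L.  Early stopping monitors validation
loss with a fixed patience and the best-validation snapshot is returned.

The Jacobian of residuals is available analytically (per-sample reverse
accumulation) or by forward finite differences with a configurable step.
A plain gradient-descent-with-momentum trainer is included as the
conventional back-propagation baseline; its learning rate eta and
momentum beta have no role in the LM path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger("fitrx")

__all__ = [
    "LayerSpec",
    "NetworkState",
    "TrainConfig",
    "LMState",
    "LossParts",
    "TrainResult",
    "init_network",
    "forward",
    "forward_batch",
    "loss",
    "jacobian",
    "gradient",
    "lm_step",
    "train",
    "hidden_neuron_range",
    "save_checkpoint",
    "load_checkpoint",
    "DEFAULT_LAYER_SIZES",
]

DEFAULT_LAYER_SIZES = (5, 12, 10, 8, 4)

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass(frozen=True)
class LayerSpec:
    """Layer widths (input first, output last) and activations."""

    sizes: tuple[int, ...] = DEFAULT_LAYER_SIZES
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if len(self.sizes) < 2 or any(s < 1 for s in self.sizes):
            raise ValueError("need >= 2 layers with all widths >= 1")
        for name in (self.hidden_activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")

    @property
    def n_params(self) -> int:
        return sum((fi + 1) * fo for fi, fo in zip(self.sizes, self.sizes[1:]))


@dataclass
class NetworkState:
    """Weights and biases per layer; weights[l] has shape (fan_in, fan_out).

    ``input_center``/``input_scale``, when set, min-max map raw inputs to
    [-1, 1] before the first layer (the optional input-scaling switch;
    off by default).  They are part of the model, not the trainer, so
    checkpoints and inference stay consistent.
    """

    spec: LayerSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_center: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    def set_input_scaling(self, X: np.ndarray) -> "NetworkState":
        """Fit min-max scaling to [-1, 1] on the given (training) inputs."""
        X = np.asarray(X, dtype=float)
        lo, hi = X.min(axis=0), X.max(axis=0)
        self.input_center = (hi + lo) / 2.0
        self.input_scale = np.where(hi > lo, (hi - lo) / 2.0, 1.0)
        return self

    def _scale_inputs(self, X: np.ndarray) -> np.ndarray:
        if self.input_center is None:
            return X
        return (X - self.input_center) / self.input_scale

    def flatten(self) -> np.ndarray:
        parts = []
        for W, b in zip(self.weights, self.biases):
            parts.append(W.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    def with_params(self, w: np.ndarray) -> "NetworkState":
        weights, biases = [], []
        i = 0
        for fi, fo in zip(self.spec.sizes, self.spec.sizes[1:]):
            weights.append(w[i : i + fi * fo].reshape(fi, fo).copy())
            i += fi * fo
            biases.append(w[i : i + fo].copy())
            i += fo
        if i != len(w):
            raise ValueError("parameter vector length mismatch")
        return NetworkState(
            self.spec, weights, biases, self.input_center, self.input_scale
        )

    def weight_mask(self) -> np.ndarray:
        """Boolean mask over the flat parameter vector: True for weights,
        False for biases (the L2 penalty scope)."""
        parts = []
        for fi, fo in zip(self.spec.sizes, self.spec.sizes[1:]):
            parts.append(np.ones(fi * fo, dtype=bool))
            parts.append(np.zeros(fo, dtype=bool))
        return np.concatenate(parts)

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.spec,
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            None if self.input_center is None else self.input_center.copy(),
            None if self.input_scale is None else self.input_scale.copy(),
        )


def init_network(spec: LayerSpec, rng: np.random.Generator) -> NetworkState:
    """Symmetric uniform initialization scaled by fan-in; biases start at 0."""
    weights, biases = [], []
    for fi, fo in zip(spec.sizes, spec.sizes[1:]):
        r = 1.0 / np.sqrt(fi)
        weights.append(rng.uniform(-r, r, size=(fi, fo)))
        biases.append(np.zeros(fo))
    return NetworkState(spec, weights, biases)


@dataclass(frozen=True)
class TrainConfig:
    """Trainer settings.

    ``eta`` (learning rate) and ``beta`` (momentum) apply only to the
    gradient-descent baseline; the LM path is governed by ``lambda0``
    and the damping schedule.  ``error_precision`` is the training-MSE
    goal, ``patience`` the early-stopping window in epochs.
    """

    eta: float = 0.01
    beta: float = 0.9
    alpha: float = 0.001
    lambda0: float = 0.01
    fd_step: float = 1e-5
    error_precision: float = 1e-7
    patience: int = 10
    max_epochs: int = 1000
    display_interval: int = 25
    jacobian_mode: str = "analytic"
    algorithm: str = "lm"
    lambda_min: float = 1e-12
    lambda_max: float = 1e12
    max_retries: int = 20
    penalize_biases: bool = False

    def __post_init__(self) -> None:
        if min(self.eta, self.beta, self.lambda0, self.fd_step, self.error_precision) <= 0:
            raise ValueError("eta, beta, lambda0, fd_step, error_precision must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if self.jacobian_mode not in ("analytic", "finite-difference"):
            raise ValueError("jacobian_mode must be 'analytic' or 'finite-difference'")
        if self.algorithm not in ("lm", "gd"):
            raise ValueError("algorithm must be 'lm' or 'gd'")


@dataclass
class LMState:
    """Mutable optimizer state across epochs."""

    lam: float
    epoch: int = 0
    best_val: float = np.inf
    since_improvement: int = 0
    J: np.ndarray | None = None
    e: np.ndarray | None = None
    delta_w: np.ndarray | None = None


@dataclass(frozen=True)
class LossParts:
    mse: float
    penalty: float

    @property
    def total(self) -> float:
        return self.mse + self.penalty


@dataclass
class TrainResult:
    state: NetworkState
    history: pd.DataFrame
    stopped: str
    final_state: NetworkState | None = None


# ---------------------------------------------------------------------------
# forward pass and loss

def _forward_cached(state: NetworkState, X: np.ndarray):
    """All-layer activations; returns (activations, pre-activations)."""
    spec = state.spec
    n_layers = len(state.weights)
    a = state._scale_inputs(X)
    acts = [a]
    zs = []
    for l, (W, b) in enumerate(zip(state.weights, state.biases)):
        z = a @ W + b
        name = spec.output_activation if l == n_layers - 1 else spec.hidden_activation
        a = _ACTIVATIONS[name][0](z)
        zs.append(z)
        acts.append(a)
    return acts, zs


def forward_batch(state: NetworkState, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    if X.ndim != 2 or X.shape[1] != state.spec.sizes[0]:
        raise ValueError(f"X must be (n, {state.spec.sizes[0]})")
    return _forward_cached(state, X)[0][-1]


def forward(state: NetworkState, x: Sequence[float]) -> np.ndarray:
    """Single-sample prediction."""
    x = np.asarray(x, dtype=float)
    return forward_batch(state, x[None, :])[0]


def loss(state: NetworkState, X: np.ndarray, Y: np.ndarray, alpha: float,
         penalize_biases: bool = False) -> LossParts:
    """Regularized loss: MSE over all (sample, output) residuals plus
    alpha times the sum of squared weights."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.size == 0 or Y.size == 0:
        raise ValueError("empty data")
    resid = forward_batch(state, X) - Y
    mse = float(np.mean(resid ** 2))
    w = state.flatten()
    if not penalize_biases:
        w = w[state.weight_mask()]
    return LossParts(mse=mse, penalty=float(alpha * np.sum(w ** 2)))


# ---------------------------------------------------------------------------
# Jacobian of residuals

def _jacobian_analytic(state: NetworkState, X: np.ndarray, Y: np.ndarray):
    spec = state.spec
    n, m = X.shape[0], spec.sizes[-1]
    acts, zs = _forward_cached(state, X)
    resid = acts[-1] - Y
    n_layers = len(state.weights)
    W_total = spec.n_params
    J = np.empty((n * m, W_total))
    # activation derivatives per layer, reused for every output unit
    dacts = []
    for l, z in enumerate(zs):
        name = spec.output_activation if l == n_layers - 1 else spec.hidden_activation
        dacts.append(_ACTIVATIONS[name][1](z))
    for k in range(m):
        # reverse accumulation of d resid[:, k] / d params for all samples
        delta = np.zeros((n, m))
        delta[:, k] = 1.0
        delta = delta * dacts[-1]
        blocks: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
        for l in range(n_layers - 1, -1, -1):
            a_prev = acts[l]
            gW = a_prev[:, :, None] * delta[:, None, :]  # (n, fan_in, fan_out)
            gb = delta
            blocks[l] = np.concatenate([gW.reshape(n, -1), gb], axis=1)
            if l > 0:
                delta = (delta @ state.weights[l].T) * dacts[l - 1]
        J[k::m] = np.concatenate(blocks, axis=1)
    return J, resid.ravel()


def _jacobian_fd(state: NetworkState, X: np.ndarray, Y: np.ndarray, step: float):
    w0 = state.flatten()
    r0 = (forward_batch(state, X) - Y).ravel()
    J = np.empty((r0.size, w0.size))
    for j in range(w0.size):
        w = w0.copy()
        w[j] += step
        r = (forward_batch(state.with_params(w), X) - Y).ravel()
        J[:, j] = (r - r0) / step
    return J, r0


def jacobian(state: NetworkState, X: np.ndarray, Y: np.ndarray,
             mode: str = "analytic", fd_step: float = 1e-5):
    """Jacobian of raw residuals r = yhat - y w.r.t. the flat parameter
    vector: one row per (sample, output) pair, sample-major."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if mode == "analytic":
        return _jacobian_analytic(state, X, Y)
    if mode == "finite-difference":
        return _jacobian_fd(state, X, Y, fd_step)
    raise ValueError(f"unknown jacobian mode {mode!r}")


def gradient(state: NetworkState, X: np.ndarray, Y: np.ndarray, alpha: float,
             penalize_biases: bool = False) -> np.ndarray:
    """Gradient of the regularized loss w.r.t. the flat parameter vector."""
    J, r = _jacobian_analytic(state, X, Y)
    g = 2.0 * (J.T @ r) / r.size
    w = state.flatten()
    mask = np.ones_like(w, dtype=bool) if penalize_biases else state.weight_mask()
    g[mask] += 2.0 * alpha * w[mask]
    return g


# ---------------------------------------------------------------------------
# Levenberg-Marquardt step

def _augmented_system(state: NetworkState, X, Y, cfg: TrainConfig, mode: str):
    """Scaled residuals and Jacobian whose squared norm is the full loss L."""
    J, r = jacobian(state, X, Y, mode=mode, fd_step=cfg.fd_step)
    scale = 1.0 / np.sqrt(r.size)
    Js = J * scale
    es = r * scale
    if cfg.alpha > 0:
        w = state.flatten()
        mask = np.ones_like(w, dtype=bool) if cfg.penalize_biases else state.weight_mask()
        idx = np.flatnonzero(mask)
        sq = np.sqrt(cfg.alpha)
        Jpen = np.zeros((idx.size, w.size))
        Jpen[np.arange(idx.size), idx] = sq
        Js = np.vstack([Js, Jpen])
        es = np.concatenate([es, sq * w[idx]])
    return Js, es, J, r


def lm_step(lm: LMState, state: NetworkState, X: np.ndarray, Y: np.ndarray,
            cfg: TrainConfig) -> tuple[NetworkState, bool]:
    """One full-batch LM update.

    Solves (J^T J + lambda I) delta = J^T e on the penalty-augmented
    system, accepts the candidate only if the regularized loss drops
    (shrinking lambda x0.1), otherwise grows lambda x10 and retries up to
    ``cfg.max_retries`` times.  Returns (possibly updated state, accepted).
    """
    Js, es, J_raw, e_raw = _augmented_system(state, X, Y, cfg, cfg.jacobian_mode)
    lm.J, lm.e = J_raw, e_raw
    current = float(es @ es)
    JtJ = Js.T @ Js
    Jte = Js.T @ es
    w0 = state.flatten()
    for _ in range(cfg.max_retries):
        A = JtJ + lm.lam * np.eye(len(w0))
        try:
            c, low = scipy.linalg.cho_factor(A)
            delta = scipy.linalg.cho_solve((c, low), Jte)
        except np.linalg.LinAlgError:
            lm.lam = min(lm.lam * 10.0, cfg.lambda_max)
            continue
        candidate = state.with_params(w0 - delta)
        new_loss = loss(candidate, X, Y, cfg.alpha, cfg.penalize_biases).total
        if np.isfinite(new_loss) and new_loss < current:
            lm.lam = max(lm.lam * 0.1, cfg.lambda_min)
            lm.delta_w = delta
            return candidate, True
        lm.lam = min(lm.lam * 10.0, cfg.lambda_max)
        if lm.lam >= cfg.lambda_max:
            break
    return state, False


def _gd_epoch(state, velocity, X, Y, cfg):
    g = gradient(state, X, Y, cfg.alpha, cfg.penalize_biases)
    velocity = cfg.beta * velocity - cfg.eta * g
    return state.with_params(state.flatten() + velocity), velocity


def train(state: NetworkState, X_train: np.ndarray, Y_train: np.ndarray,
          X_val: np.ndarray, Y_val: np.ndarray, cfg: TrainConfig) -> TrainResult:
    """Full-batch training with early stopping.

    Stops when the training MSE reaches ``error_precision``, when the
    validation loss has not improved for ``patience`` epochs, or at
    ``max_epochs``; the returned model is the best-validation snapshot.
    One epoch is one accepted (or exhausted-retry) LM update, or one
    momentum gradient-descent update for the baseline algorithm.
    """
    lm = LMState(lam=cfg.lambda0)
    velocity = np.zeros(state.spec.n_params)
    best = state.copy()
    best_val = np.inf
    since = 0
    rows = []
    stopped = "max_epochs"
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.algorithm == "lm":
            state, accepted = lm_step(lm, state, X_train, Y_train, cfg)
        else:
            state, velocity = _gd_epoch(state, velocity, X_train, Y_train, cfg)
            accepted = True
        train_parts = loss(state, X_train, Y_train, cfg.alpha, cfg.penalize_biases)
        val_mse = loss(state, X_val, Y_val, 0.0).mse
        if not np.isfinite(train_parts.total):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (loss not finite)"
            )
        rows.append(
            {"epoch": epoch, "train_mse": train_parts.mse,
             "val_mse": val_mse, "lambda": lm.lam, "accepted": accepted}
        )
        if epoch % cfg.display_interval == 0 or epoch == 1:
            logger.info(
                "epoch %4d  train MSE %.3e  val MSE %.3e  lambda %.1e",
                epoch, train_parts.mse, val_mse, lm.lam,
            )
        if val_mse < best_val:
            best_val = val_mse
            best = state.copy()
            since = 0
        else:
            since += 1
        if train_parts.mse <= cfg.error_precision:
            stopped = "error_precision"
            break
        if since >= cfg.patience:
            stopped = "patience"
            break
        if cfg.algorithm == "lm" and not accepted:
            stopped = "no_step"
            break
    history = pd.DataFrame(rows)
    return TrainResult(state=best, history=history, stopped=stopped, final_state=state)


def hidden_neuron_range(n_inputs: int, n_outputs: int,
                        a_range: Iterable[int] = range(1, 11)) -> list[int]:
    """Candidate hidden-layer widths from the classical empirical rule
    n1 = round(sqrt(n + m)) + a with a in [1, 10]."""
    a_list = sorted(a_range)
    if any(a < 1 or a > 10 for a in a_list):
        raise ValueError("a_range must lie within [1, 10]")
    base = round(np.sqrt(n_inputs + n_outputs))
    return [base + a for a in a_list]


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(state: NetworkState, path: str | Path,
                    cfg: TrainConfig | None = None,
                    meta: dict | None = None) -> None:
    payload = {
        "sizes": list(state.spec.sizes),
        "hidden_activation": state.spec.hidden_activation,
        "output_activation": state.spec.output_activation,
        "params": state.flatten().tolist(),
        "input_center": None if state.input_center is None else state.input_center.tolist(),
        "input_scale": None if state.input_scale is None else state.input_scale.tolist(),
        "config": None if cfg is None else cfg.__dict__,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_checkpoint(path: str | Path) -> NetworkState:
    payload = json.loads(Path(path).read_text())
    spec = LayerSpec(
        sizes=tuple(payload["sizes"]),
        hidden_activation=payload["hidden_activation"],
        output_activation=payload["output_activation"],
    )
    template = NetworkState(spec, *_zero_params(spec))
    state = template.with_params(np.asarray(payload["params"], dtype=float))
    if payload.get("input_center") is not None:
        state.input_center = np.asarray(payload["input_center"], dtype=float)
        state.input_scale = np.asarray(payload["input_scale"], dtype=float)
    return state


def _zero_params(spec: LayerSpec):
    weights = [np.zeros((fi, fo)) for fi, fo in zip(spec.sizes, spec.sizes[1:])]
    biases = [np.zeros(fo) for fo in spec.sizes[1:]]
    return weights, biases
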