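"""Base regression learners: a one-hidden-layer MLP and a vanilla LSTM.

Both families share the fixed blueprint used throughout the pipeline: one
hidden layer of 100 units, He-uniform initialisation, ReLU activation (MLP),
a linear dense output head of 6 or 12 units (one per 5-min step of the 30-
or 60-min prediction horizon), mean-squared-error loss, Adam optimisation,
100 epochs with batch size 32, and a reduce-on-plateau learning-rate
schedule starting at 0.01 that multiplies by 0.1 whenever the validation
loss stagnates for 10 epochs.

Implemented directly on numpy: the networks are small and the data volumes
modest, and a pure-numpy implementation is bit-reproducible for a fixed
seed, which the pipeline's determinism contracts rely on.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, ContractViolation, TrainingDivergence


@dataclass(frozen=True)
class NetworkSpec:
    kind: str  # "mlp" | "lstm"
    input_shape: tuple[int, int]  # (lag steps, channels)
    output_len: int  # horizon steps: 6 or 12
    hidden_units: int = 100

    def validate(self) -> None:
        if self.kind not in ("mlp", "lstm"):
            raise ConfigurationError(f"unsupported learner kind: {self.kind!r}")
        if len(self.input_shape) != 2 or min(self.input_shape) < 1:
            raise ConfigurationError("input_shape must be (steps, channels), both >= 1")
        if self.output_len < 1 or self.hidden_units < 1:
            raise ConfigurationError("output_len and hidden_units must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr_init: float = 0.01
    lr_factor: float = 0.1
    lr_patience: int = 10
    lr_min_delta: float = 1e-4
    val_fraction: float = 0.2
    run_seed: int = 0
    shuffle: bool = True

    def validate(self) -> None:
        if not 0 < self.lr_factor < 1:
            raise ConfigurationError("lr_factor must be in (0, 1)")
        if not 0 < self.val_fraction <= 0.5:
            raise ConfigurationError("val_fraction must be in (0, 0.5]")
        if self.epochs < 1 or self.batch_size < 1 or self.lr_init <= 0:
            raise ConfigurationError("epochs, batch_size, lr_init must be positive")


def _he_uniform(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, shape)


class Network:
    """An (initially untrained) network: parameters + forward/backward."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        L, C = spec.input_shape
        U, H = spec.hidden_units, spec.output_len
        if spec.kind == "mlp":
            D = L * C
            self.params = {
                "W1": _he_uniform(rng, D, (D, U)),
                "b1": np.zeros(U),
                "W2": _he_uniform(rng, U, (U, H)),
                "b2": np.zeros(H),
            }
        else:
            b = np.zeros(4 * U)
            b[U : 2 * U] = 1.0  # unit forget-gate bias
            self.params = {
                "Wx": _he_uniform(rng, C, (C, 4 * U)),
                "Wh": _he_uniform(rng, U, (U, 4 * U)),
                "b": b,
                "Wo": _he_uniform(rng, U, (U, H)),
                "bo": np.zeros(H),
            }

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False):
        L, C = self.spec.input_shape
        if X.ndim != 3 or X.shape[1:] != (L, C):
            raise ContractViolation(
                f"input shape {X.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        if self.spec.kind == "mlp":
            return self._forward_mlp(X, cache)
        return self._forward_lstm(X, cache)

    def _forward_mlp(self, X, cache):
        p = self.params
        flat = X.reshape(X.shape[0], -1)
        a1 = flat @ p["W1"] + p["b1"]
        h1 = np.maximum(a1, 0.0)
        y = h1 @ p["W2"] + p["b2"]
        return (y, (flat, a1, h1)) if cache else y

    def _forward_lstm(self, X, cache):
        p = self.params
        B, L, _ = X.shape
        U = self.spec.hidden_units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        xz = X @ p["Wx"] + p["b"]  # (B, L, 4U), input projections for all steps
        steps = [] if cache else None
        for t in range(L):
            z = xz[:, t, :] + h @ p["Wh"]
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if cache:
                steps.append((h_prev, c_prev, i, f, g, o, tc))
        y = h @ p["Wo"] + p["bo"]
        return (y, (X, steps, h)) if cache else y

    # -- backward ---------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray):
        y, cc = self.forward(X, cache=True)
        resid = y - Y
        loss = float(np.mean(resid**2))
        dY = 2.0 * resid / resid.size
        if self.spec.kind == "mlp":
            grads = self._grads_mlp(dY, cc)
        else:
            grads = self._grads_lstm(dY, cc)
        return loss, grads

    def _grads_mlp(self, dY, cc):
        flat, a1, h1 = cc
        p = self.params
        dW2 = h1.T @ dY
        db2 = dY.sum(axis=0)
        dh1 = dY @ p["W2"].T
        da1 = dh1 * (a1 > 0)
        dW1 = flat.T @ da1
        db1 = da1.sum(axis=0)
        return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}

    def _grads_lstm(self, dY, cc):
        X, steps, h_last = cc
        p = self.params
        U = self.spec.hidden_units
        B, L, C = X.shape
        dWo = h_last.T @ dY
        dbo = dY.sum(axis=0)
        dh = dY @ p["Wo"].T
        dc = np.zeros_like(dh)
        dWx = np.zeros_like(p["Wx"])
        dWh = np.zeros_like(p["Wh"])
        db = np.zeros_like(p["b"])
        for t in range(L - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += X[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return {"Wx": dWx, "Wh": dWh, "b": db, "Wo": dWo, "bo": dbo}

    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-7):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


@dataclass
class TrainedModel:
    spec: NetworkSpec
    net: Network
    history: dict[str, list[float]]  # train_loss, val_loss, lr per epoch
    run_seed: int

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.params)
        meta = {
            "kind": self.spec.kind,
            "input_shape": list(self.spec.input_shape),
            "output_len": self.spec.output_len,
            "hidden_units": self.spec.hidden_units,
            "run_seed": self.run_seed,
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = NetworkSpec(
            kind=meta["kind"],
            input_shape=tuple(meta["input_shape"]),
            output_len=meta["output_len"],
            hidden_units=meta["hidden_units"],
        )
        net = Network(spec, seed=0)
        with np.load(path.with_suffix(".npz")) as z:
            net.params = {k: z[k] for k in z.files}
        return cls(spec=spec, net=net, history=meta["history"], run_seed=meta["run_seed"])


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Construct an untrained network with seed-determined initial weights."""
    return Network(spec, seed=seed)


def train(model: Network, X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> TrainedModel:
    """Train with Adam + MSE under the reduce-on-plateau schedule.

    The validation split is the chronologically last ``val_fraction`` of the
    training windows (no shuffling across the split); batches are shuffled
    within the training split only, governed by ``run_seed``.
    """
    cfg.validate()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 3 or y.ndim != 2 or len(X) != len(y):
        raise ContractViolation("X must be (n, L, C) and y (n, H) with matching n")
    if y.shape[1] != model.spec.output_len:
        raise ContractViolation("target width does not match the network's output layer")
    n = len(X)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    if n_val >= n:
        raise ContractViolation("not enough windows for a validation split")
    Xtr, ytr = X[: n - n_val], y[: n - n_val]
    Xva, yva = X[n - n_val :], y[n - n_val :]

    net = copy.deepcopy(model)
    opt = _Adam(net.params)
    rng = np.random.default_rng(cfg.run_seed)
    lr = cfg.lr_init
    best_val = np.inf
    wait = 0
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    n_tr = len(Xtr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr) if cfg.shuffle else np.arange(n_tr)
        batch_losses = []
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = net.loss_and_grads(Xtr[idx], ytr[idx])
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}, lr={lr:g}, kind={net.spec.kind}"
                )
            opt.step(net.params, grads, lr)
            batch_losses.append(loss)
        val_pred = net.forward(Xva)
        val_loss = float(np.mean((val_pred - yva) ** 2))
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        # reduce-on-plateau: reset patience on improvement beyond min_delta
        if val_loss < best_val - cfg.lr_min_delta:
            best_val = val_loss
            wait = 0
        else:
            wait += 1
            if wait > cfg.lr_patience:
                lr *= cfg.lr_factor
                wait = 0
    return TrainedModel(spec=model.spec, net=net, history=history, run_seed=cfg.run_seed)


def predict(model: TrainedModel | Network, X: np.ndarray) -> np.ndarray:
    """Predict horizon sequences (transformed scale); shape (n, output_len)."""
    net = model.net if isinstance(model, TrainedModel) else model
    X = np.asarray(X, float)
    if len(X) == 0:
        return np.empty((0, net.spec.output_len))
    out = net.forward(X)
    if not np.isfinite(out).all():
        raise TrainingDivergence("model produced non-finite predictions")
    return out
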