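"""From-scratch stacked LSTM sequence regressor trained by BPTT.

The network is a three-layer structure: an affine input layer mapping the
normalised per-step features [t, f, eps] to the cell input, a hidden layer
of two stacked LSTM units (unit 1 consumes the projected input, unit 2
consumes unit 1's hidden state), and an affine output layer mapping unit 2's
hidden state to the normalised stress prediction at every step.

Each unit follows the standard gated cell:

    f(t)    = S(wf_x . x(t) + wf_h . h(t-1) + bf)        forget gate
    i(t)    = S(wi_x . x(t) + wi_h . h(t-1) + bi)        input gate
    o(t)    = S(wo_x . x(t) + wo_h . h(t-1) + bo)        output gate
    cbar(t) = T(wc_x . x(t) + wc_h . h(t-1) + bc)        candidate state
    C(t)    = f(t) * C(t-1) + i(t) * cbar(t)             history (cell) state
    h(t)    = o(t) * T(C(t))                             hidden state

with S = sigmoid, T = tanh, elementwise products, and h = C = 0 at the
start of every sequence.  The loss is the mean squared error over the
(masked) prediction steps; gradients are computed exactly by
backpropagation through time and applied by plain SGD with a step-decay
learning-rate schedule.  Everything is numpy; no autodiff framework is
involved, which is why :func:`backward` is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LSTMConfig",
    "UnitParams",
    "LSTMParams",
    "TrainingHistory",
    "TrainingDivergedError",
    "sigmoid",
    "tanh",
    "cell_forward",
    "network_forward",
    "mse_loss",
    "backward",
    "sgd_step",
    "lr_schedule",
    "init_params",
    "make_sequences",
    "train",
    "predict",
    "save_model",
    "load_model",
]

N_FEATURES = 3  # per-step inputs: time, force, strain

_GATES = ("f", "i", "o", "c")


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries the offending epoch."""

    def __init__(self, epoch: int, loss: float):
        super().__init__(f"training diverged at epoch {epoch}: loss = {loss}")
        self.epoch = epoch
        self.loss = loss


@dataclass(frozen=True)
class LSTMConfig:
    """Training hyperparameters.

    Defaults are the tuned operating point for tomato relaxation curves:
    48 hidden neurons per unit, two stacked units, initial learning rate
    0.008 decayed by 0.9 every 90 epochs, 850 epochs, mini-batch 128
    (capped at the number of training sequences).
    """

    hidden_size: int = 48
    num_units: int = 2
    initial_lr: float = 0.008
    lr_drop_period: int = 90
    lr_drop_factor: float = 0.9
    epochs: int = 850
    mini_batch: int = 128
    momentum: float = 0.9  # classical momentum; 0 gives the plain update
    seed: int = 0
    clip_grad: float | None = None  # optional global-norm clip, off by default

    def __post_init__(self):
        if min(self.hidden_size, self.num_units, self.lr_drop_period, self.epochs, self.mini_batch) < 1:
            raise ValueError("hidden_size, num_units, lr_drop_period, epochs, mini_batch must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if not (0.0 < self.lr_drop_factor < 1.0):
            raise ValueError("lr_drop_factor must lie in (0, 1)")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")


@dataclass
class UnitParams:
    """One LSTM unit's weights: per gate, an input matrix (H x d), a
    recurrent matrix (H x H) and a bias (H,)."""

    wf_x: np.ndarray
    wf_h: np.ndarray
    bf: np.ndarray
    wi_x: np.ndarray
    wi_h: np.ndarray
    bi: np.ndarray
    wo_x: np.ndarray
    wo_h: np.ndarray
    bo: np.ndarray
    wc_x: np.ndarray
    wc_h: np.ndarray
    bc: np.ndarray

    def named_arrays(self):
        for g in _GATES:
            yield f"w{g}_x", getattr(self, f"w{g}_x")
            yield f"w{g}_h", getattr(self, f"w{g}_h")
            yield f"b{g}", getattr(self, f"b{g}")


@dataclass
class LSTMParams:
    """All trainable arrays: input layer, stacked units, output layer."""

    w_in: np.ndarray  # (N_FEATURES, N_FEATURES)
    b_in: np.ndarray  # (N_FEATURES,)
    units: list[UnitParams]
    w_out: np.ndarray  # (H,)
    b_out: np.ndarray  # scalar array

    @property
    def hidden_size(self) -> int:
        return self.units[0].wf_h.shape[0]

    def named_arrays(self):
        yield "w_in", self.w_in
        yield "b_in", self.b_in
        for u, unit in enumerate(self.units):
            for name, arr in unit.named_arrays():
                yield f"unit{u}.{name}", arr
        yield "w_out", self.w_out
        yield "b_out", self.b_out

    def copy(self) -> "LSTMParams":
        return LSTMParams(
            w_in=self.w_in.copy(), b_in=self.b_in.copy(),
            units=[UnitParams(**{n: a.copy() for n, a in u.named_arrays()}) for u in self.units],
            w_out=self.w_out.copy(), b_out=self.b_out.copy(),
        )

    def zeros_like(self) -> "LSTMParams":
        z = self.copy()
        for _, arr in z.named_arrays():
            arr[...] = 0.0
        return z

    # flat-vector view used by the finite-difference gradient check
    def to_vector(self) -> np.ndarray:
        return np.concatenate([a.ravel() for _, a in self.named_arrays()])

    def from_vector(self, vec: np.ndarray) -> "LSTMParams":
        out = self.copy()
        i = 0
        for _, arr in out.named_arrays():
            arr[...] = vec[i:i + arr.size].reshape(arr.shape)
            i += arr.size
        return out


def sigmoid(x):
    """Numerically stable logistic function; maps R -> (0, 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def tanh(x):
    """Hyperbolic tangent; maps R -> (-1, 1)."""
    return np.tanh(np.asarray(x, dtype=float))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: LSTMConfig, rng: np.random.Generator | None = None) -> LSTMParams:
    """Seeded uniform Glorot-style initialisation.

    Biases start at zero except the forget gates, which start at 1 (the
    unit-forget-gate convention): the cell begins in a remembering regime,
    which markedly improves the conditioning of gradient descent here.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    H = config.hidden_size
    units = []
    for u in range(config.num_units):
        d = N_FEATURES if u == 0 else H
        kwargs = {}
        for g in _GATES:
            kwargs[f"w{g}_x"] = _glorot(rng, (H, d))
            kwargs[f"w{g}_h"] = _glorot(rng, (H, H))
            kwargs[f"b{g}"] = np.full(H, 1.0) if g == "f" else np.zeros(H)
        units.append(UnitParams(**kwargs))
    return LSTMParams(
        w_in=_glorot(rng, (N_FEATURES, N_FEATURES)),
        b_in=np.zeros(N_FEATURES),
        units=units,
        w_out=_glorot(rng, (H,)),
        b_out=np.zeros(()),
    )


def cell_forward(unit: UnitParams, x, h_prev, C_prev):
    """One time step of one unit.

    Returns (f, i, o, cbar, C_new, h_new); inputs are (B, d) / (B, H)
    batches (1-D inputs are promoted to a batch of one).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    C_prev = np.atleast_2d(np.asarray(C_prev, dtype=float))
    if x.shape[1] != unit.wf_x.shape[1] or h_prev.shape[1] != unit.wf_h.shape[1]:
        raise ValueError(
            f"shape mismatch: x has {x.shape[1]} features (unit expects {unit.wf_x.shape[1]}), "
            f"h_prev has {h_prev.shape[1]} (unit expects {unit.wf_h.shape[1]})"
        )
    f = sigmoid(x @ unit.wf_x.T + h_prev @ unit.wf_h.T + unit.bf)
    i = sigmoid(x @ unit.wi_x.T + h_prev @ unit.wi_h.T + unit.bi)
    o = sigmoid(x @ unit.wo_x.T + h_prev @ unit.wo_h.T + unit.bo)
    cbar = tanh(x @ unit.wc_x.T + h_prev @ unit.wc_h.T + unit.bc)
    C_new = f * C_prev + i * cbar
    h_new = o * tanh(C_new)
    return f, i, o, cbar, C_new, h_new


def _unit_forward(unit: UnitParams, X: np.ndarray):
    """Run one unit over a whole (B, T, d) input; returns outputs and cache."""
    B, T, _ = X.shape
    H = unit.wf_h.shape[0]
    cache = {k: np.empty((T, B, H)) for k in ("f", "i", "o", "cbar", "C", "k", "h", "h_prev", "C_prev")}
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    for t in range(T):
        cache["h_prev"][t] = h
        cache["C_prev"][t] = C
        f, i, o, cbar, C, h = cell_forward(unit, X[:, t, :], h, C)
        cache["f"][t], cache["i"][t], cache["o"][t], cache["cbar"][t] = f, i, o, cbar
        cache["C"][t] = C
        cache["k"][t] = np.tanh(C)
        cache["h"][t] = h
    return cache["h"].transpose(1, 0, 2), cache  # (B, T, H)


def network_forward(params: LSTMParams, X, return_cache: bool = False):
    """Full forward pass on normalised inputs.

    ``X`` is (B, T, N_FEATURES) or (T, N_FEATURES); the return is the
    normalised stress prediction of matching leading shape, plus (optionally)
    the cache needed for exact backpropagation.
    """
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    if X.ndim != 3 or X.shape[-1] != params.w_in.shape[1]:
        raise ValueError(f"expected input shape (B, T, {params.w_in.shape[1]}), got {X.shape}")

    I0 = X @ params.w_in.T + params.b_in
    layer_in = I0
    unit_caches = []
    for unit in params.units:
        layer_in, cache = _unit_forward(unit, layer_in)
        unit_caches.append(cache)
    yhat = layer_in @ params.w_out + float(params.b_out)

    if not return_cache:
        return yhat[0] if squeeze else yhat
    full_cache = {"X": X, "I0": I0, "units": unit_caches, "h_top": layer_in, "yhat": yhat}
    return (yhat[0] if squeeze else yhat), full_cache


def mse_loss(predicted, observed, mask=None) -> float:
    """Mean squared error over (optionally masked) prediction steps."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have identical shapes")
    sq = (predicted - observed) ** 2
    if mask is None:
        return float(sq.mean())
    mask = np.asarray(mask, dtype=float)
    return float((sq * mask).sum() / mask.sum())


def _unit_backward(unit: UnitParams, cache, X_in: np.ndarray, d_h_above: np.ndarray, grads: UnitParams):
    """BPTT through one unit.

    ``d_h_above`` is dLoss/dh(t) arriving from the layer above, (B, T, H);
    ``X_in`` the unit's input sequence (B, T, d).  Accumulates this unit's
    weight gradients into ``grads`` and returns dLoss/dX_in.
    """
    B, T, d = X_in.shape
    H = unit.wf_h.shape[0]
    dX = np.empty((B, T, d))
    dh_rec = np.zeros((B, H))
    dC_rec = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        f, i, o = cache["f"][t], cache["i"][t], cache["o"][t]
        cbar, k = cache["cbar"][t], cache["k"][t]
        h_prev, C_prev = cache["h_prev"][t], cache["C_prev"][t]
        x_t = X_in[:, t, :]

        dh = d_h_above[:, t, :] + dh_rec
        do = dh * k
        dC = dh * o * (1.0 - k**2) + dC_rec
        df = dC * C_prev
        di = dC * cbar
        dcb = dC * i

        dm_o = do * o * (1.0 - o)
        dm_f = df * f * (1.0 - f)
        dm_i = di * i * (1.0 - i)
        dm_c = dcb * (1.0 - cbar**2)

        for g, dm in zip(_GATES, (dm_f, dm_i, dm_o, dm_c)):
            getattr(grads, f"w{g}_x")[...] += dm.T @ x_t
            getattr(grads, f"w{g}_h")[...] += dm.T @ h_prev
            getattr(grads, f"b{g}")[...] += dm.sum(axis=0)

        dX[:, t, :] = dm_f @ unit.wf_x + dm_i @ unit.wi_x + dm_o @ unit.wo_x + dm_c @ unit.wc_x
        dh_rec = dm_f @ unit.wf_h + dm_i @ unit.wi_h + dm_o @ unit.wo_h + dm_c @ unit.wc_h
        dC_rec = dC * f
    return dX


def backward(params: LSTMParams, cache, observed, mask=None) -> LSTMParams:
    """Exact gradients of the MSE loss w.r.t. every weight and bias.

    ``cache`` must come from a matching ``network_forward(..., return_cache=True)``
    call; gradients are returned in an LSTMParams-shaped container.
    """
    if not isinstance(cache, dict) or "yhat" not in cache:
        raise ValueError("backward requires the cache produced by network_forward(return_cache=True)")
    observed = np.asarray(observed, dtype=float)
    yhat = cache["yhat"]
    if observed.ndim == 1:
        observed = observed[None]
    if observed.shape != yhat.shape:
        raise ValueError(f"observed shape {observed.shape} does not match cached forward {yhat.shape}")

    if mask is None:
        n_valid = observed.size
        dY = 2.0 * (yhat - observed) / n_valid
    else:
        mask = np.asarray(mask, dtype=float)
        dY = 2.0 * (yhat - observed) * mask / mask.sum()

    grads = params.zeros_like()
    h_top = cache["h_top"]
    grads.w_out[...] = np.einsum("bt,bth->h", dY, h_top)
    grads.b_out[...] = dY.sum()

    d_above = dY[:, :, None] * params.w_out  # (B, T, H)
    layer_inputs = [cache["I0"]] + [cache["units"][u]["h"].transpose(1, 0, 2)
                                    for u in range(len(params.units) - 1)]
    for u in range(len(params.units) - 1, -1, -1):
        d_above = _unit_backward(params.units[u], cache["units"][u], layer_inputs[u], d_above, grads.units[u])

    X = cache["X"]
    grads.w_in[...] = np.einsum("btd,btk->dk", d_above, X)
    grads.b_in[...] = d_above.sum(axis=(0, 1))
    return grads


def sgd_step(params: LSTMParams, grads: LSTMParams, lr: float) -> LSTMParams:
    """Plain gradient descent (no momentum): w <- w - lr * dL/dw, in place."""
    for (_, p), (_, g) in zip(params.named_arrays(), grads.named_arrays()):
        p -= lr * g
    return params


def lr_schedule(epoch: int, config: LSTMConfig) -> float:
    """Step decay: lr(epoch) = initial_lr * drop_factor ** floor(epoch / drop_period)."""
    return config.initial_lr * config.lr_drop_factor ** (epoch // config.lr_drop_period)


def _grad_norm(grads: LSTMParams) -> float:
    return float(np.sqrt(sum(float((a**2).sum()) for _, a in grads.named_arrays())))


@dataclass
class TrainingHistory:
    """Per-epoch loss, learning rate and wall time."""

    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    wall_time_s: list[float] = field(default_factory=list)


def _pad_batch(seqs: Sequence[np.ndarray], targets: Sequence[np.ndarray]):
    """Pad whole sequences to the batch's maximum length with a loss mask."""
    B = len(seqs)
    T = max(s.shape[0] for s in seqs)
    X = np.zeros((B, T, N_FEATURES))
    Y = np.zeros((B, T))
    M = np.zeros((B, T))
    for b, (s, y) in enumerate(zip(seqs, targets)):
        L = s.shape[0]
        X[b, :L] = s
        Y[b, :L] = y
        M[b, :L] = 1.0
    return X, Y, M


def make_sequences(curves, normalizer) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Normalised [t, f, eps] input sequences and sigma targets per curve."""
    seqs, targets = [], []
    for c in curves:
        t = normalizer.apply(c.times, "t")
        f = normalizer.apply(c.raw_force, "f")
        e = normalizer.apply(np.full(len(c), c.strain0), "eps")
        seqs.append(np.stack([t, f, e], axis=-1))
        targets.append(normalizer.apply(c.stress, "sigma"))
    return seqs, targets


def train(
    sequences: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    config: LSTMConfig,
    params: LSTMParams | None = None,
    progress: bool = False,
) -> tuple[LSTMParams, TrainingHistory]:
    """Train on normalised whole sequences.

    Mini-batches are whole sequences (batch size capped at the dataset
    size), padded to the batch's maximum length with the loss masked on
    padding.  One epoch is one full shuffled pass.  The update is gradient
    descent with classical momentum (``config.momentum``; 0 recovers the
    plain step).  Weight initialisation and shuffling both derive from
    ``config.seed``, so identical configurations give bit-identical
    histories.
    """
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    targets = [np.asarray(y, dtype=float) for y in targets]
    if len(sequences) != len(targets) or not sequences:
        raise ValueError("need equally many nonzero sequences and targets")
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(config, rng)
    batch_size = min(config.mini_batch, len(sequences))
    velocity = params.zeros_like()
    history = TrainingHistory()
    t0 = time.perf_counter()

    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        order = rng.permutation(len(sequences))
        epoch_sq = 0.0
        epoch_n = 0.0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            X, Y, M = _pad_batch([sequences[i] for i in idx], [targets[i] for i in idx])
            yhat, cache = network_forward(params, X, return_cache=True)
            grads = backward(params, cache, Y, mask=M)
            if config.clip_grad is not None:
                norm = _grad_norm(grads)
                if norm > config.clip_grad:
                    scale = config.clip_grad / norm
                    for _, g in grads.named_arrays():
                        g *= scale
            for (_, v), (_, g) in zip(velocity.named_arrays(), grads.named_arrays()):
                v *= config.momentum
                v += g
            sgd_step(params, velocity, lr)
            epoch_sq += float((((yhat - Y) ** 2) * M).sum())
            epoch_n += float(M.sum())
        loss = epoch_sq / epoch_n
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch, loss)
        history.loss.append(loss)
        history.lr.append(lr)
        history.wall_time_s.append(time.perf_counter() - t0)
        if progress and (epoch % 25 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d}  lr {lr:.5f}  loss {loss:.3e}")
    return params, history


def predict(params: LSTMParams, normalizer, curve) -> np.ndarray:
    """Predicted relaxation stress (MPa) for one curve's inputs.

    Builds the normalised [t, f, eps] sequence, runs the forward pass, and
    anti-normalises the output back to stress units.
    """
    seqs, _ = make_sequences([curve], normalizer)
    yhat = network_forward(params, seqs[0])
    return normalizer.invert(yhat, "sigma")


# --- serialisation ---------------------------------------------------------

def save_model(params: LSTMParams, config: LSTMConfig, path) -> None:
    """Portable single-file JSON snapshot: config echo plus all weight arrays."""
    payload = {
        "config": {k: getattr(config, k) for k in (
            "hidden_size", "num_units", "initial_lr", "lr_drop_period",
            "lr_drop_factor", "epochs", "mini_batch", "momentum", "seed", "clip_grad")},
        "arrays": {name: arr.tolist() for name, arr in params.named_arrays()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> tuple[LSTMParams, LSTMConfig]:
    payload = json.loads(Path(path).read_text())
    config = LSTMConfig(**payload["config"])
    params = init_params(config)
    for name, arr in params.named_arrays():
        arr[...] = np.asarray(payload["arrays"][name])
    return params, config
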