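"""Compact patient-specific 1D convolutional neural network.

Topology (fixed by configuration, arithmetic asserted at construction):

    input   2 channels x 128 samples      (single-beat, beat-trio)
    conv1   32 neurons, kernel 7, valid -> 122, tanh, avg-pool 3 -> 40
    conv2   16 neurons, kernel 7, valid -> 34,  tanh, avg-pool 3 -> 11
    conv3   16 neurons, kernel 7, valid -> 5,   tanh, global avg -> 1
    fc1     32 neurons, tanh
    out     5 neurons (AAMI classes), tanh

The global average at the last convolutional stage makes the
fully-connected input independent of the input length (the "adaptive"
property of this CNN family).  Targets are +1 for the true class and -1
elsewhere, matching the tanh output range; the loss is mean squared
error over batch and outputs.

Training is *shallow*, full-batch gradient descent: at most 50
iterations, stopping early when the training classification error drops
to 3%; the learning factor eps starts at 0.001 and is adapted globally
each iteration — x1.05 when the train MSE decreased, x0.70 otherwise.
Weights initialize uniformly in [-0.1, 0.1] from a seeded generator, so
a training run is exactly reproducible; an ensemble re-runs training
with consecutive seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

N_CLASSES = 5


@dataclass
class CnnConfig:
    conv_neurons: tuple = (32, 16, 16)
    fc_neurons: int = 32
    n_outputs: int = N_CLASSES
    n_input_channels: int = 2
    kernel_size: int = 7
    subsample: int = 3
    max_iters: int = 50
    min_train_error: float = 0.03
    eps0: float = 0.001
    eps_up: float = 1.05
    eps_down: float = 0.70
    seed: int = 0
    input_len: int = 128
    batch_size: int = 32  # items per incremental BP update within an iteration

    def __post_init__(self):
        if not (0 < self.min_train_error < 1):
            raise ValueError("min_train_error must be in (0, 1)")
        for v in (*self.conv_neurons, self.fc_neurons, self.n_outputs,
                  self.n_input_channels, self.kernel_size, self.subsample):
            if v <= 0:
                raise ValueError("all layer sizes must be positive")

    def layer_lengths(self) -> list[int]:
        """Feature-map lengths after each conv (+pool) stage; last is 1."""
        lens = []
        L = self.input_len
        for i in range(len(self.conv_neurons)):
            L = L - self.kernel_size + 1
            if L < 1:
                raise ValueError(f"conv stage {i + 1} consumes the whole map")
            if i < len(self.conv_neurons) - 1:
                L = L // self.subsample
                if L < 1:
                    raise ValueError(f"pool stage {i + 1} consumes the whole map")
            lens.append(L)
        return lens  # final stage length is globally pooled to 1


@dataclass
class CnnModel:
    """Parameter container; see module docstring for the topology."""

    conv_w: list  # [(out, in, k)]
    conv_b: list  # [(out,)]
    fc_w: list    # [(fc, conv_out), (n_out, fc)]
    fc_b: list
    config: CnnConfig
    #: per-channel input standardization (fitted on the training set);
    #: identity until trained
    input_mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    input_std: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self):
        cfg = self.config
        chans = (cfg.n_input_channels, *cfg.conv_neurons)
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            expect = (chans[i + 1], chans[i], cfg.kernel_size)
            if w.shape != expect or b.shape != (chans[i + 1],):
                raise ValueError(
                    f"conv layer {i + 1}: expected kernels {expect}, got {w.shape}"
                )
        cfg.layer_lengths()  # raises if the arithmetic is inconsistent
        if self.fc_w[0].shape != (cfg.fc_neurons, cfg.conv_neurons[-1]):
            raise ValueError("fc1 weight shape inconsistent with last conv layer")
        if self.fc_w[1].shape != (cfg.n_outputs, cfg.fc_neurons):
            raise ValueError("output weight shape inconsistent")

    def parameters(self):
        """Flat list of (name, array) in a fixed order."""
        out = []
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            out.append((f"conv{i + 1}_w", w))
            out.append((f"conv{i + 1}_b", b))
        for i, (w, b) in enumerate(zip(self.fc_w, self.fc_b)):
            out.append((f"fc{i + 1}_w", w))
            out.append((f"fc{i + 1}_b", b))
        return out

    def copy(self) -> "CnnModel":
        return CnnModel(
            conv_w=[w.copy() for w in self.conv_w],
            conv_b=[b.copy() for b in self.conv_b],
            fc_w=[w.copy() for w in self.fc_w],
            fc_b=[b.copy() for b in self.fc_b],
            config=self.config,
            input_mean=self.input_mean.copy(),
            input_std=self.input_std.copy(),
        )


@dataclass
class TrainingHistory:
    mse: list = field(default_factory=list)
    train_error: list = field(default_factory=list)
    eps: list = field(default_factory=list)
    stop_reason: str = ""


def init_model(cfg: CnnConfig) -> CnnModel:
    """Uniform [-0.1, 0.1] initialization from a seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    chans = (cfg.n_input_channels, *cfg.conv_neurons)
    conv_w, conv_b = [], []
    for i in range(len(cfg.conv_neurons)):
        conv_w.append(rng.uniform(-0.1, 0.1, (chans[i + 1], chans[i], cfg.kernel_size)))
        conv_b.append(rng.uniform(-0.1, 0.1, chans[i + 1]))
    fc_w = [
        rng.uniform(-0.1, 0.1, (cfg.fc_neurons, cfg.conv_neurons[-1])),
        rng.uniform(-0.1, 0.1, (cfg.n_outputs, cfg.fc_neurons)),
    ]
    fc_b = [
        rng.uniform(-0.1, 0.1, cfg.fc_neurons),
        rng.uniform(-0.1, 0.1, cfg.n_outputs),
    ]
    return CnnModel(conv_w=conv_w, conv_b=conv_b, fc_w=fc_w, fc_b=fc_b, config=cfg)


# -- forward / backward ------------------------------------------------------

def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid-mode cross-correlation: (B,C,L) x (O,C,K) -> (B,O,L-K+1)."""
    K = w.shape[-1]
    win = sliding_window_view(x, K, axis=-1)  # (B,C,L',K)
    B, C, Lp, _ = win.shape
    flat = win.transpose(0, 2, 1, 3).reshape(B * Lp, C * K)
    out = flat @ w.reshape(w.shape[0], C * K).T  # (B*L', O)
    return out.reshape(B, Lp, w.shape[0]).transpose(0, 2, 1)


def _avgpool(x: np.ndarray, s: int) -> np.ndarray:
    """Average-pool by factor s along the last axis, truncating remainder."""
    L = x.shape[-1] // s
    return x[..., : L * s].reshape(*x.shape[:-1], L, s).mean(axis=-1)


def _forward_cache(model: CnnModel, x: np.ndarray):
    """x: (B, 2, 128) -> outputs (B, 5) plus intermediate activations."""
    cfg = model.config
    x = (x - model.input_mean[None, :, None]) / model.input_std[None, :, None]
    cache = {"x": [x]}
    a = x
    acts, pools = [], []
    n_conv = len(model.conv_w)
    for i in range(n_conv):
        z = _conv_valid(a, model.conv_w[i]) + model.conv_b[i][None, :, None]
        act = np.tanh(z)
        acts.append(act)
        if i < n_conv - 1:
            a = _avgpool(act, cfg.subsample)
        else:
            a = act.mean(axis=-1)  # global average pool -> (B, O)
        pools.append(a)
        if i < n_conv - 1:
            cache["x"].append(a)
    g = pools[-1]
    h_z = g @ model.fc_w[0].T + model.fc_b[0]
    h = np.tanh(h_z)
    y_z = h @ model.fc_w[1].T + model.fc_b[1]
    y = np.tanh(y_z)
    cache.update(acts=acts, g=g, h=h, y=y)
    return y, cache


def forward(model: CnnModel, single: np.ndarray, trio: np.ndarray) -> np.ndarray:
    """Network outputs in (-1, 1) for one beat (two 128-sample channels)."""
    single = np.asarray(single, dtype=float)
    trio = np.asarray(trio, dtype=float)
    if single.shape != (model.config.input_len,) or trio.shape != single.shape:
        raise ValueError(
            f"input channels must each have {model.config.input_len} samples"
        )
    x = np.stack([single, trio])[None]
    y, _ = _forward_cache(model, x)
    return y[0]


def forward_batch(model: CnnModel, xs: np.ndarray, xt: np.ndarray) -> np.ndarray:
    x = np.stack([xs, xt], axis=1)
    y, _ = _forward_cache(model, x)
    return y


def predict(model: CnnModel, single: np.ndarray, trio: np.ndarray) -> int:
    """Argmax class; exact ties resolve to the lowest class index."""
    return int(np.argmax(forward(model, single, trio)))


def predict_batch(model: CnnModel, xs: np.ndarray, xt: np.ndarray) -> np.ndarray:
    return np.argmax(forward_batch(model, xs, xt), axis=1)


def targets_from_labels(labels: np.ndarray, n_outputs: int = N_CLASSES) -> np.ndarray:
    """+1 for the true class, -1 elsewhere (tanh-range encoding)."""
    t = -np.ones((len(labels), n_outputs))
    t[np.arange(len(labels)), labels] = 1.0
    return t


def _conv_input_grad(dz: np.ndarray, w: np.ndarray, L_in: int) -> np.ndarray:
    """Gradient w.r.t. the conv input: full correlation of dz with w."""
    K = w.shape[-1]
    O, C, _ = w.shape
    pad = np.pad(dz, ((0, 0), (0, 0), (K - 1, K - 1)))
    win = sliding_window_view(pad, K, axis=-1)[..., :L_in, :]  # (B,O,L,K)
    B = win.shape[0]
    flat = win.transpose(0, 2, 1, 3).reshape(B * L_in, O * K)
    wf = w[..., ::-1].transpose(1, 0, 2).reshape(C, O * K)  # (C, O*K)
    return (flat @ wf.T).reshape(B, L_in, C).transpose(0, 2, 1)


def _loss_and_gradients_cached(model, x, labels):
    """Internal: forward once, return (mse, grads, outputs)."""
    cfg = model.config
    y, cache = _forward_cache(model, x)
    t = targets_from_labels(labels, cfg.n_outputs).astype(y.dtype, copy=False)
    B = len(labels)
    diff = y - t
    mse = float(np.mean(diff**2))

    grads = {}
    # output layer
    dy_z = diff * (1 - y**2) * (2.0 / (B * cfg.n_outputs))
    h = cache["h"]
    grads["fc2_w"] = dy_z.T @ h
    grads["fc2_b"] = dy_z.sum(axis=0)
    dh = dy_z @ model.fc_w[1]
    dh_z = dh * (1 - h**2)
    g = cache["g"]
    grads["fc1_w"] = dh_z.T @ g
    grads["fc1_b"] = dh_z.sum(axis=0)
    dg = dh_z @ model.fc_w[0]  # (B, last_conv_neurons)

    acts = cache["acts"]
    n_conv = len(model.conv_w)
    # back through global average pool into last conv activation
    L_last = acts[-1].shape[-1]
    d_act = np.repeat(dg[:, :, None], L_last, axis=2) / L_last
    for i in range(n_conv - 1, -1, -1):
        act = acts[i]
        dz = d_act * (1 - act**2)
        x_in = cache["x"][i]
        K = cfg.kernel_size
        win = sliding_window_view(x_in, K, axis=-1)  # (B,C,L',K)
        Bw, C, Lp, _ = win.shape
        O = dz.shape[1]
        dz_flat = dz.transpose(1, 0, 2).reshape(O, Bw * Lp)
        win_flat = win.transpose(1, 3, 0, 2).reshape(C * K, Bw * Lp)
        grads[f"conv{i + 1}_w"] = (dz_flat @ win_flat.T).reshape(O, C, K)
        grads[f"conv{i + 1}_b"] = dz.sum(axis=(0, 2))
        if i > 0:
            dx = _conv_input_grad(dz, model.conv_w[i], x_in.shape[-1])
            # back through the preceding average pool
            prev_act = acts[i - 1]
            s = cfg.subsample
            L_pool = prev_act.shape[-1] // s
            d_act = np.zeros_like(prev_act)
            up = np.repeat(dx[..., :L_pool, None], s, axis=-1) / s
            d_act[..., : L_pool * s] = up.reshape(*dx.shape[:-1], L_pool * s)
    return mse, grads, y


def loss_and_gradients(model: CnnModel, xs: np.ndarray, xt: np.ndarray,
                       labels: np.ndarray):
    """Mean-squared-error loss and analytic gradients for every parameter.

    MSE is averaged over batch items and output units against the +/-1
    target encoding; gradients are exact derivatives of that MSE (mean
    over the batch).  Returns (mse, grads) with grads keyed like
    ``model.parameters()``.
    """
    if len(labels) == 0:
        raise ValueError("batch is empty")
    x = np.stack([xs, xt], axis=1)
    mse, grads, _ = _loss_and_gradients_cached(model, x, labels)
    return mse, grads


def _classification_error(model: CnnModel, xs, xt, labels) -> float:
    pred = predict_batch(model, xs, xt)
    return float(np.mean(pred != labels))


def train(dataset, cfg: Optional[CnnConfig] = None):
    """Full-batch shallow training; returns (CnnModel, TrainingHistory).

    ``dataset`` is a TrainingSet or a precomputed (xs, xt, labels)
    triple.  Refuses single-class datasets.  Reproducible given the
    config seed.

    One BP iteration sweeps the training set once in a fixed order,
    applying an update after every ``batch_size`` items — the classical
    incremental back-propagation of this CNN lineage, with the
    per-pattern error summed over the output units.  A single update
    per iteration cannot reach the shallow-training error floor within
    the iteration budget; incremental updates routinely do.  The
    learning factor is adapted once per iteration against the
    iteration's mean MSE.  Training arithmetic runs in single precision
    (ample for gradient descent on a network this size); the returned
    model carries float32 weights.
    """
    cfg = cfg or CnnConfig()
    if hasattr(dataset, "to_arrays"):
        xs, xt, labels = dataset.to_arrays()
    else:
        xs, xt, labels = dataset
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "training dataset contains a single class; the classifier needs "
            "both normal and (synthetic) abnormal beats"
        )
    model = init_model(cfg)
    model.conv_w = [w.astype(np.float32) for w in model.conv_w]
    model.conv_b = [b.astype(np.float32) for b in model.conv_b]
    model.fc_w = [w.astype(np.float32) for w in model.fc_w]
    model.fc_b = [b.astype(np.float32) for b in model.fc_b]
    # per-channel standardization fitted on the training set keeps the
    # conditioning of the problem independent of recording amplitude
    model.input_mean = np.array([xs.mean(), xt.mean()], dtype=np.float32)
    model.input_std = np.array(
        [max(xs.std(), 1e-12), max(xt.std(), 1e-12)], dtype=np.float32
    )
    history = TrainingHistory()
    eps = cfg.eps0
    prev_mse = None
    history.stop_reason = "max_iters"
    n_items = len(labels)
    x = np.stack([xs, xt], axis=1).astype(np.float32)
    # per-pattern error summed over output units (delta-rule convention)
    step_scale = cfg.n_outputs
    for _ in range(cfg.max_iters):
        eps_used = eps
        sq_sum = 0.0
        for s in range(0, n_items, cfg.batch_size):
            sl = slice(s, min(s + cfg.batch_size, n_items))
            k = sl.stop - sl.start
            mse_b, grads, _ = _loss_and_gradients_cached(model, x[sl], labels[sl])
            sq_sum += mse_b * k
            for name, p in model.parameters():
                p -= eps_used * step_scale * k * grads[name]
        mse = sq_sum / n_items  # iteration-mean train MSE
        # global adaptation for the next iteration
        if prev_mse is not None:
            eps = eps * (cfg.eps_up if mse < prev_mse else cfg.eps_down)
        prev_mse = mse
        err = _classification_error(model, xs, xt, labels)
        history.mse.append(mse)
        history.eps.append(eps_used)
        history.train_error.append(err)
        if err <= cfg.min_train_error:
            history.stop_reason = "error_floor"
            break
    return model, history


def run_ensemble(dataset, cfg: Optional[CnnConfig] = None, n_runs: int = 10):
    """Train ``n_runs`` networks with seeds seed+0 .. seed+n_runs-1.

    Evaluation cumulates the ensemble's confusion matrices, so every
    member's view of the beats is counted.
    """
    cfg = cfg or CnnConfig()
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    out = []
    for i in range(n_runs):
        out.append(train(dataset, replace(cfg, seed=cfg.seed + i)))
    return out


# -- serialization -----------------------------------------------------------

def save_model(model: CnnModel, path) -> None:
    """Single JSON container (floats via repr: bit-exact round-trip)."""
    cfg = model.config
    doc = {
        "format_version": 1,
        "config": {
            "conv_neurons": list(cfg.conv_neurons),
            "fc_neurons": cfg.fc_neurons,
            "n_outputs": cfg.n_outputs,
            "n_input_channels": cfg.n_input_channels,
            "kernel_size": cfg.kernel_size,
            "subsample": cfg.subsample,
            "max_iters": cfg.max_iters,
            "min_train_error": cfg.min_train_error,
            "eps0": cfg.eps0,
            "eps_up": cfg.eps_up,
            "eps_down": cfg.eps_down,
            "seed": cfg.seed,
            "input_len": cfg.input_len,
        },
        "params": {name: p.tolist() for name, p in model.parameters()},
        "input_mean": model.input_mean.tolist(),
        "input_std": model.input_std.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> CnnModel:
    doc = json.loads(Path(path).read_text())
    c = doc["config"]
    cfg = CnnConfig(
        conv_neurons=tuple(c["conv_neurons"]),
        fc_neurons=c["fc_neurons"],
        n_outputs=c["n_outputs"],
        n_input_channels=c["n_input_channels"],
        kernel_size=c["kernel_size"],
        subsample=c["subsample"],
        max_iters=c["max_iters"],
        min_train_error=c["min_train_error"],
        eps0=c["eps0"],
        eps_up=c["eps_up"],
        eps_down=c["eps_down"],
        seed=c["seed"],
        input_len=c["input_len"],
    )
    p = {k: np.array(v) for k, v in doc["params"].items()}
    n_conv = len(cfg.conv_neurons)
    return CnnModel(
        conv_w=[p[f"conv{i + 1}_w"] for i in range(n_conv)],
        conv_b=[p[f"conv{i + 1}_b"] for i in range(n_conv)],
        fc_w=[p["fc1_w"], p["fc2_w"]],
        fc_b=[p["fc1_b"], p["fc2_b"]],
        config=cfg,
        input_mean=np.array(doc["input_mean"]),
        input_std=np.array(doc["input_std"]),
    )
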