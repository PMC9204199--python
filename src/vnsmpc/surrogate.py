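"""Recurrent surrogate of the plant: (previous HR/MAP, command) -> next cycle.

The reference configuration is a single LSTM layer with hidden dimension 10
and tanh activations, followed by a dense tanh output layer of dimension 2,
trained with Adam on a mean-squared error in normalized space: first
teacher-forced one-step-ahead regression, then free-running fine-tuning in
which the model's own predictions are fed back (see docs/methods.md for the
schedule). Evaluation is recursive: given only the first cycle's output and
the command sequence, the model feeds its own predictions back for 99
consecutive cycles, and accuracy is the normalized mean absolute error
against the simulated trial, contextualised by a persistence baseline that
repeats the initial value.

Cells (simple recurrent, GRU, LSTM), backpropagation through time and the
Adam optimizer are implemented directly on numpy arrays: the model is small
enough (a few hundred weights) that this is both fast and dependency-free.
Simulations are float64 end to end, which keeps finite-difference gradients
well behaved when the surrogate sits inside an optimizer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datagen import Dataset, NormStats, denormalize, normalize

__all__ = [
    "SurrogateConfig", "SurrogateModel", "train", "evaluate", "baseline_mae",
    "predict_recursive", "compare_architectures", "save_model", "load_model",
]

_IN_DIM = 8   # (hr, map) + 6 command components
_OUT_DIM = 2


@dataclass(frozen=True)
class SurrogateConfig:
    """Architecture and training hyperparameters."""

    cell: str = "lstm"          # "rnn" | "gru" | "lstm"
    n_layers: int = 1
    hidden: int = 10
    epochs: int = 1000          # total; the tail runs free-running BPTT
    recursive_epochs: int = 600  # final epochs trained on own rollouts
    learning_rate: float = 3e-3
    recursive_lr: float = 1e-2
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.cell not in ("rnn", "gru", "lstm"):
            raise ValueError(f"unknown cell type {self.cell!r}")
        if self.n_layers < 1 or self.hidden < 1:
            raise ValueError("need at least one layer and one hidden unit")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _glorot(rng, shape):
    lim = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-lim, lim, shape)


class _LSTMLayer:
    """Standard LSTM cell; gate order (input, forget, cell, output)."""

    def __init__(self, rng, d_in, hidden):
        self.h = hidden
        self.Wx = _glorot(rng, (d_in, 4 * hidden))
        self.Wh = _glorot(rng, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden:2 * hidden] = 1.0  # forget-gate bias

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def init_state(self, batch):
        return (np.zeros((batch, self.h)), np.zeros((batch, self.h)))

    def init_carry(self, batch):
        return (np.zeros((batch, self.h)), np.zeros((batch, self.h)))

    def step(self, x, state):
        h_prev, c_prev = state
        z = x @ self.Wx + h_prev @ self.Wh + self.b
        H = self.h
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        cache = (x, h_prev, c_prev, i, f, g, o, tc)
        return h, (h, c), cache

    def step_back(self, cache, dh_out, carry, grads):
        dWx, dWh, db = grads
        dh_next, dc_next = carry
        x, h_prev, c_prev, i, f, g, o, tc = cache
        dh = dh_out + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dg * (1 - g * g), do * o * (1 - o)], axis=1)
        dWx += x.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        return dz @ self.Wx.T, (dz @ self.Wh.T, dc * f)


class _GRULayer:
    """GRU cell; gate order (reset, update, candidate)."""

    def __init__(self, rng, d_in, hidden):
        self.h = hidden
        self.Wx = _glorot(rng, (d_in, 3 * hidden))
        self.Wh = _glorot(rng, (hidden, 3 * hidden))
        self.b = np.zeros(3 * hidden)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def init_state(self, batch):
        return (np.zeros((batch, self.h)),)

    def init_carry(self, batch):
        return (np.zeros((batch, self.h)),)

    def step(self, x, state):
        (h_prev,) = state
        H = self.h
        zx = x @ self.Wx + self.b
        zh = h_prev @ self.Wh
        r = _sigmoid(zx[:, :H] + zh[:, :H])
        u = _sigmoid(zx[:, H:2 * H] + zh[:, H:2 * H])
        hn = zh[:, 2 * H:]
        n = np.tanh(zx[:, 2 * H:] + r * hn)
        h = (1.0 - u) * n + u * h_prev
        cache = (x, h_prev, r, u, n, hn)
        return h, (h,), cache

    def step_back(self, cache, dh_out, carry, grads):
        dWx, dWh, db = grads
        (dh_next,) = carry
        x, h_prev, r, u, n, hn = cache
        dh = dh_out + dh_next
        du = dh * (h_prev - n)
        dn = dh * (1.0 - u)
        dh_prev = dh * u
        dan = dn * (1.0 - n * n)
        dr = dan * hn
        dar = dr * r * (1.0 - r)
        dau = du * u * (1.0 - u)
        dzx = np.concatenate([dar, dau, dan], axis=1)
        dzh = np.concatenate([dar, dau, dan * r], axis=1)
        dWx += x.T @ dzx
        dWh += h_prev.T @ dzh
        db += dzx.sum(axis=0)
        return dzx @ self.Wx.T, (dh_prev + dzh @ self.Wh.T,)


class _RNNLayer:
    """Simple (Elman) recurrent cell with tanh activation."""

    def __init__(self, rng, d_in, hidden):
        self.h = hidden
        self.Wx = _glorot(rng, (d_in, hidden))
        self.Wh = _glorot(rng, (hidden, hidden))
        self.b = np.zeros(hidden)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def init_state(self, batch):
        return (np.zeros((batch, self.h)),)

    def init_carry(self, batch):
        return (np.zeros((batch, self.h)),)

    def step(self, x, state):
        (h_prev,) = state
        h = np.tanh(x @ self.Wx + h_prev @ self.Wh + self.b)
        return h, (h,), (x, h_prev, h)

    def step_back(self, cache, dh_out, carry, grads):
        dWx, dWh, db = grads
        (dh_next,) = carry
        x, h_prev, h = cache
        da = (dh_out + dh_next) * (1.0 - h * h)
        dWx += x.T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        return da @ self.Wx.T, (da @ self.Wh.T,)


_CELLS = {"rnn": _RNNLayer, "gru": _GRULayer, "lstm": _LSTMLayer}


class SurrogateModel:
    """Trained recurrent surrogate carried with its normalization statistics.

    The model is only ever evaluated with the NormStats it was trained with;
    they are stored on the object and serialized alongside the weights.
    """

    def __init__(self, config: SurrogateConfig, norm: NormStats,
                 dataset_seed: int | None = None):
        self.config = config
        self.norm = norm
        self.dataset_seed = dataset_seed
        rng = np.random.default_rng(config.seed)
        cls = _CELLS[config.cell]
        self.layers = []
        d = _IN_DIM
        for _ in range(config.n_layers):
            self.layers.append(cls(rng, d, config.hidden))
            d = config.hidden
        self.W_out = _glorot(rng, (d, _OUT_DIM))
        self.b_out = np.zeros(_OUT_DIM)

    # -- parameter plumbing ------------------------------------------------
    def params(self):
        ps = []
        for lay in self.layers:
            ps.extend(lay.params())
        ps.extend([self.W_out, self.b_out])
        return ps

    def n_weights(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward -----------------------------------------------------------
    def init_state(self, batch: int = 1):
        return [lay.init_state(batch) for lay in self.layers]

    def step(self, x: np.ndarray, state, collect=None):
        """One normalized step: x (B, 8) -> y (B, 2), with updated state."""
        h = x
        new_state = []
        for li, lay in enumerate(self.layers):
            h, s, cache = lay.step(h, state[li])
            new_state.append(s)
            if collect is not None:
                collect[li].append(cache)
        y = np.tanh(h @ self.W_out + self.b_out)
        return y, new_state, h

    def forward_seq(self, X: np.ndarray):
        """Teacher-forced forward over (B, T, 8); returns predictions and caches."""
        B, T, _ = X.shape
        state = self.init_state(B)
        caches = [[] for _ in self.layers]
        H_top = []
        Y = np.empty((B, T, _OUT_DIM))
        for t in range(T):
            y, state, h = self.step(X[:, t, :], state, collect=caches)
            H_top.append(h)
            Y[:, t, :] = y
        return Y, caches, H_top

    def _grad_zeros(self):
        per_layer = [[np.zeros_like(p) for p in lay.params()]
                     for lay in self.layers]
        return per_layer, np.zeros_like(self.W_out), np.zeros_like(self.b_out)

    def _flatten_grads(self, per_layer, dW_out, db_out):
        grads = []
        for g in per_layer:
            grads.extend(g)
        grads.extend([dW_out, db_out])
        return grads

    def backward_seq(self, X, Y_pred, dY, caches, H_top,
                     recursive: bool = False):
        """Backpropagation through time given dL/dY_pred.

        With ``recursive=True`` the first two input components of each step
        are the previous step's prediction, and gradient flows back through
        that feedback path as well (free-running rollout training).
        """
        B, T, _ = X.shape
        gl, dW_out, db_out = self._grad_zeros()
        carries = [lay.init_carry(B) for lay in self.layers]
        dy_fb = np.zeros((B, _OUT_DIM))
        for t in range(T - 1, -1, -1):
            dy = dY[:, t, :] + dy_fb
            da = dy * (1.0 - Y_pred[:, t, :] ** 2)  # output tanh
            dW_out += H_top[t].T @ da
            db_out += da.sum(axis=0)
            d_up = da @ self.W_out.T
            for li in range(len(self.layers) - 1, -1, -1):
                d_up, carries[li] = self.layers[li].step_back(
                    caches[li][t], d_up, carries[li], gl[li])
            dy_fb = d_up[:, :_OUT_DIM] if recursive else 0.0 * dy_fb
        return self._flatten_grads(gl, dW_out, db_out)

    def advance_state(self, X, state=None):
        """Teacher-forced state warmup without gradient bookkeeping."""
        B = X.shape[0]
        if state is None:
            state = self.init_state(B)
        for t in range(X.shape[1]):
            _, state, _ = self.step(X[:, t, :], state)
        return state

    def rollout_train(self, y0n, Un, state=None):
        """Free-running forward pass keeping caches for BPTT.

        ``state`` optionally seeds the recurrent state (e.g. after a
        teacher-forced warmup); gradients are truncated at the seed.
        """
        B, T, _ = Un.shape
        if state is None:
            state = self.init_state(B)
        caches = [[] for _ in self.layers]
        H_top = []
        X = np.empty((B, T, _IN_DIM))
        Y = np.empty((B, T, _OUT_DIM))
        y = y0n
        for t in range(T):
            x = np.concatenate([y, Un[:, t, :]], axis=1)
            X[:, t, :] = x
            y, state, h = self.step(x, state, collect=caches)
            H_top.append(h)
            Y[:, t, :] = y
        return X, Y, caches, H_top

    # -- rollout -----------------------------------------------------------
    def rollout(self, y0n: np.ndarray, Un: np.ndarray, state=None):
        """Recursive normalized rollout.

        y0n: (B, 2) initial normalized outputs; Un: (B, T, 6) normalized
        commands. Returns (B, T, 2) predictions; feeds each prediction back.
        """
        B, T, _ = Un.shape
        if state is None:
            state = self.init_state(B)
        y = y0n
        out = np.empty((B, T, _OUT_DIM))
        for t in range(T):
            x = np.concatenate([y, Un[:, t, :]], axis=1)
            y, state, _ = self.step(x, state)
            out[:, t, :] = y
        return out, state


def predict_recursive(model: SurrogateModel, y0, u_seq) -> np.ndarray:
    """Denormalized recursive prediction.

    y0: (HR, MAP) pair; u_seq: (T, 6) command vectors (raw units). Returns
    (T, 2) predicted (HR, MAP), one row per future cycle.
    """
    u_seq = np.atleast_2d(np.asarray(u_seq, dtype=float))
    if u_seq.shape[0] < 1:
        raise ValueError("u_seq must be non-empty")
    y0 = np.asarray(y0, dtype=float).reshape(1, 2)
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial output must be finite")
    sy = model.norm.slice(slice(0, 2))
    su = model.norm.slice(slice(2, 8))
    yn, _ = model.rollout(normalize(y0, sy), normalize(u_seq, su)[None, :, :])
    if not np.all(np.isfinite(yn)):
        raise RuntimeError("non-finite prediction during rollout")
    return denormalize(yn[0], sy)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def update(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TrainingError(RuntimeError):
    pass


def _augment_null_commands(X, norm, rng):
    """Teach the recruitment null set explicitly.

    A stimulation site contributes nothing when either its pulse width or
    its pulse frequency is zero, so a trial recorded with a site off at
    (0, 0) is equally a trial for (0, pf) and (pw, 0) at that site. For a
    random half of such sites the zero pair is replaced by a random point
    on the null set — an exact invariance of the device model that the
    uniform sampling protocol otherwise never exercises, and one the
    optimizer probes heavily when it drives single components to zero.
    """
    X = X.copy()
    mu_u = norm.mu[2:8]
    span = norm.span[2:8]
    u = X[:, 0, 2:] * span + mu_u          # raw commands, constant per trial
    hi = np.array([0.5, 50.0, 0.5, 50.0, 0.5, 50.0])
    for i in range(3):
        off = (u[:, 2 * i] == 0.0) & (u[:, 2 * i + 1] == 0.0)
        idx = np.flatnonzero(off & (rng.uniform(size=u.shape[0]) < 0.5))
        which = rng.integers(0, 2, size=idx.size)  # keep pw or pf at zero
        vals = rng.uniform(0.0, 1.0, size=idx.size)
        u[idx, 2 * i] = np.where(which == 0, 0.0, vals * hi[2 * i])
        u[idx, 2 * i + 1] = np.where(which == 0, vals * hi[2 * i + 1], 0.0)
    X[:, :, 2:] = ((u - mu_u) / span)[:, None, :]
    return X


def _clip(grads, max_norm=5.0):
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return grads


def train(config: SurrogateConfig, dataset: Dataset):
    """Fit the surrogate on the training split.

    Training has two phases: teacher-forced one-step-ahead regression, then
    free-running fine-tuning in which the model's own predictions are fed
    back and gradients flow through the full 99-step rollout — the regime in
    which the surrogate is actually used for prediction and control.

    Returns (model, history) with per-epoch "train" and "val" mean-squared
    errors. Deterministic given the config seed.
    """
    if dataset.norm is None:
        raise ValueError("dataset must carry normalization statistics")
    X, Y = dataset.sequences("train")
    Xv, Yv = dataset.sequences("val")
    X = _augment_null_commands(X, dataset.norm,
                               np.random.default_rng(config.seed + 2))
    # the output layer saturates at +-1; Eq-style scaling must leave headroom
    if np.max(np.abs(Y)) > 0.9:
        raise TrainingError("normalized training targets exceed [-0.9, 0.9]")
    model = SurrogateModel(config, dataset.norm, dataset_seed=dataset.seed)
    rng = np.random.default_rng(config.seed + 1)
    n = X.shape[0]
    bs = min(config.batch_size, n)
    n_rec = min(config.recursive_epochs, config.epochs)
    n_tf = config.epochs - n_rec
    history = {"train": [], "val": []}
    T_full = X.shape[1]
    opt = _Adam(model.params(), config.learning_rate)
    for epoch in range(config.epochs):
        if epoch == n_tf:  # fresh optimizer state for the fine-tuning phase
            opt = _Adam(model.params(), config.recursive_lr)
        recursive = epoch >= n_tf
        if not recursive and n_tf > 1:
            # decay within the teacher-forced phase to polish the one-step fit
            opt.lr = config.learning_rate * (0.1 + 0.9 * (1.0 - epoch / n_tf) ** 2)
        if recursive:
            # curriculum: rollouts lengthen over the fine-tuning phase, and
            # the learning rate decays toward the end
            frac = (epoch - n_tf) / max(n_rec - 1, 1)
            T = T_full if frac >= 0.5 else (T_full // 4 if frac < 0.25
                                            else T_full // 2)
            opt.lr = config.recursive_lr * (0.3 + 0.7 * (1.0 - frac) ** 2)
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, bs):
            idx = order[s:s + bs]
            xb, yb = X[idx], Y[idx]
            if recursive:
                # alternate full rollouts from the trial start with short
                # windows anchored mid-trajectory (teacher-forced warmup,
                # truncated gradient): the short windows match how the
                # model is used for receding-horizon prediction
                if rng.uniform() < 0.5:
                    xb, yb = xb[:, :T], yb[:, :T]
                    st = None
                else:
                    L = 12
                    w0 = int(rng.integers(1, T_full - L + 1))
                    st = model.advance_state(xb[:, :w0])
                    xb, yb = xb[:, w0:w0 + L], yb[:, w0:w0 + L]
                xb, pred, caches, H_top = model.rollout_train(
                    xb[:, 0, :2], xb[:, :, 2:], state=st)
            else:
                pred, caches, H_top = model.forward_seq(xb)
            err = pred - yb
            loss = float(np.mean(err * err))
            if not np.isfinite(loss):
                raise TrainingError("divergent training loss")
            grads = model.backward_seq(xb, pred, 2.0 * err / err.size, caches,
                                       H_top, recursive=recursive)
            opt.update(model.params(), _clip(grads))
            ep_loss += loss * len(idx)
        history["train"].append(ep_loss / n)
        if Xv.shape[0]:
            pv, _, _ = model.forward_seq(Xv)
            history["val"].append(float(np.mean((pv - Yv) ** 2)))
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _split_rollout_targets(dataset: Dataset, split: str):
    X, Y = dataset.sequences(split)   # X: (n, 99, 8) teacher-forced
    y0 = X[:, 0, :2]                  # normalized first-cycle outputs
    U = X[:, :, 2:]                   # normalized commands (constant per trial)
    return y0, U, Y


def evaluate(model: SurrogateModel, dataset: Dataset, split: str = "test") -> float:
    """Normalized MAE of recursive 99-cycle rollouts over a split."""
    y0, U, Y = _split_rollout_targets(dataset, split)
    if y0.shape[0] == 0:
        raise ValueError(f"empty split {split!r}")
    pred, _ = model.rollout(y0, U)
    return float(np.mean(np.abs(pred - Y)))


def baseline_mae(dataset: Dataset, split: str = "test") -> float:
    """Persistence baseline: repeat the initial value for all 99 cycles."""
    y0, _, Y = _split_rollout_targets(dataset, split)
    return float(np.mean(np.abs(y0[:, None, :] - Y)))


def compare_architectures(dataset: Dataset, grid=None):
    """Train every configuration in the grid identically and rank by test MAE.

    Returns a list of dicts sorted by MAE (best first).
    """
    if grid is None:
        grid = [SurrogateConfig(cell=c) for c in ("rnn", "gru", "lstm")]
    rows = []
    for cfg in grid:
        model, hist = train(cfg, dataset)
        rows.append({
            "cell": cfg.cell, "n_layers": cfg.n_layers, "hidden": cfg.hidden,
            "epochs": cfg.epochs, "test_mae": evaluate(model, dataset),
            "final_val_mse": hist["val"][-1] if hist["val"] else np.nan,
        })
    rows.sort(key=lambda r: r["test_mae"])
    return rows


# ---------------------------------------------------------------------------
# persistence: weights file + JSON sidecar
# ---------------------------------------------------------------------------


def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Write weights (npz) and a JSON sidecar with config, NormStats and a
    content hash. Both files are required to reload."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(path.with_suffix(".npz"), **arrays)
    digest = hashlib.sha256(
        b"".join(np.ascontiguousarray(p).tobytes() for p in model.params())
    ).hexdigest()
    sidecar = {
        "config": dataclasses.asdict(model.config),
        "norm": {"mu": model.norm.mu.tolist(),
                 "x_min": model.norm.x_min.tolist(),
                 "x_max": model.norm.x_max.tolist()},
        "dataset_seed": model.dataset_seed,
        "weights_sha256": digest,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> SurrogateModel:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"refusing to load {path}: sidecar {sidecar_path} is missing")
    meta = json.loads(sidecar_path.read_text())
    norm = NormStats(np.array(meta["norm"]["mu"]),
                     np.array(meta["norm"]["x_min"]),
                     np.array(meta["norm"]["x_max"]))
    model = SurrogateModel(SurrogateConfig(**meta["config"]), norm,
                           dataset_seed=meta["dataset_seed"])
    with np.load(path.with_suffix(".npz")) as f:
        for i, p in enumerate(model.params()):
            p[...] = f[f"p{i}"]
    digest = hashlib.sha256(
        b"".join(np.ascontiguousarray(p).tobytes() for p in model.params())
    ).hexdigest()
    if digest != meta["weights_sha256"]:
        raise ValueError("weights file does not match its sidecar hash")
    return model
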