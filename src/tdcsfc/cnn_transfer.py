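"""3D convolutional classifier with transfer learning, in pure numpy.

A compact, self-contained implementation of the whole-map FC classifier:
conv/max-pool feature-extraction blocks, fully connected decision layers
with dropout, softmax cross-entropy, Adam, patience-based early stopping
with checkpoint revert, and fine-tuning with frozen feature layers.
Gradients are computed analytically per layer and verified against numerical
differentiation in the test suite.

Also houses the pre-training bookkeeping: the CGI labelling rule (healthy
controls / first-degree relatives with CGI 0 -> label 0; SZ / OCD patients
with CGI > 3 -> label 1) and the sex/age-stratified minority oversampling
used to balance the pre-training classes.
"""

from __future__ import annotations

import copy
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .synthetic import PretrainRecord

__all__ = [
    "CnnArchitecture",
    "TrainConfig",
    "Cnn3d",
    "assign_cgi_labels",
    "oversample_balance",
    "build_cnn",
    "train_with_revert",
    "transfer_finetune",
]

IMPROVEMENT_RTOL = 1e-6  # relative improvement below this counts as "not decreasing"


# ---------------------------------------------------------------------------
# pre-training bookkeeping


def assign_cgi_labels(
    records: Sequence[PretrainRecord],
) -> tuple[list[tuple[PretrainRecord, int]], int]:
    """Apply the CGI labelling rule.

    HC/FDR with CGI = 0 get label 0; SZ/OCD with CGI strictly above 3 get
    label 1; anything else is excluded.  Returns (labelled records,
    excluded count); labelled + excluded always equals the input size.
    """
    labelled: list[tuple[PretrainRecord, int]] = []
    excluded = 0
    for rec in records:
        if rec.group in ("HC", "FDR") and rec.cgi == 0:
            labelled.append((rec, 0))
        elif rec.group in ("SZ", "OCD") and rec.cgi > 3:
            labelled.append((rec, 1))
        else:
            excluded += 1
    return labelled, excluded


def oversample_balance(
    labelled: Sequence[tuple[PretrainRecord, int]],
    seed: int = 0,
    n_age_bins: int = 10,
) -> list[tuple[PretrainRecord, int]]:
    """Duplicate minority-class records, stratified by (sex, age decile),
    until class counts are equal.

    All original records are kept; duplicates are allocated across strata to
    close the gap toward the majority's (sex, age-bin) composition, sampling
    within each stratum with replacement.  An empty minority stratum falls
    back to the nearest age bin with the same sex (then to any stratum).
    Output size is exactly twice the majority count; the majority class is
    untouched.
    """
    labelled = list(labelled)
    y = np.array([lab for _, lab in labelled])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts[0] == counts[1]:
        return labelled
    maj_label = classes[np.argmax(counts)]
    minority = [(r, l) for r, l in labelled if l != maj_label]
    majority = [(r, l) for r, l in labelled if l == maj_label]
    n_add = len(majority) - len(minority)

    ages = np.array([r.age for r, _ in labelled])
    edges = np.quantile(ages, np.linspace(0, 1, n_age_bins + 1))[1:-1]

    def stratum(rec: PretrainRecord) -> tuple[int, int]:
        return rec.sex, int(np.searchsorted(edges, rec.age, side="right"))

    def counts_by_stratum(group):
        out: dict[tuple[int, int], int] = {}
        for r, _ in group:
            out[stratum(r)] = out.get(stratum(r), 0) + 1
        return out

    maj_c = counts_by_stratum(majority)
    min_c = counts_by_stratum(minority)
    deficits = {s: max(0, c - min_c.get(s, 0)) for s, c in maj_c.items()}
    total_deficit = sum(deficits.values())
    strata = sorted(deficits)
    # largest-remainder allocation of n_add duplicates over strata
    raw = {s: n_add * deficits[s] / total_deficit for s in strata}
    alloc = {s: int(math.floor(raw[s])) for s in strata}
    remainder = n_add - sum(alloc.values())
    for s in sorted(strata, key=lambda s: raw[s] - alloc[s], reverse=True)[:remainder]:
        alloc[s] += 1

    pools: dict[tuple[int, int], list] = {}
    for r, l in minority:
        pools.setdefault(stratum(r), []).append((r, l))

    rng = np.random.default_rng(seed)
    duplicates: list[tuple[PretrainRecord, int]] = []
    for s in strata:
        k = alloc[s]
        if k == 0:
            continue
        pool = pools.get(s)
        if not pool:
            same_sex = [t for t in pools if t[0] == s[0]]
            if same_sex:
                nearest = min(same_sex, key=lambda t: abs(t[1] - s[1]))
                pool = pools[nearest]
            else:
                pool = minority
        picks = rng.integers(0, len(pool), size=k)
        duplicates.extend(pool[i] for i in picks)
    return labelled + duplicates


# ---------------------------------------------------------------------------
# layers


class _Layer:
    trainable = True
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(_Layer):
    def __init__(self, in_c: int, out_c: int, kernel: int, padding: int, rng):
        super().__init__()
        self.kernel, self.padding = kernel, padding
        std = math.sqrt(2.0 / (in_c * kernel**3))
        self.params["W"] = rng.normal(0, std, size=(out_c, in_c, kernel, kernel, kernel))
        self.params["b"] = np.zeros(out_c)

    def out_dims(self, dims):
        return tuple(d + 2 * self.padding - self.kernel + 1 for d in dims)

    def forward(self, x, train=False):
        p = self.padding
        self._x_padded = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        W, b = self.params["W"], self.params["b"]
        n = x.shape[0]
        ox, oy, oz = self.out_dims(x.shape[2:])
        out = np.zeros((n, W.shape[0], ox, oy, oz))
        for a in range(self.kernel):
            for bb in range(self.kernel):
                for c in range(self.kernel):
                    xs = self._x_padded[:, :, a : a + ox, bb : bb + oy, c : c + oz]
                    out += np.einsum("ncxyz,oc->noxyz", xs, W[:, :, a, bb, c])
        return out + b[None, :, None, None, None]

    def backward(self, dout):
        W = self.params["W"]
        ox, oy, oz = dout.shape[2:]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(self._x_padded)
        for a in range(self.kernel):
            for bb in range(self.kernel):
                for c in range(self.kernel):
                    xs = self._x_padded[:, :, a : a + ox, bb : bb + oy, c : c + oz]
                    dW[:, :, a, bb, c] = np.einsum("noxyz,ncxyz->oc", dout, xs)
                    dxp[:, :, a : a + ox, bb : bb + oy, c : c + oz] += np.einsum(
                        "noxyz,oc->ncxyz", dout, W[:, :, a, bb, c]
                    )
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 2, 3, 4))
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class MaxPool3d(_Layer):
    trainable = False

    def __init__(self, kernel: int = 2, stride: int = 2):
        super().__init__()
        if kernel != stride:
            raise ValueError("pooling kernel must equal stride")
        self.k = kernel

    def out_dims(self, dims):
        out = tuple(d // self.k for d in dims)
        if any(d < 1 for d in out):
            raise ValueError(f"pooling underflow: input dims {dims}")
        return out

    def forward(self, x, train=False):
        k = self.k
        n, c = x.shape[:2]
        ox, oy, oz = self.out_dims(x.shape[2:])
        self._in_shape = x.shape
        xc = x[:, :, : ox * k, : oy * k, : oz * k]
        win = xc.reshape(n, c, ox, k, oy, k, oz, k)
        win = win.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, ox, oy, oz, k**3)
        self._argmax = win.argmax(axis=-1)
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        k = self.k
        n, c, ox, oy, oz = dout.shape
        dwin = np.zeros((n, c, ox, oy, oz, k**3))
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(n, c, ox, oy, oz, k, k, k).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros(self._in_shape)
        dx[:, :, : ox * k, : oy * k, : oz * k] = dwin.reshape(
            n, c, ox * k, oy * k, oz * k
        )
        return dx


class ReLU(_Layer):
    trainable = False

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(_Layer):
    trainable = False

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(_Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        std = math.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0, std, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(_Layer):
    trainable = False

    def __init__(self, rate: float, rng):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class CnnArchitecture:
    """Configurable architecture; the default is the desk-scale network
    (four 3^3 conv blocks with 2^3 max-pooling, one hidden decision layer).

    ``conv_blocks`` entries are (kernel_size, padding, in_channels,
    n_filters); ``pool`` is (kernel_size, stride).
    """

    input_dims: tuple[int, int, int] = (24, 28, 24)
    conv_blocks: tuple[tuple[int, int, int, int], ...] = (
        (3, 1, 1, 8),
        (3, 1, 8, 16),
        (3, 1, 16, 32),
        (3, 1, 32, 64),
    )
    pool: tuple[int, int] = (2, 2)
    fc_units: int = 32
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


class Cnn3d:
    """Sequential 3D CNN split into feature-extraction and decision stages."""

    def __init__(self, arch: CnnArchitecture, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.feature_layers: list[_Layer] = []
        dims = arch.input_dims
        for i, (k, p, c_in, c_out) in enumerate(arch.conv_blocks):
            conv = Conv3d(c_in, c_out, k, p, rng)
            dims = conv.out_dims(dims)
            if any(d < 1 for d in dims):
                raise ValueError(f"conv block {i}: output dims underflow ({dims})")
            pool = MaxPool3d(*arch.pool)
            try:
                dims = pool.out_dims(dims)
            except ValueError as e:
                raise ValueError(f"conv block {i}: {e}") from None
            self.feature_layers += [conv, ReLU(), pool]
        self.feature_dims = dims
        self.n_flat = arch.conv_blocks[-1][3] * int(np.prod(dims))
        self._dropout_rng = np.random.default_rng(seed + 1)
        self.decision_layers = self._make_decision_layers(rng)

    def _make_decision_layers(self, rng) -> list[_Layer]:
        return [
            Flatten(),
            Linear(self.n_flat, self.arch.fc_units, rng),
            ReLU(),
            Dropout(self.arch.dropout_rate, self._dropout_rng),
            Linear(self.arch.fc_units, self.arch.n_classes, rng),
        ]

    @property
    def layers(self) -> list[_Layer]:
        return self.feature_layers + self.decision_layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 4:  # (N, X, Y, Z) -> single channel
            x = x[:, None]
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameter_count(self) -> int:
        return sum(p.size for l in self.layers for p in l.params.values())

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in sorted_params(l)]

    def set_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for l in self.layers:
            for name in sorted(l.params):
                l.params[name][...] = state[i]
                i += 1

    def adapt_input(self, input_dims: tuple[int, int, int]) -> None:
        """Recompute the flattened feature size for a new input grid (the
        conv/pool stack is size-agnostic; only the decision stage changes)."""
        import dataclasses

        dims = input_dims
        for layer in self.feature_layers:
            if isinstance(layer, (Conv3d, MaxPool3d)):
                dims = layer.out_dims(dims)
                if any(d < 1 for d in dims):
                    raise ValueError(f"input dims {input_dims} underflow the stack")
        self.feature_dims = dims
        self.n_flat = self.arch.conv_blocks[-1][3] * int(np.prod(dims))
        self.arch = dataclasses.replace(self.arch, input_dims=tuple(input_dims))

    def reinit_decision_layers(self, seed: int, head_scale: float = 1.0) -> None:
        """Replace the decision stage with fresh (seeded) layers.

        ``head_scale`` < 1 shrinks the new weights (initial logits near zero,
        loss near ln 2) — the usual choice when attaching a new head to a
        pre-trained feature stack, so early updates refine rather than fight
        random logits.
        """
        rng = np.random.default_rng(seed)
        self.decision_layers = self._make_decision_layers(rng)
        if head_scale != 1.0:
            for layer in self.decision_layers:
                for p in layer.params.values():
                    p *= head_scale

    def frozen_checksum(self, n_frozen_blocks: int) -> float:
        layers = self.feature_layers[: 3 * n_frozen_blocks]
        return float(sum(np.abs(p).sum() for l in layers for p in l.params.values()))


def sorted_params(layer: _Layer):
    return [layer.params[k] for k in sorted(layer.params)]


def build_cnn(arch: CnnArchitecture, seed: int = 0) -> Cnn3d:
    """Construct the network; raises naming the offending block on shape
    underflow."""
    return Cnn3d(arch, seed=seed)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(probs[np.arange(n), y] + 1e-300).mean()
    d = probs.copy()
    d[np.arange(n), y] -= 1.0
    return loss, d / n


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 1000
    patience_epochs: int = 100
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience_epochs >= self.max_epochs:
            raise ValueError("patience must be below max_epochs")


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}
        self.t = 0

    def step(self, layers: Sequence[_Layer]) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            if not layer.trainable or not layer.params:
                continue
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (li, name)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _validation_error(model: Cnn3d, Xval: np.ndarray, yval: np.ndarray) -> float:
    loss, _ = softmax_cross_entropy(model.forward(Xval, train=False), yval)
    return float(loss)


def train_with_revert(
    model: Cnn3d,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    eval_fn: Optional[Callable[[Cnn3d, int], float]] = None,
    frozen_layers: Sequence[_Layer] = (),
) -> dict:
    """Adam + cross-entropy training with revert-style early stopping.

    After each epoch the validation error is computed (``eval_fn`` overrides
    the default cross-entropy on ``val_data``, e.g. for scripted tests).  If
    the best error has not improved by a relative 1e-6 for
    ``patience_epochs`` consecutive epochs, the parameters are restored from
    the checkpoint ``patience_epochs`` epochs earlier and training stops.
    Returns a history dict with per-epoch losses and the revert event.
    """
    Xtr, ytr = train_data
    if eval_fn is None:
        Xval, yval = val_data
        eval_fn = lambda m, epoch: _validation_error(m, Xval, yval)
    opt = Adam(config.learning_rate)
    rng = np.random.default_rng(config.seed)
    frozen_ids = {id(l) for l in frozen_layers}
    trainable = [l for l in model.layers if id(l) not in frozen_ids]

    checkpoints: deque = deque(maxlen=config.patience_epochs + 1)
    history = {"train_loss": [], "val_error": [], "reverted_to_epoch": None,
               "stopped_epoch": None}
    best = math.inf
    stall = 0
    n = len(ytr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(Xtr[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step(trainable)
            losses.append(loss)
        checkpoints.append((epoch, model.get_state()))
        err = float(eval_fn(model, epoch))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_error"].append(err)
        if not math.isfinite(best) or best - err > IMPROVEMENT_RTOL * max(abs(best), 1e-12):
            best = err
            stall = 0
        else:
            stall += 1
        if stall >= config.patience_epochs:
            back_epoch, state = checkpoints[0]
            model.set_state(state)
            history["reverted_to_epoch"] = back_epoch
            history["stopped_epoch"] = epoch
            return history
    history["stopped_epoch"] = config.max_epochs - 1
    return history


def transfer_finetune(
    pretrained: Cnn3d,
    target_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    n_frozen_layers: int = 4,
) -> tuple[Cnn3d, dict]:
    """Freeze the first ``n_frozen_layers`` feature-extraction blocks,
    replace the decision layers (seeded re-init) and train on the target
    task.  The pretrained model is left untouched; frozen parameters of the
    returned model are bit-identical to the pretrained ones.
    """
    n_blocks = len(pretrained.arch.conv_blocks)
    if n_frozen_layers > n_blocks:
        raise ValueError(
            f"n_frozen_layers={n_frozen_layers} exceeds {n_blocks} feature blocks"
        )
    model = copy.deepcopy(pretrained)
    # the decision stage is rebuilt (seeded) for the target input size
    Xt = target_data[0]
    target_dims = Xt.shape[1:] if Xt.ndim == 4 else Xt.shape[2:]
    model.adapt_input(tuple(target_dims))
    model.reinit_decision_layers(config.seed, head_scale=0.1)
    frozen = model.feature_layers[: 3 * n_frozen_layers]
    history = train_with_revert(
        model, target_data, val_data, config, frozen_layers=frozen
    )
    return model, history
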