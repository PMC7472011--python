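"""Small convolutional network for raw 40 ms EEG windows, in pure numpy.

Architecture (valid padding, stride 1 throughout)::

    input 19x20x1  (zero-centred)
    conv 16 @ 3x3      -> 17x18x16
    conv 16 @ 3x3      -> 15x16x16
    maxpool 2x2 s1     -> 14x15x16
    leaky-relu (0.01)
    dropout 50%
    conv 10 @ 2x2      -> 13x14x10
    conv 10 @ 2x2      -> 12x13x10
    maxpool 2x2 s1     -> 11x12x10
    leaky-relu (0.01)
    dropout 50%
    flatten            -> 1320
    fc 1320 -> 64, leaky-relu
    fc 64 -> 2, softmax over {non_stress, stress}

Training is minibatch Adam on cross-entropy, batch 32, 20 epochs, with the
dataset reshuffled every epoch from a seeded stream; dropout is active in
training only, so inference is deterministic.  Convolution follows the
standard deep-learning cross-correlation convention.  Everything — forward,
backward, the optimiser — is implemented here so the classifier has no
framework dependency and stays reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labeling import NON_STRESS, STRESS
from .preprocess import NormStats, WindowTensor, apply_normalizer, fit_normalizer

#: Class order of the softmax output; stress is the positive class (index 1).
CLASSES = (NON_STRESS, STRESS)


# ---------------------------------------------------------------------------
# layer primitives (arrays are [batch x height x width x channels])


def conv2d(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Valid-padding stride-1 cross-correlation.

    ``x``: [N x H x W x Cin] (a single [H x W x Cin] block is promoted);
    ``kernels``: [Cout x Cin x KH x KW]; output [N x H-KH+1 x W-KW+1 x Cout].
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    n, h, w, cin = x.shape
    cout, kcin, kh, kw = kernels.shape
    if kcin != cin:
        raise ValueError(f"kernel depth {kcin} != input depth {cin}")
    if kh > h or kw > w:
        raise ValueError(f"kernel {kh}x{kw} larger than input {h}x{w}")
    ho, wo = h - kh + 1, w - kw + 1
    out = np.zeros((n, ho, wo, cout), dtype=x.dtype)
    # shift-and-accumulate: one BLAS matmul per kernel tap
    for ki in range(kh):
        for kj in range(kw):
            patch = x[:, ki : ki + ho, kj : kj + wo, :].reshape(-1, cin)
            out += (patch @ kernels[:, :, ki, kj].T).reshape(n, ho, wo, cout)
    if bias is not None:
        out += bias
    return out[0] if squeeze else out


def _conv2d_backward(x, kernels, d_out):
    n, h, w, cin = x.shape
    cout, _, kh, kw = kernels.shape
    ho, wo = h - kh + 1, w - kw + 1
    d_x = np.zeros_like(x)
    d_k = np.zeros_like(kernels)
    d_flat = d_out.reshape(-1, cout)
    for ki in range(kh):
        for kj in range(kw):
            patch = x[:, ki : ki + ho, kj : kj + wo, :].reshape(-1, cin)
            d_k[:, :, ki, kj] = d_flat.T @ patch
            d_x[:, ki : ki + ho, kj : kj + wo, :] += (d_flat @ kernels[:, :, ki, kj]).reshape(
                n, ho, wo, cin
            )
    d_b = d_out.sum(axis=(0, 1, 2))
    return d_x, d_k, d_b


def leaky_relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    """x for x > 0, slope*x for x <= 0."""
    return np.where(x > 0, x, slope * x)


def maxpool(x: np.ndarray, window: tuple[int, int] = (2, 2), stride: tuple[int, int] = (1, 1)):
    """Sliding-window maximum per feature map; returns (output, argmax_index)."""
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    n, h, w, c = x.shape
    ph, pw = window
    sh, sw = stride
    if ph > h or pw > w:
        raise ValueError(f"pool window {ph}x{pw} larger than input {h}x{w}")
    ho = (h - ph) // sh + 1
    wo = (w - pw) // sw + 1
    stacked = np.stack(
        [
            x[:, i : i + (ho - 1) * sh + 1 : sh, j : j + (wo - 1) * sw + 1 : sw, :]
            for i in range(ph)
            for j in range(pw)
        ],
        axis=-1,
    )  # [N x ho x wo x C x ph*pw]
    arg = stacked.argmax(axis=-1)
    out = np.take_along_axis(stacked, arg[..., None], axis=-1)[..., 0]
    if squeeze:
        return out[0], arg[0]
    return out, arg


def _maxpool_backward(x_shape, arg, d_out, window=(2, 2), stride=(1, 1)):
    n, h, w, c = x_shape
    ph, pw = window
    sh, sw = stride
    ho, wo = d_out.shape[1], d_out.shape[2]
    d_x = np.zeros(x_shape, dtype=d_out.dtype)
    for k, (i, j) in enumerate([(i, j) for i in range(ph) for j in range(pw)]):
        mask = arg == k
        contrib = np.where(mask, d_out, 0.0)
        d_x[:, i : i + (ho - 1) * sh + 1 : sh, j : j + (wo - 1) * sw + 1 : sw, :] += contrib
    return d_x


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class CnnSpec:
    """Layer stack parameters; defaults reproduce the reference architecture."""

    input_shape: tuple[int, int, int] = (19, 20, 1)
    conv1_filters: int = 16
    conv1_kernel: tuple[int, int] = (3, 3)
    conv2_filters: int = 16
    conv2_kernel: tuple[int, int] = (3, 3)
    conv3_filters: int = 10
    conv3_kernel: tuple[int, int] = (2, 2)
    conv4_filters: int = 10
    conv4_kernel: tuple[int, int] = (2, 2)
    pool_window: tuple[int, int] = (2, 2)
    pool_stride: tuple[int, int] = (1, 1)
    leaky_slope: float = 0.01
    dropout: float = 0.5
    fc_hidden: int = 64
    n_classes: int = 2
    seed: int = 0

    def shape_trace(self) -> list[tuple[int, int, int]]:
        """Spatial shapes after each block, ending at the flattened width."""
        h, w, c = self.input_shape
        trace = [(h, w, c)]

        def after_conv(h, w, c, k, f):
            return h - k[0] + 1, w - k[1] + 1, f

        def after_pool(h, w, c):
            ph, pw = self.pool_window
            sh, sw = self.pool_stride
            return (h - ph) // sh + 1, (w - pw) // sw + 1, c

        h, w, c = after_conv(h, w, c, self.conv1_kernel, self.conv1_filters)
        trace.append((h, w, c))
        h, w, c = after_conv(h, w, c, self.conv2_kernel, self.conv2_filters)
        trace.append((h, w, c))
        h, w, c = after_pool(h, w, c)
        trace.append((h, w, c))
        h, w, c = after_conv(h, w, c, self.conv3_kernel, self.conv3_filters)
        trace.append((h, w, c))
        h, w, c = after_conv(h, w, c, self.conv4_kernel, self.conv4_filters)
        trace.append((h, w, c))
        h, w, c = after_pool(h, w, c)
        trace.append((h, w, c))
        if h < 1 or w < 1:
            raise ValueError("layer stack shrinks the input below 1x1; shapes do not chain")
        return trace

    @property
    def n_flat_features(self) -> int:
        h, w, c = self.shape_trace()[-1]
        return h * w * c


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 32
    epochs: int = 20
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def _init_params(spec: CnnSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded He-style uniform fan-in initialisation."""

    def he(shape, fan_in):
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=shape).astype(np.float32)

    h, w, cin = spec.input_shape
    p = {}
    p["k1"] = he((spec.conv1_filters, cin, *spec.conv1_kernel), cin * np.prod(spec.conv1_kernel))
    p["b1"] = np.zeros(spec.conv1_filters, dtype=np.float32)
    p["k2"] = he(
        (spec.conv2_filters, spec.conv1_filters, *spec.conv2_kernel),
        spec.conv1_filters * np.prod(spec.conv2_kernel),
    )
    p["b2"] = np.zeros(spec.conv2_filters, dtype=np.float32)
    p["k3"] = he(
        (spec.conv3_filters, spec.conv2_filters, *spec.conv3_kernel),
        spec.conv2_filters * np.prod(spec.conv3_kernel),
    )
    p["b3"] = np.zeros(spec.conv3_filters, dtype=np.float32)
    p["k4"] = he(
        (spec.conv4_filters, spec.conv3_filters, *spec.conv4_kernel),
        spec.conv3_filters * np.prod(spec.conv4_kernel),
    )
    p["b4"] = np.zeros(spec.conv4_filters, dtype=np.float32)
    n_flat = spec.n_flat_features
    p["w5"] = he((n_flat, spec.fc_hidden), n_flat)
    p["b5"] = np.zeros(spec.fc_hidden, dtype=np.float32)
    p["w6"] = he((spec.fc_hidden, spec.n_classes), spec.fc_hidden)
    p["b6"] = np.zeros(spec.n_classes, dtype=np.float32)
    return p


def _forward_pass(
    params: dict,
    spec: CnnSpec,
    x: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
    keep_cache: bool = False,
):
    """Run the network; returns (probabilities, flat_features, cache)."""
    s = spec.leaky_slope
    cache: dict = {"x": x}

    a1 = conv2d(x, params["k1"], params["b1"])
    a2 = conv2d(a1, params["k2"], params["b2"])
    p1, arg1 = maxpool(a2, spec.pool_window, spec.pool_stride)
    r1 = leaky_relu(p1, s)
    if train:
        m1 = (rng.random(r1.shape) >= spec.dropout).astype(r1.dtype) / (1.0 - spec.dropout)
        d1 = r1 * m1
    else:
        m1 = None
        d1 = r1

    a3 = conv2d(d1, params["k3"], params["b3"])
    a4 = conv2d(a3, params["k4"], params["b4"])
    p2, arg2 = maxpool(a4, spec.pool_window, spec.pool_stride)
    r2 = leaky_relu(p2, s)
    if train:
        m2 = (rng.random(r2.shape) >= spec.dropout).astype(r2.dtype) / (1.0 - spec.dropout)
        d2 = r2 * m2
    else:
        m2 = None
        d2 = r2

    flat = d2.reshape(d2.shape[0], -1)
    h = leaky_relu(flat @ params["w5"] + params["b5"], s)
    logits = h @ params["w6"] + params["b6"]
    probs = softmax(logits)

    if keep_cache:
        cache.update(
            a1=a1, a2=a2, arg1=arg1, p1=p1, r1=r1, m1=m1, d1=d1,
            a3=a3, a4=a4, arg2=arg2, p2=p2, r2=r2, m2=m2, d2=d2,
            flat=flat, h=h,
        )
    return probs, flat, cache


def _backward_pass(params, spec, cache, probs, y_onehot):
    """Gradients of mean cross-entropy wrt every parameter."""
    s = spec.leaky_slope
    n = probs.shape[0]
    g: dict[str, np.ndarray] = {}

    d_logits = (probs - y_onehot) / n
    g["w6"] = cache["h"].T @ d_logits
    g["b6"] = d_logits.sum(axis=0)
    d_h = d_logits @ params["w6"].T
    pre_h = cache["flat"] @ params["w5"] + params["b5"]
    d_pre = d_h * np.where(pre_h > 0, 1.0, s)
    g["w5"] = cache["flat"].T @ d_pre
    g["b5"] = d_pre.sum(axis=0)
    d_flat = d_pre @ params["w5"].T
    d_d2 = d_flat.reshape(cache["d2"].shape)

    if cache["m2"] is not None:
        d_r2 = d_d2 * cache["m2"]
    else:
        d_r2 = d_d2
    d_p2 = d_r2 * np.where(cache["p2"] > 0, 1.0, s)
    d_a4 = _maxpool_backward(cache["a4"].shape, cache["arg2"], d_p2, spec.pool_window, spec.pool_stride)
    d_a3, g["k4"], g["b4"] = _conv2d_backward(cache["a3"], params["k4"], d_a4)
    d_d1, g["k3"], g["b3"] = _conv2d_backward(cache["d1"], params["k3"], d_a3)

    if cache["m1"] is not None:
        d_r1 = d_d1 * cache["m1"]
    else:
        d_r1 = d_d1
    d_p1 = d_r1 * np.where(cache["p1"] > 0, 1.0, s)
    d_a2 = _maxpool_backward(cache["a2"].shape, cache["arg1"], d_p1, spec.pool_window, spec.pool_stride)
    d_a1, g["k2"], g["b2"] = _conv2d_backward(cache["a1"], params["k2"], d_a2)
    _, g["k1"], g["b1"] = _conv2d_backward(cache["x"], params["k1"], d_a1)
    return g


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        c = self.cfg
        self.t += 1
        for k in params:
            gk = grads[k].astype(params[k].dtype)
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * gk
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * gk**2
            m_hat = self.m[k] / (1 - c.beta1**self.t)
            v_hat = self.v[k] / (1 - c.beta2**self.t)
            params[k] -= c.learning_rate * m_hat / (np.sqrt(v_hat) + c.adam_eps)


# ---------------------------------------------------------------------------
# trained-model container and the public train/predict API


@dataclass
class TrainedModel:
    spec: CnnSpec
    params: dict[str, np.ndarray]
    norm: NormStats
    history: list[dict] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params)
        (directory / "spec.json").write_text(json.dumps(self.spec.__dict__, default=list))
        (directory / "norm.json").write_text(
            json.dumps({"offset": self.norm.offset, "scale": self.norm.scale,
                        "computed_on": self.norm.computed_on})
        )
        (directory / "history.json").write_text(json.dumps(self.history))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        import json

        directory = Path(directory)
        raw = json.loads((directory / "spec.json").read_text())
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        spec = CnnSpec(**raw)
        with np.load(directory / "weights.npz") as z:
            params = {k: z[k] for k in z.files}
        nraw = json.loads((directory / "norm.json").read_text())
        hist = json.loads((directory / "history.json").read_text())
        return cls(spec=spec, params=params, norm=NormStats(**nraw), history=hist)


def _tensor_to_batch(tensor: WindowTensor) -> np.ndarray:
    # [C x S x 1 x N] -> [N x C x S x 1]
    return np.ascontiguousarray(np.transpose(tensor.data, (3, 0, 1, 2)), dtype=np.float32)


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Map {'non_stress','stress'} (or already-int) labels to class indices."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        return labels.astype(np.int64)
    lut = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.array([lut[l] for l in labels], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"unknown label {e.args[0]!r}; expected one of {CLASSES}") from None


def forward(
    model: TrainedModel, tensor: WindowTensor, batch_size: int = 1024, normalized: bool = False
) -> np.ndarray:
    """Per-window class probabilities ``[n_windows x 2]`` (eval mode, no dropout)."""
    if not normalized:
        tensor = apply_normalizer(tensor, model.norm)
    x = _tensor_to_batch(tensor)
    if x.shape[1:] != model.spec.input_shape:
        raise ValueError(f"window shape {x.shape[1:]} does not match spec {model.spec.input_shape}")
    out = np.empty((x.shape[0], model.spec.n_classes), dtype=np.float64)
    for i in range(0, x.shape[0], batch_size):
        probs, _, _ = _forward_pass(model.params, model.spec, x[i : i + batch_size], train=False)
        out[i : i + batch_size] = probs
    return out


def predict_labels(model: TrainedModel, tensor: WindowTensor, **kw) -> np.ndarray:
    probs = forward(model, tensor, **kw)
    return np.array([CLASSES[i] for i in probs.argmax(axis=1)], dtype=object)


def _loss_acc(probs: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train(
    spec: CnnSpec,
    cfg: TrainConfig,
    train_tensor: WindowTensor,
    train_labels: np.ndarray,
    val_tensor: WindowTensor | None = None,
    val_labels: np.ndarray | None = None,
    norm: NormStats | None = None,
) -> TrainedModel:
    """Train the network; normalisation statistics are frozen on the training set.

    Validation data is used for per-epoch monitoring only (no early
    stopping).  Fully deterministic for fixed ``spec.seed`` / ``cfg.seed``.
    """
    y = encode_labels(train_labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("training set contains a single class")
    if train_tensor.n_windows != len(y):
        raise ValueError("label count does not match window count")

    if norm is None:
        norm = fit_normalizer(train_tensor)
    x = _tensor_to_batch(apply_normalizer(train_tensor, norm))

    x_val = y_val = None
    if val_tensor is not None:
        x_val = _tensor_to_batch(apply_normalizer(val_tensor, norm))
        y_val = encode_labels(val_labels)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, spec.seed]))
    params = _init_params(spec, rng)
    opt = _Adam(params, cfg)
    n = x.shape[0]
    onehot = np.eye(spec.n_classes, dtype=np.float32)

    history = []
    order = np.arange(n)
    for epoch in range(cfg.epochs):
        if cfg.shuffle_each_epoch:
            order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            probs, _, cache = _forward_pass(params, spec, xb, train=True, rng=rng, keep_cache=True)
            grads = _backward_pass(params, spec, cache, probs, onehot[yb])
            opt.step(params, grads)
            loss, _ = _loss_acc(probs, yb)
            ep_loss += loss * len(idx)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
        entry = {
            "epoch": epoch + 1,
            "train_loss": ep_loss / n,
            "train_acc": ep_correct / n,
        }
        if not np.isfinite(entry["train_loss"]):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch + 1}")
        if x_val is not None:
            vprobs = _predict_probs(params, spec, x_val)
            entry["val_loss"], entry["val_acc"] = _loss_acc(vprobs, y_val)
        history.append(entry)

    return TrainedModel(spec=spec, params=params, norm=norm, history=history)


def _predict_probs(params, spec, x, batch_size: int = 1024) -> np.ndarray:
    out = np.empty((x.shape[0], spec.n_classes), dtype=np.float64)
    for i in range(0, x.shape[0], batch_size):
        probs, _, _ = _forward_pass(params, spec, x[i : i + batch_size], train=False)
        out[i : i + batch_size] = probs
    return out


def extract_cnn_features(
    model: TrainedModel,
    tensor: WindowTensor,
    labels: np.ndarray | None = None,
    subjects: np.ndarray | None = None,
    batch_size: int = 1024,
):
    """Flattened pre-FC activations (eval mode) as a feature table.

    One row per window, ``n_flat_features`` (1,320 by default) columns,
    consumable by :func:`stresswin.features.fit_baselines`.
    """
    import pandas as pd

    from .features import FeatureTable

    x = _tensor_to_batch(apply_normalizer(tensor, model.norm))
    feats = np.empty((x.shape[0], model.spec.n_flat_features), dtype=np.float32)
    for i in range(0, x.shape[0], batch_size):
        _, flat, _ = _forward_pass(model.params, model.spec, x[i : i + batch_size], train=False)
        feats[i : i + batch_size] = flat
    frame = pd.DataFrame(feats, columns=[f"cnn[{j}]" for j in range(feats.shape[1])])
    if labels is None:
        labels = np.array([""] * len(frame), dtype=object)
    if subjects is None:
        subjects = np.array([tensor.subject_id] * len(frame), dtype=object)
    return FeatureTable(
        frame=frame,
        label=np.asarray(labels, dtype=object),
        subject=np.asarray(subjects, dtype=object),
        segment=np.arange(len(frame)),
    )
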