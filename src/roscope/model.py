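"""CNN architecture for slice classification, with an exact shape calculus.

The network is small and fully pinned down by its characteristic dimensions: a
256x256 grayscale slice passes through conv(8 filters, kernel 16) -> ReLU ->
dropout 0.20 -> 5x5 max pool -> conv(16 filters, kernel 5) -> ReLU -> 5x5 max
pool -> flatten, giving an 8x48x48 tensor entering the second convolution and
a 1024-long flattened vector, which three dense layers reduce to 2 classes
(CBD vs control) or 3 classes (LPS / GP120 / Abeta42) under a softmax.
Convolutions use stride 1 and no padding; pooling uses stride = pool size
with floor division — any padding would break these shapes.

The runtime network is implemented directly in NumPy (im2col convolutions
with hand-derived backward passes), which keeps training fully deterministic
under a seed and exposes the exact feature-map gradients Grad-CAM needs.
Training operates on logits with a softmax-cross-entropy loss; the softmax is
applied at inference, which is mathematically identical to training through
an explicit softmax layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# declarative architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Layer:
    kind: str
    out_channels: int = 0
    kernel: int = 0
    stride: int = 1
    padding: int = 0
    pool_size: int = 0
    p: float = 0.0
    out_features: int = 0

    @property
    def name(self) -> str:
        if self.kind == "conv":
            return f"conv({self.out_channels}, k={self.kernel})"
        if self.kind == "maxpool":
            return f"maxpool({self.pool_size})"
        if self.kind == "dropout":
            return f"dropout({self.p})"
        if self.kind == "linear":
            return f"linear({self.out_features})"
        return self.kind


def conv(out_channels: int, kernel: int, stride: int = 1, padding: int = 0) -> Layer:
    return Layer("conv", out_channels=out_channels, kernel=kernel,
                 stride=stride, padding=padding)


def relu() -> Layer:
    return Layer("relu")


def maxpool(size: int) -> Layer:
    return Layer("maxpool", pool_size=size)


def dropout(p: float) -> Layer:
    return Layer("dropout", p=p)


def flatten() -> Layer:
    return Layer("flatten")


def linear(out_features: int) -> Layer:
    return Layer("linear", out_features=out_features)


def softmax() -> Layer:
    return Layer("softmax")


@dataclass
class ArchitectureSpec:
    """Ordered layer descriptors plus the number of output classes."""

    layers: tuple[Layer, ...]
    n_classes: int

    def validate(self) -> None:
        kinds = [l.kind for l in self.layers]
        if kinds.count("conv") != 2:
            raise ValueError("architecture must contain exactly 2 convolutional layers")
        if kinds.count("linear") != 3:
            raise ValueError("architecture must contain exactly 3 linear layers")
        last_linear = [l for l in self.layers if l.kind == "linear"][-1]
        if last_linear.out_features != self.n_classes:
            raise ValueError("final linear width must equal n_classes")
        for l in self.layers:
            if l.kind == "dropout" and abs(l.p - 0.20) > 1e-12:
                raise ValueError("dropout probability is fixed at 0.20")

    def to_json(self) -> str:
        return json.dumps({"n_classes": self.n_classes,
                           "layers": [vars(l) for l in self.layers]})

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        obj = json.loads(text)
        return cls(layers=tuple(Layer(**d) for d in obj["layers"]),
                   n_classes=obj["n_classes"])


def _build(n_classes: int, hidden: tuple[int, int] = (32, 16),
           pool_before_dropout: bool = False) -> ArchitectureSpec:
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 (treatment) or 3 (condition)")
    block1 = [conv(8, 16), relu()]
    # default order: dropout feeds the max pool ("max pooling applied to a
    # dropout layer"); pooling over dropped maps also injects far less
    # gradient noise than dropping the pooled maps
    block1 += [maxpool(5), dropout(0.20)] if pool_before_dropout else [dropout(0.20), maxpool(5)]
    layers = tuple(block1 + [
        conv(16, 5), relu(), maxpool(5), flatten(),
        linear(hidden[0]), relu(), linear(hidden[1]), relu(),
        linear(n_classes), softmax(),
    ])
    spec = ArchitectureSpec(layers=layers, n_classes=n_classes)
    spec.validate()
    return spec


def build_treatment_model(hidden: tuple[int, int] = (32, 16)) -> ArchitectureSpec:
    """Binary classifier: CBD (positive, class 1) vs control (negative, class 0)."""
    return _build(2, hidden)


def build_condition_model(hidden: tuple[int, int] = (32, 16)) -> ArchitectureSpec:
    """Ternary classifier over the challenge conditions; same architecture
    as the treatment model except the final linear width (3)."""
    return _build(3, hidden)


# ---------------------------------------------------------------------------
# shape calculus
# ---------------------------------------------------------------------------


@dataclass
class ShapeTrace:
    """Per-layer output shapes: (layer name, shape tuple)."""

    entries: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    def shape_after(self, layer_name: str) -> tuple[int, ...]:
        for name, shape in self.entries:
            if name == layer_name:
                return shape
        raise KeyError(layer_name)


def trace_shapes(spec: ArchitectureSpec,
                 input_shape: tuple[int, int, int] = (1, 256, 256)) -> ShapeTrace:
    """Exact conv/pool arithmetic through the spec.

    Convolutions: out = (in + 2*padding - kernel) // stride + 1 per spatial
    dimension; pooling: floor division by the pool size.  Raises on any layer
    that would produce a nonpositive spatial size.
    """
    trace = ShapeTrace([("input", tuple(input_shape))])
    shape = tuple(input_shape)
    for layer in spec.layers:
        if layer.kind == "conv":
            c, h, w = shape
            oh = (h + 2 * layer.padding - layer.kernel) // layer.stride + 1
            ow = (w + 2 * layer.padding - layer.kernel) // layer.stride + 1
            if oh <= 0 or ow <= 0:
                raise ValueError(f"{layer.name} would produce a {oh}x{ow} map "
                                 f"from input {h}x{w}")
            shape = (layer.out_channels, oh, ow)
        elif layer.kind == "maxpool":
            c, h, w = shape
            oh, ow = h // layer.pool_size, w // layer.pool_size
            if oh <= 0 or ow <= 0:
                raise ValueError(f"{layer.name} would produce a {oh}x{ow} map "
                                 f"from input {h}x{w}")
            shape = (c, oh, ow)
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind == "linear":
            if len(shape) != 1:
                raise ValueError("linear layer requires a flattened input")
            shape = (layer.out_features,)
        elif layer.kind in ("relu", "dropout", "softmax"):
            pass
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
        trace.entries.append((layer.name, shape))
    return trace


def count_parameters(spec: ArchitectureSpec,
                     input_shape: tuple[int, int, int] = (1, 256, 256)) -> int:
    """Total weight + bias count of the network the spec describes."""
    if not spec.layers:
        return 0
    total = 0
    shape = tuple(input_shape)
    for layer in spec.layers:
        if layer.kind == "conv":
            in_c = shape[0]
            total += layer.out_channels * in_c * layer.kernel**2 + layer.out_channels
        elif layer.kind == "linear":
            in_f = int(np.prod(shape))
            total += layer.out_features * in_f + layer.out_features
        shape = _single(layer, shape)
    return total


def _single(layer: Layer, shape):
    if layer.kind == "conv":
        c, h, w = shape
        return (layer.out_channels,
                (h + 2 * layer.padding - layer.kernel) // layer.stride + 1,
                (w + 2 * layer.padding - layer.kernel) // layer.stride + 1)
    if layer.kind == "maxpool":
        c, h, w = shape
        return (c, h // layer.pool_size, w // layer.pool_size)
    if layer.kind == "flatten":
        return (int(np.prod(shape)),)
    if layer.kind == "linear":
        return (layer.out_features,)
    return shape


# ---------------------------------------------------------------------------
# NumPy runtime
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho*Wo, C*k*k) patch matrix for a valid convolution."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    b, c, ho, wo = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)


class _Conv:
    """Valid cross-correlation, stride 1.

    Two equivalent execution paths: im2col + matmul for small feature maps,
    and an FFT path for large ones.  The FFT path computes circular
    correlations on the full frame; because the kernel-padded spectra are
    zero outside the valid region, the circular result equals the exact valid
    correlation (and the zero-padded full convolution for the input
    gradient), so both paths agree to floating-point roundoff.
    """

    CHUNK = 8           # images per im2col block, bounds memory
    FFT_MIN_PIXELS = 96 * 96  # switch to the FFT path above this map size

    def __init__(self, in_c: int, out_c: int, k: int, rng: np.random.Generator,
                 needs_input_grad: bool = True):
        scale = np.sqrt(2.0 / (in_c * k * k))  # He initialization (ReLU network)
        self.W = rng.normal(0.0, scale, (out_c, in_c, k, k)).astype(np.float32)
        self.b = np.zeros(out_c, dtype=np.float32)
        self.k, self.in_c, self.out_c = k, in_c, out_c
        self.needs_input_grad = needs_input_grad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._fx = None  # cached input spectrum (FFT path)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _use_fft(self, h: int, w: int) -> bool:
        return h * w >= self.FFT_MIN_PIXELS

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        b, c, h, w = x.shape
        ho, wo = h - self.k + 1, w - self.k + 1
        if self._use_fft(h, w):
            from scipy import fft as sfft

            self._fx = sfft.rfft2(x, axes=(2, 3))
            wpad = np.zeros((self.out_c, self.in_c, h, w), dtype=np.float32)
            wpad[:, :, :self.k, :self.k] = self.W
            self._fw = sfft.rfft2(wpad, axes=(2, 3))
            spec = np.einsum("bchw,ochw->bohw", self._fx, np.conj(self._fw))
            full = sfft.irfft2(spec, s=(h, w), axes=(2, 3))
            return full[:, :, :ho, :wo] + self.b[None, :, None, None]
        self._fx = None
        wmat = self.W.reshape(self.out_c, -1).T  # (C*k*k, out_c)
        out = np.empty((b, self.out_c, ho, wo), dtype=np.float32)
        for lo in range(0, b, self.CHUNK):
            cols = _im2col(x[lo:lo + self.CHUNK], self.k)
            res = cols @ wmat + self.b
            out[lo:lo + self.CHUNK] = res.transpose(0, 2, 1).reshape(-1, self.out_c, ho, wo)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        x = self._x
        b, c, h, w = x.shape
        k = self.k
        self.db[...] = dout.sum(axis=(0, 2, 3))
        if self._fx is not None:
            from scipy import fft as sfft

            dpad = np.zeros((b, self.out_c, h, w), dtype=np.float32)
            dpad[:, :, :dout.shape[2], :dout.shape[3]] = dout
            fd = sfft.rfft2(dpad, axes=(2, 3))
            spec_w = np.einsum("bchw,bohw->ochw", self._fx, np.conj(fd))
            self.dW[...] = sfft.irfft2(spec_w, s=(h, w), axes=(2, 3))[:, :, :k, :k]
            if not self.needs_input_grad:
                return None
            spec_x = np.einsum("bohw,ochw->bchw", fd, self._fw)
            return sfft.irfft2(spec_x, s=(h, w), axes=(2, 3)).astype(np.float32)

        dwmat = np.zeros((self.in_c * k * k, self.out_c), dtype=np.float32)
        dcols_all = dout.reshape(b, self.out_c, -1).transpose(0, 2, 1)  # (B, P, out_c)
        for lo in range(0, b, self.CHUNK):
            cols = _im2col(x[lo:lo + self.CHUNK], k)  # recomputed: cheaper than caching
            dc = dcols_all[lo:lo + self.CHUNK]
            dwmat += cols.reshape(-1, cols.shape[-1]).T @ dc.reshape(-1, self.out_c)
        self.dW[...] = dwmat.T.reshape(self.W.shape)
        if not self.needs_input_grad:
            return None
        # dx = full correlation of dout with the flipped kernels
        pad = k - 1
        dpad = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        wflip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (in_c, out_c, k, k)
        wmat = np.ascontiguousarray(wflip.reshape(self.in_c, -1).T)  # (out_c*k*k, in_c)
        dx = np.empty_like(x)
        for lo in range(0, b, self.CHUNK):
            cols = _im2col(dpad[lo:lo + self.CHUNK], k)  # (chunk, H*W, out_c*k*k)
            dx[lo:lo + self.CHUNK] = (cols @ wmat).transpose(0, 2, 1).reshape(
                -1, self.in_c, h, w)
        return dx


class _ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _MaxPool:
    def __init__(self, size: int):
        self.s = size

    def params(self):
        return []

    def forward(self, x, train):
        s = self.s
        b, c, h, w = x.shape
        ho, wo = h // s, w // s
        self._in_shape = x.shape
        xt = x[:, :, :ho * s, :wo * s].reshape(b, c, ho, s, wo, s)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, s * s)
        self._arg = xt.argmax(axis=-1)
        return np.take_along_axis(xt, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        s = self.s
        b, c, h, w = self._in_shape
        ho, wo = h // s, w // s
        dxt = np.zeros((b, c, ho, wo, s * s), dtype=dout.dtype)
        np.put_along_axis(dxt, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, :ho * s, :wo * s] = dxt.reshape(b, c, ho, wo, s, s).transpose(
            0, 1, 2, 4, 3, 5).reshape(b, c, ho * s, wo * s)
        return dx


class _Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def params(self):
        return []

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an RNG")
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class _Flatten:
    def params(self):
        return []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Linear:
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_f)
        self.W = rng.normal(0.0, scale, (out_f, in_f)).astype(np.float32)
        self.b = np.zeros(out_f, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W


class _Identity:
    """Runtime stand-in for the softmax layer: the network carries logits;
    probabilities are produced by predict_proba at inference."""

    def params(self):
        return []

    def forward(self, x, train):
        return x

    def backward(self, dout):
        return dout


def image_to_input(img8: np.ndarray) -> np.ndarray:
    """Model input convention: 8-bit pixels map to zero-centered [-0.5, 0.5].

    Centering keeps the first convolution's activations balanced, which
    matters at the small update budgets the training recipe allows.
    """
    return (np.asarray(img8, dtype=np.float32) / 255.0) - 0.5


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNClassifier:
    """A runnable network built from an :class:`ArchitectureSpec`.

    Weight initialization is seeded; forward/backward are pure NumPy, so the
    whole training computation is bit-deterministic for a fixed seed.
    """

    def __init__(self, spec: ArchitectureSpec,
                 input_shape: tuple[int, int, int] = (1, 256, 256), seed: int = 0):
        spec.validate()
        self.spec = spec
        self.input_shape = tuple(input_shape)
        trace = trace_shapes(spec, input_shape)
        rng = np.random.default_rng(seed)
        self.layers = []
        shape = self.input_shape
        first_conv = True
        for layer, (name, out_shape) in zip(spec.layers, trace.entries[1:]):
            if layer.kind == "conv":
                if layer.stride != 1 or layer.padding != 0:
                    raise NotImplementedError("runtime supports stride-1, zero-padding "
                                              "convolutions (as the architecture requires)")
                self.layers.append(_Conv(shape[0], layer.out_channels, layer.kernel,
                                         rng, needs_input_grad=not first_conv))
                first_conv = False
            elif layer.kind == "relu":
                self.layers.append(_ReLU())
            elif layer.kind == "maxpool":
                self.layers.append(_MaxPool(layer.pool_size))
            elif layer.kind == "dropout":
                self.layers.append(_Dropout(layer.p))
            elif layer.kind == "flatten":
                self.layers.append(_Flatten())
            elif layer.kind == "linear":
                self.layers.append(_Linear(int(np.prod(shape)), layer.out_features, rng))
            elif layer.kind == "softmax":
                self.layers.append(_Identity())
            shape = out_shape

    # -- plumbing ----------------------------------------------------------

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for l in self.layers:
            if isinstance(l, _Dropout):
                l.rng = rng

    def parameters(self):
        for l in self.layers:
            for name, w, g in l.params():
                yield l, name, w, g

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for _, _, w, _ in self.parameters()]

    def set_weights(self, weights) -> None:
        for (_, _, w, _), new in zip(self.parameters(), weights):
            w[...] = new

    def calibrate_activations(self, x: np.ndarray) -> None:
        """Layer-sequential unit-variance (LSUV) initialization.

        Rescales each conv/linear layer's weights so its output has unit
        standard deviation on the calibration batch ``x``.  He-normal draws
        alone leave the logit scale at the mercy of the seed, and at small
        fixed step budgets a badly scaled start never recovers; LSUV makes
        every seed start from comparably scaled activations.  Deterministic
        given the weights and the batch.
        """
        act = np.ascontiguousarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(act, False)
            if isinstance(layer, (_Conv, _Linear)):
                s = float(out.std())
                if s > 0:
                    layer.W /= s
                    out = out / s
            act = out

    # -- computation -------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (B, C, H, W) float32 batch."""
        out = np.ascontiguousarray(x, dtype=np.float32)
        for l in self.layers:
            out = l.forward(out, train)
        return out

    def backward(self, dlogits: np.ndarray, upto: int = 0) -> np.ndarray | None:
        """Backpropagate from the logits; returns the gradient flowing into
        runtime layer index ``upto`` (i.e. w.r.t. that layer's output when
        called with upto = index + 1)."""
        grad = dlogits
        for i in range(len(self.layers) - 1, upto - 1, -1):
            grad = self.layers[i].backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        probs = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(x[lo:lo + batch_size], train=False)
            probs.append(softmax_probs(logits))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def activation_and_gradient(self, x: np.ndarray, target_class: int,
                                layer_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Feature map of runtime layer ``layer_index`` and the gradient of the
        target-class logit with respect to it (no dropout: evaluation mode)."""
        logits = self.forward(x, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        grad = self.backward(dlogits, upto=layer_index + 1)
        # re-run the truncated forward to recover the activation cheaply
        act = np.ascontiguousarray(x, dtype=np.float32)
        for l in self.layers[:layer_index + 1]:
            act = l.forward(act, False)
        return act, grad


def save_model(model: CNNClassifier, path: str) -> None:
    """Checkpoint: weights as .npz with the architecture JSON alongside."""
    arrays = {f"w{i}": w for i, (_, _, w, _) in enumerate(model.parameters())}
    np.savez(path, spec=model.spec.to_json(),
             input_shape=np.array(model.input_shape), **arrays)


def load_model(path: str) -> CNNClassifier:
    data = np.load(path, allow_pickle=False)
    spec = ArchitectureSpec.from_json(str(data["spec"]))
    model = CNNClassifier(spec, input_shape=tuple(int(v) for v in data["input_shape"]))
    weights = [data[f"w{i}"] for i in range(sum(1 for _ in model.parameters()))]
    model.set_weights(weights)
    return model
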