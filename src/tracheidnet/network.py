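"""The dual-branch sparse-attention fully-convolutional classifier.

Two branches process the two input modalities:

* ``f(x)`` — a small perceptron on the optimized feature vector (sigmoid
  on the input layer, ELU on hidden layers);
* ``g(x)`` — a strided convolution stack on the gray-scale image whose
  final feature map is flattened to spatial tokens and passed through one
  sparse self-attention block (residual).

The fusion ``t(x)`` concatenates both branch outputs and shuffles them
with a fixed permutation drawn once from ``fusion_seed``; the head ``F``
is a stack of 1x1 convolutions (no dense layer) ending in a 5-way softmax
over the strength grades.  An optional parallel 1x1-conv regression head
predicts the strength itself, which can then be graded by thresholding.

Everything is plain NumPy with hand-written backward passes, which keeps
the model dependency-free, deterministic and inspectable at desk scale.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from tracheidnet.attention import build_pattern

# ---------------------------------------------------------------------------
# activations and loss (stateless functional forms)


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic function 1 / (1 + exp(-x)), numerically stable both tails."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def elu(x: np.ndarray | float, alpha: float = 1.0) -> np.ndarray | float:
    """Exponential linear unit: x for x >= 0, alpha*(e^x - 1) below."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, x, alpha * (np.expm1(np.minimum(x, 0.0))))
    return out if out.ndim else float(out)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax along ``axis``."""
    x = np.asarray(x, dtype=float)
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(pred: np.ndarray, labels: np.ndarray, n_classes: int) -> float:
    """Mean negative log-likelihood of integer ``labels`` under ``pred``.

    ``pred`` holds per-row probabilities (clamped at 1e-12); ``labels``
    are class indices 0..n_classes-1.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels)
    if pred.ndim != 2 or pred.shape[1] != n_classes:
        raise ValueError(
            f"predictions of shape {pred.shape} do not match {n_classes} classes"
        )
    if pred.shape[0] != labels.shape[0]:
        raise ValueError("prediction/label batch sizes differ")
    p = np.clip(pred[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


# ---------------------------------------------------------------------------
# layers with manual backward passes


class _Layer:
    """Minimal layer protocol: forward caches, backward returns d(input)."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Conv1x1(_Layer):
    """1x1 convolution over a channel vector (the FCN classifier block).

    Acting on a feature map collapsed to a single spatial position this is
    ``y = W x + b`` — a convolution with kernel size 1, not a dense layer
    attached to a flattened image.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.w = rng.normal(0.0, scale, size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0] += dout.T @ self._x
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.w


class Sigmoid(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class ELU(_Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._y = elu(x, self.alpha)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * np.where(self._x >= 0, 1.0, self._y + self.alpha)


class Conv2d(_Layer):
    """3x3 convolution, stride 2, zero padding 1, via im2col."""

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator,
                 ksize: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.in_c, self.out_c = in_c, out_c
        fan_in = in_c * ksize * ksize
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_c, fan_in))
        self.b = np.zeros(out_c)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _geometry(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.ksize, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        ho, wo = self._geometry(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]        # (b, c, ho, wo, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.T + self.b                   # (b, ho*wo, out_c)
        return out.transpose(0, 2, 1).reshape(b, self.out_c, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._xshape
        k, s, p = self.ksize, self.stride, self.pad
        ho, wo = self._geometry(h, w)
        d2 = dout.reshape(b, self.out_c, ho * wo).transpose(0, 2, 1)
        self.grads[0] += np.einsum("bno,bni->oi", d2, self._cols)
        self.grads[1] += d2.sum(axis=(0, 1))
        dcols = d2 @ self.w                              # (b, ho*wo, c*k*k)
        dcols = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[..., i, j]
        return dxp[:, :, p:p + h, p:p + w]


class AttentionBlock(_Layer):
    """Residual masked self-attention over spatial tokens.

    Tokens (B, n, c) are queries/keys/values under a fixed connectivity
    mask; the post-attention matrix Wp maps back to token width and the
    result is added to the input (residual), so a zero-weight block is an
    identity — convenient for ablations.
    """

    def __init__(self, n_tokens: int, dim: int, family: str, k: int | None,
                 rng: np.random.Generator):
        super().__init__()
        self.pattern = build_pattern(family, n_tokens, k)
        self.mask = self.pattern.mask()
        self.d = dim
        scale = 1.0 / np.sqrt(dim)
        self.wq = rng.normal(0.0, scale, size=(dim, dim))
        self.wk = rng.normal(0.0, scale, size=(dim, dim))
        self.wv = rng.normal(0.0, scale, size=(dim, dim))
        self.wp = rng.normal(0.0, scale, size=(dim, dim))
        self.params = [self.wq, self.wk, self.wv, self.wp]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = x @ self.wq.T
        k = x @ self.wk.T
        v = x @ self.wv.T
        s = q @ k.transpose(0, 2, 1) / np.sqrt(self.d)
        s = np.where(self.mask, s, -np.inf)
        a = softmax(s, axis=-1) * self.mask
        a = a / a.sum(axis=-1, keepdims=True)
        o = a @ v
        self._x, self._q, self._k, self._v, self._a, self._o = x, q, k, v, a, o
        return x + o @ self.wp.T

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, q, k, v, a, o = self._x, self._q, self._k, self._v, self._a, self._o
        do = dout @ self.wp
        self.grads[3] += np.einsum("bnd,bne->de", dout, o)
        da = do @ v.transpose(0, 2, 1)
        dv = a.transpose(0, 2, 1) @ do
        ds = a * (da - (a * da).sum(axis=-1, keepdims=True))
        ds = ds / np.sqrt(self.d)
        dq = ds @ k
        dk = ds.transpose(0, 2, 1) @ q
        self.grads[0] += np.einsum("bnd,bnc->dc", dq, x)
        self.grads[1] += np.einsum("bnd,bnc->dc", dk, x)
        self.grads[2] += np.einsum("bnd,bnc->dc", dv, x)
        dx = dq @ self.wq + dk @ self.wk + dv @ self.wv
        return dout + dx


# ---------------------------------------------------------------------------
# model


@dataclass(frozen=True)
class AttentionConfig:
    """Attention placement inside the image branch."""

    family: str = "sparse"      # dense | local | atrous | sparse | none
    k: int = 4
    n_h: int = 1                # heads (1 = single product)


@dataclass(frozen=True)
class DualFCNConfig:
    """Architecture of the dual-branch classifier."""

    feature_dim: int = 5
    image_size: int = 32
    f_hidden: tuple[int, ...] = (32, 32)
    g_channels: tuple[int, ...] = (8, 16)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    head: tuple[int, ...] = (64, 5)
    fusion_seed: int = 0
    elu_alpha: float = 1.0
    regression_head: bool = False
    n_classes: int = 5
    use_image_branch: bool = True
    use_feature_branch: bool = True

    def __post_init__(self) -> None:
        if self.head[-1] != self.n_classes:
            raise ValueError("head must end in one channel per grade")
        if not (self.use_image_branch or self.use_feature_branch):
            raise ValueError("at least one branch must be enabled")


class DualFCN:
    """The dual-branch model with one sparse-attention block.

    ``init_seed`` fixes the weight initialization; ``config.fusion_seed``
    fixes the fusion permutation.  Forward/backward are deterministic
    given both.
    """

    def __init__(self, config: DualFCNConfig, init_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(init_seed)
        a = config.elu_alpha
        # feature branch f: sigmoid input layer, ELU hidden layers
        self.f_layers: list[_Layer] = []
        if config.use_feature_branch:
            widths = [config.feature_dim, *config.f_hidden]
            for li in range(len(widths) - 1):
                self.f_layers.append(Conv1x1(widths[li], widths[li + 1], rng))
                self.f_layers.append(Sigmoid() if li == 0 else ELU(a))
        # image branch g: strided conv stack + attention over tokens
        self.g_layers: list[_Layer] = []
        side = config.image_size
        if config.use_image_branch:
            in_c = 1
            for out_c in config.g_channels:
                self.g_layers.append(Conv2d(in_c, out_c, rng))
                self.g_layers.append(ELU(a))
                in_c = out_c
                side = (side + 2 - 3) // 2 + 1
            self.tokens = side * side
            self.token_dim = in_c
            if config.attention.family != "none":
                self.g_layers.append(AttentionBlock(
                    self.tokens, in_c, config.attention.family,
                    None if config.attention.family == "dense" else config.attention.k,
                    rng,
                ))
        # fusion permutation
        f_out = config.f_hidden[-1] if config.use_feature_branch else 0
        g_out = self.tokens * self.token_dim if config.use_image_branch else 0
        fused = f_out + g_out
        self.perm = np.random.default_rng(config.fusion_seed).permutation(fused)
        self.inv_perm = np.argsort(self.perm)
        # head F: 1x1 conv stack ending in n_classes
        self.head_layers: list[_Layer] = []
        widths = [fused, *config.head]
        for li in range(len(widths) - 2):
            self.head_layers.append(Conv1x1(widths[li], widths[li + 1], rng))
            self.head_layers.append(ELU(a))
        self.head_layers.append(Conv1x1(widths[-2], widths[-1], rng))
        # optional regression head off the fused vector
        self.reg_layers: list[_Layer] = []
        if config.regression_head:
            self.reg_layers = [Conv1x1(fused, widths[-2], rng), ELU(a),
                               Conv1x1(widths[-2], 1, rng)]

    # -- plumbing -----------------------------------------------------------

    @property
    def layers(self) -> list[_Layer]:
        return [*self.f_layers, *self.g_layers, *self.head_layers, *self.reg_layers]

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters)

    # -- forward / backward -------------------------------------------------

    def forward(
        self, features: np.ndarray, images: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Probabilities (B, 5) and, in regression mode, strengths (B,)."""
        cfg = self.config
        batch = features.shape[0] if cfg.use_feature_branch else images.shape[0]
        parts = []
        if cfg.use_feature_branch:
            if features.shape[1] != cfg.feature_dim:
                raise ValueError(
                    f"feature branch expects {cfg.feature_dim} features, "
                    f"got {features.shape[1]}"
                )
            h = features
            for layer in self.f_layers:
                h = layer.forward(h)
            parts.append(h)
        if cfg.use_image_branch:
            if images.shape[-1] != cfg.image_size:
                raise ValueError(
                    f"image branch expects {cfg.image_size} px input, "
                    f"got {images.shape[-1]}"
                )
            z = images.reshape(batch, 1, cfg.image_size, cfg.image_size)
            for layer in self.g_layers:
                if isinstance(layer, AttentionBlock):
                    z = z.reshape(batch, self.token_dim, self.tokens)
                    z = z.transpose(0, 2, 1)
                    z = layer.forward(z)
                    z = z.transpose(0, 2, 1)
                else:
                    z = layer.forward(z)
            parts.append(z.reshape(batch, -1))
        fused = np.concatenate(parts, axis=1)[:, self.perm]
        self._fused_parts = [p.shape[1] for p in parts]
        h = fused
        for layer in self.head_layers:
            h = layer.forward(h)
        probs = softmax(h, axis=1)
        self._probs = probs
        sigma = None
        if cfg.regression_head:
            r = fused
            for layer in self.reg_layers:
                r = layer.forward(r)
            sigma = r[:, 0]
            self._sigma = sigma
        return probs, sigma

    def backward(
        self,
        labels: np.ndarray,
        sigma_true: np.ndarray | None = None,
        reg_weight: float = 1.0,
    ) -> None:
        """Accumulate gradients of CE (+ optional MSE) after a forward."""
        cfg = self.config
        probs = self._probs
        batch = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(batch), labels] -= 1.0
        dlogits /= batch
        d = dlogits
        for layer in reversed(self.head_layers):
            d = layer.backward(d)
        dfused = d
        if cfg.regression_head and sigma_true is not None:
            dr = (2.0 * reg_weight / batch) * (self._sigma - sigma_true)
            d = dr[:, None]
            for layer in reversed(self.reg_layers):
                d = layer.backward(d)
            dfused = dfused + d
        dcat = dfused[:, self.inv_perm]
        off = 0
        dparts = []
        for width in self._fused_parts:
            dparts.append(dcat[:, off:off + width])
            off += width
        idx = 0
        if cfg.use_feature_branch:
            d = dparts[idx]
            idx += 1
            for layer in reversed(self.f_layers):
                d = layer.backward(d)
        if cfg.use_image_branch:
            d = dparts[idx]
            side = int(np.sqrt(self.tokens))
            d = d.reshape(batch, self.token_dim, side, side)
            for layer in reversed(self.g_layers):
                if isinstance(layer, AttentionBlock):
                    dz = d.reshape(batch, self.token_dim, self.tokens)
                    dz = dz.transpose(0, 2, 1)
                    dz = layer.backward(dz)
                    d = dz.transpose(0, 2, 1).reshape(
                        batch, self.token_dim, side, side)
                else:
                    d = layer.backward(d)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: params + config + fusion permutation."""
        cfg = asdict(self.config)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters)}
        np.savez(path, config=json.dumps(cfg), perm=self.perm, **arrays)

    @classmethod
    def load(cls, path) -> "DualFCN":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["config"]))
        cfg["attention"] = AttentionConfig(**cfg["attention"])
        for key in ("f_hidden", "g_channels", "head"):
            cfg[key] = tuple(cfg[key])
        model = cls(DualFCNConfig(**cfg))
        model.perm = data["perm"]
        model.inv_perm = np.argsort(model.perm)
        for i, p in enumerate(model.parameters):
            p[...] = data[f"p{i}"]
        return model


def checkpoint_roundtrip(model: DualFCN) -> bytes:
    """Serialize a model to bytes (in-memory checkpoint)."""
    buf = io.BytesIO()
    model.save(buf)
    return buf.getvalue()
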