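"""The five-layer 1-D convolutional lifetime network, with hand-rolled autodiff.

Architecture: five convolution blocks operating on a length-300 normalised
histogram.  The first two blocks use large kernels and strides to condense
the decay into a short feature sequence; the remaining blocks are pointwise
(kernel 1).  Every block is convolution + batch-normalisation + ReLU except
the head, which global-average-pools the positions and applies a linear map
to a single lifetime in ns.  The three middle blocks can run with quantized
weights and input activations; quantizer gradients follow the
straight-through estimator (identity inside the clamp range).

The forward/backward passes are written directly in NumPy (im2col + BLAS
matmuls), which keeps inference and training dependency-free and makes the
quantized arithmetic explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .quantize import FULL_PRECISION, quantize_activations, quantize_weights

__all__ = ["QuantScheme", "ConvBlockSpec", "NetworkSpec", "QCNN", "default_network_spec"]

_DTYPE = np.float32


@dataclass(frozen=True)
class QuantScheme:
    """Bit widths for quantized blocks: weights ``w_bits``, activations ``a_bits``.

    Either may be the string ``"full"`` for full precision.  Defaults are the
    optimal 1-bit weights / 4-bit activations configuration.
    """

    w_bits: int | str = 1
    a_bits: int | str = 4

    def __post_init__(self) -> None:
        for name, bits in (("w_bits", self.w_bits), ("a_bits", self.a_bits)):
            if bits != FULL_PRECISION and (not isinstance(bits, int) or bits < 1):
                raise ValueError(f"{name} must be an integer >= 1 or 'full', got {bits!r}")

    @property
    def is_full(self) -> bool:
        return self.w_bits == FULL_PRECISION and self.a_bits == FULL_PRECISION


@dataclass(frozen=True)
class ConvBlockSpec:
    filters: int
    kernel_size: int
    stride: int = 1
    quantized: bool = False


@dataclass(frozen=True)
class NetworkSpec:
    """Layer hyperparameters of the five-block network."""

    blocks: tuple[ConvBlockSpec, ...] = field(
        default_factory=lambda: (
            ConvBlockSpec(16, 25, 4, quantized=False),
            ConvBlockSpec(32, 20, 4, quantized=True),
            ConvBlockSpec(64, 1, 1, quantized=True),
            ConvBlockSpec(32, 1, 1, quantized=True),
            ConvBlockSpec(1, 1, 1, quantized=False),  # scalar head
        )
    )
    input_bins: int = 300
    head_style: str = "gap"  # "gap": pool positions first; "flatten": linear over all

    def __post_init__(self) -> None:
        if len(self.blocks) != 5:
            raise ValueError("the network has exactly five convolution blocks")
        for b in self.blocks[2:]:
            if b.kernel_size != 1:
                raise ValueError("blocks 3-5 must be pointwise (kernel_size 1)")
        if self.blocks[0].quantized or self.blocks[-1].quantized:
            raise ValueError("first and last blocks stay full precision")
        if self.blocks[-1].filters != 1:
            raise ValueError("the head must produce a single scalar")


def default_network_spec() -> NetworkSpec:
    return NetworkSpec()


class _Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class _ConvBN:
    """Conv1d (no bias) + batch norm + optional ReLU, with manual backward.

    When ``w_bits``/``a_bits`` are set, the convolution runs on quantized
    weights and quantized (clamped) input activations; backward applies the
    straight-through estimator: identity through the quantizers, zero outside
    the activation clamp range.
    """

    def __init__(
        self,
        c_in: int,
        spec: ConvBlockSpec,
        rng: np.random.Generator,
        w_bits: int | str,
        a_bits: int | str,
        relu: bool = True,
        eps: float = 1e-5,
        momentum: float = 0.1,
        gamma_init: float = 1.0,
    ):
        self.spec = spec
        fan_in = c_in * spec.kernel_size
        self.weight = _Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (spec.filters, c_in, spec.kernel_size)))
        self.gamma = _Param(np.full(spec.filters, gamma_init))
        self.beta = _Param(np.zeros(spec.filters))
        self.w_bits = w_bits if spec.quantized else FULL_PRECISION
        self.a_bits = a_bits if spec.quantized else FULL_PRECISION
        self.relu = relu
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(spec.filters, dtype=_DTYPE)
        self.running_var = np.ones(spec.filters, dtype=_DTYPE)
        self._cache: dict = {}

    @property
    def params(self) -> list[_Param]:
        return [self.weight, self.gamma, self.beta]

    def effective_weight(self) -> np.ndarray:
        return quantize_weights(self.weight.value, self.w_bits)

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s = self.spec.kernel_size, self.spec.stride
        if self.a_bits != FULL_PRECISION:
            a_mask = (x >= 0.0) & (x <= 1.0)  # STE pass-through region
            x_q = quantize_activations(x, self.a_bits)
        else:
            a_mask, x_q = None, x
        w_q = self.effective_weight()

        b, c_in, l_in = x_q.shape
        l_out = (l_in - k) // s + 1
        if k == 1 and s == 1:
            cols = x_q.transpose(0, 2, 1).reshape(b * l_in, c_in)
        else:
            patches = sliding_window_view(x_q, k, axis=2)[:, :, ::s]  # (b, c_in, l_out, k)
            cols = patches.transpose(0, 2, 1, 3).reshape(b * l_out, c_in * k)
        wmat = w_q.reshape(self.spec.filters, c_in * k)
        y = (cols @ wmat.T).reshape(b, l_out, self.spec.filters).transpose(0, 2, 1)

        # batch normalisation over (batch, position) per channel
        if train:
            mean = y.mean(axis=(0, 2))
            var = y.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (y - mean[:, None]) * inv_std[:, None]
        out = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        if self.relu:
            relu_mask = out > 0
            out = out * relu_mask
        else:
            relu_mask = None

        if train:
            self._cache = dict(
                cols=cols, wmat=wmat, xhat=xhat, inv_std=inv_std,
                relu_mask=relu_mask, a_mask=a_mask, in_shape=x.shape, l_out=l_out,
            )
        return out.astype(_DTYPE)

    # -- backward --------------------------------------------------------
    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self._cache
        k, s = self.spec.kernel_size, self.spec.stride
        b, c_in, l_in = c["in_shape"]
        l_out = c["l_out"]
        if c["relu_mask"] is not None:
            dout = dout * c["relu_mask"]

        xhat, inv_std = c["xhat"], c["inv_std"]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))

        n = dout.shape[0] * dout.shape[2]
        dxhat = dout * self.gamma.value[:, None]
        dy = (inv_std[:, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2))[:, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2))[:, None]
        )

        dymat = dy.transpose(0, 2, 1).reshape(b * l_out, self.spec.filters)
        # STE: gradient lands on the latent full-precision weights directly
        self.weight.grad += (dymat.T @ c["cols"]).reshape(self.weight.value.shape)
        dcols = dymat @ c["wmat"]

        if k == 1 and s == 1:
            dx = dcols.reshape(b, l_in, c_in).transpose(0, 2, 1)
        else:
            dpatch = dcols.reshape(b, l_out, c_in, k).transpose(0, 2, 1, 3)
            dx = np.zeros((b, c_in, l_in), dtype=_DTYPE)
            span = s * (l_out - 1) + 1
            for kk in range(k):  # strided views are disjoint within one offset
                dx[:, :, kk : kk + span : s] += dpatch[:, :, :, kk]
        if c["a_mask"] is not None:
            dx = dx * c["a_mask"]
        self._cache = {}
        return dx


class _Head:
    """Linear map from the last block's features to one scalar lifetime (ns).

    ``style="flatten"`` applies the 1-filter pointwise map across every
    remaining position with per-position weights (a linear layer over the
    flattened feature map); ``style="gap"`` global-average-pools positions
    first.  Both are full precision.
    """

    def __init__(self, c_in: int, l_in: int, rng: np.random.Generator, style: str = "flatten"):
        if style not in ("flatten", "gap"):
            raise ValueError(f"unknown head style {style!r}")
        self.style = style
        n_feat = c_in * l_in if style == "flatten" else c_in
        self.weight = _Param(rng.normal(0.0, np.sqrt(1.0 / n_feat), (n_feat,)))
        self.bias = _Param(np.zeros(1))
        self._cache: dict = {}

    @property
    def params(self) -> list[_Param]:
        return [self.weight, self.bias]

    def _features(self, x: np.ndarray) -> np.ndarray:
        if self.style == "flatten":
            return x.reshape(x.shape[0], -1)
        return x.mean(axis=2)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        feat = self._features(x)
        out = feat @ self.weight.value + self.bias.value[0]
        if train:
            self._cache = dict(feat=feat, in_shape=x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self._cache
        b, c_in, l_in = c["in_shape"]
        self.weight.grad += dout @ c["feat"]
        self.bias.grad += dout.sum(keepdims=True)
        if self.style == "flatten":
            dx = (dout[:, None] * self.weight.value[None, :]).reshape(b, c_in, l_in)
        else:
            dx = np.broadcast_to(
                (dout[:, None] * self.weight.value[None, :])[:, :, None] / l_in,
                (b, c_in, l_in),
            )
        self._cache = {}
        return dx.astype(_DTYPE)


class QCNN:
    """The assembled network: four conv-BN-ReLU blocks and the scalar head.

    The declared fifth block (pointwise, 1 filter) is realised as the global
    average pool followed by a linear 1x1 map — the two orders commute for a
    linear head.
    """

    def __init__(
        self,
        spec: NetworkSpec | None = None,
        quant: QuantScheme | None = None,
        seed: int = 0,
        gamma_init: float = 1.0,
    ):
        self.spec = spec or NetworkSpec()
        self.quant = quant or QuantScheme()
        rng = np.random.default_rng(seed)
        self.blocks: list[_ConvBN] = []
        c_in, l_in = 1, self.spec.input_bins
        for bspec in self.spec.blocks[:-1]:
            self.blocks.append(
                _ConvBN(c_in, bspec, rng, self.quant.w_bits, self.quant.a_bits,
                        gamma_init=gamma_init)
            )
            c_in = bspec.filters
            l_in = (l_in - bspec.kernel_size) // bspec.stride + 1
        self.head = _Head(c_in, l_in, rng, style=self.spec.head_style)

    @property
    def params(self) -> list[_Param]:
        out: list[_Param] = []
        for blk in self.blocks:
            out.extend(blk.params)
        out.extend(self.head.params)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map ``(batch, input_bins)`` normalised histograms to lifetimes (ns)."""
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.spec.input_bins:
            raise ValueError(
                f"input length {x.shape[1]} != network input {self.spec.input_bins}"
            )
        h = x[:, None, :]
        for blk in self.blocks:
            h = blk.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dout: np.ndarray) -> None:
        dh = self.head.backward(dout)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    # -- checkpoint ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, blk in enumerate(self.blocks):
            state[f"block{i}.weight"] = blk.weight.value
            state[f"block{i}.gamma"] = blk.gamma.value
            state[f"block{i}.beta"] = blk.beta.value
            state[f"block{i}.running_mean"] = blk.running_mean
            state[f"block{i}.running_var"] = blk.running_var
        state["head.weight"] = self.head.weight.value
        state["head.bias"] = self.head.bias.value
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, blk in enumerate(self.blocks):
            blk.weight.value = np.asarray(state[f"block{i}.weight"], dtype=_DTYPE)
            blk.gamma.value = np.asarray(state[f"block{i}.gamma"], dtype=_DTYPE)
            blk.beta.value = np.asarray(state[f"block{i}.beta"], dtype=_DTYPE)
            blk.running_mean = np.asarray(state[f"block{i}.running_mean"], dtype=_DTYPE)
            blk.running_var = np.asarray(state[f"block{i}.running_var"], dtype=_DTYPE)
        self.head.weight.value = np.asarray(state["head.weight"], dtype=_DTYPE)
        self.head.bias.value = np.asarray(state["head.bias"], dtype=_DTYPE)
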