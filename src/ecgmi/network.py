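"""Compact 1-D residual network evaluated with plain numpy.

The feature vector enters as a one-channel sequence; a stem convolution,
max-pooling and one or more residual blocks (two conv->batch-norm->ReLU
stages with an identity or 1x1-projection shortcut) feed a global average
pool and a softmax linear classifier.  All weights, biases and
normalisation parameters live in one flat :class:`ParamVector`, which is
what the population optimizer searches — there is no gradient training
anywhere, so presets are deliberately small (``tiny`` under 1000
parameters, ``small`` under 20000).

Batch normalisation uses the statistics of the evaluation batch: with no
gradient loop there are no running averages to maintain, and the forward
pass stays deterministic for a fixed batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

BN_EPS = 1e-5


@dataclass
class ResBlockSpec:
    in_channels: int
    out_channels: int
    kernel: int = 3

    @property
    def needs_projection(self) -> bool:
        return self.in_channels != self.out_channels


@dataclass
class NetworkSpec:
    """Architecture description.

    ``bn_gain_offset`` shifts the stored batch-norm gain parameters:
    the effective gain is ``offset + stored value``, so a centred random
    parameter vector behaves like a conventionally initialised network
    (unit BN gain) instead of a mostly-dead one — important when weights
    are found by bounded population search rather than gradient descent.
    """

    input_len: int
    stem_channels: int = 2
    stem_kernel: int = 3
    pool_size: int = 2
    blocks: List[ResBlockSpec] = field(default_factory=lambda: [ResBlockSpec(2, 4)])
    n_classes: int = 2
    bn_gain_offset: float = 1.0
    preset: str = "custom"

    def __post_init__(self):
        if self.input_len < 1:
            raise ValueError("input_len must be >= 1")
        ch = self.stem_channels
        for b in self.blocks:
            if b.in_channels != ch:
                raise ValueError(
                    f"block expects {b.in_channels} input channels but receives {ch}"
                )
            ch = b.out_channels

    def param_layout(self) -> List[Tuple[str, tuple]]:
        """Ordered (name, shape) pairs of every trainable tensor."""
        layout: List[Tuple[str, tuple]] = [
            ("stem.w", (self.stem_channels, 1, self.stem_kernel)),
            ("stem.b", (self.stem_channels,)),
            ("stem.bn.gamma", (self.stem_channels,)),
            ("stem.bn.beta", (self.stem_channels,)),
        ]
        for i, blk in enumerate(self.blocks):
            p = f"block{i}"
            layout += [
                (f"{p}.conv1.w", (blk.out_channels, blk.in_channels, blk.kernel)),
                (f"{p}.conv1.b", (blk.out_channels,)),
                (f"{p}.bn1.gamma", (blk.out_channels,)),
                (f"{p}.bn1.beta", (blk.out_channels,)),
                (f"{p}.conv2.w", (blk.out_channels, blk.out_channels, blk.kernel)),
                (f"{p}.conv2.b", (blk.out_channels,)),
                (f"{p}.bn2.gamma", (blk.out_channels,)),
                (f"{p}.bn2.beta", (blk.out_channels,)),
            ]
            if blk.needs_projection:
                layout += [
                    (f"{p}.proj.w", (blk.out_channels, blk.in_channels, 1)),
                    (f"{p}.proj.b", (blk.out_channels,)),
                ]
        last_ch = self.blocks[-1].out_channels if self.blocks else self.stem_channels
        layout += [("fc.w", (self.n_classes, last_ch)), ("fc.b", (self.n_classes,))]
        return layout

    def n_params(self) -> int:
        return sum(int(np.prod(shape)) for _n, shape in self.param_layout())


def make_preset(name: str, input_len: int) -> NetworkSpec:
    """``tiny``: stem(2ch,k3) -> pool2 -> resblock 2->4 -> FC (~130 params,
    the default for population-search training budgets).
    ``base``: stem(4ch,k5) -> pool2 -> resblock 4->8 -> FC (~430 params).
    ``small``: stem(8ch,k7) -> pool2 -> resblocks 8->16 -> 16->16 -> FC."""
    if name == "tiny":
        return NetworkSpec(input_len=input_len, stem_channels=2, stem_kernel=3,
                           blocks=[ResBlockSpec(2, 4)], preset="tiny")
    if name == "base":
        return NetworkSpec(input_len=input_len, stem_channels=4, stem_kernel=5,
                           blocks=[ResBlockSpec(4, 8)], preset="base")
    if name == "small":
        return NetworkSpec(input_len=input_len, stem_channels=8, stem_kernel=7,
                           blocks=[ResBlockSpec(8, 16), ResBlockSpec(16, 16)],
                           preset="small")
    raise ValueError(f"unknown preset {name!r}; expected 'tiny', 'base' or 'small'")


@dataclass
class ParamVector:
    """Flat parameter array plus the name -> (offset, shape) map."""

    flat: np.ndarray
    layout: Dict[str, Tuple[int, tuple]]

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "ParamVector":
        layout, off = {}, 0
        for name, shape in spec.param_layout():
            size = int(np.prod(shape))
            layout[name] = (off, shape)
            off += size
        return cls(flat=np.zeros(off), layout=layout)

    @classmethod
    def from_flat(cls, spec: NetworkSpec, flat: np.ndarray) -> "ParamVector":
        pv = cls.zeros(spec)
        flat = np.asarray(flat, dtype=float).ravel()
        if flat.size != pv.flat.size:
            raise ValueError(f"parameter vector of length {flat.size}; spec needs {pv.flat.size}")
        pv.flat = flat.copy()
        return pv

    def get(self, name: str) -> np.ndarray:
        off, shape = self.layout[name]
        size = int(np.prod(shape))
        return self.flat[off : off + size].reshape(shape)

    def set(self, name: str, value: np.ndarray) -> None:
        off, shape = self.layout[name]
        value = np.asarray(value, dtype=float)
        if value.shape != tuple(shape):
            raise ValueError(f"{name}: expected shape {shape}, got {value.shape}")
        self.flat[off : off + value.size] = value.ravel()


# ---------------------------------------------------------------------------
# layer primitives

def conv1d(x: np.ndarray, kernel: np.ndarray, bias: float = 0.0, padding: str = "same") -> np.ndarray:
    """Single-channel 1-D cross-correlation, stride 1.

    ``same`` zero padding keeps the output length equal to the input.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(kernel, dtype=float)
    if x.ndim != 1 or k.ndim != 1:
        raise ValueError(f"conv1d expects 1-D input and kernel, got shapes {x.shape} and {k.shape}")
    if k.size > x.size and padding != "same":
        raise ValueError(f"kernel of {k.size} taps does not fit input of {x.size} samples")
    if padding == "same":
        left = (k.size - 1) // 2
        right = k.size - 1 - left
        xp = np.pad(x, (left, right))
        return np.correlate(xp, k, mode="valid") + bias
    if padding == "valid":
        return np.correlate(x, k, mode="valid") + bias
    raise ValueError(f"unknown padding {padding!r}")


def conv2d(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid-mode 2-D cross-correlation with an h x h kernel (kernel-level
    operation; the network itself operates on 1-D feature sequences)."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(kernel, dtype=float)
    h, w = k.shape
    if x.shape[0] < h or x.shape[1] < w:
        raise ValueError(f"kernel {k.shape} does not fit input {x.shape}")
    out = np.zeros((x.shape[0] - h + 1, x.shape[1] - w + 1))
    for u in range(h):
        for v in range(w):
            out += k[u, v] * x[u : u + out.shape[0], v : v + out.shape[1]]
    return out


def relu(u: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(u, dtype=float), 0.0)


def maxpool(x: np.ndarray, size: int) -> np.ndarray:
    """Non-overlapping max pooling along the last axis; a trailing partial
    window is kept."""
    if size < 1:
        raise ValueError(f"pool size must be >= 1, got {size}")
    x = np.asarray(x, dtype=float)
    n_full = x.shape[-1] // size
    pieces = []
    if n_full:
        pieces.append(x[..., : n_full * size].reshape(*x.shape[:-1], n_full, size).max(axis=-1))
    if x.shape[-1] % size:
        pieces.append(x[..., n_full * size :].max(axis=-1, keepdims=True))
    return np.concatenate(pieces, axis=-1)


def avgpool(x: np.ndarray, size: int | None = None) -> np.ndarray:
    """Non-overlapping average pooling; ``size=None`` pools globally."""
    x = np.asarray(x, dtype=float)
    if size is None:
        return x.mean(axis=-1)
    if size < 1:
        raise ValueError(f"pool size must be >= 1, got {size}")
    n_full = x.shape[-1] // size
    pieces = []
    if n_full:
        pieces.append(x[..., : n_full * size].reshape(*x.shape[:-1], n_full, size).mean(axis=-1))
    if x.shape[-1] % size:
        pieces.append(x[..., n_full * size :].mean(axis=-1, keepdims=True))
    return np.concatenate(pieces, axis=-1)


def batch_norm(batch: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = BN_EPS) -> np.ndarray:
    """Per-channel batch normalisation of a (batch, channels, length) map."""
    batch = np.asarray(batch, dtype=float)
    mu = batch.mean(axis=(0, 2), keepdims=True)
    var = batch.var(axis=(0, 2), keepdims=True)
    norm = (batch - mu) / np.sqrt(var + eps)
    return norm * np.asarray(gamma)[None, :, None] + np.asarray(beta)[None, :, None]


def _multi_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(batch, c_in, L) x (c_out, c_in, k) -> (batch, c_out, L), same padding."""
    batch, c_in, L = x.shape
    c_out, _c_in, k = w.shape
    if _c_in != c_in:
        raise ValueError(f"conv expects {_c_in} input channels, got {c_in}")
    left = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (left, k - 1 - left)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B, c_in, L, k)
    return np.einsum("bilk,oik->bol", windows, w) + b[None, :, None]


def residual_block(x: np.ndarray, params: ParamVector, prefix: str, spec: ResBlockSpec,
                   activation: bool = True, gain_offset: float = 0.0) -> np.ndarray:
    """Two conv->BN->ReLU stages plus shortcut: I = k(U) + [lambda_U] U."""
    h = _multi_conv(x, params.get(f"{prefix}.conv1.w"), params.get(f"{prefix}.conv1.b"))
    h = relu(batch_norm(h, gain_offset + params.get(f"{prefix}.bn1.gamma"),
                        params.get(f"{prefix}.bn1.beta")))
    h = _multi_conv(h, params.get(f"{prefix}.conv2.w"), params.get(f"{prefix}.conv2.b"))
    h = batch_norm(h, gain_offset + params.get(f"{prefix}.bn2.gamma"),
                   params.get(f"{prefix}.bn2.beta"))
    if spec.needs_projection:
        shortcut = _multi_conv(x, params.get(f"{prefix}.proj.w"), params.get(f"{prefix}.proj.b"))
    else:
        if x.shape[1] != h.shape[1]:
            raise ValueError(
                f"shortcut shape mismatch: {x.shape[1]} vs {h.shape[1]} channels and no projection"
            )
        shortcut = x
    out = h + shortcut
    return relu(out) if activation else out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(spec: NetworkSpec, params: ParamVector | np.ndarray, features: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of feature rows (batch, input_len)."""
    if not isinstance(params, ParamVector):
        params = ParamVector.from_flat(spec, params)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != spec.input_len:
        raise ValueError(f"features have length {X.shape[1]}; spec expects {spec.input_len}")
    x = X[:, None, :]  # one input channel
    h = _multi_conv(x, params.get("stem.w"), params.get("stem.b"))
    h = relu(batch_norm(h, spec.bn_gain_offset + params.get("stem.bn.gamma"),
                        params.get("stem.bn.beta")))
    h = maxpool(h, spec.pool_size)
    for i, blk in enumerate(spec.blocks):
        h = residual_block(h, params, f"block{i}", blk, gain_offset=spec.bn_gain_offset)
    pooled = avgpool(h)  # (batch, channels)
    logits = pooled @ params.get("fc.w").T + params.get("fc.b")
    return softmax(logits)


def save_params(spec: NetworkSpec, params: ParamVector, spec_path, weights_path) -> None:
    """Serialise the architecture as JSON and the flat weights as CSV."""
    import json

    spec_dict = {
        "input_len": spec.input_len, "stem_channels": spec.stem_channels,
        "stem_kernel": spec.stem_kernel, "pool_size": spec.pool_size,
        "blocks": [[b.in_channels, b.out_channels, b.kernel] for b in spec.blocks],
        "n_classes": spec.n_classes, "bn_gain_offset": spec.bn_gain_offset,
        "preset": spec.preset,
    }
    with open(spec_path, "w") as fh:
        json.dump(spec_dict, fh)
    np.savetxt(weights_path, params.flat, delimiter=",")


def load_params(spec_path, weights_path) -> tuple:
    import json

    with open(spec_path) as fh:
        d = json.load(fh)
    spec = NetworkSpec(
        input_len=d["input_len"], stem_channels=d["stem_channels"],
        stem_kernel=d["stem_kernel"], pool_size=d["pool_size"],
        blocks=[ResBlockSpec(*b) for b in d["blocks"]],
        n_classes=d["n_classes"], bn_gain_offset=d.get("bn_gain_offset", 1.0),
        preset=d.get("preset", "custom"),
    )
    flat = np.loadtxt(weights_path, delimiter=",")
    return spec, ParamVector.from_flat(spec, flat)
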