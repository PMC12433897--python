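"""Detection-network building blocks in plain NumPy.

Implements, as standalone inference-time operators:

* detail-enhanced convolution (DEConv): five parallel branches — vanilla,
  center-difference, horizontal-difference, vertical-difference and
  adaptive-difference convolution — whose kernels, by linearity, sum into a
  single equivalent kernel K_cvt, so inference needs one convolution where
  training used five (structural reparameterization);
* fine-grained channel attention (FCA): channel weights fused from a global
  (per-channel diagonal scaling) and a local (1-D cross-channel convolution)
  view of the pooled channel descriptor through their cross-correlation
  matrix and a learnable fusion factor theta;
* group normalization, the shared lightweight detection head (1x1 channel
  reduction, one DEConv+GN block and one cls/reg head pair shared across
  pyramid levels, a learnable per-level scale on the regression output), and
  integral ("distribution focal") box decoding.

Everything operates on N x C x H x W float arrays; convolutions use zero
padding that preserves spatial size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "conv2d",
    "transform_kernel",
    "KernelBank",
    "merge_kernels",
    "deconv_forward",
    "gap",
    "FCAParams",
    "ChannelWeights",
    "fca_weights",
    "fca_apply",
    "group_norm",
    "HeadParams",
    "DetectionOutput",
    "lsd_head_forward",
    "head_param_count",
    "dfl_decode",
    "nms",
    "save_head_weights",
    "load_head_weights",
    "silu",
]

DIFFERENCE_KINDS = ("vanilla", "center", "horizontal", "vertical", "adaptive")

# Adaptive-difference neighbour permutation for a 3x3 kernel (flattened
# row-major): each tap is differenced against its angular neighbour.
_AD_PERM_3X3 = np.array([3, 0, 1, 6, 4, 2, 7, 8, 5])


def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def conv2d(x: np.ndarray, w: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Same-padding 2-D cross-correlation: (N,Ci,H,W) x (Co,Ci,k,k) -> (N,Co,H,W)."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv2d expects a 4-D input and a 4-D kernel")
    if x.shape[1] != w.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, kernel expects {w.shape[1]}"
        )
    k = w.shape[2]
    if w.shape[3] != k or k % 2 == 0:
        raise ValueError("kernel must be square with odd side")
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    out = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float64)[None, :, None, None]
    return out


def transform_kernel(kind: str, w: np.ndarray) -> np.ndarray:
    """Equivalent vanilla-convolution kernel of a difference-convolution branch.

    The raw weights ``w`` (shape (..., k, k), k odd) parameterise the branch;
    the returned kernel produces, under ordinary convolution, exactly the
    branch's difference-form output:

    * ``vanilla``    — identity;
    * ``center``     — each tap unchanged, center tap reduced by the sum of
      all taps (responds to deviations from the center pixel);
    * ``horizontal`` / ``vertical`` — kernel minus its column-/row-mirrored
      copy (antisymmetric horizontal/vertical pairwise differences);
    * ``adaptive``   — kernel minus an angularly permuted copy (3x3 only),
      following the detail-enhanced-convolution lineage.
    """
    w = np.asarray(w, dtype=np.float64)
    k = w.shape[-1]
    if w.shape[-2] != k or k % 2 == 0:
        raise ValueError("weights must be (..., k, k) with odd k")
    if kind == "vanilla":
        return w.copy()
    if kind == "center":
        out = w.copy()
        out[..., k // 2, k // 2] -= w.sum(axis=(-2, -1))
        return out
    if kind == "horizontal":
        return w - w[..., :, ::-1]
    if kind == "vertical":
        return w - w[..., ::-1, :]
    if kind == "adaptive":
        if k != 3:
            raise ValueError("adaptive difference convolution is defined for 3x3 kernels")
        flat = w.reshape(*w.shape[:-2], 9)
        return (flat - flat[..., _AD_PERM_3X3]).reshape(w.shape)
    raise ValueError(f"unknown difference-convolution kind {kind!r}")


@dataclass
class KernelBank:
    """Raw weights of the five DEConv branches plus their merged kernel.

    ``weights`` maps each branch kind to a (Co, Ci, k, k) array of raw
    branch weights; ``merged`` holds the equivalent single kernel K_cvt
    after :func:`merge_kernels`.
    """

    weights: dict[str, np.ndarray]
    merged: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = set(DIFFERENCE_KINDS) - set(self.weights)
        if missing:
            raise ValueError(f"missing branch weights: {sorted(missing)}")
        shapes = {self.weights[k].shape for k in DIFFERENCE_KINDS}
        if len(shapes) != 1:
            raise ValueError(f"branch weight shapes differ: {shapes}")

    @classmethod
    def random(cls, seed: int, c_out: int, c_in: int, k: int = 3, scale: float = 0.1) -> "KernelBank":
        rng = np.random.default_rng(seed)
        return cls(
            weights={
                kind: scale * rng.standard_normal((c_out, c_in, k, k))
                for kind in DIFFERENCE_KINDS
            }
        )

    def transformed(self) -> dict[str, np.ndarray]:
        return {k: transform_kernel(k, v) for k, v in self.weights.items()}


def merge_kernels(bank: KernelBank) -> np.ndarray:
    """Sum the five transformed branch kernels into K_cvt (stored on the bank).

    Because convolution is linear, convolving with K_cvt equals summing the
    five branch outputs — the reparameterization that lets inference run a
    single convolution.
    """
    transformed = list(bank.transformed().values())
    merged = np.sum(transformed, axis=0)
    bank.merged = merged
    return merged


def deconv_forward(
    x: np.ndarray, bank: KernelBank, mode: str = "merged", bias: np.ndarray | None = None
) -> np.ndarray:
    """Detail-enhanced convolution: five parallel branches or one merged kernel.

    ``parallel`` sums the five branch convolutions; ``merged`` convolves once
    with K_cvt.  The two modes agree to floating-point precision.
    """
    if mode == "parallel":
        t = bank.transformed()
        out = np.sum([conv2d(x, t[kind]) for kind in DIFFERENCE_KINDS], axis=0)
        if bias is not None:
            out = out + np.asarray(bias)[None, :, None, None]
        return out
    if mode == "merged":
        merged = bank.merged if bank.merged is not None else merge_kernels(bank)
        return conv2d(x, merged, bias=bias)
    raise ValueError(f"mode must be 'parallel' or 'merged', got {mode!r}")


def gap(x: np.ndarray) -> np.ndarray:
    """Global average pooling: channel-wise spatial mean, (N,C,H,W) -> (N,C)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError("expected an N x C x H x W array")
    return x.mean(axis=(2, 3))


@dataclass
class FCAParams:
    """Parameters of the fine-grained channel attention.

    ``b``: width-k 1-D convolution weights capturing local cross-channel
    correlation (k odd, default 3, circular padding).  ``d``: per-channel
    diagonal weights scaling the global descriptor.  ``theta``: learnable
    fusion factor; sigma(theta) balances the global against the local branch.
    The cross-correlation matrix M is reduced to the two branch summaries by
    fixed row-/column-averaging.
    """

    b: np.ndarray
    d: np.ndarray
    theta: float = 0.0

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.float64)
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.b.ndim != 1 or self.b.size % 2 == 0:
            raise ValueError("b must be a 1-D array of odd length")
        if self.d.ndim != 1:
            raise ValueError("d must be 1-D (one weight per channel)")

    @classmethod
    def random(cls, seed: int, channels: int, k: int = 3) -> "FCAParams":
        rng = np.random.default_rng(seed)
        return cls(
            b=rng.standard_normal(k) / np.sqrt(k),
            d=1.0 + 0.1 * rng.standard_normal(channels),
            theta=float(rng.standard_normal()),
        )


@dataclass(frozen=True)
class ChannelWeights:
    """FCA channel weights W in (0,1) with the intermediate quantities."""

    w: np.ndarray       # (N, C) fused weights, strictly in (0, 1)
    U: np.ndarray       # (N, C) pooled descriptor
    Ulc: np.ndarray     # (N, C) local branch
    Ugc: np.ndarray     # (N, C) global branch
    M: np.ndarray       # (N, C, C) cross-correlation matrix
    Uwgc: np.ndarray    # (N, C) row-mean of M
    Uwlc: np.ndarray    # (N, C) column-mean of M


def fca_weights(x: np.ndarray, p: FCAParams) -> ChannelWeights:
    """Fine-grained channel attention weights for a feature map.

    U is the pooled descriptor; the local branch convolves U across the
    channel axis with the width-k kernel b (circular padding), the global
    branch scales U per channel by d; their outer product M couples the two
    views, is averaged along rows/columns, and the two summaries are fused
    through sigmoids with factor sigma(theta).
    """
    U = gap(x)
    c = U.shape[1]
    if p.d.size != c:
        raise ValueError(f"d has {p.d.size} weights but input has {c} channels")
    k = p.b.size
    idx = (np.arange(c)[:, None] + np.arange(k)[None, :] - k // 2) % c
    Ulc = (U[:, idx] * p.b[None, None, :]).sum(axis=-1)
    Ugc = U * p.d[None, :]
    M = Ugc[:, :, None] * Ulc[:, None, :]
    Uwgc = M.mean(axis=2)
    Uwlc = M.mean(axis=1)
    t = _sigmoid(p.theta)
    w = _sigmoid(t * _sigmoid(Uwgc) + (1.0 - t) * _sigmoid(Uwlc))
    return ChannelWeights(w=w, U=U, Ulc=Ulc, Ugc=Ugc, M=M, Uwgc=Uwgc, Uwlc=Uwlc)


def fca_apply(x: np.ndarray, w: ChannelWeights | np.ndarray) -> np.ndarray:
    """Channel-wise reweighting F* = W (x) F (broadcast multiply)."""
    x = np.asarray(x, dtype=np.float64)
    wv = w.w if isinstance(w, ChannelWeights) else np.asarray(w, dtype=np.float64)
    if x.ndim != 4 or wv.ndim != 2 or wv.shape[1] != x.shape[1] or wv.shape[0] != x.shape[0]:
        raise ValueError("weights must be (N, C) matching the feature map")
    return x * wv[:, :, None, None]


def group_norm(
    x: np.ndarray,
    groups: int,
    eps: float = 1e-5,
    gamma: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Group normalization: zero mean / unit variance per sample and group."""
    x = np.asarray(x, dtype=np.float64)
    n, c, h, w = x.shape
    if c % groups != 0:
        raise ValueError(f"{c} channels not divisible into {groups} groups")
    g = x.reshape(n, groups, c // groups, h, w)
    mu = g.mean(axis=(2, 3, 4), keepdims=True)
    var = g.var(axis=(2, 3, 4), keepdims=True)
    out = ((g - mu) / np.sqrt(var + eps)).reshape(n, c, h, w)
    if gamma is not None:
        out = out * np.asarray(gamma)[None, :, None, None]
    if beta is not None:
        out = out + np.asarray(beta)[None, :, None, None]
    return out


@dataclass
class HeadParams:
    """Weights of the shared lightweight detection head.

    Per level only the 1x1 channel-reduction differs; the DEConv+GN block,
    the classification 1x1 and the regression 1x1 are the *same* arrays for
    every pyramid level (weight sharing), and a learnable scalar per level
    rescales the regression logits to compensate for the shared head seeing
    different strides.
    """

    reduce_w: list[np.ndarray]          # per level: (hidden, c_in, 1, 1)
    reduce_b: list[np.ndarray]          # per level: (hidden,)
    bank: KernelBank                    # shared DEConv, hidden -> hidden
    gn_gamma: np.ndarray
    gn_beta: np.ndarray
    gn_groups: int
    cls_w: np.ndarray                   # (nc, hidden, 1, 1), shared
    cls_b: np.ndarray
    reg_w: np.ndarray                   # (4*reg_max, hidden, 1, 1), shared
    reg_b: np.ndarray
    level_scales: np.ndarray            # one learnable scalar per level
    strides: tuple[int, ...] = (8, 16, 32)
    reg_max: int = 16
    nc: int = 3

    @classmethod
    def init(
        cls,
        seed: int,
        in_channels: tuple[int, ...] = (64, 128, 256),
        hidden: int = 64,
        nc: int = 3,
        reg_max: int = 16,
        strides: tuple[int, ...] = (8, 16, 32),
        gn_groups: int = 16,
    ) -> "HeadParams":
        if reg_max < 2:
            raise ValueError("reg_max must be >= 2")
        if len(in_channels) != len(strides):
            raise ValueError("need one stride per level")
        rng = np.random.default_rng(seed)

        def w(*shape):
            fan_in = int(np.prod(shape[1:]))
            return rng.standard_normal(shape) / np.sqrt(fan_in)

        return cls(
            reduce_w=[w(hidden, c, 1, 1) for c in in_channels],
            reduce_b=[np.zeros(hidden) for _ in in_channels],
            bank=KernelBank.random(int(rng.integers(2**31 - 1)), hidden, hidden, 3,
                                   scale=1.0 / (3 * np.sqrt(hidden))),
            gn_gamma=np.ones(hidden),
            gn_beta=np.zeros(hidden),
            gn_groups=gn_groups,
            cls_w=w(nc, hidden, 1, 1),
            cls_b=np.zeros(nc),
            reg_w=w(4 * reg_max, hidden, 1, 1),
            reg_b=np.zeros(4 * reg_max),
            level_scales=np.ones(len(in_channels)),
            strides=tuple(strides),
            reg_max=reg_max,
            nc=nc,
        )


@dataclass(frozen=True)
class DetectionOutput:
    """Raw per-level head outputs: classification and regression logits."""

    cls_logits: list[np.ndarray]  # per level: (N, nc, H, W)
    reg_logits: list[np.ndarray]  # per level: (N, 4*reg_max, H, W)
    strides: tuple[int, ...]
    reg_max: int


def lsd_head_forward(levels: list[np.ndarray], p: HeadParams) -> DetectionOutput:
    """Shared detection head over the feature pyramid.

    Per level: 1x1 reduce -> shared DEConv (merged kernel) -> group norm ->
    SiLU -> shared cls 1x1 and shared reg 1x1; the regression logits are
    multiplied by the level's learnable scale.  Spatial dimensions are
    preserved throughout.
    """
    if len(levels) != len(p.strides):
        raise ValueError(f"expected {len(p.strides)} pyramid levels, got {len(levels)}")
    cls_out, reg_out = [], []
    for i, x in enumerate(levels):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != p.reduce_w[i].shape[1]:
            raise ValueError(
                f"level {i}: expected {p.reduce_w[i].shape[1]} channels, got shape {x.shape}"
            )
        h = conv2d(x, p.reduce_w[i], bias=p.reduce_b[i])
        h = deconv_forward(h, p.bank, mode="merged")
        h = group_norm(h, p.gn_groups, gamma=p.gn_gamma, beta=p.gn_beta)
        h = silu(h)
        cls_out.append(conv2d(h, p.cls_w, bias=p.cls_b))
        reg_out.append(conv2d(h, p.reg_w, bias=p.reg_b) * p.level_scales[i])
    return DetectionOutput(cls_logits=cls_out, reg_logits=reg_out,
                           strides=p.strides, reg_max=p.reg_max)


def head_param_count(p: HeadParams, shared: bool = True) -> int:
    """Learnable-parameter count of the head; ``shared=False`` counts the
    per-level unshared equivalent (identical channel settings, one DEConv+GN
    and one cls/reg pair per level)."""
    n_levels = len(p.strides)
    reduce_n = sum(w.size for w in p.reduce_w) + sum(b.size for b in p.reduce_b)
    body = sum(w.size for w in p.bank.weights.values()) + p.gn_gamma.size + p.gn_beta.size
    heads = p.cls_w.size + p.cls_b.size + p.reg_w.size + p.reg_b.size
    scales = p.level_scales.size
    mult = 1 if shared else n_levels
    return reduce_n + mult * (body + heads) + scales


def dfl_decode(
    reg_logits: np.ndarray,
    reg_max: int,
    stride: int,
    anchor_points: np.ndarray | None = None,
    img_size: tuple[int, int] | None = None,
) -> np.ndarray:
    """Integral (distribution-focal) box decoding.

    Each box side is a softmax distribution over ``reg_max`` bins; the
    decoded side distance is its expectation sum(b * p(b)), in grid units,
    scaled by the level stride and offset from the anchor point (the grid
    cell center by default).  Returns (N, H, W, 4) boxes (x1, y1, x2, y2);
    with ``img_size`` = (H_img, W_img) the boxes are clamped to the image.
    """
    reg_logits = np.asarray(reg_logits, dtype=np.float64)
    n, ch, h, w = reg_logits.shape
    if ch != 4 * reg_max:
        raise ValueError(f"expected {4 * reg_max} regression channels, got {ch}")
    logits = reg_logits.reshape(n, 4, reg_max, h, w)
    logits = logits - logits.max(axis=2, keepdims=True)
    prob = np.exp(logits)
    prob /= prob.sum(axis=2, keepdims=True)
    bins = np.arange(reg_max, dtype=np.float64)
    dist = np.einsum("nsbhw,b->nshw", prob, bins)  # (N, 4=l,t,r,b, H, W)
    if anchor_points is None:
        ax, ay = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    else:
        ax, ay = anchor_points
    x1 = (ax[None] - dist[:, 0]) * stride
    y1 = (ay[None] - dist[:, 1]) * stride
    x2 = (ax[None] + dist[:, 2]) * stride
    y2 = (ay[None] + dist[:, 3]) * stride
    boxes = np.stack([x1, y1, x2, y2], axis=-1)
    if img_size is not None:
        hi, wi = img_size
        boxes[..., 0] = np.clip(boxes[..., 0], 0, wi)
        boxes[..., 2] = np.clip(boxes[..., 2], 0, wi)
        boxes[..., 1] = np.clip(boxes[..., 1], 0, hi)
        boxes[..., 3] = np.clip(boxes[..., 3], 0, hi)
    return boxes


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.45) -> np.ndarray:
    """Greedy IoU-based non-maximum suppression; returns kept indices."""
    from .metrics import iou as _iou

    boxes = np.asarray(boxes, dtype=np.float64)
    order = np.argsort(-np.asarray(scores))
    keep: list[int] = []
    for i in order:
        if all(_iou(boxes[i], boxes[j]) <= iou_thr for j in keep):
            keep.append(int(i))
    return np.array(keep, dtype=int)


# Weight archive key schema: reduce{i}_w / reduce{i}_b per level,
# bank_{kind} per DEConv branch, gn_gamma, gn_beta, cls_w, cls_b, reg_w,
# reg_b, level_scales, and a meta array [gn_groups, reg_max, nc, n_levels,
# stride_0, ..].
def save_head_weights(p: HeadParams, path: str | Path) -> None:
    """Save head weights as a flat named-array .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for i, (w, b) in enumerate(zip(p.reduce_w, p.reduce_b)):
        arrays[f"reduce{i}_w"] = w
        arrays[f"reduce{i}_b"] = b
    for kind, w in p.bank.weights.items():
        arrays[f"bank_{kind}"] = w
    arrays.update(
        gn_gamma=p.gn_gamma, gn_beta=p.gn_beta,
        cls_w=p.cls_w, cls_b=p.cls_b, reg_w=p.reg_w, reg_b=p.reg_b,
        level_scales=p.level_scales,
        meta=np.array([p.gn_groups, p.reg_max, p.nc, len(p.strides), *p.strides]),
    )
    np.savez(path, **arrays)


def load_head_weights(path: str | Path) -> HeadParams:
    """Load head weights written by :func:`save_head_weights`."""
    z = np.load(path)
    meta = z["meta"].astype(int)
    gn_groups, reg_max, nc, n_levels = meta[:4]
    strides = tuple(int(s) for s in meta[4:4 + n_levels])
    return HeadParams(
        reduce_w=[z[f"reduce{i}_w"] for i in range(n_levels)],
        reduce_b=[z[f"reduce{i}_b"] for i in range(n_levels)],
        bank=KernelBank(weights={k: z[f"bank_{k}"] for k in DIFFERENCE_KINDS}),
        gn_gamma=z["gn_gamma"], gn_beta=z["gn_beta"], gn_groups=int(gn_groups),
        cls_w=z["cls_w"], cls_b=z["cls_b"], reg_w=z["reg_w"], reg_b=z["reg_b"],
        level_scales=z["level_scales"], strides=strides,
        reg_max=int(reg_max), nc=int(nc),
    )
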