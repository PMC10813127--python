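"""Stage-1 feature distillation: attention-guided masked generative reconstruction.

The student's adapted feature map is occluded by a binary mask and must
regenerate the teacher's complete feature map through a small convolutional
generation block.  The mask is derived either at random (the masked
generative distillation baseline) or from a hierarchical-fusion (HF)
attention map built top-down across the teacher's feature pyramid, so that
the most salient teacher regions are the ones hidden from the student.

Feature tensors are arrays shaped ``(C, H, W)``; attention maps and masks
are ``(H, W)``.  All losses use the summed squared-error form
``sum_{c,h,w} (a - b)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Conv2d, GELU, Module, ReLU, Sequential

__all__ = [
    "AdapterConfig",
    "GenerationBlock",
    "FeatureAdapter",
    "Stage1Config",
    "adapt_student_features",
    "orig_feature_loss",
    "random_mask",
    "level_attention",
    "hf_fuse",
    "guided_mask",
    "generate_features",
    "stage1_loss",
    "mgd_loss",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AdapterConfig:
    """Channel alignment between student and teacher feature maps.

    ``kind`` is ``"identity"`` exactly when the channel counts already
    agree; otherwise a learnable 1x1 convolution maps student channels onto
    teacher channels.
    """

    in_channels: int
    out_channels: int

    @property
    def kind(self) -> str:
        return "identity" if self.in_channels == self.out_channels else "one_by_one_conv"


@dataclass
class Stage1Config:
    """Hyper-parameters of the Stage-1 loss.

    alpha
        Balance between the masked-reconstruction term and the plain
        feature-mimicry term; must be >= 0.  Optionally learnable.
    mask_mode / phi_or_ratio
        ``"threshold"``: mask positions whose attention >= phi.
        ``"ratio"``: mask the top fraction of positions by attention
        (default, ratio 0.5).
    distill_levels
        Pyramid levels at which reconstruction is applied (default: the
        deepest level only).
    fusion_weights
        Per-level weights of the top-down attention merge; ``None`` means
        equal 0.5/0.5 weighting at every merge.
    """

    alpha: float = 1.0
    mask_mode: str = "ratio"
    phi_or_ratio: float = 0.5
    distill_levels: tuple[int, ...] = (4,)
    fusion_weights: tuple[float, ...] | None = None
    alpha_learnable: bool = False

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.mask_mode not in ("threshold", "ratio"):
            raise ValueError("mask_mode must be 'threshold' or 'ratio'")
        if self.mask_mode == "ratio" and not 0.0 <= self.phi_or_ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")
        if self.mask_mode == "threshold" and not 0.0 < self.phi_or_ratio <= 1.0:
            raise ValueError("threshold phi must lie in (0, 1]")
        if self.fusion_weights is not None and any(w < 0 for w in self.fusion_weights):
            raise ValueError("fusion weights must be >= 0")


# ---------------------------------------------------------------------------
# Learnable components
# ---------------------------------------------------------------------------

class FeatureAdapter(Module):
    """Aligns student channels to teacher channels.

    Identity when channel counts match; a learnable 1x1 convolution
    otherwise.  Operates on batched ``(N, C, H, W)`` arrays.
    """

    def __init__(self, cfg: AdapterConfig, seed: int = 0):
        self.cfg = cfg
        if cfg.kind == "identity":
            self.conv = None
        else:
            self.conv = Conv2d(cfg.in_channels, cfg.out_channels, kernel=1,
                               padding=0, rng=np.random.default_rng(seed))

    def forward(self, x, train=True):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"adapter configured for {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if self.conv is None:
            return x
        return self.conv.forward(x, train=train)

    def backward(self, dout):
        if self.conv is None:
            return dout
        return self.conv.backward(dout)


class GenerationBlock(Module):
    """Two 3x3 convolutions with one activation in between.

    The spatial shape is preserved (padding 1).  The attention-guided
    variant uses GELU; the random-mask baseline uses ReLU.
    """

    def __init__(self, channels: int, activation: str = "gelu", seed: int = 0):
        rng = np.random.default_rng(seed)
        act: Module = GELU() if activation == "gelu" else ReLU()
        self.activation = activation
        self.net = Sequential(
            Conv2d(channels, channels, kernel=3, stride=1, rng=rng),
            act,
            Conv2d(channels, channels, kernel=3, stride=1, rng=rng),
        )

    def forward(self, x, train=True):
        return self.net.forward(x, train=train)

    def backward(self, dout):
        return self.net.backward(dout)


# ---------------------------------------------------------------------------
# Functional operations (single feature maps, (C, H, W))
# ---------------------------------------------------------------------------

def adapt_student_features(f: np.ndarray, cfg: AdapterConfig,
                           adapter: FeatureAdapter | None = None) -> np.ndarray:
    """Apply the channel-alignment function to one student feature map.

    For the identity configuration the input is returned unchanged.  For a
    1x1-convolution configuration, a :class:`FeatureAdapter` carrying the
    learnable weights may be supplied; a freshly initialized one is created
    otherwise.
    """
    f = np.asarray(f, dtype=np.float32)
    if f.ndim != 3:
        raise ValueError("expected a (C, H, W) feature map")
    if f.shape[0] != cfg.in_channels:
        raise ValueError(f"feature has {f.shape[0]} channels, adapter expects {cfg.in_channels}")
    if cfg.kind == "identity":
        return f
    adapter = adapter or FeatureAdapter(cfg)
    return adapter.forward(f[None], train=False)[0]


def orig_feature_loss(f_s_adapted: np.ndarray, f_t: np.ndarray) -> float:
    """Plain feature-mimicry loss: summed squared error over (c, h, w)."""
    f_s_adapted = np.asarray(f_s_adapted, dtype=np.float64)
    f_t = np.asarray(f_t, dtype=np.float64)
    if f_s_adapted.shape != f_t.shape:
        raise ValueError(f"shape mismatch: {f_s_adapted.shape} vs {f_t.shape}")
    return float(np.sum((f_s_adapted - f_t) ** 2))


def random_mask(height: int, width: int, mask_prob: float, seed: int) -> np.ndarray:
    """Bernoulli spatial mask: each position is 0 with probability ``mask_prob``."""
    if not 0.0 <= mask_prob <= 1.0:
        raise ValueError("mask_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((height, width)) >= mask_prob).astype(np.float32)


def level_attention(f: np.ndarray) -> np.ndarray:
    """Per-position saliency of one feature map.

    Channel-mean of absolute activations, min-max rescaled to [0, 1].  A
    constant map (no preferred position) rescales to all zeros.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("expected a (C, H, W) feature map")
    sal = np.abs(f).mean(axis=0)
    lo, hi = sal.min(), sal.max()
    if hi - lo <= 0:
        return np.zeros_like(sal)
    return (sal - lo) / (hi - lo)


def _upsample_nearest(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = a.shape
    th, tw = shape
    rows = (np.arange(th) * h) // th
    cols = (np.arange(tw) * w) // tw
    return a[np.ix_(rows, cols)]


def _rescale_max(a: np.ndarray) -> np.ndarray:
    """Normalize a non-negative saliency map by its maximum."""
    hi = a.max()
    if hi <= 0:
        return np.zeros_like(a)
    return a / hi


def hf_fuse(levels: list[np.ndarray], weights: list[float] | None = None) -> np.ndarray:
    """Top-down hierarchical fusion of per-level attention maps.

    ``levels`` is ordered shallow -> deep with strictly shrinking spatial
    sizes.  Each input map is first normalized by its maximum (which makes
    the fusion invariant to any common positive rescaling of the inputs);
    then, starting from the deepest map, each map is upsampled
    (nearest-neighbor) to the next-shallower resolution, merged by weighted
    summation and re-normalized; the result lives at the shallowest
    (level-1) resolution.  ``weights[i]`` weights level ``i`` at its merge;
    default is 0.5 everywhere.
    """
    if not levels:
        raise ValueError("need at least one attention map")
    levels = [_rescale_max(np.abs(np.asarray(a, dtype=np.float64))) for a in levels]
    for shallow, deep in zip(levels, levels[1:]):
        if not (deep.shape[0] < shallow.shape[0] and deep.shape[1] < shallow.shape[1]):
            raise ValueError("spatial sizes must strictly shrink with depth")
    if weights is None:
        weights = [0.5] * len(levels)
    if len(weights) != len(levels):
        raise ValueError("one fusion weight per level is required")
    acc = levels[-1]
    for i in range(len(levels) - 2, -1, -1):
        up = _upsample_nearest(acc, levels[i].shape)
        acc = _rescale_max(weights[i] * levels[i] + weights[i + 1] * up)
    return acc


def guided_mask(a: np.ndarray, cfg: Stage1Config) -> np.ndarray:
    """Binarize an attention map into an occlusion mask.

    Threshold mode: positions with attention >= phi are masked (0).
    Ratio mode: the top ``ratio`` fraction of positions by attention are
    masked, ties broken by row-major order.
    """
    a = np.asarray(a, dtype=np.float64)
    h, w = a.shape
    if cfg.mask_mode == "threshold":
        return (a < cfg.phi_or_ratio).astype(np.float32)
    k = int(round(cfg.phi_or_ratio * h * w))
    mask = np.ones(h * w, dtype=np.float32)
    if k > 0:
        # stable sort on negated attention: ties resolve in row-major order
        order = np.argsort(-a.ravel(), kind="stable")
        mask[order[:k]] = 0.0
    return mask.reshape(h, w)


def generate_features(f_s_adapted: np.ndarray, m: np.ndarray,
                      block: GenerationBlock) -> np.ndarray:
    """Occlude the adapted student feature and regenerate through the block.

    The spatial mask broadcasts across channels; output shape equals input
    shape.
    """
    f_s_adapted = np.asarray(f_s_adapted, dtype=np.float32)
    m = np.asarray(m, dtype=np.float32)
    if f_s_adapted.shape[1:] != m.shape:
        raise ValueError(f"mask shape {m.shape} does not match feature spatial shape "
                         f"{f_s_adapted.shape[1:]}")
    masked = f_s_adapted * m[None, :, :]
    return block.forward(masked[None], train=False)[0]


def stage1_loss(g: np.ndarray, f_t: np.ndarray, f_s_adapted: np.ndarray,
                cfg: Stage1Config) -> dict[str, float]:
    """Stage-1 objective: alpha * reconstruction + plain mimicry.

    total = alpha * sum (g - f_t)^2  +  sum (f_s_adapted - f_t)^2,
    with the two components reported separately.
    """
    if cfg.alpha < 0:
        raise ValueError("alpha must be >= 0")
    g = np.asarray(g, dtype=np.float64)
    f_t = np.asarray(f_t, dtype=np.float64)
    if g.shape != f_t.shape or f_s_adapted.shape != f_t.shape:
        raise ValueError("all feature maps must share a shape")
    recon = float(np.sum((g - f_t) ** 2))
    orig = orig_feature_loss(f_s_adapted, f_t)
    return {"reconstruction": recon, "orig": orig,
            "total": cfg.alpha * recon + orig}


def mgd_loss(f_s_adapted: np.ndarray, f_t: np.ndarray, mask_prob: float,
             seed: int, block: GenerationBlock) -> float:
    """Masked generative distillation baseline with a random mask.

    The student feature is occluded at random positions and must regenerate
    the teacher feature through the (ReLU-variant) generation block; the
    loss is the summed squared error of the regenerated map against the
    teacher map.
    """
    f_s_adapted = np.asarray(f_s_adapted, dtype=np.float32)
    f_t = np.asarray(f_t, dtype=np.float32)
    if f_s_adapted.shape != f_t.shape:
        raise ValueError("shape mismatch between student and teacher features")
    m = random_mask(f_s_adapted.shape[1], f_s_adapted.shape[2], mask_prob, seed)
    g = generate_features(f_s_adapted, m, block)
    return float(np.sum((np.asarray(g, dtype=np.float64) - f_t) ** 2))
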