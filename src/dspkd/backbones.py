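"""Reference backbones for CPU-scale distillation experiments.

Two tiny four-stage CNNs are bundled so the full dual-stage distillation
pipeline runs in minutes on one CPU: ``tiny-teacher`` (wider) and
``tiny-student`` (narrower).  Each stage halves the spatial resolution and
exposes its output as a pyramid tap, giving the four hierarchical feature
levels the attention-fusion machinery expects.

Standard lightweight architectures referenced in the skin-lesion literature
(ShuffleNetV2 and friends) are not re-implemented here; their learnable
parameter counts are available analytically via
:func:`architecture_parameter_count` so that model-size comparisons can be
reproduced without a deep-learning framework.
"""

from __future__ import annotations

import numpy as np

from .engine import BatchNorm2d, Conv2d, GlobalAvgPool, Linear, Module, ReLU, Sequential

#: stage widths of the bundled reference backbones
TINY_ARCHS = {
    "tiny-teacher": (16, 32, 64, 96),
    "tiny-student": (8, 16, 24, 48),
}


class TinyCNN(Module):
    """Four-stage CNN with pyramid taps and a linear classification head.

    Each stage is Conv(3x3, stride 2) -> BatchNorm -> ReLU, so for a
    ``side x side`` input the taps have spatial sizes ``side/2 .. side/16``
    at strictly decreasing resolution.

    Parameters
    ----------
    channels : per-stage output channels (4 entries).
    n_classes : width of the classification head.
    in_channels : input channels (3 for RGB).
    seed : initialization seed; identical seeds give identical weights.
    """

    def __init__(self, channels=(8, 16, 24, 48), n_classes: int = 6,
                 in_channels: int = 3, seed: int = 0):
        if len(channels) != 4:
            raise ValueError("TinyCNN expects exactly 4 stage widths")
        rng = np.random.default_rng(seed)
        self.channels = tuple(int(c) for c in channels)
        self.n_classes = int(n_classes)
        self.stages = []
        c_in = in_channels
        for c_out in self.channels:
            self.stages.append(Sequential(
                Conv2d(c_in, c_out, kernel=3, stride=2, rng=rng),
                BatchNorm2d(c_out),
                ReLU(),
            ))
            c_in = c_out
        self.pool = GlobalAvgPool()
        self.head = Linear(self.channels[-1], self.n_classes, rng=rng)

    # -- forward ---------------------------------------------------------
    def forward_with_taps(self, x: np.ndarray, train: bool = True):
        """Return ``(logits, [tap1..tap4])``; taps are the stage outputs."""
        taps = []
        h = np.asarray(x, dtype=np.float32)
        for stage in self.stages:
            h = stage.forward(h, train=train)
            taps.append(h)
        pooled = self.pool.forward(h, train=train)
        logits = self.head.forward(pooled, train=train)
        return logits, taps

    def forward(self, x, train=True):
        return self.forward_with_taps(x, train=train)[0]

    # -- backward --------------------------------------------------------
    def backward(self, dlogits: np.ndarray, dtaps: list[np.ndarray | None] | None = None):
        """Backpropagate logits gradient plus optional per-tap gradients.

        ``dtaps[i]`` (if given) is added to the gradient flowing into the
        output of stage ``i`` — this is how feature-distillation losses
        inject gradients at intermediate pyramid levels.
        """
        dh = self.pool.backward(self.head.backward(dlogits))
        for i in range(3, -1, -1):
            if dtaps is not None and dtaps[i] is not None:
                dh = dh + dtaps[i]
            dh = self.stages[i].backward(dh)
        return dh

    def predict_logits(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Inference-mode logits (BatchNorm running statistics)."""
        outs = []
        for start in range(0, len(x), batch_size):
            outs.append(self.forward(x[start:start + batch_size], train=False))
        return np.concatenate(outs, axis=0)


def build_backbone(name: str, n_classes: int, seed: int = 0) -> TinyCNN:
    """Instantiate a bundled reference backbone by identifier."""
    if name not in TINY_ARCHS:
        raise ValueError(f"unknown backbone {name!r}; available: {sorted(TINY_ARCHS)}")
    return TinyCNN(TINY_ARCHS[name], n_classes=n_classes, seed=seed)


# ---------------------------------------------------------------------------
# Analytic parameter counts for standard architectures
# ---------------------------------------------------------------------------

_SHUFFLENET_V2_WIDTHS = {
    "0.5x": (24, 48, 96, 192, 1024),
    "1.0x": (24, 116, 232, 464, 1024),
    "1.5x": (24, 176, 352, 704, 1024),
    "2.0x": (24, 244, 488, 976, 2048),
}
_SHUFFLENET_V2_REPEATS = (4, 8, 4)  # units per stage, first unit is the downsampling one


def _bn(c: int) -> int:
    return 2 * c  # affine scale + shift; running stats are not learnable


def _shufflenet_unit_params(c_in: int, c_out: int, downsample: bool) -> int:
    """Learnable parameters of one ShuffleNetV2 unit (convs bias-free)."""
    branch = c_out // 2
    total = 0
    if downsample:
        # branch 1: 3x3 depthwise on c_in + 1x1 to `branch`
        total += 9 * c_in + _bn(c_in)
        total += c_in * branch + _bn(branch)
        c_mid = c_in
    else:
        c_mid = c_in // 2  # channel split: branch 2 sees half the channels
    # branch 2: 1x1 -> 3x3 depthwise -> 1x1
    total += c_mid * branch + _bn(branch)
    total += 9 * branch + _bn(branch)
    total += branch * branch + _bn(branch)
    return total


def shufflenet_v2_parameter_count(width: str = "1.0x", num_classes: int = 1000) -> int:
    """Learnable-parameter count of ShuffleNetV2 at a given width multiplier.

    Computed from the architecture table (stem 3x3/24, three stages of
    4/8/4 units, 1x1 conv to the final width, linear classifier); agrees
    with framework implementations, e.g. 2,278,604 for 1.0x/1000 classes.
    """
    if width not in _SHUFFLENET_V2_WIDTHS:
        raise ValueError(f"unknown width {width!r}")
    stem, s2, s3, s4, final = _SHUFFLENET_V2_WIDTHS[width]
    total = 3 * stem * 9 + _bn(stem)  # stem conv 3x3 stride 2
    c_in = stem
    for c_out, repeats in zip((s2, s3, s4), _SHUFFLENET_V2_REPEATS):
        total += _shufflenet_unit_params(c_in, c_out, downsample=True)
        total += (repeats - 1) * _shufflenet_unit_params(c_out, c_out, downsample=False)
        c_in = c_out
    total += c_in * final + _bn(final)  # final 1x1 conv
    total += final * num_classes + num_classes  # classifier (with bias)
    return total


def architecture_parameter_count(name: str, num_classes: int) -> int:
    """Parameter count for a named architecture.

    Bundled tiny backbones are instantiated and counted directly; standard
    lightweight architectures use the analytic tables above.
    """
    if name in TINY_ARCHS:
        return build_backbone(name, n_classes=num_classes).num_parameters()
    key = name.lower().replace("-", "").replace("_", "")
    for width in _SHUFFLENET_V2_WIDTHS:
        if key in {f"shufflenetv2{width}", f"shufflenetv2x{width.replace('.', '')}",
                   "shufflenetv2" if width == "1.0x" else ""}:
            return shufflenet_v2_parameter_count(width, num_classes)
    raise ValueError(f"no parameter table for architecture {name!r}")
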