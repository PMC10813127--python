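"""Seeded generator of dermatoscopy-like labeled images.

Each image is a skin-tone background carrying one elliptical lesion whose
hue, size, eccentricity and sinusoidal texture follow a class-specific
signature, plus Gaussian pixel noise and (optionally) dark curvilinear hair
strands with exact ground-truth artifact masks.  Labels are correct by
construction and everything is determined by a single seed, so the full
distillation pipeline is exercisable without any downloaded data.

The default configuration mirrors a six-class clinical task; an eight-class
challenge-style preset is also shipped.  Images default to 64 x 64 so that
CPU training finishes in minutes; the preprocessing resize op covers
full-scale geometries (224 or 512 pixels).
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

__all__ = ["ClassSignature", "HairParams", "SynthSpec", "SynthDataset",
           "default_signatures", "generate_dataset", "overlay_hair",
           "save_dataset", "make_spec"]


@dataclass
class ClassSignature:
    """Visual identity of one lesion class."""

    hue: float             # HSV hue of the lesion body, in [0, 1)
    radius_frac: float     # mean lesion radius as a fraction of image side
    eccentricity: float    # minor/major axis ratio in (0, 1]
    texture_freq: float    # cycles of sinusoidal texture across the lesion


@dataclass
class HairParams:
    """Geometry of simulated hair artifacts."""

    n_strands: int = 5
    thickness: int = 2
    darkness: int = 40     # grey level of the strand color
    curvature: float = 0.3

    def __post_init__(self):
        if self.thickness < 1:
            raise ValueError("thickness must be >= 1 pixel")
        if self.n_strands < 0:
            raise ValueError("n_strands must be >= 0")


def default_signatures(n_classes: int) -> list[ClassSignature]:
    """Evenly spread hues with cycling shape/texture signatures."""
    eccs = [1.0, 0.7, 0.55]
    freqs = [0.0, 2.0, 4.0, 6.0]
    radii = np.linspace(0.14, 0.30, n_classes)
    # hues span half the wheel so neighboring classes overlap once per-image
    # jitter is applied — lesion classes should be confusable, not trivial
    return [ClassSignature(hue=0.5 * i / n_classes,
                           radius_frac=float(radii[i]),
                           eccentricity=eccs[i % len(eccs)],
                           texture_freq=freqs[i % len(freqs)])
            for i in range(n_classes)]


@dataclass
class SynthSpec:
    """Full parametric description of a generated dataset."""

    n_classes: int = 6
    images_per_class: int | list[int] = 100
    side: int = 64
    signatures: list[ClassSignature] = field(default_factory=list)
    skin_tone_low: tuple[float, float, float] = (0.75, 0.58, 0.48)
    skin_tone_high: tuple[float, float, float] = (0.88, 0.72, 0.62)
    hue_jitter: float = 0.05
    noise_sd: float = 0.10
    hair_probability: float = 0.0
    hair: HairParams = field(default_factory=HairParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if not 0.0 <= self.hair_probability <= 1.0:
            raise ValueError("hair_probability must lie in [0, 1]")
        if not self.signatures:
            self.signatures = default_signatures(self.n_classes)
        if len(self.signatures) != self.n_classes:
            raise ValueError("one signature per class is required")
        for sig in self.signatures:
            if sig.radius_frac >= 0.5:
                raise ValueError("lesion radius must be below half the image side")
        counts = self.counts()
        if any(c < 1 for c in counts):
            raise ValueError("images_per_class must be >= 1 for every class")

    def counts(self) -> list[int]:
        if isinstance(self.images_per_class, int):
            return [self.images_per_class] * self.n_classes
        if len(self.images_per_class) != self.n_classes:
            raise ValueError("per-class counts must have n_classes entries")
        return [int(c) for c in self.images_per_class]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SynthDataset:
    """Generated images plus ground truth.

    ``images`` are uint8 RGB arrays ``(N, H, W, 3)``; ``clean_images`` are
    the pre-artifact versions (identical where no hair was overlaid);
    ``hair_masks`` are boolean ``(N, H, W)`` marking exactly the altered
    pixels.
    """

    images: np.ndarray
    clean_images: np.ndarray
    labels: np.ndarray
    hair_masks: np.ndarray
    manifest: pd.DataFrame
    spec: SynthSpec


def make_spec(preset: str = "psd6", images_per_class: int | list[int] = 100,
              seed: int = 0, **overrides) -> SynthSpec:
    """Build a spec from a named preset (``psd6``: 6 classes, ``isic8``: 8)."""
    presets = {"psd6": 6, "isic8": 8}
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}")
    return SynthSpec(n_classes=presets[preset], images_per_class=images_per_class,
                     seed=seed, **overrides)


def _render_lesion(spec: SynthSpec, sig: ClassSignature, rng: np.random.Generator) -> np.ndarray:
    """One clean lesion image in [0, 1] floats, (H, W, 3)."""
    side = spec.side
    lo = np.asarray(spec.skin_tone_low)
    hi = np.asarray(spec.skin_tone_high)
    background = lo + (hi - lo) * rng.random(3)
    img = np.empty((side, side, 3))
    img[:] = background
    # subtle background gradient so the skin is not perfectly flat
    grad = (np.linspace(-1, 1, side)[:, None] * rng.uniform(-0.03, 0.03)
            + np.linspace(-1, 1, side)[None, :] * rng.uniform(-0.03, 0.03))
    img += grad[:, :, None]

    hue = (sig.hue + rng.uniform(-spec.hue_jitter, spec.hue_jitter)) % 1.0
    sat = rng.uniform(0.45, 0.6)
    val = rng.uniform(0.35, 0.5)
    lesion_rgb = np.asarray(colorsys.hsv_to_rgb(hue, sat, val))

    radius = sig.radius_frac * side * rng.uniform(0.85, 1.15)
    a_ax = radius
    b_ax = radius * sig.eccentricity
    theta = rng.uniform(0, np.pi)
    cy = side / 2 + rng.uniform(-0.1, 0.1) * side
    cx = side / 2 + rng.uniform(-0.1, 0.1) * side

    yy, xx = np.mgrid[0:side, 0:side]
    yr = (yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)
    xr = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    dist = np.sqrt((xr / a_ax) ** 2 + (yr / b_ax) ** 2)
    # soft lesion boundary: fully lesion inside, smooth 15% falloff band
    alpha = np.clip((1.1 - dist) / 0.15, 0.0, 1.0)

    if sig.texture_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.uniform(0, np.pi)
        coord = (xx * np.cos(direction) + yy * np.sin(direction)) / side
        texture = 0.05 * np.sin(2 * np.pi * sig.texture_freq * coord + phase)
    else:
        texture = 0.0
    lesion = np.clip(lesion_rgb[None, None, :] + np.atleast_3d(texture), 0, 1)
    img = img * (1 - alpha[:, :, None]) + lesion * alpha[:, :, None]
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def overlay_hair(img: np.ndarray, p: HairParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw dark curved strands on a copy of ``img``.

    Strands are quadratic Bezier arcs rasterized as polylines.  Returns the
    corrupted image and a boolean mask marking exactly the pixels whose
    value changed.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    rng = np.random.default_rng(seed)
    out = Image.fromarray(img.astype(np.uint8))
    draw = ImageDraw.Draw(out)
    h, w = img.shape[:2]
    for _ in range(p.n_strands):
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        p2 = rng.uniform([0, 0], [h - 1, w - 1])
        mid = (p0 + p2) / 2
        chord = p2 - p0
        perp = np.array([-chord[1], chord[0]])
        p1 = mid + p.curvature * perp * rng.uniform(-1, 1)
        t = np.linspace(0, 1, 64)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
        shade = int(np.clip(p.darkness + rng.integers(-10, 11), 0, 255))
        xy = [(float(x), float(y)) for y, x in pts]
        draw.line(xy, fill=(shade, shade, shade), width=p.thickness, joint="curve")
    out = np.asarray(out, dtype=np.uint8)
    mask = np.any(out != img.astype(np.uint8), axis=2)
    return out, mask


def generate_dataset(spec: SynthSpec) -> SynthDataset:
    """Render the full labeled dataset described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.counts()
    images, clean, labels, masks, rows = [], [], [], [], []
    idx = 0
    for cls, count in enumerate(counts):
        sig = spec.signatures[cls]
        for _ in range(count):
            base = (_render_lesion(spec, sig, rng) * 255).round().astype(np.uint8)
            has_hair = spec.hair_probability > 0 and rng.random() < spec.hair_probability
            if has_hair:
                corrupted, mask = overlay_hair(base, spec.hair, int(rng.integers(0, 2 ** 31)))
            else:
                corrupted, mask = base, np.zeros(base.shape[:2], dtype=bool)
            fname = f"img_{idx:05d}_c{cls}.png"
            images.append(corrupted)
            clean.append(base)
            labels.append(cls)
            masks.append(mask)
            rows.append({"filename": fname, "class": f"class{cls}", "label": cls,
                         "has_hair": bool(has_hair)})
            idx += 1
    manifest = pd.DataFrame(rows)
    return SynthDataset(
        images=np.stack(images), clean_images=np.stack(clean),
        labels=np.asarray(labels, dtype=np.int64),
        hair_masks=np.stack(masks), manifest=manifest, spec=spec)


def save_dataset(ds: SynthDataset, outdir) -> Path:
    """Write PNG images, labels CSV, artifact masks and the spec JSON."""
    outdir = Path(outdir)
    img_dir = outdir / "images"
    mask_dir = outdir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    for i, row in ds.manifest.iterrows():
        Image.fromarray(ds.images[i]).save(img_dir / row["filename"])
        if row["has_hair"]:
            Image.fromarray((ds.hair_masks[i] * 255).astype(np.uint8)).save(
                mask_dir / row["filename"])
    ds.manifest[["filename", "class"]].to_csv(outdir / "labels.csv", index=False)
    (outdir / "spec.json").write_text(ds.spec.to_json())
    return outdir
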