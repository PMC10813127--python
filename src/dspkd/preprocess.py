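"""Dataset preparation for dermatoscopy classification.

Resizing, hair-artifact removal (morphological black-hat detection followed
by inpainting, the classical approach for dermoscopy hair), RandAugment-based
oversampling of under-represented classes, and a stratified 8:2 train/test
split in which augmented copies always follow their source image, so no
augmented view of a test image can leak into training.

Images are uint8 RGB arrays; dataset manifests are pandas DataFrames with
columns ``filename``, ``class`` and optional ``provenance`` (the source
record of an augmented copy) and ``split``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance, ImageOps
from scipy.ndimage import gaussian_filter
from skimage.morphology import black_tophat, dilation, disk
from skimage.restoration import inpaint_biharmonic

__all__ = ["HairRemovalParams", "RANDAUGMENT_OPS", "resize_image", "remove_hair",
           "hair_artifact_score", "rand_augment", "balance_classes", "split_dataset",
           "preprocess_folder"]


@dataclass
class HairRemovalParams:
    """Knobs of the black-hat + inpaint hair-removal scheme."""

    element_size: int = 9       # diameter of the morphological structuring element
    threshold: int = 50         # black-hat response above which a pixel is "hair"
    inpaint_radius: int = 3     # dilation of the detected mask before inpainting
    smoothing_sigma: float = 0.8  # Gaussian denoising before detection

    def __post_init__(self):
        if min(self.element_size, self.inpaint_radius) <= 0 or not 0 <= self.threshold <= 255:
            raise ValueError("invalid hair-removal parameters")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def _to_pil(img) -> Image.Image:
    if isinstance(img, Image.Image):
        return img.convert("RGB")
    return Image.fromarray(np.asarray(img, dtype=np.uint8)).convert("RGB")


def resize_image(img, side: int) -> np.ndarray:
    """Resize to ``side x side`` RGB (bilinear); identical input size passes through."""
    if side <= 0:
        raise ValueError("side must be positive")
    pil = _to_pil(img)
    if pil.size == (side, side):
        return np.asarray(pil)
    return np.asarray(pil.resize((side, side), Image.BILINEAR))


def hair_artifact_score(img, p: HairRemovalParams | None = None) -> float:
    """Mean black-hat response — a proxy for how much dark-strand noise an image carries."""
    p = p or HairRemovalParams()
    return float(_hair_response(img, p).mean())


def _hair_response(img, p: HairRemovalParams) -> np.ndarray:
    gray = np.asarray(_to_pil(img).convert("L")).astype(np.float64)
    if p.smoothing_sigma > 0:  # denoise so pixel noise stays below threshold
        gray = gaussian_filter(gray, p.smoothing_sigma)
    return black_tophat(gray, disk(p.element_size // 2))


def remove_hair(img, p: HairRemovalParams | None = None) -> np.ndarray:
    """Detect thin dark curvilinear structures and replace them by inpainting.

    Dark strands light up in the black-hat transform of the grayscale image;
    responses above ``threshold`` form the artifact mask, which is slightly
    dilated and filled by biharmonic inpainting.  Pixels outside the mask
    are returned unchanged; a hair-free image passes through identically.
    """
    p = p or HairRemovalParams()
    arr = np.asarray(_to_pil(img))
    mask = _hair_response(img, p) > p.threshold
    if not mask.any():
        return arr.copy()
    mask = dilation(mask, disk(p.inpaint_radius // 2 or 1))
    filled = inpaint_biharmonic(arr.astype(np.float64) / 255.0, mask, channel_axis=-1)
    out = arr.copy()
    out[mask] = np.clip(filled[mask] * 255.0, 0, 255).round().astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# RandAugment
# ---------------------------------------------------------------------------

def _affine(img: Image.Image, coeffs) -> Image.Image:
    return img.transform(img.size, Image.AFFINE, coeffs, resample=Image.BILINEAR,
                         fillcolor=(128, 128, 128))


def _enhance(kind, img, magnitude, sign):
    factor = 1.0 + sign * 0.9 * magnitude / 10.0
    return kind(img).enhance(max(factor, 0.05))


_OPS = {
    "identity": lambda img, m, s: img,
    "autoContrast": lambda img, m, s: ImageOps.autocontrast(img),
    "equalize": lambda img, m, s: ImageOps.equalize(img),
    "rotate": lambda img, m, s: img.rotate(s * 30.0 * m / 10.0, resample=Image.BILINEAR,
                                           fillcolor=(128, 128, 128)),
    "solarize": lambda img, m, s: ImageOps.solarize(img, threshold=int(255 - 25.5 * m)),
    "color": lambda img, m, s: _enhance(ImageEnhance.Color, img, m, s),
    "posterize": lambda img, m, s: ImageOps.posterize(img, bits=max(8 - int(m * 4 / 10), 4)),
    "contrast": lambda img, m, s: _enhance(ImageEnhance.Contrast, img, m, s),
    "brightness": lambda img, m, s: _enhance(ImageEnhance.Brightness, img, m, s),
    "sharpness": lambda img, m, s: _enhance(ImageEnhance.Sharpness, img, m, s),
    "shear-x": lambda img, m, s: _affine(img, (1, s * 0.3 * m / 10.0, 0, 0, 1, 0)),
    "shear-y": lambda img, m, s: _affine(img, (1, 0, 0, s * 0.3 * m / 10.0, 1, 0)),
    "translate-x": lambda img, m, s: _affine(
        img, (1, 0, s * img.size[0] / 3.0 * m / 10.0, 0, 1, 0)),
    "translate-y": lambda img, m, s: _affine(
        img, (1, 0, 0, 0, 1, s * img.size[1] / 3.0 * m / 10.0)),
}

#: the 14 available RandAugment operations
RANDAUGMENT_OPS = tuple(_OPS)


def rand_augment(img, n_ops: int, magnitude: int = 9, seed: int = 0,
                 ops: list[str] | None = None) -> np.ndarray:
    """Apply ``n_ops`` operations sampled without replacement from the 14.

    ``ops`` forces an explicit operation list (bypassing sampling), which is
    useful for deterministic pipelines and tests.  Signed operations draw a
    random direction.  Identical seeds give identical outputs.
    """
    if ops is None and not 1 <= n_ops <= 3:
        raise ValueError("n_ops must lie in 1..3")
    if not 0 <= magnitude <= 10:
        raise ValueError("magnitude must lie in 0..10")
    rng = np.random.default_rng(seed)
    if ops is None:
        chosen = list(rng.choice(len(RANDAUGMENT_OPS), size=n_ops, replace=False))
        ops = [RANDAUGMENT_OPS[i] for i in chosen]
    pil = _to_pil(img)
    for name in ops:
        if name not in _OPS:
            raise ValueError(f"unknown augmentation op {name!r}")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pil = _OPS[name](pil, magnitude, sign)
    return np.asarray(pil)


# ---------------------------------------------------------------------------
# Manifest-level operations
# ---------------------------------------------------------------------------

def _ensure_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    manifest = manifest.copy()
    if "provenance" not in manifest.columns:
        manifest["provenance"] = ""
    manifest["provenance"] = manifest["provenance"].fillna("")
    return manifest


def balance_classes(manifest: pd.DataFrame, target_fraction: float = 0.5,
                    seed: int = 0, magnitude: int = 9,
                    images_dir=None, out_dir=None) -> pd.DataFrame:
    """Oversample minority classes with augmented copies.

    Every class whose count is below ``target_fraction`` of the largest
    class gains augmented copies of randomly drawn source images until it
    reaches that level.  Originals are never removed; each new record's
    ``provenance`` column names its source file.  When ``images_dir`` is
    given, the augmented images are actually rendered (1-3 random ops each)
    and written next to the originals (or into ``out_dir``).
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in (0, 1]")
    manifest = _ensure_manifest(manifest)
    counts = manifest["class"].value_counts()
    if (counts < 1).any() or manifest.empty:
        raise ValueError("every class needs at least one record")
    target = int(np.ceil(target_fraction * counts.max()))
    rng = np.random.default_rng(seed)
    new_rows = []
    for cls, count in counts.items():
        if count >= target:
            continue
        sources = manifest.loc[(manifest["class"] == cls) & (manifest["provenance"] == ""),
                               "filename"].to_numpy()
        if sources.size == 0:  # nothing original to augment from
            raise ValueError(f"class {cls!r} has no source records")
        for j in range(target - count):
            src = str(sources[rng.integers(0, sources.size)])
            aug_seed = int(rng.integers(0, 2 ** 31))
            fname = f"aug_{cls}_{j:04d}_{Path(src).stem}.png"
            row = {"filename": fname, "class": cls, "provenance": src}
            if "split" in manifest.columns:
                row["split"] = manifest.loc[manifest["filename"] == src, "split"].iloc[0]
            new_rows.append(row)
            if images_dir is not None:
                n_ops = int(rng.integers(1, 4))
                img = np.asarray(Image.open(Path(images_dir) / src).convert("RGB"))
                aug = rand_augment(img, n_ops, magnitude=magnitude, seed=aug_seed)
                dest = Path(out_dir or images_dir) / fname
                dest.parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray(aug).save(dest)
    if not new_rows:
        return manifest
    return pd.concat([manifest, pd.DataFrame(new_rows)], ignore_index=True)


def split_dataset(manifest: pd.DataFrame, ratio: float = 0.8, seed: int = 0,
                  stratified: bool = True) -> pd.DataFrame:
    """Assign a ``split`` column: stratified random 8:2 partition.

    Only source records are drawn; augmented copies inherit the split of
    their source, so augmentation can never leak test content into
    training.  Per class the train fraction is within one record of
    ``ratio``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    manifest = _ensure_manifest(manifest)
    sources = manifest[manifest["provenance"] == ""]
    rng = np.random.default_rng(seed)
    split_of: dict[str, str] = {}
    groups = sources.groupby("class")["filename"] if stratified else \
        [("all", sources["filename"])]
    for _, filenames in groups:
        files = filenames.to_numpy()
        if files.size < 2:
            raise ValueError("each class needs at least 2 source records to split")
        perm = rng.permutation(files.size)
        n_train = int(round(ratio * files.size))
        n_train = min(max(n_train, 1), files.size - 1)
        for i, idx in enumerate(perm):
            split_of[str(files[idx])] = "train" if i < n_train else "test"
    def assign(row):
        key = row["filename"] if row["provenance"] == "" else row["provenance"]
        return split_of[str(key)]
    manifest["split"] = manifest.apply(assign, axis=1)
    return manifest


def preprocess_folder(in_dir, labels_csv, out_dir, side: int = 224,
                      balance: float | None = 0.5, hair_removal: str = "auto",
                      seed: int = 0, hair_params: HairRemovalParams | None = None,
                      split_ratio: float = 0.8) -> pd.DataFrame:
    """Full file-based pipeline: resize -> (hair removal) -> balance -> split.

    ``hair_removal`` is ``"never"``, ``"always"`` or ``"auto"`` (apply when
    the black-hat energy of an image exceeds twice the dataset median).
    Writes processed images, ``manifest.csv`` and a ``summary.json`` of
    class counts before/after balancing to ``out_dir``.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    img_out = out_dir / "images"
    img_out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(labels_csv, dtype=str)[["filename", "class"]]
    hair_params = hair_params or HairRemovalParams()

    resized = {}
    for fname in manifest["filename"]:
        resized[fname] = resize_image(Image.open(in_dir / fname), side)
    if hair_removal == "auto":
        scores = {f: hair_artifact_score(img, hair_params) for f, img in resized.items()}
        cutoff = 2.0 * float(np.median(list(scores.values())))
        flagged = {f for f, s in scores.items() if s > cutoff}
    elif hair_removal == "always":
        flagged = set(resized)
    elif hair_removal == "never":
        flagged = set()
    else:
        raise ValueError("hair_removal must be 'never', 'always' or 'auto'")
    for fname, img in resized.items():
        if fname in flagged:
            img = remove_hair(img, hair_params)
        Image.fromarray(img).save(img_out / fname)

    before = manifest["class"].value_counts().to_dict()
    if balance is not None:
        manifest = balance_classes(manifest, target_fraction=balance, seed=seed,
                                   images_dir=img_out)
    manifest = split_dataset(manifest, ratio=split_ratio, seed=seed)
    after = manifest["class"].value_counts().to_dict()
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    summary = {"class_counts_before": before, "class_counts_after": after,
               "hair_removed": sorted(flagged),
               "split_counts": manifest["split"].value_counts().to_dict()}
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return manifest
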