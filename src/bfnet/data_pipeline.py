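"""Dataset IO, mask encoding, size conformance and augmentation.

Samples are image/mask raster pairs; mask foreground is encoded as pixel
value 1 (any nonzero value in the file binarises to 1, so masks saved with
foreground 255 or as RGB (1,1,1) both load identically).  Images smaller
than the configured network size are upscaled bicubically (masks with
nearest-neighbour, then re-binarised); larger images are centre-cropped.
Augmentation applies an identical random rotation (default within +/-15
degrees) and horizontal/vertical flips to image and mask, then rescales
image intensities to [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass(frozen=True)
class SegSample:
    """An image (H, W, 3 float32 in [0, 1]) with its binary mask (H, W uint8)."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _binarize_mask(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # RGB-encoded mask: foreground where any channel nonzero
        arr = arr.max(axis=2)
    return (arr > 0).astype(np.uint8)


def load_pair(image_path, mask_path) -> SegSample:
    img = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.float32) / 255.0
    mask = _binarize_mask(np.asarray(Image.open(mask_path)))
    if img.shape[:2] != mask.shape:
        raise ValueError(
            f"{image_path}: image size {img.shape[:2]} != mask size {mask.shape}"
        )
    return SegSample(image=img, mask=mask, id=Path(image_path).stem)


def conform_size(s: SegSample, target: int = 512) -> SegSample:
    """Bring a sample to exactly target x target (bicubic upscale / centre crop)."""
    h, w = s.mask.shape
    if (h, w) == (target, target):
        return s
    if h < target or w < target:
        img = Image.fromarray((s.image * 255).astype(np.uint8)).resize(
            (target, target), Image.BICUBIC
        )
        msk = Image.fromarray(s.mask * 255).resize((target, target), Image.NEAREST)
        image = np.asarray(img, dtype=np.float32) / 255.0
        mask = _binarize_mask(np.asarray(msk))
    else:
        top = (h - target) // 2
        left = (w - target) // 2
        image = s.image[top : top + target, left : left + target]
        mask = s.mask[top : top + target, left : left + target]
    return replace(s, image=image, mask=mask)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image min-max rescale to [0, 1] (constant images map to 0)."""
    lo = image.min()
    span = image.max() - lo
    if span <= 0:
        return np.zeros_like(image)
    return (image - lo) / span


def augment(
    s: SegSample,
    rng: np.random.Generator,
    max_angle: float = 15.0,
    hflip: bool = True,
    vflip: bool = True,
) -> SegSample:
    """Randomly rotate/flip image and mask identically; normalise intensities."""
    angle = float(rng.uniform(-max_angle, max_angle))
    image, mask = s.image, s.mask
    if angle != 0.0:
        image = ndimage.rotate(
            image, angle, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0
        )
        mask = ndimage.rotate(
            mask, angle, reshape=False, order=0, mode="constant", cval=0
        ).astype(np.uint8)
        mask = (mask > 0).astype(np.uint8)
    if hflip and rng.random() < 0.5:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if vflip and rng.random() < 0.5:
        image = image[::-1].copy()
        mask = mask[::-1].copy()
    return replace(s, image=normalize_image(image).astype(np.float32), mask=mask)


def to_model_input(s: SegSample) -> np.ndarray:
    """(H, W, 3) sample image -> (3, H, W) float32 network input."""
    return np.ascontiguousarray(s.image.transpose(2, 0, 1), dtype=np.float32)


# -- manifest IO -----------------------------------------------------------


def write_manifest(rows: list[dict], path) -> None:
    """rows: dicts with image_path, mask_path, split."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image_path", "mask_path", "split"])
        writer.writeheader()
        writer.writerows(rows)


def load_manifest(path, split: str | None = None, conform_to: int | None = None):
    """Load (and optionally size-conform) all samples of one split."""
    base = Path(path).parent
    samples = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if split is not None and row["split"] != split:
                continue
            s = load_pair(base / row["image_path"], base / row["mask_path"])
            if conform_to is not None:
                s = conform_size(s, conform_to)
            samples.append(s)
    return samples
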