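"""Seeded generator of CT-like lesion phantoms with exact binary masks.

Each phantom emulates the gross appearance of an axial chest CT slice with
small, bright, irregular lesions: a smooth dark soft-tissue background, two
elliptical lung-field regions of intermediate intensity, and one to a few
bright elliptical lesions whose boundaries are perturbed by low-order
harmonics (so the network must learn irregular boundaries, not just discs).
The mask is the exact analytic union of the lesion supports, and the whole
corpus is a deterministic function of the seed.

This is an appearance phantom, not a physical CT simulation: there is no
projection/reconstruction model, no Hounsfield calibration and no anatomy
beyond the lung-field ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data_pipeline import SegSample, write_manifest


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom corpus generator.

    Intensities are on the [0, 1] gray scale.  ``lesion_contrast`` is the
    lesion brightness above the lung-field level; keeping it above
    ``texture_amplitude`` guarantees lesions are the brightest structures.
    """

    n_images: int = 100
    size: int = 64
    lesions: tuple[int, int] = (1, 3)
    radius: tuple[float, float] = (3.0, 7.0)
    lesion_contrast: float = 0.45
    lung_level: float = 0.40
    background_level: float = 0.15
    texture_amplitude: float = 0.08
    noise_sd: float = 0.03
    boundary_wobble: float = 0.25
    seed: int = 2024

    def __post_init__(self):
        if self.n_images < 1 or self.size < 16:
            raise ValueError("need n_images >= 1 and size >= 16")
        if not (0 < self.lesions[0] <= self.lesions[1]):
            raise ValueError("lesion count range must be positive and ordered")
        if not (0 < self.radius[0] <= self.radius[1]):
            raise ValueError("radius range must be positive and ordered")
        if self.radius[1] >= self.size / 2:
            raise ValueError(
                f"max lesion radius {self.radius[1]} does not fit in a "
                f"{self.size}px image (must be < size/2)"
            )


def _lung_fields(size: int):
    """Two rotated ellipses (cy, cx, a, b, theta) roughly placed as lungs."""
    return [
        (0.52 * size, 0.30 * size, 0.30 * size, 0.15 * size, 0.25),
        (0.52 * size, 0.70 * size, 0.30 * size, 0.15 * size, -0.25),
    ]


def _ellipse_mask(size: int, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _lesion_support(size, cy, cx, r0, axis_ratio, theta, harm) -> np.ndarray:
    """Rotated ellipse with multiplicative radial harmonic perturbation."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rnorm = np.sqrt((u / r0) ** 2 + (v / (r0 * axis_ratio)) ** 2)
    phi = np.arctan2(v, u)
    pert = np.ones_like(phi)
    for m, (amp, phase) in enumerate(harm, start=2):
        pert += amp * np.cos(m * phi + phase)
    return rnorm <= pert


def generate(spec: PhantomSpec) -> list[SegSample]:
    """Generate the phantom corpus; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    lungs = _lung_fields(size)
    lung_mask = np.zeros((size, size), dtype=bool)
    for ell in lungs:
        lung_mask |= _ellipse_mask(size, *ell)
    samples = []
    for idx in range(spec.n_images):
        texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 16)
        tmax = np.abs(texture).max()
        if tmax > 0:
            texture = texture / tmax  # in [-1, 1]
        image = spec.background_level + spec.texture_amplitude * texture
        image = np.where(lung_mask, spec.lung_level + spec.texture_amplitude * texture,
                         image)
        mask = np.zeros((size, size), dtype=bool)
        k = int(rng.integers(spec.lesions[0], spec.lesions[1] + 1))
        for _ in range(k):
            r0 = float(rng.uniform(*spec.radius))
            # place the lesion centre inside a lung field, margin r0 from its rim
            cy0, cx0, a, b, th = lungs[int(rng.integers(len(lungs)))]
            shrink_a = max(a - r0, 1.0)
            shrink_b = max(b - r0, 1.0)
            t = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform())
            uu = rad * shrink_a * np.cos(t)
            vv = rad * shrink_b * np.sin(t)
            cy = cy0 + uu * np.sin(th) + vv * np.cos(th)
            cx = cx0 + uu * np.cos(th) - vv * np.sin(th)
            axis_ratio = float(rng.uniform(0.6, 1.0))
            theta = float(rng.uniform(0, np.pi))
            # low-order harmonics, amplitudes capped so the radius stays positive
            harm = [
                (spec.boundary_wobble * float(rng.uniform(-1, 1)) / m, float(rng.uniform(0, 2 * np.pi)))
                for m in (2, 3, 4)
            ]
            mask |= _lesion_support(size, cy, cx, r0, axis_ratio, theta, harm)
        image = np.where(mask, spec.lung_level + spec.lesion_contrast + spec.texture_amplitude * texture, image)
        if spec.noise_sd > 0:
            image = image + spec.noise_sd * rng.standard_normal((size, size))
        image = np.clip(image, 0.0, 1.0).astype(np.float32)
        samples.append(
            SegSample(
                image=np.repeat(image[:, :, None], 3, axis=2),
                mask=mask.astype(np.uint8),
                id=f"phantom_{idx:04d}",
            )
        )
    return samples


def foreground_fraction_bounds(spec: PhantomSpec) -> tuple[float, float]:
    """Analytic per-image bounds on the mask foreground fraction.

    Lower bound: one minimally-sized lesion shrunk by the worst-case
    boundary perturbation and axis ratio; upper bound: the maximum lesion
    count at maximal radius and perturbation (ignoring overlap and lung-rim
    clipping, which only lower the true fraction).
    """
    wob = spec.boundary_wobble * (1 / 2 + 1 / 3 + 1 / 4)
    area_min = np.pi * (spec.radius[0] * (1 - wob)) ** 2 * 0.6
    area_max = np.pi * (spec.radius[1] * (1 + wob)) ** 2
    return (
        spec.lesions[0] * area_min / spec.size**2,
        spec.lesions[1] * area_max / spec.size**2,
    )


def write_corpus(
    samples: list[SegSample], out_dir, val_fraction: float = 0.1
) -> Path:
    """Write PNG image/mask pairs plus a manifest CSV; returns manifest path.

    The last ``val_fraction`` of samples (in generation order) form the
    validation split.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    n_val = int(round(len(samples) * val_fraction))
    rows = []
    for i, s in enumerate(samples):
        img_rel = f"images/{s.id}.png"
        msk_rel = f"masks/{s.id}.png"
        Image.fromarray(np.rint(s.image * 255).astype(np.uint8)).save(out / img_rel)
        Image.fromarray(s.mask, mode="L").save(out / msk_rel)
        rows.append(
            {
                "image_path": img_rel,
                "mask_path": msk_rel,
                "split": "val" if i >= len(samples) - n_val else "train",
            }
        )
    manifest = out / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
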