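"""Seeded synthetic CT head phantoms with paired lesion masks.

Each phantom slice emulates the statistical shape of an axial head CT in
normalised [0, 1] intensity units: a dark background, a bright elliptical
skull ring (~0.95), mid-intensity brain parenchyma (~0.45) carrying smooth
low-frequency texture, and one or more hyperdense haemorrhage blobs placed
strictly inside the brain at a small, configurable contrast above the
parenchyma, plus additive Gaussian acquisition noise.  Lesions are ellipses
deformed by a low-order radial harmonic, spanning few-pixel "tiny" lesions
to larger bleeds, and the ground-truth mask is the exact union of their
supports — so lesion pixels occupy only a few percent of the image,
reproducing the severe class imbalance of clinical slices.

The module also provides the paired augmentation pipeline used during
training: random rotation, flips, scaling, contrast transformation and
noise, with geometric transforms applied identically to image (bilinear)
and mask (nearest-neighbour, so masks stay exactly binary).

Everything is deterministic given a configuration and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GenerationError

__all__ = [
    "PhantomConfig", "SlicePair", "generate_slice", "generate_dataset",
    "augment", "rotate_pair", "flip_pair", "scale_pair",
    "adjust_contrast", "add_noise", "AUGMENT_OPS",
]

PARENCHYMA_INTENSITY = 0.45
SKULL_INTENSITY = 0.95
TEXTURE_AMPLITUDE = 0.03


@dataclass
class PhantomConfig:
    """Phantom generator settings (intensities in normalised [0, 1] units).

    ``n_lesions`` and ``lesion_radius`` are inclusive [min, max] ranges
    sampled uniformly per slice/lesion; radii down to 2 px cover the tiny
    low-contrast lesions the clinical regime is hardest on.
    ``lesion_contrast`` is the lesion-minus-parenchyma intensity gap.
    ``radial_perturbation`` bounds the harmonic boundary deformation (0
    gives exact discs, useful for area-bound checks).
    """

    size: int = 128
    n_lesions: tuple[int, int] = (1, 3)
    lesion_radius: tuple[float, float] = (2.0, 7.0)
    lesion_contrast: tuple[float, float] = (0.08, 0.25)
    noise_sigma: float = 0.02
    skull_thickness: int = 5
    radial_perturbation: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.size < 32 or self.size % 32:
            raise ConfigurationError(
                f"size must be a positive multiple of 32, got {self.size}")
        if self.n_lesions[0] < 0 or self.n_lesions[1] < self.n_lesions[0]:
            raise ConfigurationError(f"invalid n_lesions range {self.n_lesions}")
        if self.lesion_radius[0] < 1 or self.lesion_radius[1] < self.lesion_radius[0]:
            raise ConfigurationError(f"invalid lesion_radius range {self.lesion_radius}")
        if self.lesion_contrast[0] <= 0 or self.lesion_contrast[1] < self.lesion_contrast[0]:
            raise ConfigurationError(
                f"lesion_contrast min must be positive, got {self.lesion_contrast}")
        if self.noise_sigma < 0:
            raise ConfigurationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.skull_thickness < 1:
            raise ConfigurationError("skull_thickness must be >= 1")
        if self.radial_perturbation < 0:
            raise ConfigurationError("radial_perturbation must be >= 0")


@dataclass
class SlicePair:
    """One grayscale slice with its co-registered binary lesion mask."""

    image: np.ndarray          # float in [0, 1], shape (H, W)
    mask: np.ndarray           # uint8 in {0, 1}, same shape
    slice_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.image.shape != self.mask.shape:
            raise ConfigurationError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ")


def _ellipse_interior(size: int, semi_r: float, semi_c: float) -> np.ndarray:
    rr, cc = np.mgrid[:size, :size].astype(np.float64)
    ctr = (size - 1) / 2.0
    return ((rr - ctr) / semi_r) ** 2 + ((cc - ctr) / semi_c) ** 2 <= 1.0


def _lesion_support(size: int, center: tuple[float, float], radius: float,
                    perturb: tuple[float, float, float, float]) -> np.ndarray:
    rr, cc = np.mgrid[:size, :size].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    theta = np.arctan2(dr, dc)
    a1, phi1, a2, phi2 = perturb
    boundary = radius * (1.0 + a1 * np.cos(2 * theta + phi1)
                         + a2 * np.cos(3 * theta + phi2))
    return np.hypot(dr, dc) <= boundary


def generate_slice(cfg: PhantomConfig, rng: np.random.Generator,
                   slice_id: str = "phantom-0000") -> SlicePair:
    """One phantom slice, deterministic given `cfg` and the RNG state."""
    size = cfg.size
    skull_outer_r = 0.46 * size
    skull_outer_c = 0.40 * size
    t = cfg.skull_thickness
    outer = _ellipse_interior(size, skull_outer_r, skull_outer_c)
    brain = _ellipse_interior(size, skull_outer_r - t, skull_outer_c - t)

    image = np.zeros((size, size))
    image[outer & ~brain] = SKULL_INTENSITY
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), size / 10.0)
    peak = np.abs(texture).max()
    if peak > 0:
        texture *= TEXTURE_AMPLITUDE / peak
    image[brain] = PARENCHYMA_INTENSITY + texture[brain]

    mask = np.zeros((size, size), dtype=np.uint8)
    n = int(rng.integers(cfg.n_lesions[0], cfg.n_lesions[1] + 1))
    # shrink the admissible centre region so every lesion fits strictly inside
    ctr = (size - 1) / 2.0
    placed = 0
    for _ in range(n):
        radius = rng.uniform(*cfg.lesion_radius)
        contrast = rng.uniform(*cfg.lesion_contrast)
        if cfg.radial_perturbation > 0:
            amp = cfg.radial_perturbation
            perturb = (rng.uniform(0, amp / 2), rng.uniform(0, 2 * np.pi),
                       rng.uniform(0, amp / 2), rng.uniform(0, 2 * np.pi))
        else:
            perturb = (0.0, 0.0, 0.0, 0.0)
        reach = radius * (1.0 + cfg.radial_perturbation) + 2.0
        semi_r = skull_outer_r - t - reach
        semi_c = skull_outer_c - t - reach
        if semi_r <= 0 or semi_c <= 0:
            raise GenerationError(
                f"lesion of radius {radius:.1f} px cannot fit inside a brain of "
                f"size {size} with skull_thickness {t}")
        for attempt in range(100):
            u, v = rng.uniform(-1, 1), rng.uniform(-1, 1)
            if u * u + v * v > 1:
                continue
            center = (ctr + u * semi_r, ctr + v * semi_c)
            support = _lesion_support(size, center, radius, perturb)
            if support.any() and (support <= brain).all():
                image[support] += contrast
                mask[support] = 1
                placed += 1
                break
        else:
            raise GenerationError(
                "could not place a lesion inside the brain after 100 attempts; "
                f"lesion_radius {cfg.lesion_radius} is too large for size {size}")
    if cfg.noise_sigma > 0:
        image = image + rng.normal(0.0, cfg.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return SlicePair(image=image, mask=mask, slice_id=slice_id,
                     meta={"n_lesions": placed,
                           "lesion_area_px": int(mask.sum())})


def generate_dataset(cfg: PhantomConfig, n: int) -> list[SlicePair]:
    """`n` independent slices from a stream seeded by ``cfg.seed``."""
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    seeds = np.random.SeedSequence(cfg.seed).spawn(n)
    pairs = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        pairs.append(generate_slice(cfg, rng, slice_id=f"phantom-{cfg.seed}-{i:04d}"))
    return pairs


# -- paired augmentation ------------------------------------------------------


def rotate_pair(pair: SlicePair, angle_deg: float) -> SlicePair:
    """Rotate image (bilinear) and mask (nearest) about the centre."""
    image = ndimage.rotate(pair.image, angle_deg, reshape=False, order=1,
                           mode="constant", cval=0.0)
    mask = ndimage.rotate(pair.mask, angle_deg, reshape=False, order=0,
                          mode="constant", cval=0)
    return SlicePair(np.clip(image, 0, 1), mask, pair.slice_id, dict(pair.meta))


def flip_pair(pair: SlicePair, axis: int) -> SlicePair:
    """Mirror both image and mask along `axis` (0 vertical, 1 horizontal)."""
    return SlicePair(np.flip(pair.image, axis=axis).copy(),
                     np.flip(pair.mask, axis=axis).copy(),
                     pair.slice_id, dict(pair.meta))


def scale_pair(pair: SlicePair, factor: float) -> SlicePair:
    """Zoom by `factor` about the centre, then crop or pad back to size."""
    h, w = pair.image.shape
    image = ndimage.zoom(pair.image, factor, order=1)
    mask = ndimage.zoom(pair.mask, factor, order=0)
    out_img = np.zeros((h, w))
    out_msk = np.zeros((h, w), dtype=np.uint8)
    zh, zw = image.shape
    # centred crop (factor > 1) or centred paste (factor < 1)
    src_r, dst_r = max(0, (zh - h) // 2), max(0, (h - zh) // 2)
    src_c, dst_c = max(0, (zw - w) // 2), max(0, (w - zw) // 2)
    ch, cw = min(h, zh), min(w, zw)
    out_img[dst_r:dst_r + ch, dst_c:dst_c + cw] = image[src_r:src_r + ch, src_c:src_c + cw]
    out_msk[dst_r:dst_r + ch, dst_c:dst_c + cw] = mask[src_r:src_r + ch, src_c:src_c + cw]
    return SlicePair(np.clip(out_img, 0, 1), out_msk, pair.slice_id, dict(pair.meta))


def adjust_contrast(pair: SlicePair, gain: float) -> SlicePair:
    """Linear contrast about the image mean; the mask is untouched."""
    mu = pair.image.mean()
    image = np.clip(mu + gain * (pair.image - mu), 0.0, 1.0)
    return SlicePair(image, pair.mask, pair.slice_id, dict(pair.meta))


def add_noise(pair: SlicePair, sigma: float, rng: np.random.Generator) -> SlicePair:
    """Additive Gaussian noise on the image only."""
    image = np.clip(pair.image + rng.normal(0.0, sigma, pair.image.shape), 0.0, 1.0)
    return SlicePair(image, pair.mask, pair.slice_id, dict(pair.meta))


AUGMENT_OPS = ("rotate", "flip", "scale", "contrast", "noise")


def augment(pair: SlicePair, rng: np.random.Generator,
            ops: tuple[str, ...] = AUGMENT_OPS) -> SlicePair:
    """Randomly compose the requested augmentations on one pair.

    Magnitudes: rotation ±30°, horizontal/vertical flip, scale 0.9–1.1,
    contrast gain 0.8–1.2, noise σ = 0.02 — strong enough to deform, mild
    enough not to destroy few-pixel lesions.  Each requested op is applied
    with probability 1/2 (at least one always fires).
    """
    if not ops:
        raise ValueError("augment requires a non-empty set of operations")
    unknown = set(ops) - set(AUGMENT_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation op(s): {sorted(unknown)}")
    fire = rng.random(len(ops)) < 0.5
    if not fire.any():
        fire[rng.integers(len(ops))] = True
    out = pair
    for op, active in zip(ops, fire):
        if not active:
            continue
        if op == "rotate":
            out = rotate_pair(out, rng.uniform(-30.0, 30.0))
        elif op == "flip":
            out = flip_pair(out, axis=int(rng.integers(2)))
        elif op == "scale":
            out = scale_pair(out, rng.uniform(0.9, 1.1))
        elif op == "contrast":
            out = adjust_contrast(out, rng.uniform(0.8, 1.2))
        elif op == "noise":
            out = add_noise(out, 0.02, rng)
    return out
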