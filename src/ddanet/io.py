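"""On-disk formats: paired PNG slices, NIfTI single slices, manifests.

Conventions: images are 8-bit grayscale PNGs scaled from [0, 1]; masks are
8-bit PNGs with values {0, 255}, binarised on read at > 127; probability
maps are written as 16-bit PNGs so they can be re-thresholded downstream;
single-slice NIfTI inputs are min-max scaled to [0, 1].  Coordinates are
(row, col) with the origin at the top-left throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DimensionError, ImageFormatError
from .phantom import SlicePair

__all__ = [
    "read_slice_pair", "write_slice_pair", "write_dataset", "read_dataset",
    "write_probability_map", "read_image",
]

_GRAY_MODES = {"L", "I", "I;16", "F", "1"}


def _read_gray_png(path: Path) -> np.ndarray:
    try:
        img = Image.open(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises various decode errors
        raise ImageFormatError(f"cannot read image {path}: {exc}") from exc
    if img.mode not in _GRAY_MODES:
        raise ImageFormatError(
            f"{path} is not a grayscale image (mode {img.mode!r}); convert it "
            "to single-channel first")
    arr = np.asarray(img, dtype=np.float64)
    scale = 65535.0 if img.mode in ("I", "I;16") else 255.0
    if img.mode == "F":
        scale = max(arr.max(), 1.0)
    return arr / scale


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib
    data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
    if data.ndim != 2:
        raise DimensionError(
            f"{path} is not a single slice: squeezed shape {data.shape}")
    data = data.astype(np.float64)
    lo, hi = data.min(), data.max()
    return (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)


def read_image(path: str | Path) -> np.ndarray:
    """A single grayscale slice as float64 in [0, 1]."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return _read_nifti(path)
    return _read_gray_png(path)


def read_slice_pair(image_path: str | Path, mask_path: str | Path) -> SlicePair:
    """Load a co-registered (image, mask) pair; masks binarise at > 127/255."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    image = read_image(image_path)
    mask = read_image(mask_path)
    if image.shape != mask.shape:
        raise DimensionError(
            f"image {image.shape} and mask {mask.shape} dimensions differ "
            f"({image_path.name} vs {mask_path.name})")
    return SlicePair(image=image, mask=(mask > 127.0 / 255.0).astype(np.uint8),
                     slice_id=image_path.stem)


def write_slice_pair(pair: SlicePair, directory: str | Path) -> tuple[Path, Path]:
    """Write `<id>.png` (8-bit image) and `<id>_mask.png` ({0,255} mask)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{pair.slice_id}.png"
    msk_path = directory / f"{pair.slice_id}_mask.png"
    img8 = np.clip(np.round(pair.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(img_path)
    Image.fromarray((pair.mask * 255).astype(np.uint8), mode="L").save(msk_path)
    return img_path, msk_path


def write_probability_map(prob: np.ndarray, path: str | Path) -> Path:
    """16-bit PNG of a [0, 1] probability map."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.round(np.asarray(prob) * 65535.0), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)
    return path


def write_dataset(pairs: list[SlicePair], directory: str | Path,
                  seed: int | None = None) -> Path:
    """Write paired PNGs plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    rows = []
    for pair in pairs:
        write_slice_pair(pair, directory)
        rows.append({"slice_id": pair.slice_id,
                     "n_lesions": pair.meta.get("n_lesions", int(pair.mask.max())),
                     "lesion_area_px": pair.meta.get("lesion_area_px", int(pair.mask.sum())),
                     "seed": seed if seed is not None else ""})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(directory: str | Path) -> list[SlicePair]:
    """Load every `<id>.png` / `<id>_mask.png` pair under a directory."""
    directory = Path(directory)
    pairs = []
    for img_path in sorted(directory.glob("*.png")):
        if img_path.stem.endswith("_mask"):
            continue
        msk_path = directory / f"{img_path.stem}_mask.png"
        if not msk_path.exists():
            continue
        pairs.append(read_slice_pair(img_path, msk_path))
    if not pairs:
        raise FileNotFoundError(f"no image/mask PNG pairs found under {directory}")
    return pairs
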