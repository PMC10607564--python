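"""Grayscale image and manifest I/O.

Display artifacts go to 8-bit PNG (rounded); metric-bearing intermediates
go to 32-bit float TIFF so quantization never contaminates SSIM/PSNR.
A manifest is a plain-text TSV with one row per image: path, label, seed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize


def resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize preserving the intensity range."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape == tuple(shape):
        return image
    shrinking = shape[0] < image.shape[0] or shape[1] < image.shape[1]
    return _sk_resize(image, shape, order=1, preserve_range=True,
                      anti_aliasing=shrinking)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write PNG (8-bit, rounded+clipped) or TIFF (float32) by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".png":
        data = np.clip(np.rint(image), 0, 255).astype(np.uint8)
        iio.imwrite(path, data)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        raise ValueError(f"unsupported image format: {suffix}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float64; RGB(A) inputs are averaged."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., :3].mean(axis=-1)
    return data


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "seed"], delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_kaggle_breast(root: str | Path, classes=("benign", "malignant")):
    """Optional adapter for the public breast-ultrasound folder layout.

    Expects ``root`` to contain one subfolder per class of PNG images; mask
    files (``*_mask*``) are skipped.  Never downloads anything.
    """
    root = Path(root)
    items = []
    for cls in classes:
        folder = root / cls
        if not folder.is_dir():
            raise FileNotFoundError(f"expected class folder {folder}")
        for p in sorted(folder.glob("*.png")):
            if "_mask" in p.stem:
                continue
            items.append((read_image(p), cls))
    return items
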