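"""Internal image conventions and raster I/O.

Every image inside the package is a ``float`` array of shape ``(h, w, 3)``
with values in [0, 1], RGB channel order, row-major, origin at the top-left
corner.  All file I/O converts to and from this convention (8-bit PNG on
disk).
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "as_float_image",
    "to_uint8",
    "save_png",
    "load_png",
    "rgb_to_gray",
    "downsample_mean",
    "resize_image",
    "image_grid",
]


def as_float_image(arr: np.ndarray) -> np.ndarray:
    """Coerce ``arr`` to the internal float [0,1] h x w x 3 convention."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[-1] != 3:
        raise ValueError(f"expected (h, w, 3) image, got shape {a.shape}")
    if a.dtype == np.uint8:
        a = a.astype(np.float64) / 255.0
    else:
        a = a.astype(np.float64, copy=False)
    return a


def to_uint8(img: np.ndarray) -> np.ndarray:
    a = np.clip(as_float_image(img), 0.0, 1.0)
    return np.round(a * 255.0).astype(np.uint8)


def save_png(img: np.ndarray, path: str) -> None:
    Image.fromarray(to_uint8(img), mode="RGB").save(path, format="PNG")


def load_png(path: str) -> np.ndarray:
    with Image.open(path) as im:
        return as_float_image(np.asarray(im.convert("RGB")))


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma of an internal-convention image -> (h, w) array."""
    a = as_float_image(img)
    return a[..., 0] * 0.299 + a[..., 1] * 0.587 + a[..., 2] * 0.114


def downsample_mean(plane: np.ndarray, out_size: int) -> np.ndarray:
    """Downsample a 2-D plane to ``out_size**2`` by block averaging.

    Falls back to area-style resampling when the input side is not an
    integer multiple of ``out_size``.
    """
    plane = np.asarray(plane, dtype=np.float64)
    h, w = plane.shape
    if h % out_size == 0 and w % out_size == 0:
        bh, bw = h // out_size, w // out_size
        return plane.reshape(out_size, bh, out_size, bw).mean(axis=(1, 3))
    return _sk_resize(plane, (out_size, out_size), order=1, mode="reflect",
                      anti_aliasing=True, preserve_range=True)


def resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an internal-convention image to ``size x size``."""
    a = as_float_image(img)
    if a.shape[0] == size and a.shape[1] == size:
        return a.copy()
    out = _sk_resize(a, (size, size), order=1, mode="reflect",
                     anti_aliasing=a.shape[0] > size, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def image_grid(images, ncol: int = 8, pad: int = 2, fill: float = 1.0) -> np.ndarray:
    """Tile a list of equally sized images into one inspection image."""
    images = [as_float_image(im) for im in images]
    if not images:
        raise ValueError("no images to tile")
    h, w, _ = images[0].shape
    ncol = min(ncol, len(images))
    nrow = int(np.ceil(len(images) / ncol))
    grid = np.full((nrow * (h + pad) + pad, ncol * (w + pad) + pad, 3), fill)
    for i, im in enumerate(images):
        r, c = divmod(i, ncol)
        y, x = pad + r * (h + pad), pad + c * (w + pad)
        grid[y:y + h, x:x + w] = im
    return grid
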