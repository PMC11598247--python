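"""Reading and writing images, label maps and HV maps.

Images are 8-bit RGB PNG/TIFF; label maps are 16-bit grayscale PNG or NPY;
HV maps are float32 NPY of shape H x W x 2.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
    "read_hv_map",
    "write_hv_map",
]


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image")
    return np.asarray(img, dtype=np.uint8)


def write_image(img: np.ndarray, path) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def read_label_map(path) -> np.ndarray:
    """Read an instance/class label map from 16-bit PNG or NPY."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"{path}: label maps must be integer-typed NPY")
    else:
        arr = iio.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: label maps must be single-channel")
    arr = np.asarray(arr)
    if arr.min(initial=0) < 0:
        raise ValueError(f"{path}: negative label values")
    return arr.astype(np.int32)


def write_label_map(m: np.ndarray, path) -> None:
    """Write a label map as 16-bit PNG or NPY (chosen by extension)."""
    m = np.asarray(m)
    if not np.issubdtype(m.dtype, np.integer):
        raise ValueError("label maps must be integer-typed")
    if m.min(initial=0) < 0:
        raise ValueError("negative label values")
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, m.astype(np.int32))
        return
    if m.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit image")
    iio.imwrite(path, m.astype(np.uint16))


def read_hv_map(path) -> np.ndarray:
    hv = np.load(path)
    if hv.ndim != 3 or hv.shape[2] != 2:
        raise ValueError(f"{path}: HV maps must be H x W x 2")
    return np.asarray(hv, dtype=np.float64)


def write_hv_map(hv: np.ndarray, path) -> None:
    hv = np.asarray(hv)
    if hv.ndim != 3 or hv.shape[2] != 2:
        raise ValueError("HV maps must be H x W x 2")
    np.save(path, hv.astype(np.float32))
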