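"""Volume I/O, preprocessing, and the augmentation group.

Volumes are plain numpy arrays in (z, y, x) axis order — the multi-page
TIFF stack convention, one XY slice per page.  XY-plane operations act on
the last two axes.  The seven-element augmentation set (identity, three XY
rotations, two XY mirrors, z-flip) forms a closed set under inversion and
is used both for training-time augmentation and for test-time prediction
averaging with the inverse transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from skimage import exposure

__all__ = [
    "VolumeImage", "UnsupportedFormatError", "read_stack", "write_stack",
    "preprocess", "AUGMENT_NAMES", "apply_transform", "invert_transform",
    "augment_pair", "predict_averaged",
]


class UnsupportedFormatError(ValueError):
    """Input file is not a grayscale multi-page TIFF stack."""


@dataclass
class VolumeImage:
    """A 3D grayscale intensity grid with voxel-spacing metadata.

    ``data`` is (z, y, x); ``spacing`` is the physical voxel size in µm and
    is metadata only — no operation in this package uses it numerically.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


def as_array(vol) -> np.ndarray:
    """Accept either a :class:`VolumeImage` or a bare ndarray."""
    return np.asarray(vol.data if isinstance(vol, VolumeImage) else vol)


def read_stack(path) -> VolumeImage:
    """Read a multi-page grayscale TIFF into a (z, y, x) volume.

    A single-page TIFF yields a volume with z-extent 1.  RGB(A) input is
    rejected: the pipeline is defined on scalar intensities only.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            if tf.pages[0].photometric not in (
                tifffile.PHOTOMETRIC.MINISBLACK, tifffile.PHOTOMETRIC.MINISWHITE,
            ):
                raise UnsupportedFormatError("only grayscale TIFF stacks are supported")
            data = tf.asarray()
    except tifffile.TiffFileError as exc:
        raise UnsupportedFormatError(f"not a readable TIFF: {path}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise UnsupportedFormatError(f"expected a grayscale z-stack, got shape {data.shape}")
    return VolumeImage(data=data)


def write_stack(vol, path) -> None:
    """Write a volume as a multi-page grayscale TIFF (one page per z-slice)."""
    data = as_array(vol)
    if data.ndim != 3:
        raise UnsupportedFormatError(f"expected 3D (z, y, x) data, got shape {data.shape}")
    tifffile.imwrite(path, data, photometric="minisblack")


def preprocess(vol, equalize: bool = True) -> np.ndarray:
    """Contrast-stretch and normalize a volume onto [0, 1].

    With ``equalize`` the whole volume is histogram-equalized over 256 bins
    (a global, monotone CDF remapping) before the division by 255; without
    it the intensities are simply divided by 255.
    """
    data = as_array(vol).astype(np.float64)
    if equalize:
        # equalize_hist maps intensities through the global CDF onto [0, 1];
        # the subsequent 8-bit rounding keeps the 256-level convention.
        eq = exposure.equalize_hist(data, nbins=256)
        return np.rint(eq * 255.0) / 255.0
    return data / 255.0


# name -> (axis spec applied by apply_transform, inverse name)
_TRANSFORMS = {
    "identity": ("identity", "identity"),
    "rot90_xy": ("rot90_xy", "rot-90_xy"),
    "rot-90_xy": ("rot-90_xy", "rot90_xy"),
    "rot180_xy": ("rot180_xy", "rot180_xy"),
    "mirror_h_xy": ("mirror_h_xy", "mirror_h_xy"),
    "mirror_v_xy": ("mirror_v_xy", "mirror_v_xy"),
    "flip_z": ("flip_z", "flip_z"),
}

AUGMENT_NAMES = tuple(_TRANSFORMS)


def apply_transform(vol: np.ndarray, name: str) -> np.ndarray:
    """Apply one named spatial transform to a (z, y, x) volume."""
    if name not in _TRANSFORMS:
        raise ValueError(f"unknown transform {name!r}; choose from {AUGMENT_NAMES}")
    v = np.asarray(vol)
    if name == "identity":
        return v.copy()
    if name == "rot90_xy":
        return np.rot90(v, 1, axes=(1, 2)).copy()
    if name == "rot-90_xy":
        return np.rot90(v, -1, axes=(1, 2)).copy()
    if name == "rot180_xy":
        return np.rot90(v, 2, axes=(1, 2)).copy()
    if name == "mirror_h_xy":
        return v[:, :, ::-1].copy()
    if name == "mirror_v_xy":
        return v[:, ::-1, :].copy()
    if name == "flip_z":
        return v[::-1].copy()
    raise AssertionError(name)


def invert_transform(vol: np.ndarray, name: str) -> np.ndarray:
    """Apply the inverse of a named transform."""
    if name not in _TRANSFORMS:
        raise ValueError(f"unknown transform {name!r}; choose from {AUGMENT_NAMES}")
    return apply_transform(vol, _TRANSFORMS[name][1])


def augment_pair(image, label, transforms) -> list[tuple[np.ndarray, np.ndarray]]:
    """Apply each named transform identically to an (image, label) pair."""
    img = as_array(image)
    lab = as_array(label)
    if img.shape != lab.shape:
        raise ValueError(f"image/label shape mismatch: {img.shape} vs {lab.shape}")
    return [(apply_transform(img, t), apply_transform(lab, t)) for t in transforms]


def predict_averaged(predict_fn, vol, transforms=AUGMENT_NAMES) -> np.ndarray:
    """Test-time augmented prediction.

    Runs ``predict_fn`` on the volume under each transform (the identity is
    always included), maps every probability map back through the inverse
    transform, and averages.
    """
    v = as_array(vol)
    names = ["identity"] + [t for t in transforms if t != "identity"]
    acc = np.zeros(v.shape, dtype=np.float64)
    for t in names:
        tv = apply_transform(v, t)
        pred = np.asarray(predict_fn(tv))
        if pred.shape != tv.shape:
            raise ValueError("predict_fn must be shape-preserving")
        acc += invert_transform(pred, t)
    return acc / len(names)
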