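"""Reading, writing and normalizing microscopy images and label images.

Conventions shared by every module in the package:

* arrays are 2D, row-major, 0-based, indexed ``(row, col)``;
* intensity images are ``float64`` in arbitrary units on read and in
  ``[0, 1]`` after :func:`normalize`;
* label images are non-negative integers where 0 marks watershed-line /
  background pixels and each positive label is one 4-connected cell.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
import imageio.v3 as iio
from scipy import ndimage as ndi

__all__ = [
    "read_image",
    "normalize",
    "read_labels",
    "write_labels",
    "validate_labels",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class IntensityImage:
    """A single-channel image plus the bit depth it was read from.

    Thin record: most of the package passes bare ``float64`` arrays around;
    this wrapper only survives the I/O boundary where the source bit depth
    matters (e.g. for writing previews back out).
    """

    pixels: np.ndarray
    source_dtype: np.dtype | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_image(path: str | os.PathLike) -> IntensityImage:
    """Read a TIFF or PNG micrograph as a 2D float image.

    Color images are converted to grayscale by the unweighted channel mean.
    Multi-page TIFFs (z-stacks) are rejected: projection is a preprocessing
    step outside this package.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read image: no such file {path!r}")
    try:
        if path.lower().endswith((".tif", ".tiff")):
            with tifffile.TiffFile(path) as tf:
                if len(tf.pages) > 1:
                    raise ValueError(
                        f"{path!r}: z-stacks unsupported; project first"
                    )
                arr = tf.asarray()
        else:
            arr = iio.imread(path)
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    src_dtype = arr.dtype
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[0] > 4 and arr.shape[-1] <= 4:
            arr = arr.mean(axis=-1)  # H x W x C
        elif arr.shape[0] <= 4:
            arr = arr.mean(axis=0)  # C x H x W
        else:
            raise ValueError(f"{path!r}: z-stacks unsupported; project first")
    if arr.ndim != 2:
        raise ValueError(f"{path!r}: expected a 2D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path!r}: image contains NaN/Inf pixels")
    return IntensityImage(pixels=arr, source_dtype=src_dtype)


def normalize(
    img: np.ndarray | IntensityImage,
    low_pct: float = 1.0,
    high_pct: float = 99.9,
) -> np.ndarray:
    """Percentile-rescale an image to [0, 1].

    The ``low_pct`` percentile maps to 0 and the ``high_pct`` percentile to
    1; values outside are clipped. Percentile (rather than min/max) scaling
    is robust to hot pixels. A constant image maps to all zeros.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(
            f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})"
        )
    pixels = img.pixels if isinstance(img, IntensityImage) else np.asarray(img)
    pixels = pixels.astype(np.float64, copy=False)
    lo, hi = np.percentile(pixels, [low_pct, high_pct])
    if hi <= lo:
        return np.zeros_like(pixels)
    return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)


def read_labels(path: str | os.PathLike) -> np.ndarray:
    """Read an integer label TIFF (0 = watershed line / background)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read labels: no such file {path!r}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path!r}: label image must be 2D, got {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.round(arr)):
            raise ValueError(f"{path!r}: label image has non-integer pixel values")
        arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise ValueError(f"{path!r}: label image has negative labels")
    return arr.astype(np.int32)


def write_labels(path: str | os.PathLike, labels: np.ndarray) -> None:
    """Write a label image as a 32-bit integer TIFF (lossless round-trip)."""
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label image must have an integer dtype")
    if labels.max(initial=0) > np.iinfo(np.int32).max:
        raise ValueError("labels exceed int32 range")
    tifffile.imwrite(os.fspath(path), labels.astype(np.int32))


def validate_labels(labels: np.ndarray) -> list[str]:
    """Check the label-image invariants; return a list of violation messages.

    Checked: non-negative integers; each positive label occupies exactly one
    4-connected component; distinct labels never touch 4-connectedly (the
    watershed-line convention of at least one 0 pixel between cells).
    """
    problems: list[str] = []
    labels = np.asarray(labels)
    if labels.ndim != 2:
        return [f"label image must be 2D, got shape {labels.shape}"]
    if not np.issubdtype(labels.dtype, np.integer):
        problems.append(f"dtype {labels.dtype} is not integer")
        if not np.all(labels == np.round(labels)):
            return problems
        labels = labels.astype(np.int64)
    if labels.min() < 0:
        problems.append("negative labels present")
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        _, n = ndi.label(labels == lab, structure=_FOUR_CONN)
        if n != 1:
            problems.append(f"label {lab} splits into {n} 4-connected components")
    # adjacent distinct positive labels (4-connectivity) violate the
    # watershed-line convention
    for axis in (0, 1):
        a = np.take(labels, range(labels.shape[axis] - 1), axis=axis)
        b = np.take(labels, range(1, labels.shape[axis]), axis=axis)
        bad = (a > 0) & (b > 0) & (a != b)
        if bad.any():
            problems.append(
                f"{int(bad.sum())} pairs of touching distinct labels along axis {axis}"
            )
    return problems
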