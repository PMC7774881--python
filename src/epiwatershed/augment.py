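"""Paired geometric/photometric augmentation of an image and its targets.

The same sampled geometric transform (rotation, translation, zoom, flips)
is applied to the input image and to all seven target planes; intensity
jitter touches the input only. Flips and right-angle rotations are applied
as exact array operations, so they commute exactly with target encoding;
arbitrary angles go through an affine warp with bilinear interpolation for
the image and nearest-neighbour for the targets (keeping one-pixel
boundaries one pixel wide, at the price of some aliasing).

Out-of-field pixels are filled respecting channel polarity — 0 for the
image and mask/seed channels, 1 for the negative channels — so the
complement invariants of a TargetStack survive any transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .targets import CHANNEL_FILL, TargetStack

__all__ = ["AugmentSpec", "SampledTransform", "sample_transform", "apply_paired"]


@dataclass
class AugmentSpec:
    """Parameter ranges the per-sample transforms are drawn from."""

    rotation_deg: tuple[float, float] = (0.0, 360.0)
    translation_frac: tuple[float, float] = (-0.1, 0.1)
    zoom: tuple[float, float] = (0.8, 1.2)
    flip_h: float = 0.5
    flip_v: float = 0.5
    intensity_jitter: tuple[float, float] = (-0.1, 0.1)

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "translation_frac", "zoom", "intensity_jitter"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered, got ({lo}, {hi})")
        for name in ("flip_h", "flip_v"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass
class SampledTransform:
    """One concrete draw from an AugmentSpec."""

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)  # (rows, cols), pixels/frac applied
    zoom: float = 1.0
    flip_h: bool = False
    flip_v: bool = False
    jitter: float = 0.0

    @property
    def is_identity_geometry(self) -> bool:
        return (
            self.rotation_deg % 360 == 0
            and self.translation == (0.0, 0.0)
            and self.zoom == 1.0
            and not self.flip_h
            and not self.flip_v
        )


def sample_transform(
    spec: AugmentSpec, rng: np.random.Generator | int
) -> SampledTransform:
    """Draw each parameter uniformly from its range; deterministic in rng."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return SampledTransform(
        rotation_deg=float(rng.uniform(*spec.rotation_deg)),
        translation=(
            float(rng.uniform(*spec.translation_frac)),
            float(rng.uniform(*spec.translation_frac)),
        ),
        zoom=float(rng.uniform(*spec.zoom)),
        flip_h=bool(rng.random() < spec.flip_h),
        flip_v=bool(rng.random() < spec.flip_v),
        jitter=float(rng.uniform(*spec.intensity_jitter)),
    )


def _warp_plane(
    plane: np.ndarray, t: SampledTransform, order: int, cval: float
) -> np.ndarray:
    """Rotation/zoom/translation as one affine resample about the center."""
    h, w = plane.shape
    rot = t.rotation_deg % 360
    zoomed = t.zoom != 1.0
    shifted = t.translation != (0.0, 0.0)
    if rot in (0.0, 90.0, 180.0, 270.0) and not zoomed and not shifted:
        # exact lossless path (square arrays only for 90/270)
        k = int(rot // 90)
        if k == 0 or h == w or k == 2:
            return np.rot90(plane, k=k) if k else plane
    theta = np.deg2rad(rot)
    c, s = np.cos(theta), np.sin(theta)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([t.translation[0] * h, t.translation[1] * w])
    # output->input mapping: undo translation, rotation, zoom about center
    mat = np.array([[c, -s], [s, c]]) / t.zoom
    offset = center - mat @ (center + shift)
    return ndi.affine_transform(
        plane, mat, offset=offset, order=order, mode="constant", cval=cval,
        prefilter=order > 1,
    )


def apply_paired(
    t: SampledTransform,
    image: np.ndarray,
    targets: TargetStack,
) -> tuple[np.ndarray, TargetStack]:
    """Apply the identical geometric transform to image and all 7 targets.

    The image is resampled bilinearly and jittered multiplicatively; the
    targets use nearest-neighbour resampling and are re-binarized, with
    per-role out-of-field fill values.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != targets.shape:
        raise ValueError(
            f"image shape {image.shape} != target shape {targets.shape}"
        )
    out_img = _warp_plane(image, t, order=1, cval=0.0)
    planes = []
    for ch, fill in zip(targets.channels, CHANNEL_FILL):
        warped = _warp_plane(np.asarray(ch, dtype=np.float64), t, order=0, cval=fill)
        planes.append((warped >= 0.5).astype(np.float64))
    if t.flip_h:
        out_img = out_img[:, ::-1]
        planes = [p[:, ::-1] for p in planes]
    if t.flip_v:
        out_img = out_img[::-1, :]
        planes = [p[::-1, :] for p in planes]
    out_img = np.clip(out_img * (1.0 + t.jitter), 0.0, None)
    out_targets = TargetStack(
        channels=np.ascontiguousarray(np.stack(planes)), flavor=targets.flavor
    )
    return np.ascontiguousarray(out_img), out_targets
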