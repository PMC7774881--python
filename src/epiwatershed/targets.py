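"""Seven-channel target codec: the core of the segmentation paradigm.

A curated watershed label image is *encoded* into seven aligned training
targets that an encoder-decoder network learns to reproduce:

====  ===========  ====================================================
 #    role         content
====  ===========  ====================================================
 0    mask         the one-pixel watershed boundary mask itself
 1    mask_dil1    the mask after one 3x3 binary dilation
 2    mask_dil2    the mask after two 3x3 binary dilations
 3    neg_dil1     pixelwise complement of mask_dil1
 4    neg_dil2     pixelwise complement of mask_dil2
 5    seeds        one size-scaled seed region per cell, strictly interior
 6    neg_seeds    pixelwise complement of seeds
====  ===========  ====================================================

At inference time the seven predicted probability maps are *decoded*:
each map is turned into a one-pixel watershed mask (boundary-type channels
by ridge flooding, seed-type channels by seeded flooding), the seven masks
are averaged, thresholded, and re-closed into a single refined boundary
mask — the pipeline's final segmentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .watershed import (
    FOUR_CONN,
    boundary_to_labels,
    close_candidate_boundary,
    labels_to_boundary,
    seeded_watershed,
    watershed_lines,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNEL_ROLES",
    "TargetStack",
    "FusionConfig",
    "encode_targets",
    "seed_radius",
    "targets_to_masks",
    "fuse_masks",
    "refined_mask_to_labels",
    "decode_targets",
]

CHANNEL_ROLES = (
    "mask",
    "mask_dil1",
    "mask_dil2",
    "neg_dil1",
    "neg_dil2",
    "seeds",
    "neg_seeds",
)

#: fill value used for out-of-field pixels, per channel (negatives are 1)
CHANNEL_FILL = (0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 1.0)

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class TargetStack:
    """Seven aligned planes: binary targets or probability predictions."""

    channels: np.ndarray  # (7, H, W)
    flavor: str = "target"  # {"target", "prediction"}
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != 7:
            raise ValueError(
                f"TargetStack needs shape (7, H, W), got {self.channels.shape}"
            )
        if self.flavor not in ("target", "prediction"):
            raise ValueError(f"unknown flavor {self.flavor!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[CHANNEL_ROLES.index(role)]

    def validate(self) -> list[str]:
        """Target-flavor structural invariants; returns violation messages."""
        problems: list[str] = []
        c = self.channels
        if np.isnan(c).any() or np.isinf(c).any():
            problems.append("non-finite values")
        if c.min() < 0 or c.max() > 1:
            problems.append("values outside [0, 1]")
        if self.flavor == "target":
            if not np.array_equal(np.unique(c), np.unique(c.astype(bool).astype(c.dtype))):
                if not np.all(np.isin(c, [0, 1])):
                    problems.append("target channels are not binary")
            for neg, pos in ((3, 1), (4, 2), (6, 5)):
                if not np.array_equal(c[neg], 1 - c[pos]):
                    problems.append(
                        f"channel {neg} is not the exact complement of channel {pos}"
                    )
            m, d1, d2 = c[0] > 0, c[1] > 0, c[2] > 0
            if (m & ~d1).any() or (d1 & ~d2).any():
                problems.append("dilation containment mask <= dil1 <= dil2 violated")
            if ((c[5] > 0) & d2).any():
                problems.append("seeds overlap mask_dil2")
        return problems


@dataclass
class FusionConfig:
    """How seven predicted maps become one refined boundary mask.

    threshold:
        Vote fraction above which a pixel is candidate boundary; 0.5 is a
        strict majority of the seven masks.
    seed_binarize_level:
        Probability level at which the two seed channels are binarized
        before seeded flooding.
    min_region_px:
        Complement regions of the fused mask at or below this area are
        absorbed into the boundary; no epithelial cell is a few pixels
        large, but wedged junction pixels and vote noise can leave such
        fragments.
    boundary_channel_weights:
        Per-mask weights for the average (default: all equal).
    h_min:
        h-minima suppression depth used when flooding smooth probability
        maps; shallow spurious minima below this depth do not seed basins.
        Binary masks (basin depth 1) are unaffected.
    """

    threshold: float = 0.5
    seed_binarize_level: float = 0.5
    boundary_channel_weights: tuple[float, ...] = (1.0,) * 7
    h_min: float = 0.02
    min_region_px: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0 < self.seed_binarize_level < 1):
            raise ValueError("seed_binarize_level must lie in (0, 1)")
        if len(self.boundary_channel_weights) != 7:
            raise ValueError("need exactly 7 channel weights")
        if any(w < 0 for w in self.boundary_channel_weights):
            raise ValueError("channel weights must be >= 0")


def seed_radius(area: float, c: float = 0.2) -> int:
    """Seed radius law: r = max(1, floor(c * sqrt(area)))."""
    return max(1, math.floor(c * math.sqrt(area)))


def encode_targets(labels: np.ndarray, seed_scale: float = 0.2) -> TargetStack:
    """Encode a label image into the seven binary training targets.

    Seeds are built from the cell's Euclidean distance transform: the seed
    of a cell with max interior distance ``d`` and radius ``r = seed_radius
    (area)`` is the region ``{EDT >= max(d - r, 3)}`` — the inscribed
    disk-like core of radius ~``r``, guaranteed at least 3 px away from the
    boundary so it never touches ``mask_dil2``. The construction is a pure
    function of the distance transform, so it commutes exactly with flips
    and right-angle rotations. Cells too small to host such a core degrade
    to their single farthest-interior pixel plateau; cells where even that
    lies inside ``mask_dil2`` are reported in the stack's ``warnings``.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label image must be 2D")
    mask = labels_to_boundary(labels).astype(np.float64)
    dil1 = ndi.binary_dilation(mask > 0, structure=_SQUARE3).astype(np.float64)
    dil2 = ndi.binary_dilation(dil1 > 0, structure=_SQUARE3).astype(np.float64)

    seeds = np.zeros(labels.shape, dtype=np.float64)
    warnings: list[str] = []
    # distance to any non-cell pixel (boundary/background and image border)
    interior = (labels > 0) & ~(mask > 0)
    edt = ndi.distance_transform_edt(interior)
    objects = ndi.find_objects(labels.astype(np.int64))
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        cell = labels[sl] == lab
        d = np.where(cell, edt[sl], 0.0)
        d_max = d.max()
        area = int(cell.sum())
        r = seed_radius(area)
        level = max(d_max - r, 3.0)
        core = d >= level
        if not core.any():
            # too small for a clearance-3 core: fall back to the farthest
            # interior plateau (still equivariant: argmax set of the EDT)
            if d_max > 0:
                core = cell & (d == d_max)
            else:
                core = _center_pixel(cell)
            if (core & (dil2[sl] > 0)).any():
                warnings.append(
                    f"cell {lab}: seed cannot clear mask_dil2 "
                    f"(max boundary clearance {d_max:.2f} px)"
                )
        if core.sum() > 1:
            # keep one component (largest, raster order on ties) so each
            # cell contributes exactly one seed
            comp, n = ndi.label(core, structure=FOUR_CONN)
            if n > 1:
                sizes = ndi.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
                core = comp == (int(np.argmax(sizes)) + 1)
        seeds[sl][core] = 1.0

    channels = np.stack([
        mask, dil1, dil2, 1.0 - dil1, 1.0 - dil2, seeds, 1.0 - seeds,
    ])
    stack = TargetStack(channels=channels, flavor="target", warnings=warnings)
    return stack


def _center_pixel(cell: np.ndarray) -> np.ndarray:
    """First pixel of a cell in raster order, as a boolean mask."""
    out = np.zeros_like(cell, dtype=bool)
    idx = np.argwhere(cell)
    if len(idx):
        out[tuple(idx[0])] = True
    return out


#: weight of the ridge-medial tie-break relative to the probability scale
_RIDGE_DELTA = 1e-3


def _ridge_height(prob: np.ndarray, level: float = 0.5) -> np.ndarray:
    """Height map for ridge flooding with a medial-axis tie-break.

    Inside the super-threshold boundary band the probability is lifted by a
    tiny multiple of the distance to the band's edge, so that flooding from
    both sides meets exactly on the band's medial line (for a binary mask:
    on the original one-pixel boundary it was dilated from). The lift is
    capped far below any meaningful probability difference.
    """
    band = prob >= level
    if not band.any() or band.all():
        return prob
    d = ndi.distance_transform_edt(band)
    return prob + _RIDGE_DELTA * np.minimum(d, 10.0)


def _band_to_mask(prob: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Mask for a dilated-boundary probability map.

    The dilated channels predict thick bands, which binarize into robustly
    closed curves; the band's medial line (via the re-closure watershed) is
    then the one-pixel mask. Exact for binary dilated targets. If nothing
    exceeds the binarization level the channel degrades to ridge flooding
    of the raw probabilities.
    """
    band = prob >= 0.5
    if band.any() and not band.all():
        return labels_to_boundary(close_candidate_boundary(band))
    return watershed_lines(_ridge_height(prob), h_min=cfg.h_min)


def _mean_boundary_probability(channels: np.ndarray) -> np.ndarray:
    """Boundary-oriented average of the five watershed-like channels."""
    return (
        channels[0] + channels[1] + channels[2]
        + (1.0 - channels[3]) + (1.0 - channels[4])
    ) / 5.0


def targets_to_masks(stack: TargetStack, cfg: FusionConfig | None = None) -> list[np.ndarray]:
    """Turn the seven predicted maps into seven one-pixel watershed masks.

    Boundary-type channels (mask, dil1, dil2) are flooded directly as
    height maps; negative channels are inverted first. Each seed channel is
    binarized, then drives a seeded flooding of the mean boundary
    probability, whose region outlines give the mask. A seed channel left
    empty after binarization falls back to unseeded flooding of the mean
    boundary probability (logged, never silent).
    """
    cfg = cfg or FusionConfig()
    c = np.asarray(stack.channels, dtype=np.float64)
    mean_boundary = _mean_boundary_probability(c)
    masks: list[np.ndarray] = [
        watershed_lines(_ridge_height(c[0]), h_min=cfg.h_min)
    ]
    for i in (1, 2, 3, 4):
        prob = 1.0 - c[i] if i in (3, 4) else c[i]
        masks.append(_band_to_mask(prob, cfg))
    for i, invert in ((5, False), (6, True)):
        prob = 1.0 - c[i] if invert else c[i]
        seeds = prob >= cfg.seed_binarize_level
        if seeds.any():
            lab = seeded_watershed(mean_boundary, seeds)
            masks.append(labels_to_boundary(lab))
        else:
            logger.warning(
                "channel %d (%s): no seeds above %.2f; falling back to "
                "unseeded flooding of the mean boundary probability",
                i, CHANNEL_ROLES[i], cfg.seed_binarize_level,
            )
            masks.append(watershed_lines(mean_boundary, h_min=cfg.h_min))
    return masks


def fuse_masks(masks: list[np.ndarray], cfg: FusionConfig | None = None) -> np.ndarray:
    """Average seven binary masks, threshold, and re-close into one mask.

    The vote is tolerant to one-pixel line jitter: each mask supports every
    pixel within one pixel of its boundary (3x3 dilation), because seven
    independent watershed decodings of the same tissue route equivalent
    lines with +-1 px discretization differences and a strictly pixelwise
    vote would open spurious gaps. Pixels whose weighted vote exceeds
    ``cfg.threshold`` form the candidate band, which is then thinned back
    to its one-pixel medial line by a seeded watershed of the band's
    interior distance transform (markers = 4-connected regions of the
    candidate's complement), yielding a valid closed partition.
    """
    cfg = cfg or FusionConfig()
    if len(masks) != 7:
        raise ValueError(f"expected 7 masks, got {len(masks)}")
    arr = np.stack(
        [
            ndi.binary_dilation(np.asarray(m) > 0, structure=_SQUARE3).astype(
                np.float64
            )
            for m in masks
        ]
    )
    if arr.ndim != 3:
        raise ValueError("masks must be 2D and same shape")
    w = np.asarray(cfg.boundary_channel_weights, dtype=np.float64)
    if w.sum() <= 0:
        raise ValueError("at least one fusion weight must be positive")
    vote = np.tensordot(w, arr, axes=1) / w.sum()
    candidate = vote > cfg.threshold
    if not candidate.any() or candidate.all():
        return candidate
    # re-skeletonize/re-close: basins grown from the candidate's complement
    # meet on the candidate's medial line, restoring a one-pixel partition
    labels = close_candidate_boundary(candidate)
    dropped = np.zeros(labels.shape, dtype=bool)
    if cfg.min_region_px > 0 and labels.max() > 0:
        sizes = ndi.sum_labels(
            np.ones_like(labels), labels, index=np.arange(1, labels.max() + 1)
        )
        tiny = np.flatnonzero(np.atleast_1d(sizes) <= cfg.min_region_px) + 1
        if tiny.size:
            dropped = np.isin(labels, tiny)
            labels[dropped] = 0
    return labels_to_boundary(labels) | dropped


def refined_mask_to_labels(boundary: np.ndarray) -> np.ndarray:
    """Final label image of a refined mask (delegates to boundary_to_labels)."""
    return boundary_to_labels(boundary)


def decode_targets(stack: TargetStack, cfg: FusionConfig | None = None) -> np.ndarray:
    """Full decode: seven maps -> seven masks -> fused mask -> label image."""
    cfg = cfg or FusionConfig()
    masks = targets_to_masks(stack, cfg)
    fused = fuse_masks(masks, cfg)
    return refined_mask_to_labels(fused)
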