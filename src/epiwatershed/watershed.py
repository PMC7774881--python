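"""Watershed primitives shared by target encoding and prediction fusion.

Conventions (used consistently across the package):

* cells are **4-connected** regions of positive labels;
* boundary lines are one pixel wide and may run 8-connectedly (a diagonal
  line still separates 4-connected regions);
* the image border is treated as boundary, so cells touching the edge of
  the field are closed (``close_border=True`` everywhere by default).

The flooding itself is scikit-image's priority-queue watershed, which is
deterministic: ties in height are broken by insertion order, i.e. raster
order of the first flooded pixel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima
from skimage.segmentation import watershed as _skimage_watershed

__all__ = [
    "watershed_lines",
    "seeded_watershed",
    "labels_to_boundary",
    "boundary_to_labels",
    "close_candidate_boundary",
    "validate_boundary",
]

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _frame_mask(shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def watershed_lines(
    height_map: np.ndarray,
    h_min: float = 0.0,
    close_border: bool = True,
) -> np.ndarray:
    """One-pixel watershed lines of flooding ``height_map`` from its minima.

    Parameters
    ----------
    height_map:
        Finite 2D array; boundaries are its ridges.
    h_min:
        Optional h-minima suppression depth. Minima whose basin is shallower
        than ``h_min`` are merged into their neighbours before flooding;
        with the default 0 every regional minimum seeds a basin. Useful for
        decoding smooth probability maps, harmless on binary ridge images.
    close_border:
        Mark the 1-pixel image frame as boundary in the output.

    Returns
    -------
    Binary boundary mask (True = watershed line).
    """
    height_map = np.asarray(height_map, dtype=np.float64)
    if not np.all(np.isfinite(height_map)):
        raise ValueError("height map must be finite")
    if h_min > 0:
        height_map = _fill_shallow_minima(height_map, h_min)
    minima = local_minima(height_map, connectivity=1)
    markers, n = ndi.label(minima, structure=FOUR_CONN)
    if n <= 1:  # zero or one basin: no internal lines
        lines = np.zeros(height_map.shape, dtype=bool)
    else:
        labels = _skimage_watershed(
            height_map, markers=markers, connectivity=1, watershed_line=True
        )
        lines = labels == 0
        lines = _absorb_markerless_fragments(lines, markers > 0)
    if close_border:
        lines |= _frame_mask(height_map.shape)
    return lines


def _absorb_markerless_fragments(lines: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Enforce 'one regional minimum per region': fragments squeezed off on
    plateau ties contain no marker pixel and are absorbed into the lines."""
    comp, n = ndi.label(~lines, structure=FOUR_CONN)
    if n == 0:
        return lines
    has_marker = np.zeros(n + 1, dtype=bool)
    has_marker[np.unique(comp[markers])] = True
    has_marker[0] = True
    if has_marker.all():
        return lines
    return lines | ~has_marker[comp]


def _fill_shallow_minima(height_map: np.ndarray, h: float) -> np.ndarray:
    """Morphological h-minima filling: suppress basins shallower than h."""
    from skimage.morphology import reconstruction

    filled = reconstruction(height_map + h, height_map, method="erosion")
    return filled


def seeded_watershed(
    height_map: np.ndarray,
    seeds: np.ndarray,
    close_border: bool = True,
) -> np.ndarray:
    """Flood ``height_map`` from marker regions; return a label image.

    Each 4-connected component of ``seeds`` becomes one positive label
    (numbered in raster order of first pixel); watershed-line pixels are 0.
    """
    height_map = np.asarray(height_map, dtype=np.float64)
    seeds = np.asarray(seeds).astype(bool)
    if seeds.shape != height_map.shape:
        raise ValueError("seeds and height map shapes differ")
    if not seeds.any():
        raise ValueError("seeded watershed requires at least one seed")
    markers, n = ndi.label(seeds, structure=FOUR_CONN)
    if n == 1:
        labels = np.ones(height_map.shape, dtype=np.int32)
    else:
        labels = _skimage_watershed(
            height_map, markers=markers, connectivity=1, watershed_line=True
        ).astype(np.int32)
        lines = _absorb_markerless_fragments(labels == 0, seeds)
        labels[lines] = 0
    if close_border:
        labels[_frame_mask(height_map.shape)] = 0
    return labels


def labels_to_boundary(labels: np.ndarray, close_border: bool = True) -> np.ndarray:
    """Boundary mask of a label image: 0-pixels 8-adjacent to any cell.

    With ``close_border`` the image frame is included, closing the outlines
    of cells that touch the field edge.
    """
    labels = np.asarray(labels)
    fg = labels > 0
    near_cell = ndi.binary_dilation(fg, structure=np.ones((3, 3), dtype=bool))
    boundary = (~fg) & near_cell
    if close_border:
        boundary |= _frame_mask(labels.shape)
    return boundary


def boundary_to_labels(boundary: np.ndarray) -> np.ndarray:
    """Label the 4-connected components of the boundary complement.

    Labels are consecutive positive integers in raster-scan order of each
    component's first pixel; boundary pixels stay 0.
    """
    boundary = np.asarray(boundary).astype(bool)
    labels, _ = ndi.label(~boundary, structure=FOUR_CONN)
    return labels.astype(np.int32)


def close_candidate_boundary(candidate: np.ndarray) -> np.ndarray:
    """Regularize a (possibly thick) candidate boundary set into a label image.

    The 4-connected components of the candidate's complement seed a
    watershed of the candidate's interior distance transform (zero outside
    the candidate, rising towards its centre), so basins climbing the band
    from both sides meet exactly on its medial line. Thick bands thin to
    one pixel, already-thin closed lines are reproduced exactly, and the
    output is always a valid closed partition. The operator is idempotent
    on its own output.
    """
    candidate = np.asarray(candidate).astype(bool)
    if candidate.all():
        return np.zeros(candidate.shape, dtype=np.int32)
    if not candidate.any():
        labels = np.ones(candidate.shape, dtype=np.int32)
        labels[_frame_mask(candidate.shape)] = 0
        return labels
    height = ndi.distance_transform_edt(candidate)
    return seeded_watershed(height, ~candidate, close_border=True)


def validate_boundary(boundary: np.ndarray) -> list[str]:
    """Check BoundaryMask invariants; return violation messages.

    A valid mask is binary, its complement has at least one 4-connected
    region, and its lines are thin: no 3x3 block is entirely boundary
    (fat blobs of line pixels indicate an unskeletonized mask).
    """
    problems: list[str] = []
    boundary = np.asarray(boundary)
    vals = np.unique(boundary)
    if not np.all(np.isin(vals, [0, 1])):
        problems.append("mask is not binary")
        return problems
    boundary = boundary.astype(bool)
    _, n = ndi.label(~boundary, structure=FOUR_CONN)
    if boundary.size and not boundary.all() and n < 1:
        problems.append("complement has no regions")
    interior = boundary[1:-1, 1:-1]
    if interior.size:
        fat = ndi.minimum_filter(boundary.astype(np.uint8), size=3)[1:-1, 1:-1]
        if fat.any():
            problems.append(f"{int(fat.sum())} interior pixels sit in solid 3x3 boundary blocks")
    return problems
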