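"""Watershed primitives against an independently coded flooding oracle."""

import heapq

import numpy as np
import pytest
from scipy import ndimage as ndi

from epiwatershed.watershed import (
    boundary_to_labels,
    labels_to_boundary,
    seeded_watershed,
    validate_boundary,
    watershed_lines,
)

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def flooding_oracle(height, markers):
    """Literal priority-queue flooding with (height, age) ordering.

    Independent of the package (and of scikit-image): a textbook
    Vincent-Soille flood from the given marker pixels, 4-connected, pixels
    reached by two different labels become watershed line (0).
    """
    h, w = height.shape
    labels = np.zeros((h, w), dtype=np.int64)
    heap = []
    age = 0
    for r, c in np.argwhere(markers > 0):
        heapq.heappush(heap, (height[r, c], age, r, c, markers[r, c]))
        age += 1
    line = np.zeros((h, w), dtype=bool)
    while heap:
        v, _, r, c, lab = heapq.heappop(heap)
        if labels[r, c] != 0 or line[r, c]:
            continue
        neighbour_labels = set()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] > 0:
                neighbour_labels.add(labels[rr, cc])
        if len(neighbour_labels - {lab}) > 0 and markers[r, c] != lab:
            line[r, c] = True
            continue
        labels[r, c] = lab
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0 and not line[rr, cc]:
                heapq.heappush(heap, (height[rr, cc], age, rr, cc, lab))
                age += 1
    return labels, line


def double_pit(shape=(32, 32)):
    """Two Gaussian pits separated by a vertical ridge at the midline."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pit1 = np.exp(-(((rr - 16) ** 2 + (cc - 8) ** 2)) / 30.0)
    pit2 = np.exp(-(((rr - 16) ** 2 + (cc - 24) ** 2)) / 30.0)
    return 1.0 - np.maximum(pit1, pit2)


def test_constant_image_single_basin():
    lines = watershed_lines(np.zeros((16, 16)), close_border=False)
    assert not lines.any()


def test_double_pit_splits_field_like_oracle():
    height = double_pit()
    lines = watershed_lines(height, close_border=False)
    regions = ndi.label(~lines, structure=FOUR)[0]
    assert regions.max() == 2
    # the dividing line sits near the midline column
    cols = np.where(lines.any(axis=0))[0]
    assert np.all(np.abs(cols - 16) <= 1)
    # oracle comparison: same two-region membership away from the line
    from skimage.morphology import local_minima

    markers = ndi.label(local_minima(height, connectivity=1), structure=FOUR)[0]
    olab, oline = flooding_oracle(height, markers)
    both = (~lines) & (olab > 0)
    a = regions[both]
    b = olab[both]
    # membership sets agree up to label naming
    remap = {}
    agree = 0
    for x, y in zip(a, b):
        remap.setdefault(x, y)
        agree += remap[x] == y
    assert agree / len(a) > 0.99


def test_seeded_double_pit():
    height = double_pit()
    seeds = np.zeros((32, 32), dtype=bool)
    seeds[16, 8] = seeds[16, 24] = True
    lab = seeded_watershed(height, seeds, close_border=False)
    assert lab.max() == 2
    assert lab[16, 4] != lab[16, 28] and lab[16, 4] > 0


def test_single_seed_floods_everything():
    seeds = np.zeros((16, 16), dtype=bool)
    seeds[8, 8] = True
    lab = seeded_watershed(np.random.default_rng(0).random((16, 16)), seeds,
                           close_border=False)
    assert (lab == 1).all()


def test_empty_seed_image_rejected():
    with pytest.raises(ValueError):
        seeded_watershed(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))


def test_region_count_equals_minimum_count_random_maps():
    """Unseeded region count == regional-minimum count on 100 random maps."""
    from skimage.morphology import local_minima

    rng = np.random.default_rng(5)
    for _ in range(100):
        height = rng.random((32, 32))
        n_min = ndi.label(local_minima(height, connectivity=1), structure=FOUR)[1]
        lines = watershed_lines(height, close_border=False)
        n_reg = ndi.label(~lines, structure=FOUR)[1]
        assert n_reg == n_min


def test_seeded_region_count_equals_seed_count():
    rng = np.random.default_rng(6)
    for _ in range(30):
        height = rng.random((32, 32))
        seeds = rng.random((32, 32)) > 0.98
        if not seeds.any():
            continue
        n_seeds = ndi.label(seeds, structure=FOUR)[1]
        lab = seeded_watershed(height, seeds, close_border=False)
        assert len(np.unique(lab[lab > 0])) == n_seeds


def test_boundary_label_round_trip(tissue_batch):
    for sample in tissue_batch:
        L = sample.truth
        B = labels_to_boundary(L)
        L2 = boundary_to_labels(B)
        # identical region membership sets (labels may be renumbered)
        assert np.array_equal(L > 0, L2 > 0)
        for lab in np.unique(L[L > 0]):
            vals = np.unique(L2[L == lab])
            assert len(vals) == 1 and vals[0] > 0


def test_two_by_two_grid_of_squares():
    L = np.zeros((33, 33), dtype=np.int32)
    L[1:16, 1:16] = 1
    L[1:16, 17:32] = 2
    L[17:32, 1:16] = 3
    L[17:32, 17:32] = 4
    B = labels_to_boundary(L)
    assert B[16, :].all() and B[:, 16].all()  # the cross
    assert B[0, :].all() and B[:, 0].all() and B[32, :].all() and B[:, 32].all()
    L2 = boundary_to_labels(B)
    assert L2.max() == 4
    assert not validate_boundary(B)


def test_single_cell_frame_behaviour():
    L = np.zeros((10, 10), dtype=np.int32)
    L[1:-1, 1:-1] = 1
    closed = labels_to_boundary(L, close_border=True)
    frame = np.zeros((10, 10), dtype=bool)
    frame[0, :] = frame[-1, :] = True
    frame[:, 0] = frame[:, -1] = True
    assert np.array_equal(closed, frame)
    assert not labels_to_boundary(np.ones((10, 10), np.int32), close_border=False).any()


def test_seeded_watershed_on_distance_transform_recovers_truth(tissue_batch):
    """One interior seed per cell + exact EDT height -> ground truth back."""
    for sample in tissue_batch[:5]:
        L = sample.truth
        edt = ndi.distance_transform_edt(L > 0)
        seeds = np.zeros_like(L, dtype=bool)
        for lab in np.unique(L[L > 0]):
            cell = L == lab
            d = np.where(cell, edt, -1)
            seeds[np.unravel_index(np.argmax(d), d.shape)] = True
        rec = seeded_watershed(-edt, seeds)
        assert np.array_equal(rec > 0, L > 0)
        for lab in np.unique(L[L > 0]):
            assert len(np.unique(rec[L == lab])) == 1
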