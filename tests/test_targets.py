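"""Seven-channel codec: encoding structure, decoding, fusion votes."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from epiwatershed.metrics import average_precision, seg_score
from epiwatershed.targets import (
    FusionConfig,
    TargetStack,
    decode_targets,
    encode_targets,
    fuse_masks,
    refined_mask_to_labels,
    seed_radius,
    targets_to_masks,
)
from epiwatershed.watershed import labels_to_boundary

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def grid_labels(cell=16, n=2):
    """n x n grid of square cells separated by one-pixel lines."""
    size = n * cell + n + 1
    L = np.zeros((size, size), dtype=np.int32)
    lab = 1
    for i in range(n):
        for j in range(n):
            r = 1 + i * (cell + 1)
            c = 1 + j * (cell + 1)
            L[r : r + cell, c : c + cell] = lab
            lab += 1
    return L


def test_encode_grid_structure():
    L = grid_labels()
    st = encode_targets(L)
    assert st.channels.shape[0] == 7
    B = labels_to_boundary(L)
    assert np.array_equal(st["mask"] > 0, B)
    dil1 = ndi.binary_dilation(B, np.ones((3, 3), bool))
    assert np.array_equal(st["mask_dil1"] > 0, dil1)
    assert np.array_equal(st["neg_dil1"], 1 - st["mask_dil1"])
    assert np.array_equal(st["neg_dil2"], 1 - st["mask_dil2"])
    assert np.array_equal(st["neg_seeds"], 1 - st["seeds"])
    assert not st.validate()


def test_one_seed_per_cell(tissue_batch):
    for sample in tissue_batch:
        st = encode_targets(sample.truth)
        n_seeds = ndi.label(st["seeds"] > 0, structure=FOUR)[1]
        assert n_seeds == sample.truth.max()
        # every seed lies strictly inside one cell, clear of mask_dil2
        assert not ((st["seeds"] > 0) & (st["mask_dil2"] > 0)).any()


def test_seed_radius_law_and_monotonicity():
    assert seed_radius(100, c=0.2) == 2
    assert seed_radius(400, c=0.2) == 4
    assert seed_radius(1) == 1  # floor never drops below one pixel
    rng = np.random.default_rng(0)
    areas = np.sort(rng.uniform(10, 5000, 50))
    radii = [seed_radius(a) for a in areas]
    assert radii == sorted(radii)


def test_seed_scales_with_cell_size(tissue_batch):
    """Bigger cells carry bigger seeds (rank correlation on one tissue)."""
    st = encode_targets(tissue_batch[0].truth)
    L = tissue_batch[0].truth
    seed_lab, n = ndi.label(st["seeds"] > 0, structure=FOUR)
    cell_area, seed_area = [], []
    for s in range(1, n + 1):
        cells = np.unique(L[seed_lab == s])
        cell_area.append((L == cells[0]).sum())
        seed_area.append((seed_lab == s).sum())
    order = np.argsort(cell_area)
    big_half = np.array(seed_area)[order[len(order) // 2 :]]
    small_half = np.array(seed_area)[order[: len(order) // 2]]
    assert big_half.mean() >= small_half.mean()


def test_round_trip_recovers_partition(tissue_batch):
    for sample in tissue_batch:
        st = encode_targets(sample.truth)
        pred = TargetStack(st.channels.astype(float), flavor="prediction")
        L2 = decode_targets(pred)
        rep = average_precision(sample.truth, L2)
        assert rep.seg == 1.0 and rep.ap == 1.0


def test_perfect_prediction_masks_match_boundary(small_tissue):
    """Masks decoded from a perfect prediction equal the true boundary up
    to the one-pixel skeleton: exact for the undilated and seed channels,
    within one pixel (same cell correspondence, AP=1) for the dilated ones.
    """
    st = encode_targets(small_tissue.truth)
    pred = TargetStack(st.channels.astype(float), flavor="prediction")
    masks = targets_to_masks(pred)
    B = labels_to_boundary(small_tissue.truth)
    assert len(masks) == 7
    for i in (0, 5, 6):
        assert np.array_equal(masks[i], B)
    for i in (1, 2, 3, 4):
        moved = masks[i] ^ B
        assert not (moved & ~ndi.binary_dilation(B, np.ones((5, 5), bool))).any()
        from epiwatershed.watershed import boundary_to_labels

        rep = average_precision(small_tissue.truth, boundary_to_labels(masks[i]))
        assert rep.ap == 1.0


def test_inverted_negative_channel_gives_identical_mask(small_tissue):
    st = encode_targets(small_tissue.truth)
    pred = TargetStack(st.channels.astype(float), flavor="prediction")
    masks = targets_to_masks(pred)
    assert np.array_equal(masks[1], masks[3])  # dil1 vs its negative
    assert np.array_equal(masks[2], masks[4])  # dil2 vs its negative


def test_all_zero_prediction_degenerates_gracefully(caplog):
    pred = TargetStack(np.zeros((7, 32, 32)), flavor="prediction")
    with caplog.at_level("WARNING"):
        masks = targets_to_masks(pred)
    assert len(masks) == 7
    assert "no seeds" in caplog.text


def test_fusion_majority_vote(small_tissue):
    B = labels_to_boundary(small_tissue.truth)
    empty = np.zeros_like(B)
    cfg = FusionConfig(threshold=0.5)
    # unanimity
    assert np.array_equal(fuse_masks([B] * 7, cfg), B)
    # 4-of-7 passes the strict majority (4/7 > 0.5)
    fused = fuse_masks([B] * 4 + [empty] * 3, cfg)
    assert np.array_equal(fused, B)
    # 3-of-7 is rejected (3/7 < 0.5)
    fused = fuse_masks([B] * 3 + [empty] * 4, cfg)
    assert not fused.any()


def test_fusion_permutation_invariance(small_tissue):
    B = labels_to_boundary(small_tissue.truth)
    empty = np.zeros_like(B)
    masks = [B, B, empty, B, empty, B, empty]
    ref = fuse_masks(masks)
    rng = np.random.default_rng(1)
    for _ in range(5):
        perm = rng.permutation(7)
        assert np.array_equal(fuse_masks([masks[i] for i in perm]), ref)


def test_fusion_monotonicity(small_tissue):
    """Adding boundary pixels to one input never shrinks the candidate set.

    The candidate set is the thresholded mean of the (1-px-tolerant,
    i.e. dilated) masks; growing any input mask can only add support.
    """
    B = labels_to_boundary(small_tissue.truth)
    masks = [B.copy() for _ in range(7)]
    cfg = FusionConfig(threshold=0.5, min_region_px=0)

    def candidate(ms):
        votes = np.stack(
            [ndi.binary_dilation(m, np.ones((3, 3), bool)) for m in ms]
        ).astype(float)
        return votes.mean(axis=0) > cfg.threshold

    grown = [m.copy() for m in masks]
    grown[0] = ndi.binary_dilation(grown[0], np.ones((5, 5), bool))
    assert (candidate(masks) <= candidate(grown)).all()


def test_fuse_rejects_wrong_count(small_tissue):
    B = labels_to_boundary(small_tissue.truth)
    with pytest.raises(ValueError):
        fuse_masks([B] * 6)


def test_refined_mask_to_labels_delegates(small_tissue):
    B = labels_to_boundary(small_tissue.truth)
    L2 = refined_mask_to_labels(B)
    assert np.array_equal(L2 > 0, small_tissue.truth > 0)
    assert seg_score(small_tissue.truth, L2) == 1.0


def test_dilation_containment_strict(tissue_batch):
    for sample in tissue_batch[:5]:
        st = encode_targets(sample.truth)
        m, d1, d2 = st["mask"] > 0, st["mask_dil1"] > 0, st["mask_dil2"] > 0
        assert not (m & ~d1).any() and not (d1 & ~d2).any()
        assert d1.sum() > m.sum() and d2.sum() > d1.sum()


def test_fusion_config_validation():
    with pytest.raises(ValueError):
        FusionConfig(threshold=0.0)
    with pytest.raises(ValueError):
        FusionConfig(boundary_channel_weights=(1.0,) * 6)
    with pytest.raises(ValueError):
        FusionConfig(boundary_channel_weights=(-1.0,) + (1.0,) * 6)
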