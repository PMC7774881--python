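"""Tiled inference: cover arbitrarily large images with fixed-size tiles.

The image is reflect-padded and decomposed into overlapping tiles; each
tile is predicted independently and only its central crop (the tile minus
half the overlap on each inner edge) is written to the output, so every
output pixel is produced by exactly one tile and no blending seams arise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .targets import TargetStack

__all__ = ["TilingPlan", "plan_tiles", "predict_tiled"]


@dataclass
class TilingPlan:
    image_shape: tuple[int, int]
    tile_size: int
    overlap: int
    pad: tuple[int, int]  # extra rows/cols added (reflect) at the bottom/right
    windows: list[tuple[int, int, int, int]]  # (r0, c0, r1, c1), half-open
    crops: list[tuple[int, int, int, int]]  # central crop of each window

    @property
    def padded_shape(self) -> tuple[int, int]:
        return (self.image_shape[0] + self.pad[0], self.image_shape[1] + self.pad[1])

    def coverage(self) -> np.ndarray:
        """How many central crops claim each padded pixel (should be 1)."""
        cov = np.zeros(self.padded_shape, dtype=np.int32)
        for r0, c0, r1, c1 in self.crops:
            cov[r0:r1, c0:c1] += 1
        return cov


def plan_tiles(
    shape: tuple[int, int], tile_size: int = 256, overlap: int = 32
) -> TilingPlan:
    """Plan a stride ``tile_size - overlap`` tiling with central-crop stitching."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError(f"image shape {shape} is empty")
    if tile_size % 32 != 0:
        raise ValueError("tile size must be divisible by 32")
    if overlap % 2 != 0 or overlap < 0 or overlap >= tile_size / 2:
        raise ValueError("overlap must be even, >= 0 and < tile_size/2")
    stride = tile_size - overlap
    half = overlap // 2

    def axis_layout(extent: int) -> tuple[int, list[int]]:
        n = max(1, -(-(extent - overlap) // stride))  # ceil
        padded = overlap + n * stride
        return padded - extent, [i * stride for i in range(n)]

    pad_r, row_starts = axis_layout(h)
    pad_c, col_starts = axis_layout(w)
    ph, pw = h + pad_r, w + pad_c
    windows, crops = [], []
    for r0 in row_starts:
        for c0 in col_starts:
            windows.append((r0, c0, r0 + tile_size, c0 + tile_size))
            cr0 = r0 if r0 == 0 else r0 + half
            cc0 = c0 if c0 == 0 else c0 + half
            cr1 = ph if r0 == row_starts[-1] else r0 + tile_size - half
            cc1 = pw if c0 == col_starts[-1] else c0 + tile_size - half
            crops.append((cr0, cc0, cr1, cc1))
    return TilingPlan(
        image_shape=(h, w),
        tile_size=tile_size,
        overlap=overlap,
        pad=(pad_r, pad_c),
        windows=windows,
        crops=crops,
    )


def _reflect_pad(image: np.ndarray, pad_r: int, pad_c: int) -> np.ndarray:
    """Reflect-pad bottom/right, chunked so pads wider than the image work."""
    out = image
    for axis, todo in ((0, pad_r), (1, pad_c)):
        while todo > 0:
            step = min(todo, out.shape[axis] - 1)
            if step <= 0:
                spec = [(0, 0), (0, 0)]
                spec[axis] = (0, todo)
                out = np.pad(out, spec, mode="edge")
                break
            spec = [(0, 0), (0, 0)]
            spec[axis] = (0, step)
            out = np.pad(out, spec, mode="reflect")
            todo -= step
    return out


def predict_tiled(model, image: np.ndarray, plan: TilingPlan | None = None) -> TargetStack:
    """Predict a 7-channel probability stack for an image of any size.

    ``model`` needs a ``predict(tile) -> (7, tile, tile)`` method (a
    TrainedModel, or any stub with the same signature).
    """
    image = np.asarray(image, dtype=np.float64)
    if plan is None:
        tile = getattr(getattr(model, "spec", None), "input_tile", 256)
        plan = plan_tiles(image.shape, tile_size=tile, overlap=min(32, tile // 2 - 2))
    if plan.image_shape != image.shape:
        raise ValueError("plan was made for a different image shape")
    padded = _reflect_pad(image, plan.pad[0], plan.pad[1])
    out = np.zeros((7,) + plan.padded_shape, dtype=np.float64)
    for window, crop in zip(plan.windows, plan.crops):
        r0, c0, r1, c1 = window
        pred = np.asarray(model.predict(padded[r0:r1, c0:c1]))
        if pred.shape != (7, plan.tile_size, plan.tile_size):
            raise ValueError(
                f"model returned shape {pred.shape}, expected (7, tile, tile)"
            )
        gr0, gc0, gr1, gc1 = crop
        out[:, gr0:gr1, gc0:gc1] = pred[
            :, gr0 - r0 : gr1 - r0, gc0 - c0 : gc1 - c0
        ]
    h, w = plan.image_shape
    return TargetStack(channels=out[:, :h, :w], flavor="prediction")
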