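"""Automatic 3-D segmentation of the tissue of interest.

The mask is grown from a coarse single-slice seed ROI placed inside the
tissue: the magnitude volume is smoothed with a box kernel (default 7x7x7),
thresholded at ``mean - 4*SD`` of the smoothed signal inside the seed ROI, and
eroded with a six-connected structuring element to keep distance from edges.
Low-signal regions admitted into the mask would later seed streaking in the
susceptibility maps, hence the deliberately conservative threshold rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_model import BinaryMask, VoxelGrid

__all__ = [
    "SegmentationParams",
    "box_smooth",
    "roi_statistics",
    "threshold_mask",
    "erode_mask",
    "generate_segmentation",
    "fine_tune_mask",
    "box_seed_roi",
]

logger = logging.getLogger(__name__)

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # 3-D cross, 6-connected


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the automatic segmentation.

    ``box_size``: odd edge length (voxels) of the smoothing kernel.
    ``k_sigma``: threshold is ``mean - k_sigma * SD`` over the seed ROI.
    ``erosions``: six-connected erosions applied after thresholding (one more
    is added automatically, up to ``max_erosions``, if the eroded mask still
    touches the volume boundary).
    """

    box_size: int = 7
    k_sigma: float = 4.0
    erosions: int = 1
    max_erosions: int = 2
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.box_size < 3 or self.box_size % 2 == 0:
            raise ValueError("box_size must be odd and >= 3")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.erosions < 0:
            raise ValueError("erosions must be >= 0")
        if self.connectivity != 6:
            raise ValueError("only 6-connected erosion is supported")


def box_smooth(volume: np.ndarray, box_size: int) -> np.ndarray:
    """Box-mean smoothing; boundaries use nearest-edge replication."""
    if box_size < 1 or box_size % 2 == 0:
        raise ValueError("box_size must be odd")
    return ndimage.uniform_filter(np.asarray(volume, dtype=float), size=box_size, mode="nearest")


def roi_statistics(volume: np.ndarray, seed_roi: BinaryMask) -> tuple[float, float]:
    """Arithmetic mean and population SD over the seed-ROI voxels."""
    sel = np.asarray(volume, dtype=float)[seed_roi.values]
    if sel.size == 0:
        raise ValueError("seed ROI is empty")
    return float(sel.mean()), float(sel.std())


def threshold_mask(smoothed: np.ndarray, threshold: float, grid: VoxelGrid) -> BinaryMask:
    """Voxels with smoothed signal >= threshold (inclusive)."""
    return BinaryMask(values=np.asarray(smoothed) >= threshold, grid=grid)


def erode_mask(mask: BinaryMask, n: int, connectivity: int = 6) -> BinaryMask:
    """``n`` successive six-connected erosions; outside the volume counts as background."""
    if connectivity != 6:
        raise ValueError("only 6-connected erosion is supported")
    if n < 0:
        raise ValueError("n must be >= 0")
    values = mask.values
    if n > 0:
        values = ndimage.binary_erosion(values, structure=_STRUCT_6, iterations=n, border_value=0)
    if not values.any():
        raise ValueError(f"mask empty after {n} erosion(s); use a smaller erosion count")
    return BinaryMask(values=values, grid=mask.grid)


def _touches_boundary(values: np.ndarray) -> bool:
    return bool(
        values[0].any() or values[-1].any()
        or values[:, 0].any() or values[:, -1].any()
        or values[:, :, 0].any() or values[:, :, -1].any()
    )


def generate_segmentation(
    magnitude: np.ndarray,
    seed_roi: BinaryMask,
    params: SegmentationParams = SegmentationParams(),
) -> BinaryMask:
    """Full automatic chain: smooth, threshold at mean - k*SD, erode.

    If the eroded mask still touches the volume boundary a further erosion is
    applied (at most ``max_erosions`` in total) -- the surrogate used here for
    the operator's judgement that a second erosion is "necessary"; the event
    is logged.
    """
    grid = seed_roi.grid
    smoothed = box_smooth(magnitude, params.box_size)
    mean, sd = roi_statistics(smoothed, seed_roi)
    threshold = mean - params.k_sigma * sd
    mask = threshold_mask(smoothed, threshold, grid)
    logger.info(
        "segmentation: ROI mean=%.4g sd=%.4g threshold=%.4g -> %d voxels above",
        mean, sd, threshold, mask.count,
    )
    if not mask.values.any():
        raise ValueError("threshold mask is empty: seed ROI statistics exclude all voxels")
    mask = erode_mask(mask, params.erosions)
    logger.info("segmentation: after %d erosion(s) %d voxels", params.erosions, mask.count)
    n_done = params.erosions
    while _touches_boundary(mask.values) and n_done < params.max_erosions:
        mask = erode_mask(mask, 1)
        n_done += 1
        logger.info(
            "segmentation: eroded mask touched the volume boundary, applied erosion %d -> %d voxels",
            n_done, mask.count,
        )
    return mask


def fine_tune_mask(
    supplied: BinaryMask, params: SegmentationParams = SegmentationParams()
) -> BinaryMask:
    """Fine-tune an externally supplied (e.g. manual) segmentation mask.

    Mirrors the automatic path applied to a binary input: box smoothing of the
    indicator (majority-style cleanup at >= 0.5) followed by the configured
    erosions.
    """
    smoothed = box_smooth(supplied.values.astype(float), params.box_size)
    mask = BinaryMask(values=smoothed >= 0.5, grid=supplied.grid)
    return erode_mask(mask, params.erosions)


def box_seed_roi(
    grid: VoxelGrid,
    slice_axis: int,
    slice_index: int,
    lo: tuple[int, int],
    hi: tuple[int, int],
) -> BinaryMask:
    """Single-slice rectangular seed ROI (the coarse manual ROI surrogate).

    ``lo``/``hi`` are inclusive/exclusive corner indices in the two in-plane
    axes (order: remaining axes in ascending order).
    """
    values = np.zeros(grid.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[slice_axis] = slice_index
    plane_axes = [a for a in range(3) if a != slice_axis]
    sl[plane_axes[0]] = slice(lo[0], hi[0])
    sl[plane_axes[1]] = slice(lo[1], hi[1])
    values[tuple(sl)] = True
    return BinaryMask(values=values, grid=grid)
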