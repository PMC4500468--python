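"""Canal-ROI construction, truncation sweeps, slab projections and profiles.

These are the analysis instruments: an automatic canal ROI grown from a seed,
the susceptibility-versus-truncation sweep with histograms, thick-slab
minimum/maximum intensity projections in the three principal planes, and the
splitting-profile counter that turns the vessel-splitting artifact into an
assertable number.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .qsm import tkd_invert
from .volume_model import AcquisitionParams, BinaryMask, SusceptibilityMap, VoxelGrid

__all__ = [
    "SweepResult",
    "ProjectionImage",
    "ProfileMinima",
    "canal_roi_from_chi",
    "truncation_sweep",
    "slab_projection",
    "invert_display_contrast",
    "splitting_profile",
]

logger = logging.getLogger(__name__)

_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}  # projection (normal) axis


@dataclass
class SweepResult:
    """Canal-ROI susceptibility statistics versus TKD truncation factor."""

    truncation_values: list[float]
    mean_chi: list[float]
    sd_chi: list[float]
    background_sd: list[float]
    histograms: list[np.ndarray]
    bin_edges: np.ndarray
    roi_size: int

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["t", "mean_chi_ppm", "sd_chi_ppm", "background_sd_ppm", "roi_voxels"])
            for t, m, s, b in zip(
                self.truncation_values, self.mean_chi, self.sd_chi, self.background_sd
            ):
                writer.writerow([t, m, s, b, self.roi_size])
        return path

    def histograms_to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["bin_center_ppm"] + [f"t={t:g}" for t in self.truncation_values])
            for i, c in enumerate(centers):
                writer.writerow([c] + [int(h[i]) for h in self.histograms])
        return path


@dataclass
class ProjectionImage:
    """A single slab extremum projection."""

    pixels: np.ndarray
    plane: str
    slab_thickness_mm: float
    mode: str
    slab_range: tuple[int, int]
    partial: bool = False


@dataclass
class ProfileMinima:
    """Result of a splitting-profile count."""

    count: int
    indices: list[int]
    profile: np.ndarray
    threshold: float


def canal_roi_from_chi(
    chi: SusceptibilityMap, seed_roi: BinaryMask, k_sigma: float = 1.0
) -> BinaryMask:
    """Grow a canal-only ROI from a small seed placed on a canal.

    Voxels with chi >= mean(seed) - k_sigma*SD(seed) form an intermediate ROI
    (canals are the high-susceptibility tail); of these, only 26-connected
    components intersecting the seed are retained.  The connected-component
    retention is a reproducible surrogate for the operator's manual exclusion
    of non-canal areas -- it does not claim to replicate the operator.
    """
    seed_vals = chi.values[seed_roi.values]
    if seed_vals.size == 0:
        raise ValueError("seed ROI is empty")
    threshold = float(seed_vals.mean() - k_sigma * seed_vals.std())
    above = chi.values >= threshold
    if chi.valid_mask is not None:
        above &= chi.valid_mask.values
    labels, n_labels = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=bool))
    seed_labels = np.unique(labels[seed_roi.values & above])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        raise ValueError("no connected component above threshold intersects the seed ROI")
    roi = np.isin(labels, seed_labels)
    logger.info(
        "canal ROI: threshold %.4g ppm, %d/%d components kept, %d voxels",
        threshold, seed_labels.size, n_labels, int(roi.sum()),
    )
    return BinaryMask(values=roi, grid=chi.grid)


def truncation_sweep(
    local_phase: np.ndarray,
    acq: AcquisitionParams,
    grid: VoxelGrid,
    canal_roi: BinaryMask,
    t_values,
    valid_mask: BinaryMask | None = None,
    phase_sign: float = -1.0,
    bins: int = 64,
    bin_range: tuple[float, float] = (-0.1, 0.2),
) -> SweepResult:
    """Re-run the TKD inversion over a ladder of truncation factors.

    Records the canal-ROI mean/SD and histogram of chi and the background SD
    (streak energy: SD of chi over the valid mask outside the canal ROI) for
    each truncation value.  Deterministic in its inputs.
    """
    t_values = list(t_values)
    if any(b > a for a, b in zip(t_values[1:], t_values[:-1])):
        raise ValueError("t_values must be sorted ascending")
    edges = np.linspace(bin_range[0], bin_range[1], bins + 1)
    means, sds, bg_sds, hists = [], [], [], []
    for t in t_values:
        chi = tkd_invert(
            local_phase, acq, grid, tkd_truncation=t, valid_mask=valid_mask, phase_sign=phase_sign
        )
        roi_vals = chi.values[canal_roi.values]
        means.append(float(roi_vals.mean()))
        sds.append(float(roi_vals.std()))
        if valid_mask is not None:
            bg = chi.values[valid_mask.values & ~canal_roi.values]
        else:
            bg = chi.values[~canal_roi.values]
        bg_sds.append(float(bg.std()))
        clipped = np.clip(roi_vals, edges[0], edges[-1])  # histogram conserves ROI size
        hist, _ = np.histogram(clipped, bins=edges)
        hists.append(hist)
    return SweepResult(
        truncation_values=t_values,
        mean_chi=means,
        sd_chi=sds,
        background_sd=bg_sds,
        histograms=hists,
        bin_edges=edges,
        roi_size=canal_roi.count,
    )


def slab_projection(
    volume: np.ndarray,
    grid: VoxelGrid,
    plane: str,
    slab_thickness_mm: float,
    mode: str = "min",
) -> list[ProjectionImage]:
    """Partition the volume into consecutive slabs and project each.

    ``plane`` names the image plane (axial = perpendicular to +z); the
    projection runs along the plane normal.  The slab voxel count is
    ``round(thickness / voxel_size)``; a shorter remainder slab at the end is
    kept and flagged ``partial``.
    """
    if plane not in _PLANE_AXIS:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXIS)}")
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    axis = _PLANE_AXIS[plane]
    n = grid.shape[axis]
    step = int(round(slab_thickness_mm / grid.voxel_size[axis]))
    if step < 1:
        raise ValueError("slab thickness must cover at least one voxel")
    reduce = np.min if mode == "min" else np.max
    out = []
    for start in range(0, n, step):
        stop = min(start + step, n)
        sl = [slice(None)] * 3
        sl[axis] = slice(start, stop)
        pixels = reduce(np.asarray(volume)[tuple(sl)], axis=axis)
        out.append(
            ProjectionImage(
                pixels=pixels,
                plane=plane,
                slab_thickness_mm=slab_thickness_mm,
                mode=mode,
                slab_range=(start, stop),
                partial=(stop - start) < step,
            )
        )
    return out


def slab_projection_at(
    volume: np.ndarray,
    grid: VoxelGrid,
    plane: str,
    slab_thickness_mm: float,
    center_index: int,
    mode: str = "min",
) -> ProjectionImage:
    """Single slab of the stated thickness centered on ``center_index``."""
    axis = _PLANE_AXIS[plane]
    step = max(int(round(slab_thickness_mm / grid.voxel_size[axis])), 1)
    start = int(np.clip(center_index - step // 2, 0, grid.shape[axis] - step))
    stop = start + step
    sl = [slice(None)] * 3
    sl[axis] = slice(start, stop)
    reduce = np.min if mode == "min" else np.max
    pixels = reduce(np.asarray(volume)[tuple(sl)], axis=axis)
    return ProjectionImage(
        pixels=pixels, plane=plane, slab_thickness_mm=slab_thickness_mm,
        mode=mode, slab_range=(start, stop),
    )


def invert_display_contrast(values: np.ndarray, valid_mask: BinaryMask) -> np.ndarray:
    """Affine intensity flip x -> max + min - x inside the valid mask (involutive)."""
    out = np.array(values, dtype=float, copy=True)
    sel = valid_mask.values
    if sel.any():
        lo = out[sel].min()
        hi = out[sel].max()
        out[sel] = hi + lo - out[sel]
    return out


def splitting_profile(
    projection: ProjectionImage,
    line_axis: int,
    line_index: int,
    crop: tuple[int, int] | None = None,
    sd_factor: float = 0.5,
) -> ProfileMinima:
    """Count dark-vessel minima along a line crossing the vessel image.

    Extracts the profile along image axis ``line_axis`` at ``line_index`` in
    the other axis, smooths it with a 3-point mean, and counts strict local
    minima deeper than ``mean - sd_factor*SD`` of the (cropped) profile.  A
    vessel imaged without artifact yields one minimum; the SWI splitting
    artifact yields two or more.
    """
    if line_axis not in (0, 1):
        raise ValueError("line_axis must be 0 or 1 (projection images are 2-D)")
    profile = projection.pixels[:, line_index] if line_axis == 0 else projection.pixels[line_index, :]
    profile = np.asarray(profile, dtype=float)
    offset = 0
    if crop is not None:
        offset = crop[0]
        profile = profile[crop[0] : crop[1]]
    smooth = np.convolve(profile, np.ones(3) / 3.0, mode="same")
    # guard the convolution edges (2-point means) from counting as minima
    smooth[0] = profile[0]
    smooth[-1] = profile[-1]
    threshold = float(smooth.mean() - sd_factor * smooth.std())
    indices = [
        i + offset
        for i in range(1, len(smooth) - 1)
        if smooth[i] < smooth[i - 1] and smooth[i] < smooth[i + 1] and smooth[i] < threshold
    ]
    return ProfileMinima(count=len(indices), indices=indices, profile=smooth, threshold=threshold)
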