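"""Shared fixtures: phantoms are generated at test time, never stored on disk.

The expensive 96-cube pipeline runs are session-scoped so the splitting,
sweep and recovery tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from canalqsm.phantom import (
    inclusion_mask,
    rasterize_susceptibility,
    single_canal_94T,
    synthesize_gre,
    three_canals_94T,
    tissue_mask,
)
from canalqsm.qsm import QsmParams, laplacian_unwrap, qsm_pipeline, sharp_filter
from canalqsm.qsmwi import QsmwiParams, qsmwi_pipeline
from canalqsm.segmentation import box_seed_roi, erode_mask
from canalqsm.swi import SwiParams, swi_pipeline
from canalqsm.volume_model import AcquisitionParams, BinaryMask, VoxelGrid

#: Visualization processing as printed: SHARP 9^3 / 0.5, TKD floor 3/2.
VIZ_PARAMS = QsmParams(sharp_kernel_voxels=9, sharp_truncation=0.5, tkd_truncation=1.5)
#: Quantitative processing: reference-code SHARP truncation, relaxed TKD.
QUANT_PARAMS = QsmParams(sharp_kernel_voxels=9, sharp_truncation=0.05, tkd_truncation=10.0)


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    return VoxelGrid(shape=(32, 32, 32), voxel_size=(0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def acq_94T() -> AcquisitionParams:
    return AcquisitionParams(field_strength=9.4, echo_time=15e-3)


def _process_perp(noise_sd: float) -> dict:
    """Full four-method processing of the perpendicular-canal phantom."""
    from canalqsm.analysis_viz import canal_roi_from_chi

    spec = single_canal_94T("perp", noise_sd=noise_sd)
    grid = spec.grid
    c = grid.shape[0] // 2
    vol = synthesize_gre(spec)
    seg = erode_mask(tissue_mask(spec), 1)
    swi_img = swi_pipeline(vol, SwiParams(), seg)
    chi = qsm_pipeline(vol, seg, VIZ_PARAMS)
    canal_seed = box_seed_roi(grid, 0, c, (c - 1, c - 1), (c + 2, c + 2))
    canal_roi = canal_roi_from_chi(chi, canal_seed)
    qsmwi_img = qsmwi_pipeline(vol, chi, canal_roi, seg, QsmwiParams())
    return {
        "spec": spec,
        "grid": grid,
        "center": c,
        "vol": vol,
        "seg": seg,
        "swi": swi_img,
        "chi": chi,
        "canal_roi": canal_roi,
        "qsmwi": qsmwi_img,
    }


@pytest.fixture(scope="session")
def perp_noiseless() -> dict:
    return _process_perp(0.0)


@pytest.fixture(scope="session")
def perp_snr20() -> dict:
    return _process_perp(0.05)


@pytest.fixture(scope="session")
def quant_recovery() -> dict:
    """Noiseless single-canal recovery at TKD t=10 for all three orientations."""
    out = {}
    for orientation in ("parallel", "perp", "oblique"):
        spec = single_canal_94T(orientation)
        vol = synthesize_gre(spec)
        seg = erode_mask(tissue_mask(spec), 1)
        chi = qsm_pipeline(vol, seg, QUANT_PARAMS)
        core = inclusion_mask(spec, dilate_mm=-0.1)
        out[orientation] = float(chi.values[core.values].mean())
    return out


@pytest.fixture(scope="session")
def fixture_sweep_inputs() -> dict:
    """Local phase + ROI of the bundled three-canal fixture, ready for TKD sweeps."""
    spec = three_canals_94T()
    vol = synthesize_gre(spec)
    seg = erode_mask(tissue_mask(spec), 1)
    unwrapped = laplacian_unwrap(vol.phase, spec.grid)
    local, reliability = sharp_filter(unwrapped, seg, VIZ_PARAMS)
    core = inclusion_mask(spec, dilate_mm=-0.1)
    return {
        "spec": spec,
        "local": local,
        "reliability": reliability,
        "canal_roi": core,
    }
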