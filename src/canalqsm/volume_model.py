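"""Core data types, k-space geometry and NIfTI I/O shared by all pipeline stages.

Conventions used throughout the package
---------------------------------------
* Volumes are 3-D numpy arrays indexed ``(x, y, z)``; the main field B0 points
  along ``+z`` in image axes unless an oblique ``b0_direction`` is given.
* All FFT-based stages use the *centered* transform: the DC component sits at
  voxel index ``floor(N/2)`` on every axis.  Kernels are built on the same
  centered grid, so the convention is internally consistent.
* Field maps and susceptibility maps are expressed in ppm (parts per million
  of B0).  The phase accumulated at echo time TE by a relative field shift
  ``delta`` (in ppm) is ``phase = sign * 2*pi * f0 * TE * delta * 1e-6`` with
  ``f0 = (gamma / 2 pi) * B0`` the Larmor frequency; the default ``sign`` is
  set in :mod:`canalqsm.phantom` so that paramagnetic inclusions accumulate
  negative phase on the dipole lobes along B0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml
from scipy import fft as spfft

__all__ = [
    "GAMMA_1H",
    "AcquisitionParams",
    "VoxelGrid",
    "ComplexVolume",
    "KSpaceGrid",
    "BinaryMask",
    "FieldMap",
    "SusceptibilityMap",
    "wrap_phase",
    "phase_scale_rad_per_ppm",
    "phase_to_ppm",
    "ppm_to_phase",
    "centered_fft",
    "centered_ifft",
    "make_kspace_grid",
    "read_volume_pair",
    "write_volume",
    "read_acquisition_sidecar",
    "write_acquisition_sidecar",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (gamma / 2 pi = 42.577 MHz/T).
GAMMA_1H = 2.0 * np.pi * 42.577478518e6


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase values into the half-open interval (-pi, pi]."""
    phase = np.asarray(phase, dtype=float)
    return np.pi - np.mod(np.pi - phase, 2.0 * np.pi)


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition metadata needed for phase-to-ppm conversion.

    Parameters
    ----------
    field_strength : float
        Main field B0 in tesla.
    echo_time : float
        Echo time TE in seconds.
    b0_direction : sequence of 3 floats
        Unit vector of B0 in image axes (default ``+z``).
    gyromagnetic_ratio : float
        In rad s^-1 T^-1; defaults to the proton value.
    """

    field_strength: float
    echo_time: float
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    gyromagnetic_ratio: float = GAMMA_1H

    def __post_init__(self) -> None:
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")
        if self.echo_time <= 0:
            raise ValueError("echo_time must be positive")
        b0 = np.asarray(self.b0_direction, dtype=float)
        if b0.shape != (3,):
            raise ValueError("b0_direction must be a 3-vector")
        n = float(np.linalg.norm(b0))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"b0_direction must be unit length, got |b|={n!r}")
        object.__setattr__(self, "b0_direction", tuple(float(v) for v in b0))

    @property
    def larmor_frequency_hz(self) -> float:
        return self.gyromagnetic_ratio / (2.0 * np.pi) * self.field_strength

    @property
    def b0_unit(self) -> np.ndarray:
        return np.asarray(self.b0_direction, dtype=float)


@dataclass(frozen=True)
class VoxelGrid:
    """Image geometry: array shape and voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 8 for s in shape):
            raise ValueError("grid shape must be 3-D with every dimension >= 8")
        vs = self.voxel_size
        if np.isscalar(vs):
            vs = (float(vs),) * 3
        vs = tuple(float(v) for v in np.atleast_1d(vs))
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be 3 positive lengths (mm)")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates in mm, origin at the DC voxel.

        The DC voxel (index ``floor(N/2)``) sits at coordinate 0, matching the
        centered-FFT convention used by every k-space stage.
        """
        return tuple(
            (np.arange(n) - n // 2) * d for n, d in zip(self.shape, self.voxel_size)
        )


def _check_shape(values: np.ndarray, grid: VoxelGrid, name: str) -> None:
    if tuple(values.shape) != grid.shape:
        raise ValueError(f"{name} shape {values.shape} does not match grid {grid.shape}")


@dataclass
class ComplexVolume:
    """A complex GRE volume stored as a magnitude/phase pair."""

    magnitude: np.ndarray
    phase: np.ndarray
    grid: VoxelGrid
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        _check_shape(self.magnitude, self.grid, "magnitude")
        _check_shape(self.phase, self.grid, "phase")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        self.phase = wrap_phase(self.phase)

    @property
    def complex(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)

    @classmethod
    def from_complex(
        cls, signal: np.ndarray, grid: VoxelGrid, acq: AcquisitionParams
    ) -> "ComplexVolume":
        return cls(np.abs(signal), np.angle(signal), grid, acq)


@dataclass
class KSpaceGrid:
    """Centered spatial-frequency coordinates in cycles/mm.

    ``kx, ky, kz`` broadcast against each other; ``k2 = kx**2 + ky**2 + kz**2``
    is zero at exactly one voxel, the DC voxel at index ``floor(N/2)``.
    """

    kx: np.ndarray
    ky: np.ndarray
    kz: np.ndarray
    k2: np.ndarray
    grid: VoxelGrid

    @property
    def dc_index(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.grid.shape)

    def k_dot(self, direction: Sequence[float]) -> np.ndarray:
        """Projection of k onto a direction vector (cycles/mm)."""
        d = np.asarray(direction, dtype=float)
        return self.kx * d[0] + self.ky * d[1] + self.kz * d[2]


@dataclass
class BinaryMask:
    """3-D boolean region-of-interest mask."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        _check_shape(self.values, self.grid, "mask")

    @property
    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class FieldMap:
    """Relative field perturbation Delta-B / B0 in ppm."""

    values: np.ndarray
    grid: VoxelGrid
    valid_mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.values, self.grid, "field")
        if self.valid_mask is not None and not np.all(
            np.isfinite(self.values[self.valid_mask.values])
        ):
            raise ValueError("field map contains non-finite values inside valid_mask")


@dataclass
class SusceptibilityMap:
    """Relative susceptibility chi in ppm.

    The DC component of the dipole inversion is undefined, so maps produced by
    the inversion are zero-mean over their valid mask: values are relative to
    the surrounding tissue.
    """

    values: np.ndarray
    grid: VoxelGrid
    valid_mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.values, self.grid, "chi")


# ---------------------------------------------------------------------------
# phase <-> ppm


def phase_scale_rad_per_ppm(acq: AcquisitionParams, sign: float = -1.0) -> float:
    """Radians of GRE phase accumulated per ppm of relative field shift."""
    return sign * 2.0 * np.pi * acq.larmor_frequency_hz * acq.echo_time * 1e-6


def phase_to_ppm(phase: np.ndarray, acq: AcquisitionParams, sign: float = -1.0) -> np.ndarray:
    return np.asarray(phase, dtype=float) / phase_scale_rad_per_ppm(acq, sign)


def ppm_to_phase(ppm: np.ndarray, acq: AcquisitionParams, sign: float = -1.0) -> np.ndarray:
    return np.asarray(ppm, dtype=float) * phase_scale_rad_per_ppm(acq, sign)


# ---------------------------------------------------------------------------
# centered FFT


def centered_fft(volume: np.ndarray) -> np.ndarray:
    """Forward 3-D FFT with the DC component at index ``floor(N/2)``."""
    return spfft.fftshift(spfft.fftn(spfft.ifftshift(volume)))


def centered_ifft(kvolume: np.ndarray) -> np.ndarray:
    """Inverse of :func:`centered_fft`."""
    return spfft.fftshift(spfft.ifftn(spfft.ifftshift(kvolume)))


def make_kspace_grid(grid: VoxelGrid) -> KSpaceGrid:
    """Spatial-frequency coordinates (cycles/mm) matching :func:`centered_fft`."""
    axes = [
        spfft.fftshift(spfft.fftfreq(n, d=d)) for n, d in zip(grid.shape, grid.voxel_size)
    ]
    kx = axes[0][:, None, None]
    ky = axes[1][None, :, None]
    kz = axes[2][None, None, :]
    k2 = kx**2 + ky**2 + kz**2
    return KSpaceGrid(kx=kx, ky=ky, kz=kz, k2=k2, grid=grid)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _nifti_affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size) + [1.0])
    return aff


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    shape = tuple(int(s) for s in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(shape=shape, voxel_size=zooms)


def write_volume(volume_or_map, path: str | Path) -> Path:
    """Write a volume, map or mask as NIfTI-1 with the voxel size in the header.

    Masks are stored as uint8 {0, 1}; scalar maps and magnitude/phase as
    float32.  Non-finite values are rejected (a silent NaN in a susceptibility
    map would corrupt every downstream statistic).
    """
    path = Path(path)
    if isinstance(volume_or_map, BinaryMask):
        data = volume_or_map.values.astype(np.uint8)
        grid = volume_or_map.grid
    elif isinstance(volume_or_map, (FieldMap, SusceptibilityMap)):
        data = volume_or_map.values.astype(np.float32)
        grid = volume_or_map.grid
    elif isinstance(volume_or_map, np.ndarray):
        raise TypeError("write_volume needs an object with a grid; wrap the array first")
    else:
        raise TypeError(f"cannot write object of type {type(volume_or_map).__name__}")
    n_bad = int(np.size(data) - np.isfinite(data.astype(float)).sum())
    if n_bad:
        raise ValueError(f"refusing to write {path}: {n_bad} non-finite voxels")
    img = nib.Nifti1Image(data, _nifti_affine(grid))
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))
    return path


def write_volume_pair(
    volume: ComplexVolume, magnitude_path: str | Path, phase_path: str | Path
) -> tuple[Path, Path]:
    """Write a ComplexVolume as a magnitude + phase NIfTI pair (float32, radians)."""
    out = []
    for data, path in ((volume.magnitude, magnitude_path), (volume.phase, phase_path)):
        if not np.all(np.isfinite(data)):
            n_bad = int(np.size(data) - np.isfinite(data).sum())
            raise ValueError(f"refusing to write {path}: {n_bad} non-finite voxels")
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _nifti_affine(volume.grid))
        img.header.set_zooms(volume.grid.voxel_size)
        nib.save(img, str(path))
        out.append(Path(path))
    return tuple(out)


def read_scalar_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), _grid_from_nifti(img)


def read_mask(path: str | Path) -> BinaryMask:
    data, grid = read_scalar_volume(path)
    return BinaryMask(values=data > 0.5, grid=grid)


def read_volume_pair(
    magnitude_path: str | Path,
    phase_path: str | Path,
    acq: AcquisitionParams,
    phase_dialect: str = "radians",
) -> ComplexVolume:
    """Read a magnitude + phase NIfTI pair into a :class:`ComplexVolume`.

    Parameters
    ----------
    phase_dialect : {"radians", "two_pi"}
        How phase is stored on disk.  ``"radians"`` expects values already in
        radians (any wrap); ``"two_pi"`` expects values in [0, 2*pi) as written
        by some scanner exports.  The dialect is never auto-detected: a silent
        misscaling would corrupt QSM quantitation invisibly.
    """
    mag, mag_grid = read_scalar_volume(magnitude_path)
    phase, phase_grid = read_scalar_volume(phase_path)
    if mag_grid.shape != phase_grid.shape or not np.allclose(
        mag_grid.voxel_size, phase_grid.voxel_size, rtol=1e-4
    ):
        raise ValueError(
            "magnitude/phase geometry mismatch: "
            f"{magnitude_path} has {mag_grid.shape} @ {mag_grid.voxel_size} mm, "
            f"{phase_path} has {phase_grid.shape} @ {phase_grid.voxel_size} mm"
        )
    if phase_dialect == "radians":
        pass
    elif phase_dialect == "two_pi":
        phase = phase  # wrap_phase in the constructor maps [0, 2pi) onto (-pi, pi]
    else:
        raise ValueError(f"unknown phase dialect {phase_dialect!r}")
    return ComplexVolume(magnitude=mag, phase=phase, grid=mag_grid, acq=acq)


def write_acquisition_sidecar(acq: AcquisitionParams, path: str | Path) -> Path:
    """Write acquisition metadata as a YAML/JSON sidecar next to the volumes."""
    path = Path(path)
    payload = {
        "field_strength_T": acq.field_strength,
        "echo_time_s": acq.echo_time,
        "b0_direction": list(acq.b0_direction),
        "gyromagnetic_ratio_rad_s_T": acq.gyromagnetic_ratio,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload))
    return path


def read_acquisition_sidecar(path: str | Path) -> AcquisitionParams:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return AcquisitionParams(
            field_strength=float(payload["field_strength_T"]),
            echo_time=float(payload["echo_time_s"]),
            b0_direction=tuple(payload.get("b0_direction", (0.0, 0.0, 1.0))),
            gyromagnetic_ratio=float(payload.get("gyromagnetic_ratio_rad_s_T", GAMMA_1H)),
        )
    except KeyError as exc:  # no silent defaults for TE / B0
        raise ValueError(f"sidecar {path} is missing required key {exc}") from exc
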