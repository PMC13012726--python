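"""Core gridded containers: image volumes, binary masks, and PSF models.

All volumes are stored as numpy arrays indexed ``(z, y, x)`` with a physical
voxel size in micrometers per axis in the same order.  Physical position of a
voxel is ``index * voxel_size`` (0-based indices; z is depth below the first
slice).  Raw detector intensities live on a 10-bit scale, 0–1023 signal units
(SU); :meth:`ImageVolume.normalized` maps them onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: 10-bit detector range in signal units.
BIT_RANGE = (0.0, 1023.0)


def _as_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in np.atleast_1d(voxel_size))
    if len(vs) == 1:
        vs = vs * 3
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 positive floats, got {voxel_size!r}")
    return vs  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar field with physical voxel size and a channel role.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity grid, finite values.
    voxel_size : tuple of float
        Micrometers per voxel along (z, y, x).
    channel : {"vascular", "neuron"}
        Which fluorescence channel the volume represents.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "vascular"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("ImageVolume expects a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("ImageVolume voxels must be finite")
        self.voxel_size = _as_size(self.voxel_size)
        if self.channel not in ("vascular", "neuron"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def extent(self) -> np.ndarray:
        """Physical extent (μm) spanned by voxel centers, per axis."""
        return (np.array(self.shape) - 1) * np.array(self.voxel_size)

    def copy_with(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64))

    def normalized(self) -> "ImageVolume":
        """Divide raw 10-bit intensities by 1023 so values lie in [0, 1]."""
        lo, hi = BIT_RANGE
        if self.voxels.min() < lo or self.voxels.max() > hi:
            raise ValueError("intensities outside the 10-bit range 0–1023 SU")
        return self.copy_with(self.voxels / hi)


@dataclass
class BinaryMask:
    """A {0,1} segmentation mask on the same grid as its source volume."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    label: str = "vessel"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError("BinaryMask expects a 3D array")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("BinaryMask values must be in {0, 1}")
        self.voxels = vox.astype(bool)
        self.voxel_size = _as_size(self.voxel_size)
        if self.label not in ("vessel", "neuron"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def copy_with(self, voxels: np.ndarray) -> "BinaryMask":
        return replace(self, voxels=np.asarray(voxels).astype(bool))


@dataclass
class PSFModel:
    """A point-spread-function kernel on a voxel grid.

    The kernel is non-negative with finite support and is normalized to sum
    to one on construction (a tolerance of 1e-6 is accepted before
    renormalizing; anything further off is rejected as not a density).
    """

    kernel: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=np.float64)
        if k.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if np.any(k < 0) or not np.all(np.isfinite(k)):
            raise ValueError("PSF kernel must be finite and nonnegative")
        total = k.sum()
        if total <= 0:
            raise ValueError("PSF kernel must have positive mass")
        self.kernel = k / total
        self.voxel_size = _as_size(self.voxel_size)

    @classmethod
    def delta(cls, voxel_size=(0.99, 0.99, 0.99)) -> "PSFModel":
        """Identity kernel (single central voxel)."""
        k = np.zeros((1, 1, 1))
        k[0, 0, 0] = 1.0
        return cls(k, voxel_size)

    @classmethod
    def gaussian(
        cls,
        voxel_size=(0.99, 0.99, 0.99),
        fwhm_lateral_um: float = 0.99,
        fwhm_axial_um: float = 2.64,
        truncate: float = 4.0,
    ) -> "PSFModel":
        """Anisotropic Gaussian PSF from nominal lateral/axial resolutions.

        The default FWHMs match the nominal 0.99 μm lateral resolution and
        2.64 μm axial step of resonant-scanner two-photon acquisitions.
        """
        vs = _as_size(voxel_size)
        fwhm = np.array([fwhm_axial_um, fwhm_lateral_um, fwhm_lateral_um])
        sigma_um = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox = sigma_um / np.array(vs)
        half = np.maximum(np.ceil(truncate * sigma_vox).astype(int), 1)
        zz, yy, xx = np.meshgrid(
            *(np.arange(-h, h + 1) for h in half), indexing="ij"
        )
        r2 = sum((c / s) ** 2 for c, s in zip((zz, yy, xx), sigma_vox))
        k = np.exp(-0.5 * r2)
        return cls(k, vs)
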