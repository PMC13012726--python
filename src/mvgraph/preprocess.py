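"""Volume preparation: isotropic resampling, normalization, rigid
registration, mask cleanup, temporal union, and mask-evaluation metrics.

Registration aligns repeated acquisitions of one field of view onto a
reference frame (the first baseline scan) by minimizing mean squared error
under a rigid transform, so that segmentation masks from all time points can
be dilated and unioned into a single gap-free mask for centerline
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, disk

from .volume import BinaryMask, ImageVolume

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class RigidTransform:
    """A rigid map from the fixed (reference) frame to the moving frame.

    ``apply(p)`` sends physical points ``p`` (μm, (z, y, x)) from the fixed
    frame into the moving image's space: ``R p + t``.  Resampling a moving
    volume onto the fixed grid therefore pulls intensities back through this
    map.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, translation_um) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(translation_um, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def invert(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform(r, -r @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix acting on (z, y, x, 1) μm columns."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])


def upsample_isotropic(volume, target_spacing: float = 0.99):
    """Resample onto an isotropic grid, preserving physical extent.

    Intensity volumes use trilinear interpolation, masks nearest-neighbor.
    The output voxel count per axis is ``round(extent / target) + 1`` so the
    span of voxel centers is preserved within one output voxel.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    is_mask = isinstance(volume, BinaryMask)
    vs = np.array(volume.voxel_size)
    shape = np.array(volume.shape)
    if np.allclose(vs, target_spacing):
        return volume
    new_shape = np.round((shape - 1) * vs / target_spacing).astype(int) + 1
    idx = np.meshgrid(
        *(np.arange(n) * target_spacing / v for n, v in zip(new_shape, vs)),
        indexing="ij",
    )
    src = volume.voxels.astype(float)
    out = ndimage.map_coordinates(
        src, np.stack([i.ravel() for i in idx]),
        order=0 if is_mask else 1, mode="nearest",
    ).reshape(tuple(new_shape))
    iso = (target_spacing,) * 3
    if is_mask:
        return BinaryMask(out > 0.5, iso, label=volume.label)
    return ImageVolume(out, iso, channel=volume.channel)


def normalize_intensity(volume: ImageVolume) -> ImageVolume:
    """Map raw 10-bit intensities onto [0, 1] (divide by 1023)."""
    return volume.normalized()


def _euler_matrix(angles: np.ndarray) -> np.ndarray:
    """Rotation about the (z, y, x) axes, composed R = Rz @ Ry @ Rx."""
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rigid_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    smoothing_sigma_vox: float = 2.0,
    refine_rotation: bool = True,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Mean squared error is the similarity metric, evaluated on images
    smoothed with a Gaussian of ``smoothing_sigma_vox`` voxels.  The
    translation is initialized by sub-voxel phase cross-correlation and the
    full rigid pose (rotation about the volume center + translation)
    refined by Powell descent on the MSE.  Deterministic for fixed inputs.
    """
    from skimage.registration import phase_cross_correlation

    for name, vol in (("moving", moving), ("fixed", fixed)):
        if vol.voxels.max() == vol.voxels.min():
            raise ValueError(f"{name} image has constant intensity")
    vs = np.array(fixed.voxel_size)
    f_sm = ndimage.gaussian_filter(fixed.voxels, smoothing_sigma_vox)
    m_sm = ndimage.gaussian_filter(moving.voxels, smoothing_sigma_vox)
    shift_vox, _, _ = phase_cross_correlation(f_sm, m_sm, upsample_factor=20,
                                              normalization=None)
    # fixed(x) ~ moving(x - shift) => pullback map t0 = -shift (physical)
    t0 = -np.asarray(shift_vox) * vs
    center = (np.array(fixed.shape) - 1) * vs / 2.0

    def cost(params: np.ndarray) -> float:
        angles, t = np.deg2rad(params[:3]), params[3:]
        rot = _euler_matrix(angles)
        # out(x) = moving(R (x - c) + c + t), sampled on the fixed grid
        matrix = (rot * vs[None, :]) / vs[:, None]
        offset = (center + t - rot @ center) / vs
        res = ndimage.affine_transform(m_sm, matrix, offset=offset, order=1,
                                       mode="constant", cval=np.nan)
        diff = res - f_sm
        return float(np.nanmean(diff * diff))

    from scipy.optimize import minimize

    # angles carried in degrees so Powell steps are commensurate with μm
    if refine_rotation:
        x0 = np.concatenate([np.zeros(3), t0])
        res = minimize(cost, x0, method="Powell",
                       options={"xtol": 1e-3, "ftol": 1e-9, "maxiter": 200})
        angles, t = np.deg2rad(res.x[:3]), res.x[3:]
    else:
        res = minimize(lambda t: cost(np.concatenate([np.zeros(3), t])), t0,
                       method="Powell",
                       options={"xtol": 1e-3, "ftol": 1e-9, "maxiter": 200})
        angles, t = np.zeros(3), res.x
    rot = _euler_matrix(angles)
    return RigidTransform(rot, center + t - rot @ center)


def apply_transform(volume, transform: RigidTransform, interpolation=None):
    """Resample a moving volume onto the fixed (reference) grid.

    Masks default to nearest-neighbor, images to trilinear.
    """
    is_mask = isinstance(volume, BinaryMask)
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    order = {"nearest": 0, "linear": 1}[interpolation]
    vs = np.array(volume.voxel_size)
    # out[i] = in[(R @ (i * vs) + t) / vs]; images extend edge values so the
    # resampled frame carries no artificial zero band, masks stay hard zero
    matrix = (transform.rotation * vs[None, :]) / vs[:, None]
    offset = transform.translation / vs
    out = ndimage.affine_transform(
        volume.voxels.astype(float), matrix, offset=offset,
        order=order, mode="constant" if is_mask else "nearest", cval=0.0,
    )
    if is_mask:
        return volume.copy_with(out > 0.5)
    return volume.copy_with(out)


def mse(a: ImageVolume, b: ImageVolume) -> float:
    """Mean squared intensity difference between two volumes."""
    return float(np.mean((a.voxels - b.voxels) ** 2))


def clean_mask(mask: BinaryMask, min_component_voxels: int = 50) -> BinaryMask:
    """Fill enclosed background pockets, then drop small components.

    A background component (6-connectivity) is enclosed iff it does not
    touch the volume boundary and every outside 26-neighbor is vessel; such
    pockets break centerline extraction and are filled in.  Vessel
    components (26-connectivity) with fewer than ``min_component_voxels``
    voxels are assumed to be noise and removed.  Idempotent.
    """
    vox = mask.voxels.copy()
    bg_labels, n_bg = ndimage.label(~vox, structure=_STRUCT_6)
    if n_bg:
        border = np.zeros_like(vox)
        border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
        touching = np.unique(bg_labels[border & ~vox])
        slices = ndimage.find_objects(bg_labels)
        for lab, sl in enumerate(slices, start=1):
            if lab in touching or sl is None:
                continue
            sl = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in sl)
            comp = bg_labels[sl] == lab
            shell = ndimage.binary_dilation(comp, structure=_STRUCT_26) & ~comp
            if vox[sl][shell].all():
                vox[sl][comp] = True
    fg_labels, n_fg = ndimage.label(vox, structure=_STRUCT_26)
    if n_fg:
        counts = np.bincount(fg_labels.ravel())
        small = np.flatnonzero(counts < min_component_voxels)
        small = small[small != 0]
        if small.size:
            vox[np.isin(fg_labels, small)] = False
    return mask.copy_with(vox)


def dilate_mask(mask: BinaryMask, rounds: int = 3,
                footprint: str = "disk") -> BinaryMask:
    """Dilate ``rounds`` times with a radius-1 footprint.

    ``"disk"`` applies a 2D radius-1 disk slicewise in the xy plane each
    round; ``"ball"`` uses a 3D radius-1 ball.
    """
    vox = mask.voxels.copy()
    if footprint == "disk":
        fp = disk(1).astype(bool)
        for _ in range(rounds):
            for z in range(vox.shape[0]):
                vox[z] = ndimage.binary_dilation(vox[z], structure=fp)
    elif footprint == "ball":
        vox = ndimage.binary_dilation(vox, structure=ball(1).astype(bool),
                                      iterations=rounds)
    else:
        raise ValueError("footprint must be 'disk' or 'ball'")
    return mask.copy_with(vox)


def union_masks(masks: list[BinaryMask], dilation_rounds: int = 3,
                footprint: str = "disk") -> BinaryMask:
    """Dilate each registered mask, then take the voxelwise union.

    The union across time points bridges transient gaps (e.g. red blood
    cell plugs occluding the dye at single time points).
    """
    if not masks:
        raise ValueError("need at least one mask")
    shape, vs = masks[0].shape, masks[0].voxel_size
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        if m.shape != shape or not np.allclose(m.voxel_size, vs):
            raise ValueError("masks must share one grid")
        out |= dilate_mask(m, rounds=dilation_rounds, footprint=footprint).voxels
    return BinaryMask(out, vs, label=masks[0].label)


def _surface_points(mask: BinaryMask) -> np.ndarray:
    """Boundary voxel centers (μm): foreground with a background 6-neighbor."""
    vox = mask.voxels
    eroded = ndimage.binary_erosion(vox, structure=_STRUCT_6, border_value=0)
    pts = np.argwhere(vox & ~eroded)
    return pts * np.array(mask.voxel_size)


def segmentation_metrics(truth: BinaryMask, pred: BinaryMask) -> dict:
    """Overlap and surface agreement between truth and prediction.

    Returns ``dsc``, ``precision``, ``recall`` (voxel counts) and ``hd95``,
    ``mean_surface_distance`` in μm (Euclidean, between boundary voxel
    centers).
    """
    from scipy.spatial import cKDTree

    if truth.shape != pred.shape:
        raise ValueError("masks must share one grid")
    x, y = truth.voxels, pred.voxels
    if not x.any() or not y.any():
        raise ValueError("surface metrics undefined for empty masks")
    tp = float(np.sum(x & y))
    fp = float(np.sum(~x & y))
    fn = float(np.sum(x & ~y))
    dsc = 2 * tp / (x.sum() + y.sum())
    sx, sy = _surface_points(truth), _surface_points(pred)
    d_xy, _ = cKDTree(sy).query(sx, workers=-1)
    d_yx, _ = cKDTree(sx).query(sy, workers=-1)
    hd95 = max(np.percentile(d_xy, 95), np.percentile(d_yx, 95))
    msd = (d_xy.sum() + d_yx.sum()) / (len(d_xy) + len(d_yx))
    return {
        "dsc": float(dsc),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "hd95": float(hd95),
        "mean_surface_distance": float(msd),
    }
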