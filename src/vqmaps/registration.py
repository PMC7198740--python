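"""CT-driven rigid + deformable registration onto a reference geometry.

The registration contract mirrors the clinical workflow: a rigid
"box-based" alignment of the lung-mask bounding boxes initializes an
intensity-based free-form (diffeomorphic-demons) registration between
masked CTs; the composed transform is then applied to the SPECT volumes
(linear interpolation) or label volumes (nearest neighbour).

SimpleITK provides the demons optimizer and resampling; this module owns
the conventions: transforms map *reference (fixed) world points to moving
world points* (the resampling direction), all stored in RAS mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import SimpleITK as sitk

from .image_io import VolumeImage
from .segmentation import LungMask

__all__ = [
    "RigidTransform",
    "DeformationField",
    "RegistrationError",
    "register_rigid",
    "register_deformable",
    "apply_transform",
    "dice",
]

log = logging.getLogger(__name__)

_F = np.diag([-1.0, -1.0, 1.0])  # RAS <-> LPS world flip

# multi-resolution schedule: (shrink factor, demons iterations)
DEMONS_LEVELS = ((4, 60), (2, 40), (1, 15))
DEMONS_SMOOTHING = 0.8  # displacement-field Gaussian sigma (grid units)


class RegistrationError(RuntimeError):
    """Raised on degenerate inputs or non-convergence."""


# ---------------------------------------------------------------------------
# SimpleITK interop


def to_sitk(vol: VolumeImage, dtype=np.float32) -> sitk.Image:
    arr = np.ascontiguousarray(np.transpose(vol.values, (2, 1, 0)).astype(dtype))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(_F @ np.asarray(vol.origin)))
    img.SetDirection(tuple((_F @ vol.direction).flatten()))
    return img


def from_sitk(img: sitk.Image, like: VolumeImage) -> VolumeImage:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return like.with_values(arr)


# ---------------------------------------------------------------------------
# Transform types


@dataclass
class RigidTransform:
    """x_moving = rotation @ x_fixed + translation, world RAS mm."""

    rotation: np.ndarray = dfield(default_factory=lambda: np.eye(3))
    translation: np.ndarray = dfield(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-5):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=1e-9) and np.allclose(
            self.translation, 0, atol=1e-9
        )

    def to_sitk(self) -> sitk.Transform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple((_F @ self.rotation @ _F).flatten()))
        t.SetTranslation(tuple(_F @ self.translation))
        return t

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class DeformationField:
    """Composed transform onto the reference grid.

    ``displacement`` holds per-voxel RAS world-mm vectors u on the
    reference grid; a reference point x maps to the moving point
    ``rigid(x + u(x))`` (rigid first in the anatomical sense: the
    deformable correction is expressed in the rigidly aligned frame).
    ``jacobian_positive_fraction`` is a logged diagnostic over the grid.
    """

    displacement: np.ndarray  # (nx, ny, nz, 3) mm RAS
    rigid: RigidTransform
    reference: VolumeImage    # carries the target grid geometry
    jacobian_positive_fraction: float = 1.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def is_identity(self) -> bool:
        return self.rigid.is_identity and not np.any(self.displacement)

    def _disp_sitk(self) -> sitk.Image:
        return _displacement_image(self.displacement, self.reference)

    def to_sitk(self) -> sitk.Transform:
        comp = sitk.CompositeTransform(3)
        comp.AddTransform(self.rigid.to_sitk())
        # added last => applied first: x -> x + u(x), then rigid
        comp.AddTransform(sitk.DisplacementFieldTransform(self._disp_sitk()))
        return comp

    @property
    def max_displacement_mm(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=-1).max())


def _displacement_image(disp_ras: np.ndarray, ref: VolumeImage) -> sitk.Image:
    """Pack an (nx, ny, nz, 3) RAS-mm displacement array as a sitk image."""
    disp_lps = disp_ras @ _F  # flip x,y vector components
    arr = np.ascontiguousarray(np.transpose(disp_lps, (2, 1, 0, 3)).astype(np.float64))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(ref.spacing))
    img.SetOrigin(tuple(_F @ np.asarray(ref.origin)))
    img.SetDirection(tuple((_F @ ref.direction).flatten()))
    return img


# ---------------------------------------------------------------------------
# Rigid stage


def _mask_bbox_center(mask: LungMask) -> np.ndarray:
    coords = np.argwhere(mask.binary)
    if coords.size == 0:
        raise RegistrationError("empty lung mask")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    return mask.labels.voxel_to_world((lo + hi) / 2.0)


def register_rigid(
    moving_ct: VolumeImage,
    fixed_ct: VolumeImage,
    moving_mask: LungMask,
    fixed_mask: LungMask,
    refine: bool = True,
    refine_iterations: int = 40,
) -> RigidTransform:
    """Box-based rigid alignment of lung masks, optionally refined.

    The initial translation aligns the lung-mask bounding-box centers;
    refinement runs a short mean-squares Euler3D optimization on the
    masked CT intensities.
    """
    c_m = _mask_bbox_center(moving_mask)
    c_f = _mask_bbox_center(fixed_mask)
    init = RigidTransform(translation=c_m - c_f)

    if (
        moving_ct.same_grid(fixed_ct)
        and np.array_equal(moving_ct.values, fixed_ct.values)
        and np.allclose(init.translation, 0, atol=1e-6)
    ):
        return RigidTransform()

    if not refine:
        _warn_low_overlap(moving_mask, fixed_mask, init)
        return init

    fixed_img = to_sitk(fixed_ct)
    moving_img = to_sitk(moving_ct)
    tx = sitk.Euler3DTransform()
    tx.SetCenter(tuple(_F @ c_f))
    tx.SetTranslation(tuple(_F @ init.translation))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-3, numberOfIterations=refine_iterations
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetShrinkFactorsPerLevel([2])
    reg.SetSmoothingSigmasPerLevel([1.0])
    try:
        reg.Execute(fixed_img, moving_img)
    except RuntimeError as exc:  # pragma: no cover - optimizer edge cases
        log.warning("rigid refinement failed (%s); keeping box alignment", exc)
        return init
    A = _F @ np.asarray(tx.GetMatrix()).reshape(3, 3) @ _F
    c = _F @ np.asarray(tx.GetCenter())
    t = _F @ np.asarray(tx.GetTranslation())
    out = RigidTransform(rotation=A, translation=c + t - A @ c)
    _warn_low_overlap(moving_mask, fixed_mask, out)
    return out


def _warn_low_overlap(moving_mask: LungMask, fixed_mask: LungMask,
                      transform: RigidTransform) -> None:
    """Log a warning when box alignment leaves the masks non-overlapping."""
    zero = DeformationField(
        displacement=np.zeros(fixed_mask.labels.shape + (3,)),
        rigid=transform,
        reference=fixed_mask.labels,
    )
    moved = apply_transform(moving_mask.labels, zero, interpolation="nearest")
    overlap = np.logical_and(moved.values > 0, fixed_mask.binary).sum()
    if overlap == 0:
        log.warning("zero lung-mask overlap after rigid box alignment")


# ---------------------------------------------------------------------------
# Deformable stage


_LAPLACE_KERNEL = np.zeros((3, 3, 3))
for _offset in ((1, 1, 0), (1, 1, 2), (1, 0, 1), (1, 2, 1), (0, 1, 1), (2, 1, 1)):
    _LAPLACE_KERNEL[_offset] = 1.0 / 6.0


def _harmonic_interior(disp: np.ndarray, interior: np.ndarray,
                       coarse_iters: int = 150, fine_iters: int = 15) -> np.ndarray:
    """Replace the field inside ``interior`` by a harmonic extension.

    The lung interior is (nearly) homogeneous on CT, so intensities carry
    no correspondence information there; the demons update fills it with
    a poorly constrained diffusion of noise and edge forces.  Solving the
    Laplace equation per displacement component, with the demons field on
    the boundary shell as Dirichlet data, interpolates the interior
    smoothly — exactly reproducing any affine (hence linear, hence
    harmonic) component of the true inter-subject warp.  A coarse-grid
    relaxation followed by a short fine-grid polish keeps this fast.
    """
    from scipy import ndimage

    def relax(u, region, iters):
        for _ in range(iters):
            for a in range(3):
                avg = ndimage.convolve(u[..., a], _LAPLACE_KERNEL, mode="nearest")
                u[..., a][region] = avg[region]
        return u

    coarse = np.stack([ndimage.zoom(disp[..., a], 0.5, order=1)
                       for a in range(3)], axis=-1)
    region_c = ndimage.zoom(interior.astype(float), 0.5, order=1) > 0.5
    coarse = relax(coarse, region_c, coarse_iters)
    factors = np.asarray(disp.shape[:3]) / np.asarray(coarse.shape[:3])
    up = np.stack([ndimage.zoom(coarse[..., a], factors, order=1)
                   for a in range(3)], axis=-1)
    out = disp.copy()
    out[interior] = up[interior]
    return relax(out, interior, fine_iters)


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(
        img, [factor * s / 2.0 for s in img.GetSpacing()]
    )
    return sitk.Shrink(smoothed, [factor] * 3)


def register_deformable(
    moving_ct: VolumeImage,
    fixed_ct: VolumeImage,
    init: RigidTransform = None,
    levels=None,
    smoothing_sigma: float = None,
) -> DeformationField:
    """Multi-resolution diffeomorphic-demons registration of masked CTs.

    Returns the composed transform (rigid initialization + displacement
    field on the fixed grid).  Raises :class:`RegistrationError` when the
    coarsest level fails to reduce the mean-squared intensity difference.
    """
    if init is None:
        init = RigidTransform()
    if levels is None:
        levels = DEMONS_LEVELS
    if smoothing_sigma is None:
        smoothing_sigma = DEMONS_SMOOTHING
    if (
        moving_ct.same_grid(fixed_ct)
        and np.array_equal(moving_ct.values, fixed_ct.values)
        and init.is_identity
    ):
        # exact fixed point of self-registration
        return DeformationField(
            displacement=np.zeros(fixed_ct.shape + (3,)),
            rigid=init,
            reference=fixed_ct,
        )

    fixed_img = to_sitk(fixed_ct)
    moving_img = to_sitk(moving_ct)
    if not init.is_identity or not moving_ct.same_grid(fixed_ct):
        moving_img = sitk.Resample(
            moving_img, fixed_img, init.to_sitk(), sitk.sitkLinear, 0.0
        )

    disp = None
    for li, (shrink, iters) in enumerate(levels):
        fi = _shrink(fixed_img, shrink)
        mi = _shrink(moving_img, shrink)
        if disp is None:
            disp = sitk.Image(fi.GetSize(), sitk.sitkVectorFloat64, 3)
            disp.CopyInformation(fi)
        else:
            disp = sitk.Resample(disp, fi, sitk.Transform(), sitk.sitkLinear)
            disp = sitk.Cast(disp, sitk.sitkVectorFloat64)
        demons = sitk.DiffeomorphicDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(smoothing_sigma)
        if li == 0:
            before = _mean_sq_diff(fi, mi, disp)
        disp = demons.Execute(fi, mi, disp)
        if li == 0:
            after = _mean_sq_diff(fi, mi, disp)
            if after > before:
                raise RegistrationError(
                    f"demons diverged at coarsest level: MSD {before:.1f} -> {after:.1f}"
                )

    disp_ras = np.transpose(sitk.GetArrayFromImage(disp), (2, 1, 0, 3)) @ _F

    # intensities carry no correspondence in the homogeneous lung interior:
    # fill it by harmonic interpolation of the boundary-shell field
    from scipy import ndimage

    interior = ndimage.binary_erosion(np.asarray(fixed_ct.values) != 0,
                                      iterations=1)
    if interior.any():
        disp_ras = _harmonic_interior(disp_ras, interior)

    jac = sitk.GetArrayFromImage(
        sitk.DisplacementFieldJacobianDeterminant(
            _displacement_image(disp_ras, fixed_ct)))
    jac_pos = float((jac > 0).mean())
    if jac_pos < 0.99:
        log.warning("deformation field folds at %.1f%% of voxels", 100 * (1 - jac_pos))

    return DeformationField(
        displacement=disp_ras,
        rigid=init,
        reference=fixed_ct,
        jacobian_positive_fraction=jac_pos,
    )


def _mean_sq_diff(fixed: sitk.Image, moving: sitk.Image, disp) -> float:
    if disp is not None:
        tx = sitk.DisplacementFieldTransform(sitk.Image(disp))
        moving = sitk.Resample(moving, fixed, tx, sitk.sitkLinear, 0.0)
    d = sitk.GetArrayFromImage(fixed) - sitk.GetArrayFromImage(moving)
    return float(np.mean(d ** 2))


# ---------------------------------------------------------------------------
# Resampling and diagnostics


def apply_transform(vol: VolumeImage, field: DeformationField,
                    interpolation: str = "linear") -> VolumeImage:
    """Resample ``vol`` onto the reference grid through the composed transform.

    ``interpolation`` is "linear" for intensity volumes or "nearest" for
    labels; passing "linear" with an integer label volume is an error.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    is_label = np.issubdtype(np.asarray(vol.values).dtype, np.integer)
    if is_label and interpolation == "linear":
        raise ValueError("label volumes must use nearest-neighbour interpolation")

    if field.is_identity and vol.same_grid(field.reference):
        return field.reference.with_values(
            vol.values.copy(), modality=vol.modality, ac_flag=vol.ac_flag
        )

    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    dtype = vol.values.dtype if is_label else np.float64
    img = to_sitk(vol, dtype=dtype)
    ref = to_sitk(field.reference, dtype=dtype)
    out = sitk.Resample(img, ref, field.to_sitk(), interp, 0.0)
    arr = np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0)).astype(dtype)
    return field.reference.with_values(arr, modality=vol.modality,
                                       ac_flag=vol.ac_flag)


def dice(a, b) -> float:
    """Dice overlap 2|A^B| / (|A| + |B|) of two foreground label volumes."""
    av = a.values if isinstance(a, VolumeImage) else np.asarray(a)
    bv = b.values if isinstance(b, VolumeImage) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("dice requires volumes on the same grid")
    af = av > 0
    bf = bv > 0
    denom = af.sum() + bf.sum()
    if denom == 0:
        log.warning("dice of two empty masks: defined as 1.0")
        return 1.0
    return float(2.0 * np.logical_and(af, bf).sum() / denom)
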