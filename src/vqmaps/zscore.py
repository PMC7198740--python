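"""Patient-space Z-score maps against the normal database.

The database (reference-space) mean and SD maps are transported into the
patient's geometry by registering the reference CT onto the patient CT
(the same rigid + deformable scheme used for database construction, run
in the database-to-patient direction) and applying the transform to both
maps with linear interpolation.  The patient SPECT is normalized to an
in-lung mean of 1000 using the patient's own CT lung segmentation, and

    z(x) = (patient(x) - mean_map(x)) / sd_map(x)

is evaluated on a validity mask: lung voxels whose transported SD is at
least a floor (a small fraction of the in-lung median SD), guarding the
division against near-zero SD voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .image_io import VolumeImage, require_same_grid
from .registration import (
    DeformationField,
    RegistrationError,
    apply_transform,
    dice,
    register_deformable,
    register_rigid,
)
from .segmentation import LungMask, mask_outside
from .statmaps import StatMapSet, normalize_mean

__all__ = [
    "ZScoreMap",
    "register_database_to_patient",
    "map_database_to_patient",
    "compute_zscore",
    "region_summary",
]

log = logging.getLogger(__name__)

SD_FLOOR_FRACTION = 0.05
PATIENT_DICE_GATE = 0.85


@dataclass
class ZScoreMap:
    """Voxel-wise z values on the patient grid plus the validity mask."""

    z: VolumeImage
    validity: np.ndarray
    floor: float
    modality: str = "perfusion"
    ac_flag: str = "AC"

    def __post_init__(self):
        if not np.all(np.isfinite(self.z.values[self.validity])):
            raise ValueError("z values must be finite on the validity mask")


def register_database_to_patient(
    reference_ct: VolumeImage,
    reference_mask: LungMask,
    patient_ct: VolumeImage,
    patient_mask: LungMask,
    dice_gate: float = PATIENT_DICE_GATE,
    rigid_refine: bool = False,
) -> DeformationField:
    """Register the reference CT onto the patient CT (database -> patient).

    Raises :class:`RegistrationError` when the transported reference lung
    mask reaches a Dice below ``dice_gate`` against the patient's lungs.
    """
    moving = mask_outside(reference_ct, reference_mask)
    fixed = mask_outside(patient_ct, patient_mask)
    rigid = register_rigid(moving, fixed, reference_mask, patient_mask,
                           refine=rigid_refine)
    field = register_deformable(moving, fixed, init=rigid)
    moved_mask = apply_transform(reference_mask.labels, field, "nearest")
    d = dice(moved_mask, patient_mask.labels)
    if d < dice_gate:
        raise RegistrationError(
            f"database-to-patient registration quality gate failed: "
            f"lung Dice {d:.3f} < {dice_gate}"
        )
    log.info("database-to-patient lung Dice %.3f", d)
    return field


def map_database_to_patient(
    maps: StatMapSet,
    reference_ct: VolumeImage,
    patient_ct: VolumeImage,
    patient_mask: LungMask,
    reference_mask: LungMask = None,
    field: DeformationField = None,
) -> StatMapSet:
    """Transport one mean/SD map set into the patient's geometry.

    A precomputed ``field`` (from :func:`register_database_to_patient`)
    can be passed to reuse one registration for several map sets;
    otherwise the reference mask is required (or segmented here).
    """
    if field is None:
        if reference_mask is None:
            from .segmentation import segment_lungs

            reference_mask = segment_lungs(reference_ct)
        field = register_database_to_patient(
            reference_ct, reference_mask, patient_ct, patient_mask
        )
    mean_p = apply_transform(maps.mean_map, field, "linear")
    sd_p = apply_transform(maps.sd_map, field, "linear")
    return replace(maps, mean_map=mean_p, sd_map=sd_p)


def compute_zscore(
    patient_spect: VolumeImage,
    maps_in_patient_space: StatMapSet,
    patient_mask: LungMask,
    sd_floor_fraction: float = SD_FLOOR_FRACTION,
) -> ZScoreMap:
    """Normalize the patient SPECT and score it against the database.

    The validity mask keeps lung voxels whose SD is at least
    ``sd_floor_fraction`` of the in-lung median SD; z is 0 outside it.
    """
    maps = maps_in_patient_space
    require_same_grid(patient_spect, maps.mean_map, "patient SPECT and maps")
    require_same_grid(patient_spect, patient_mask.labels, "patient SPECT and mask")
    normalized = normalize_mean(patient_spect, patient_mask)

    lung = patient_mask.binary
    sd = np.asarray(maps.sd_map.values, dtype=np.float64)
    in_lung_sd = sd[lung]
    floor = float(sd_floor_fraction * np.median(in_lung_sd[in_lung_sd > 0]))
    validity = lung & (sd >= floor)

    z = np.zeros_like(sd)
    z[validity] = (
        np.asarray(normalized.values, dtype=np.float64)[validity]
        - np.asarray(maps.mean_map.values, dtype=np.float64)[validity]
    ) / sd[validity]
    return ZScoreMap(
        z=patient_spect.with_values(z, modality=maps.modality, ac_flag=maps.ac_flag),
        validity=validity,
        floor=floor,
        modality=maps.modality,
        ac_flag=maps.ac_flag,
    )


def region_summary(zmap: ZScoreMap, region: np.ndarray) -> dict:
    """Mean and minimum z over a region, restricted to the validity mask."""
    region = np.asarray(region) > 0
    sel = region & zmap.validity
    if not sel.any():
        raise ValueError("region has no valid voxels")
    vals = np.asarray(zmap.z.values)[sel]
    return {
        "mean_z": float(vals.mean()),
        "min_z": float(vals.min()),
        "n_voxels": int(sel.sum()),
    }
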