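"""Mean-based normalization and voxel-wise mean / SD statistical maps.

Each co-registered SPECT is scaled so its mean value inside the reference
lung mask equals 1000 (the whole-lung mean is stored, every voxel is
multiplied by 1000 and divided by it).  Normalizing by the mean rather
than the maximum makes the scale insensitive to bronchial hot spots.
The normal database is then the voxel-wise arithmetic mean and the
sample standard deviation (n-1 denominator) over the n normalized cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import VolumeImage, require_same_grid
from .segmentation import LungMask

__all__ = ["NormalizationParams", "StatMapSet", "normalize_mean", "build_stat_maps"]

TARGET_MEAN = 1000.0


@dataclass
class NormalizationParams:
    """Record of one case's normalization: scale = target_mean / stored_mean."""

    stored_mean: float
    target_mean: float = TARGET_MEAN

    def __post_init__(self):
        if not self.stored_mean > 0:
            raise ValueError("stored in-mask mean must be positive")

    @property
    def scale(self) -> float:
        return self.target_mean / self.stored_mean


@dataclass
class StatMapSet:
    """Voxel-wise mean and SD maps over a normalized, co-registered cohort."""

    mean_map: VolumeImage
    sd_map: VolumeImage
    n: int
    modality: str
    ac_flag: str
    case_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("statistical maps need n >= 2 cases")
        if (self.sd_map.values < 0).any():
            raise ValueError("SD map must be non-negative")


def normalize_mean(vol: VolumeImage, mask: LungMask) -> VolumeImage:
    """Scale all voxels so the in-mask mean equals 1000.

    The uniform global factor is applied to every voxel, inside and
    outside the mask.  Raises ``ValueError`` when the in-mask mean is not
    positive.
    """
    require_same_grid(vol, mask.labels, "volume and normalization mask")
    m = mask.binary
    if not m.any():
        raise ValueError("normalization mask is empty")
    stored = float(np.asarray(vol.values, dtype=np.float64)[m].mean())
    params = NormalizationParams(stored_mean=stored)  # validates stored > 0
    return vol.with_values(np.asarray(vol.values, dtype=np.float64) * params.scale)


def build_stat_maps(normalized: list, modality: str, ac_flag: str,
                    case_ids: list = None) -> StatMapSet:
    """Voxel-wise mean and sample SD (n-1) over >= 2 normalized volumes."""
    if len(normalized) < 2:
        raise ValueError("need at least 2 volumes to build statistical maps")
    ref = normalized[0]
    for v in normalized[1:]:
        require_same_grid(ref, v, "normalized volumes")
    stack = np.stack([np.asarray(v.values, dtype=np.float64) for v in normalized])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return StatMapSet(
        mean_map=ref.with_values(mean, modality=modality, ac_flag=ac_flag),
        sd_map=ref.with_values(sd, modality=modality, ac_flag=ac_flag),
        n=len(normalized),
        modality=modality,
        ac_flag=ac_flag,
        case_ids=list(case_ids) if case_ids else [],
    )
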