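"""CT lung segmentation, masking, lobe handling and reference selection.

Lungs are segmented by Hounsfield thresholding (air-like voxels below
-400 HU), removal of background air connected to the volume border,
keeping the two largest remaining components, and a binary closing to
fill vessel-sized holes.  Components are labeled right (1) / left (2) by
their world x centroid (RAS: +x is the patient's right).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image_io import CaseRecord, VolumeImage, require_same_grid

__all__ = [
    "LungMask",
    "SegmentationError",
    "segment_lungs",
    "mask_outside",
    "select_reference",
    "attach_lobes",
    "lung_volume_ml",
]

log = logging.getLogger(__name__)

HU_THRESHOLD = -400.0
CLOSING_RADIUS_VOX = 2


class SegmentationError(RuntimeError):
    """Raised when no lung candidate component can be found."""


@dataclass
class LungMask:
    """Label volume: 0 background, 1 right lung, 2 left lung."""

    labels: VolumeImage

    @property
    def binary(self) -> np.ndarray:
        return self.labels.values > 0

    @property
    def right(self) -> np.ndarray:
        return self.labels.values == 1

    @property
    def left(self) -> np.ndarray:
        return self.labels.values == 2

    @property
    def volume_ml(self) -> float:
        """Total (left + right) lung volume in mL."""
        voxel_mm3 = float(np.prod(self.labels.spacing))
        return float(self.binary.sum()) * voxel_mm3 / 1000.0


def lung_volume_ml(mask: LungMask) -> float:
    return mask.volume_ml


def _ball(radius: int) -> np.ndarray:
    z = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(z, z, z, indexing="ij")
    return xx ** 2 + yy ** 2 + zz ** 2 <= radius ** 2


def segment_lungs(ct: VolumeImage) -> LungMask:
    """Segment the lungs on a CT volume (HU).

    Raises :class:`SegmentationError` when no candidate component
    remains after background removal.  A single remaining component is
    accepted (single-lung failure mode) and labeled by its side.
    """
    air = ct.values < HU_THRESHOLD
    lab, n = ndimage.label(air)
    if n == 0:
        raise SegmentationError("no sub-threshold voxels: cannot find lungs")
    # drop components touching the volume border (outside-body air)
    border = np.zeros(ct.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    touching = np.unique(lab[border & air])
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    candidates = [
        i + 1 for i in range(n) if (i + 1) not in touching and sizes[i] >= 10
    ]
    if not candidates:
        raise SegmentationError("no interior air component: cannot find lungs")
    candidates.sort(key=lambda i: -sizes[i - 1])
    keep = candidates[:2]
    if len(keep) == 1:
        log.warning("single lung candidate found; proceeding with one lung")

    # label right/left by world x of centroid (RAS: +x = right)
    out = np.zeros(ct.shape, dtype=np.int16)
    cents = []
    for comp in keep:
        m = lab == comp
        cx = ct.voxel_to_world(np.argwhere(m).mean(axis=0))[0]
        cents.append((cx, m))
    cents.sort(key=lambda t: -t[0])  # largest x first = right
    codes = [1, 2] if len(cents) == 2 else [1 if cents[0][0] >= 0 else 2]
    # single-lung: decide side by sign of x relative to grid center
    if len(cents) == 1:
        center_x = ct.voxel_to_world((np.asarray(ct.shape) - 1) / 2.0)[0]
        codes = [1 if cents[0][0] >= center_x else 2]
    struct = _ball(CLOSING_RADIUS_VOX)
    for code, (_, m) in zip(codes, cents):
        closed = ndimage.binary_closing(m, structure=struct)
        out[closed & (out == 0)] = code
    return LungMask(labels=ct.with_values(out, modality="label"))


def mask_outside(vol: VolumeImage, mask: LungMask) -> VolumeImage:
    """Set every voxel outside the lung mask to exactly 0 (idempotent)."""
    require_same_grid(vol, mask.labels, "volume and mask")
    m = mask.binary
    if not m.any():
        log.warning("mask_outside called with an empty mask: output all zero")
    return vol.with_values(np.where(m, vol.values, 0))


def select_reference(cohort: list, masks: dict = None) -> str:
    """Pick the case whose total lung volume is closest to the cohort median.

    ``masks`` optionally maps case_id -> LungMask; otherwise masks come
    from ``lung_truth`` labels or are segmented from the CT.  Ties are
    broken by lexicographically smallest case_id.
    """
    if not cohort:
        raise ValueError("empty cohort")
    vols = {}
    for case in cohort:
        if masks is not None and case.case_id in masks:
            m = masks[case.case_id]
        elif case.lung_truth is not None:
            m = LungMask(labels=case.lung_truth)
        else:
            m = segment_lungs(case.ct)
        vols[case.case_id] = m.volume_ml
    median = float(np.median(list(vols.values())))
    return min(vols, key=lambda cid: (abs(vols[cid] - median), cid))


def attach_lobes(case: CaseRecord, lobes: VolumeImage,
                 tolerance: float = 0.01) -> CaseRecord:
    """Attach a supplied 5-lobe label map to a case.

    The lobe voxels must lie within the case's lung mask up to
    ``tolerance`` (fraction of lobe voxels); lobes are supplied (phantom
    truth or user labels), never inferred from fissures.
    """
    require_same_grid(case.ct, lobes, "case and lobe map")
    if case.lung_truth is not None:
        lung = case.lung_truth.values > 0
    else:
        lung = segment_lungs(case.ct).binary
    lobe_fg = lobes.values > 0
    n_lobe = int(lobe_fg.sum())
    if n_lobe == 0:
        raise ValueError("lobe map is empty")
    outside = int((lobe_fg & ~lung).sum())
    if outside > tolerance * n_lobe:
        raise ValueError(
            f"{outside}/{n_lobe} lobe voxels fall outside the lung mask "
            f"(> {tolerance:.0%} tolerance)"
        )
    return replace(case, lobe_truth=lobes)
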