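"""Regional quantification: lobar function, AP/SI gradients, statistics.

Lobar relative function is total counts in a lobe divided by total
counts in the whole lungs.  The gravity gradient is summarized by two
relative differences measured on four spherical ROIs placed on the
anterior, posterior, superior and inferior aspects of the right lung:

    PArd = (anterior - posterior) / posterior  (%)
    ISrd = (superior - inferior) / inferior    (%)

A negative PArd means posterior-dominant uptake (the supine perfusion
pattern).  Statistical helpers cover the Kolmogorov-Smirnov normality
check, the one-sample Student t comparison of individual gradient values
against the map measurement, and the random split-half validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image_io import CaseRecord, VolumeImage, require_same_grid
from .segmentation import LungMask

__all__ = [
    "Roi",
    "RoiSet",
    "GradientMetrics",
    "LobarFunctionTable",
    "lobar_function",
    "place_gradient_rois",
    "gradient_metrics",
    "individual_gradient_metrics",
    "ks_normality",
    "one_sample_t",
    "split_validation",
]

log = logging.getLogger(__name__)

ROI_RADIUS_MM = 10.0
ROI_MIN_RADIUS_MM = 5.0
LOBE_NAMES = ("LLL", "LUL", "RLL", "RML", "RUL")


@dataclass
class Roi:
    name: str
    center_voxel: tuple
    center_world: tuple
    radius_mm: float

    def member_voxels(self, vol: VolumeImage) -> np.ndarray:
        """Boolean grid of voxels whose centers lie within the sphere."""
        grids = np.meshgrid(*[np.arange(n) for n in vol.shape], indexing="ij")
        idx = np.stack(grids, axis=-1).astype(float)
        w = vol.voxel_to_world(idx)
        d2 = ((w - np.asarray(self.center_world)) ** 2).sum(axis=-1)
        return d2 <= self.radius_mm ** 2


@dataclass
class RoiSet:
    """Anterior / posterior / superior / inferior spheres on the right lung."""

    rois: dict  # name -> Roi

    def __post_init__(self):
        names = set(self.rois)
        if names != {"anterior", "posterior", "superior", "inferior"}:
            raise ValueError(f"RoiSet needs the 4 canonical ROIs, got {names}")

    def means(self, vol: VolumeImage) -> dict:
        out = {}
        for name, roi in self.rois.items():
            m = roi.member_voxels(vol)
            out[name] = float(np.asarray(vol.values, dtype=np.float64)[m].mean())
        return out


@dataclass
class GradientMetrics:
    pard: float  # %
    isrd: float  # %
    source: str = "individual case"  # or "statistical map"


@dataclass
class LobarFunctionTable:
    """Per-lobe fraction of whole-lung counts; fractions sum to 1."""

    fractions: dict  # lobe name -> fraction

    def __post_init__(self):
        vals = np.array([self.fractions[k] for k in LOBE_NAMES])
        if (vals < 0).any():
            raise ValueError("lobar fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"lobar fractions sum to {vals.sum()}, not 1")


def lobar_function(vol: VolumeImage, lobes: VolumeImage) -> LobarFunctionTable:
    """Relative lobar function: lobe counts / whole-lung counts."""
    from .phantom import LOBE_CODES

    require_same_grid(vol, lobes, "volume and lobe map")
    vals = np.asarray(vol.values, dtype=np.float64)
    lab = np.asarray(lobes.values)
    total = vals[lab > 0].sum()
    if total <= 0:
        raise ValueError("whole-lung counts are zero")
    fractions = {
        name: float(vals[lab == code].sum() / total)
        for name, code in LOBE_CODES.items()
    }
    return LobarFunctionTable(fractions=fractions)


# ---------------------------------------------------------------------------
# Gradient ROIs


def _fit_roi(mask: LungMask, name: str, center_vox: np.ndarray,
             centroid_vox: np.ndarray) -> Roi:
    """Shift the ROI inward (toward the lung centroid), then shrink, until
    the sphere lies fully inside the right-lung mask."""
    labels = mask.labels
    right = mask.right
    spacing = np.asarray(labels.spacing)
    radius = ROI_RADIUS_MM
    center = center_vox.astype(int).astype(float)
    for _ in range(40):
        roi = Roi(
            name=name,
            center_voxel=tuple(int(c) for c in center),
            center_world=tuple(labels.voxel_to_world(center)),
            radius_mm=radius,
        )
        member = roi.member_voxels(labels)
        if member.any() and not (member & ~right).any():
            return roi
        step = np.sign(centroid_vox - center)
        if np.any(step != 0):
            center = center + step
        else:
            radius -= 1.0
        if radius < ROI_MIN_RADIUS_MM:
            break
    raise ValueError(f"right lung too small to host the {name} ROI sphere")


def place_gradient_rois(mask: LungMask) -> RoiSet:
    """Deterministically place the four gradient ROIs on the right lung.

    Spheres of radius 10 mm centered at 25% / 75% of the right lung's AP
    extent (at mid-SI, mid-LR) and of its SI extent (at mid-AP, mid-LR),
    snapped to voxel centers and shifted/shrunk inward until fully inside
    the mask.
    """
    coords = np.argwhere(mask.right)
    if coords.size == 0:
        raise ValueError("no right lung in mask")
    lo = coords.min(axis=0).astype(float)
    hi = coords.max(axis=0).astype(float)
    mid = (lo + hi) / 2.0
    centroid = coords.mean(axis=0)

    def at(frac_axis, frac):
        c = mid.copy()
        c[frac_axis] = lo[frac_axis] + frac * (hi[frac_axis] - lo[frac_axis])
        return np.round(c)

    targets = {
        "anterior": at(1, 0.75),
        "posterior": at(1, 0.25),
        "superior": at(2, 0.75),
        "inferior": at(2, 0.25),
    }
    rois = {
        name: _fit_roi(mask, name, c, centroid) for name, c in targets.items()
    }
    # sanity: pairwise disjoint spheres
    names = list(rois)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = np.linalg.norm(
                np.asarray(rois[a].center_world) - np.asarray(rois[b].center_world)
            )
            if d < rois[a].radius_mm + rois[b].radius_mm:
                raise ValueError(f"ROIs {a} and {b} overlap")
    return RoiSet(rois=rois)


def gradient_metrics(vol: VolumeImage, rois: RoiSet,
                     source: str = "individual case") -> GradientMetrics:
    """PArd and ISrd (%) from the four ROI mean values."""
    m = rois.means(vol)
    if m["posterior"] <= 0 or m["inferior"] <= 0:
        raise ValueError("posterior/inferior ROI mean must be positive")
    return GradientMetrics(
        pard=100.0 * (m["anterior"] - m["posterior"]) / m["posterior"],
        isrd=100.0 * (m["superior"] - m["inferior"]) / m["inferior"],
        source=source,
    )


def individual_gradient_metrics(case: CaseRecord, modality: str,
                                ac_flag: str) -> GradientMetrics:
    """Gradients of one non-registered case, with ROIs on its native mask."""
    from .segmentation import segment_lungs

    if case.lung_truth is not None:
        mask = LungMask(labels=case.lung_truth)
    else:
        mask = segment_lungs(case.ct)
    rois = place_gradient_rois(mask)
    return gradient_metrics(case.spect(modality, ac_flag), rois)


# ---------------------------------------------------------------------------
# Statistics


def ks_normality(values) -> tuple:
    """One-sample KS test against a normal law with the sample mean/SD.

    Because the parameters are estimated from the same sample, the
    p-value is liberal (Lilliefors situation); a log message records the
    caveat.  Requires >= 5 values and a non-degenerate SD.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("KS normality test needs at least 5 values")
    sd = values.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate sample: SD is zero")
    log.info("KS test with estimated parameters: p-value is liberal (Lilliefors)")
    res = stats.kstest(values, "norm", args=(values.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def one_sample_t(values=None, reference: float = 0.0, *, summary=None) -> tuple:
    """Two-sided one-sample Student t test against a reference value.

    Accepts either raw ``values`` or a printed ``summary=(mean, sd, n)``;
    t = (mean - reference) / (sd / sqrt(n)) with n-1 degrees of freedom.
    """
    if summary is not None:
        mean, sd, n = float(summary[0]), float(summary[1]), int(summary[2])
    else:
        arr = np.asarray(values, dtype=float)
        mean, sd, n = arr.mean(), arr.std(ddof=1), arr.size
    if n < 2:
        raise ValueError("t test needs n >= 2")
    if sd <= 0:
        raise ValueError("t test undefined for zero SD")
    t = (mean - reference) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def split_indices(n: int, seed: int) -> tuple:
    """Random disjoint split of range(n): ceil(n/2) map-building, rest held out."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_build = math.ceil(n / 2)
    return list(order[:n_build]), list(order[n_build:])


def split_validation(cohort: list, seed: int, **pipeline_kwargs):
    """Random split-half validation of the map-building workflow.

    The cohort is split into a map-building subset of ceil(n/2) cases and
    a held-out subset of floor(n/2); mean/SD maps are built from the
    first, gradients of each held-out non-registered case are compared to
    the map measurement with a one-sample t test per modality/AC
    combination.  Returns (report DataFrame, split dict).
    """
    import pandas as pd

    from .pipeline import build_database, map_gradient_metrics

    n = len(cohort)
    if n < 4:
        raise ValueError("split validation needs at least 4 cases")
    build_idx, held_idx = split_indices(n, seed)
    build = [cohort[i] for i in build_idx]
    held = [cohort[i] for i in held_idx]

    db = build_database(build, **pipeline_kwargs)
    rows = []
    for modality in ("perfusion", "ventilation"):
        for ac in ("AC", "NoAC"):
            map_gm = map_gradient_metrics(db, modality, ac)
            indiv = [
                individual_gradient_metrics(c, modality, ac).pard for c in held
            ]
            t, p = one_sample_t(indiv, reference=map_gm.pard)
            rows.append(
                dict(
                    modality=modality,
                    ac_flag=ac,
                    n_individual=len(indiv),
                    individual_mean_pard=float(np.mean(indiv)),
                    individual_sd_pard=float(np.std(indiv, ddof=1)),
                    map_pard=map_gm.pard,
                    map_isrd=map_gm.isrd,
                    t=t,
                    p=p,
                )
            )
    split = {
        "build": [c.case_id for c in build],
        "held_out": [c.case_id for c in held],
    }
    return pd.DataFrame(rows), split
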