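"""End-to-end orchestration: cohort -> normal database -> patient scoring.

`build_database` runs the full map-creation workflow on a cohort:
lung segmentation, reference selection (median lung volume), masked
rigid + deformable registration of every case onto the reference,
propagation of the transform to the four SPECT reconstructions,
mean-based normalization with the reference lung mask, and voxel-wise
mean/SD map construction — eight map volumes per cohort (perfusion and
ventilation, AC and NoAC, mean and SD).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_io import CaseRecord, VolumeImage, read_volume, write_volume
from .registration import apply_transform, dice, register_deformable, register_rigid
from .segmentation import LungMask, mask_outside, segment_lungs, select_reference
from .statmaps import StatMapSet, build_stat_maps, normalize_mean
from .quantify import GradientMetrics, gradient_metrics, place_gradient_rois
from .zscore import ZScoreMap, compute_zscore, map_database_to_patient, \
    register_database_to_patient

__all__ = [
    "NormalDatabase",
    "build_database",
    "map_gradient_metrics",
    "score_patient",
    "save_database",
    "load_database",
    "COMBOS",
]

log = logging.getLogger(__name__)

COMBOS = tuple(
    (modality, ac) for modality in ("perfusion", "ventilation") for ac in ("AC", "NoAC")
)

DATABASE_DICE_GATE = 0.90


@dataclass
class NormalDatabase:
    """The eight statistical map volumes plus provenance."""

    maps: dict                    # (modality, ac_flag) -> StatMapSet
    reference_id: str
    reference_ct: VolumeImage
    reference_mask: LungMask
    case_dice: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return next(iter(self.maps.values())).n


def build_database(
    cohort: list,
    use_truth_masks: bool = True,
    dice_gate: float = DATABASE_DICE_GATE,
    rigid_refine: bool = False,
) -> NormalDatabase:
    """Build the normal mean/SD database from a cohort of cases.

    ``use_truth_masks`` selects phantom ground-truth lung labels when
    present (falling back to CT segmentation); cases whose registered
    lung Dice against the reference falls below ``dice_gate`` are logged
    and excluded from the maps.
    """
    if len(cohort) < 2:
        raise ValueError("database needs at least 2 cases")

    masks = {}
    for case in cohort:
        if use_truth_masks and case.lung_truth is not None:
            masks[case.case_id] = LungMask(labels=case.lung_truth)
        else:
            masks[case.case_id] = segment_lungs(case.ct)

    ref_id = select_reference(cohort, masks)
    ref_case = next(c for c in cohort if c.case_id == ref_id)
    ref_mask = masks[ref_id]
    ref_ct_masked = mask_outside(ref_case.ct, ref_mask)

    registered = {combo: [] for combo in COMBOS}
    case_ids, case_dice, excluded = [], {}, []
    for case in cohort:
        moving_masked = mask_outside(case.ct, masks[case.case_id])
        rigid = register_rigid(
            moving_masked, ref_ct_masked, masks[case.case_id], ref_mask,
            refine=rigid_refine,
        )
        field_ = register_deformable(moving_masked, ref_ct_masked, init=rigid)
        moved_mask = apply_transform(masks[case.case_id].labels, field_, "nearest")
        d = dice(moved_mask, ref_mask.labels)
        case_dice[case.case_id] = d
        if d < dice_gate:
            log.warning("case %s excluded: lung Dice %.3f < %.2f",
                        case.case_id, d, dice_gate)
            excluded.append(case.case_id)
            continue
        for modality, ac in COMBOS:
            moved = apply_transform(case.spect(modality, ac), field_, "linear")
            registered[(modality, ac)].append(normalize_mean(moved, ref_mask))
        case_ids.append(case.case_id)

    if len(case_ids) < 2:
        raise ValueError("fewer than 2 cases passed the registration quality gate")
    maps = {
        combo: build_stat_maps(registered[combo], combo[0], combo[1], case_ids)
        for combo in COMBOS
    }
    return NormalDatabase(
        maps=maps,
        reference_id=ref_id,
        reference_ct=ref_case.ct,
        reference_mask=ref_mask,
        case_dice=case_dice,
        excluded=excluded,
    )


def map_gradient_metrics(db: NormalDatabase, modality: str,
                         ac_flag: str) -> GradientMetrics:
    """PArd/ISrd measured on a database mean map (ROIs on the reference mask)."""
    rois = place_gradient_rois(db.reference_mask)
    return gradient_metrics(db.maps[(modality, ac_flag)].mean_map, rois,
                            source="statistical map")


def score_patient(
    db: NormalDatabase,
    patient: CaseRecord,
    use_truth_mask: bool = True,
    combos=COMBOS,
) -> dict:
    """Z-score a patient case against the database for each combination.

    One database-to-patient registration is shared by all four map sets.
    Returns ``{(modality, ac_flag): ZScoreMap}``.
    """
    if use_truth_mask and patient.lung_truth is not None:
        pmask = LungMask(labels=patient.lung_truth)
    else:
        pmask = segment_lungs(patient.ct)
    field_ = register_database_to_patient(
        db.reference_ct, db.reference_mask, patient.ct, pmask
    )
    out = {}
    for modality, ac in combos:
        maps_p = map_database_to_patient(
            db.maps[(modality, ac)], db.reference_ct, patient.ct, pmask,
            field=field_,
        )
        out[(modality, ac)] = compute_zscore(
            patient.spect(modality, ac), maps_p, pmask
        )
    return out


# ---------------------------------------------------------------------------
# Database persistence (NIfTI maps + JSON provenance)


def save_database(db: NormalDatabase, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (modality, ac), maps in db.maps.items():
        write_volume(maps.mean_map, out_dir / f"{modality}_{ac}_mean.nii.gz")
        write_volume(maps.sd_map, out_dir / f"{modality}_{ac}_sd.nii.gz")
    write_volume(db.reference_ct, out_dir / "reference_ct.nii.gz")
    write_volume(db.reference_mask.labels, out_dir / "reference_lung_mask.nii.gz")
    prov = {
        "n": db.n,
        "reference_id": db.reference_id,
        "case_ids": next(iter(db.maps.values())).case_ids,
        "case_dice": db.case_dice,
        "excluded": db.excluded,
    }
    (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2))


def load_database(db_dir) -> NormalDatabase:
    db_dir = Path(db_dir)
    prov = json.loads((db_dir / "provenance.json").read_text())
    ref_ct = read_volume(db_dir / "reference_ct.nii.gz", "CT")
    ref_mask = LungMask(labels=read_volume(db_dir / "reference_lung_mask.nii.gz",
                                           "label"))
    maps = {}
    for modality, ac in COMBOS:
        mean = read_volume(db_dir / f"{modality}_{ac}_mean.nii.gz", modality, ac)
        sd = read_volume(db_dir / f"{modality}_{ac}_sd.nii.gz", modality, ac)
        maps[(modality, ac)] = StatMapSet(
            mean_map=mean, sd_map=sd, n=prov["n"], modality=modality,
            ac_flag=ac, case_ids=prov["case_ids"],
        )
    return NormalDatabase(
        maps=maps,
        reference_id=prov["reference_id"],
        reference_ct=ref_ct,
        reference_mask=ref_mask,
        case_dice=prov.get("case_dice", {}),
        excluded=prov.get("excluded", []),
    )
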