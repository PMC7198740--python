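"""Lobar function, gradient ROIs/metrics, statistical helpers, split-half."""

import numpy as np
import pytest
from scipy import stats

from vqmaps.image_io import VolumeImage
from vqmaps.phantom import (
    LOBE_CODES,
    PhantomConfig,
    analytic_pard,
    generate_case,
    generate_cohort,
)
from vqmaps.quantify import (
    gradient_metrics,
    individual_gradient_metrics,
    ks_normality,
    lobar_function,
    one_sample_t,
    place_gradient_rois,
    split_indices,
    split_validation,
)
from vqmaps.segmentation import LungMask


def _label_vol(arr, spacing=(4.8,) * 3):
    return VolumeImage(values=arr.astype(np.int16), spacing=spacing,
                       modality="label")


# ---------------------------------------------------------------------------
# Lobar function


def test_uniform_activity_gives_volume_fractions():
    lobes = np.zeros((10, 10, 10))
    lobes[0:2] = LOBE_CODES["RLL"]   # 20% of the 10-slab lung
    lobes[2:10] = LOBE_CODES["LUL"]
    vol = VolumeImage(values=np.ones((10, 10, 10)), spacing=(4.8,) * 3)
    table = lobar_function(vol, _label_vol(lobes))
    assert table.fractions["RLL"] == pytest.approx(0.20)
    assert table.fractions["LUL"] == pytest.approx(0.80)


def test_all_activity_in_one_lobe():
    lobes = np.zeros((6, 6, 6))
    lobes[:3] = LOBE_CODES["RLL"]
    lobes[3:] = LOBE_CODES["LLL"]
    vals = np.zeros((6, 6, 6))
    vals[:3] = 5.0
    table = lobar_function(VolumeImage(values=vals, spacing=(1,) * 3),
                           _label_vol(lobes, (1,) * 3))
    assert table.fractions["RLL"] == pytest.approx(1.0)
    assert table.fractions["LLL"] == 0.0


def test_phantom_lobar_fractions_match_brute_force_sums():
    case = generate_case(PhantomConfig(seed=19), 0)
    table = lobar_function(case.perf_ac, case.lobe_truth)
    vals = case.perf_ac.values
    lab = case.lobe_truth.values
    total = vals[lab > 0].sum()
    for name, code in LOBE_CODES.items():
        assert abs(table.fractions[name] - vals[lab == code].sum() / total) < 1e-12
    assert sum(table.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_zero_counts_rejected():
    lobes = np.zeros((4, 4, 4))
    lobes[:2] = LOBE_CODES["LLL"]
    with pytest.raises(ValueError):
        lobar_function(VolumeImage(values=np.zeros((4, 4, 4)),
                                   spacing=(1,) * 3),
                       _label_vol(lobes, (1,) * 3))


# ---------------------------------------------------------------------------
# Gradient ROIs


@pytest.fixture(scope="module")
def template_mask():
    case = generate_case(PhantomConfig(seed=19, deform_amp_mm=0.0,
                                       affine_scale_range=0.0, noise=False), 0)
    return LungMask(labels=case.lung_truth)


def test_rois_inside_right_lung_and_oriented(template_mask):
    rois = place_gradient_rois(template_mask)
    right = template_mask.right
    for roi in rois.rois.values():
        member = roi.member_voxels(template_mask.labels)
        assert member.any()
        assert not (member & ~right).any()
    assert (rois.rois["anterior"].center_world[1]
            > rois.rois["posterior"].center_world[1])
    assert (rois.rois["superior"].center_world[2]
            > rois.rois["inferior"].center_world[2])


def test_roi_placement_is_deterministic(template_mask):
    a = place_gradient_rois(template_mask)
    b = place_gradient_rois(template_mask)
    for name in a.rois:
        assert a.rois[name].center_voxel == b.rois[name].center_voxel
        assert a.rois[name].radius_mm == b.rois[name].radius_mm


def test_tiny_lung_cannot_host_rois():
    arr = np.zeros((20, 20, 20))
    arr[10, 10, 10] = 1
    with pytest.raises(ValueError):
        place_gradient_rois(LungMask(labels=_label_vol(arr)))


def test_gradient_metric_arithmetic(template_mask):
    rois = place_gradient_rois(template_mask)
    vals = np.zeros(template_mask.labels.shape)
    for name, value in [("anterior", 0.9), ("posterior", 1.1),
                        ("superior", 1.0), ("inferior", 1.0)]:
        vals[rois.rois[name].member_voxels(template_mask.labels)] = value
    gm = gradient_metrics(VolumeImage(values=vals, spacing=(4.8,) * 3), rois)
    assert gm.pard == pytest.approx(-18.18, abs=0.01)
    assert gm.isrd == pytest.approx(0.0, abs=1e-9)


def test_noise_free_phantom_matches_closed_form():
    cfg = PhantomConfig(seed=19, g_sigma=0.0, deform_amp_mm=0.0,
                        affine_scale_range=0.0, noise=False)
    case = generate_case(cfg, 0)
    rois = place_gradient_rois(LungMask(labels=case.lung_truth))
    for modality, ac in [("perfusion", "AC"), ("perfusion", "NoAC"),
                         ("ventilation", "AC")]:
        gm = gradient_metrics(case.spect(modality, ac), rois)
        assert gm.pard == pytest.approx(analytic_pard(cfg, modality, ac),
                                        abs=0.1)


# ---------------------------------------------------------------------------
# Statistics


def test_ks_statistic_matches_brute_force_ecdf():
    rng = np.random.default_rng(0)
    values = rng.normal(10, 3, size=40)
    stat, _ = ks_normality(values)
    xs = np.sort(values)
    cdf = stats.norm.cdf(xs, values.mean(), values.std(ddof=1))
    n = len(xs)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    assert stat == pytest.approx(max(d_plus, d_minus), abs=1e-12)


def test_ks_accepts_normal_samples_most_of_the_time():
    rng = np.random.default_rng(123)
    accepted = sum(
        ks_normality(rng.normal(-18.1, 16.2, size=73))[1] > 0.05
        for _ in range(100))
    assert accepted >= 90


def test_ks_degenerate_and_short_samples_rejected():
    with pytest.raises(ValueError):
        ks_normality([1.0, 1.0, 1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        ks_normality([1.0, 2.0])


@pytest.mark.parametrize(
    "summary, reference, expected_p",
    [((-18.1, 16.2, 73), -18.3, 0.91),   # perfusion NoAC, whole series
     ((7.9, 28.7, 73), 10.4, 0.46)],     # ventilation AC, whole series
)
def test_t_test_reproduces_published_rows(summary, reference, expected_p):
    """Printed cohort summaries reproduce the published p-values (+-0.02;
    the printed inputs are rounded to one decimal)."""
    _, p = one_sample_t(summary=summary, reference=reference)
    assert p == pytest.approx(expected_p, abs=0.02)


def test_t_test_exact_null():
    t, p = one_sample_t([1.0, 2.0, 3.0], reference=2.0)
    assert t == 0.0
    assert p == 1.0


def test_t_test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        one_sample_t([2.0, 2.0], reference=1.0)
    with pytest.raises(ValueError):
        one_sample_t(summary=(5.0, 1.0, 1), reference=1.0)


# ---------------------------------------------------------------------------
# Split-half validation


def test_split_sizes_match_published_design():
    build, held = split_indices(73, seed=0)
    assert (len(build), len(held)) == (37, 36)
    build, held = split_indices(10, seed=0)
    assert (len(build), len(held)) == (5, 5)
    assert set(build).isdisjoint(held)
    assert sorted(build + held) == list(range(10))


def test_split_is_seeded_and_seed_sensitive():
    assert split_indices(20, seed=7) == split_indices(20, seed=7)
    assert split_indices(20, seed=7) != split_indices(20, seed=8)


def test_split_validation_report(default_cohort):
    report, split = split_validation(default_cohort[:8], seed=5)
    assert len(report) == 4
    assert set(report["modality"]) == {"perfusion", "ventilation"}
    assert len(split["build"]) == 4 and len(split["held_out"]) == 4
    assert set(split["build"]).isdisjoint(split["held_out"])
    assert np.isfinite(report["p"]).all()


def test_split_validation_needs_four_cases(default_cohort):
    with pytest.raises(ValueError):
        split_validation(default_cohort[:3], seed=0)
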