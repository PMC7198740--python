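"""Phantom generator: determinism, count statistics, defects, closed forms."""

import numpy as np
import pytest
from scipy import integrate

from vqmaps.phantom import (
    DefectSpec,
    PhantomConfig,
    analytic_pard,
    default_pe_defect,
    generate_case,
    generate_cohort,
    inject_defect,
    _ball_mean_lin_exp,
)
from vqmaps.quantify import gradient_metrics, place_gradient_rois
from vqmaps.segmentation import LungMask


def test_generation_is_deterministic():
    cfg = PhantomConfig(seed=5)
    a = generate_case(cfg, 3)
    b = generate_case(cfg, 3)
    for name in ("ct", "perf_ac", "perf_noac", "vent_ac", "vent_noac"):
        np.testing.assert_array_equal(getattr(a, name).values,
                                      getattr(b, name).values)
    np.testing.assert_array_equal(a.lobe_truth.values, b.lobe_truth.values)


def test_counts_nonnegative_and_lobes_partition_lungs():
    case = generate_case(PhantomConfig(seed=2), 0)
    for name in ("perf_ac", "perf_noac", "vent_ac", "vent_noac"):
        assert getattr(case, name).values.min() >= 0
    lung = case.lung_truth.values
    lobe = case.lobe_truth.values
    assert np.array_equal(lobe > 0, lung > 0)
    right_lobes = np.isin(lobe, [3, 4, 5])
    assert np.array_equal(right_lobes, lung == 1)


def test_no_gradient_case_is_uniform_with_zero_pard():
    cfg = PhantomConfig(seed=1, g_pa_perf=0.0, g_pa_vent=0.0, g_sigma=0.0,
                        atten_mu=0.0, deform_amp_mm=0.0, affine_scale_range=0.0,
                        noise=False)
    case = generate_case(cfg, 0)
    lung = case.lung_truth.values > 0
    in_lung = case.perf_ac.values[lung]
    np.testing.assert_allclose(in_lung, in_lung[0], rtol=1e-12)
    rois = place_gradient_rois(LungMask(labels=case.lung_truth))
    gm = gradient_metrics(case.perf_ac, rois)
    assert gm.pard == pytest.approx(0.0, abs=1e-9)
    assert analytic_pard(cfg, "perfusion", "AC") == pytest.approx(0.0, abs=1e-12)


def test_in_lung_counts_hit_budget():
    """Poisson-mean oracle: 100 replicate subjects average to the budget."""
    cfg = PhantomConfig(seed=9, deform_amp_mm=0.0, count_budget=1e6)
    totals = []
    for i in range(100):
        case = generate_case(cfg, i)
        totals.append(case.perf_ac.values[case.lung_truth.values > 0].sum())
    totals = np.asarray(totals)
    se = totals.std(ddof=1) / np.sqrt(totals.size)
    assert abs(totals.mean() - 1e6) < 3 * se + 1e-6 * 1e6


def test_cohort_cases_are_distinct():
    cohort = generate_cohort(PhantomConfig(seed=4), 5)
    assert len({c.case_id for c in cohort}) == 5
    assert not np.array_equal(cohort[0].ct.values, cohort[1].ct.values)


def test_single_case_cohort_rejected():
    with pytest.raises(ValueError):
        generate_cohort(PhantomConfig(seed=4), 1)


def test_gradient_spread_recovered():
    """Sampling-distribution oracle: truth g SD ~ g_sigma over 200 subjects."""
    cfg = PhantomConfig(seed=8, g_sigma=0.05, deform_amp_mm=0.0, noise=False)
    gs = [generate_case(cfg, i).truth_params["g_perf"] for i in range(200)]
    assert np.std(gs, ddof=1) == pytest.approx(0.05, rel=0.20)


# ---------------------------------------------------------------------------
# Defect injection


@pytest.fixture(scope="module")
def clean_defect_pair():
    cfg = PhantomConfig(seed=6, noise=False)
    case = generate_case(cfg, 0)
    spec = default_pe_defect(case, defect_fraction=0.2)
    return case, inject_defect(case, spec)


def test_defect_scales_expected_perfusion_exactly(clean_defect_pair):
    case, (pe_case, wedge) = clean_defect_pair
    w = wedge.values > 0
    assert w.any()
    np.testing.assert_allclose(pe_case.perf_ac.values[w],
                               0.2 * case.perf_ac.values[w], rtol=1e-6)
    np.testing.assert_allclose(pe_case.perf_ac.values[~w],
                               case.perf_ac.values[~w], rtol=1e-6)


def test_defect_leaves_ventilation_untouched(clean_defect_pair):
    case, (pe_case, _) = clean_defect_pair
    np.testing.assert_array_equal(pe_case.vent_ac.values, case.vent_ac.values)
    np.testing.assert_array_equal(pe_case.vent_noac.values,
                                  case.vent_noac.values)


def test_defect_counts_match_poisson_expectation():
    """In-wedge noisy counts agree with the scaled expectation."""
    from scipy import ndimage

    cfg = PhantomConfig(seed=6)
    case = generate_case(cfg, 0)
    spec = default_pe_defect(case, defect_fraction=0.2)
    pe_case, wedge = inject_defect(case, spec)
    w = wedge.values > 0
    lam = pe_case.truth_params["lam"]["perf_ac"].astype(float)
    expected = ndimage.gaussian_filter(
        lam, pe_case.truth_params["recon_sigma_vox"])[w].sum()
    observed = pe_case.perf_ac.values[w].sum()
    # smoothing only reduces the variance of the Poisson sum
    assert abs(observed - expected) < 4 * np.sqrt(lam[w].sum())


def test_wedge_outside_lung_rejected():
    case = generate_case(PhantomConfig(seed=6, noise=False), 0)
    spec = DefectSpec(apex_position=(1, 1, 1), axis_direction=(-1, 0, 0),
                      half_angle_deg=5.0, defect_fraction=0.2)
    with pytest.raises(ValueError, match="wedge"):
        inject_defect(case, spec)


def test_defect_fraction_validated():
    with pytest.raises(ValueError):
        DefectSpec(apex_position=(0, 0, 0), axis_direction=(1, 0, 0),
                   defect_fraction=1.0)


# ---------------------------------------------------------------------------
# Closed-form gradient


def test_posterior_dominant_gradient_gives_negative_pard():
    cfg = PhantomConfig()  # default g_pa_perf < 0 (posterior-high)
    assert analytic_pard(cfg, "perfusion", "AC") < 0
    assert analytic_pard(cfg, "ventilation", "AC") > 0


def test_ball_mean_matches_numerical_quadrature():
    """Exact ball average of (a+by)e^{mu y} vs independent 1-D quadrature."""
    for (yc, R, alpha, beta, mu) in [
        (120.0, 10.0, 1.4, -0.006, 0.003),
        (185.0, 10.0, 0.7, 0.0012, 0.003),
        (150.0, 8.0, 1.0, 0.002, 0.0),
        (90.0, 12.0, 2.0, -0.004, 0.02),
    ]:
        closed = _ball_mean_lin_exp(yc, R, alpha, beta, mu)

        def integrand(u):
            y = yc + u
            return (alpha + beta * y) * np.exp(mu * y) * (R ** 2 - u ** 2)

        num, _ = integrate.quad(integrand, -R, R, epsabs=1e-13, epsrel=1e-13)
        num *= 3.0 / (4.0 * R ** 3)
        assert closed == pytest.approx(num, rel=1e-9, abs=1e-12)


def test_noac_contrast_direction():
    """Attenuation suppresses deep posterior counts: NoAC PArd > AC PArd."""
    cfg = PhantomConfig(seed=1, g_sigma=0.0, deform_amp_mm=0.0,
                        affine_scale_range=0.0, noise=False)
    case = generate_case(cfg, 0)
    rois = place_gradient_rois(LungMask(labels=case.lung_truth))
    pard_ac = gradient_metrics(case.perf_ac, rois).pard
    pard_noac = gradient_metrics(case.perf_noac, rois).pard
    assert pard_noac > pard_ac
    assert analytic_pard(cfg, "perfusion", "NoAC") > analytic_pard(
        cfg, "perfusion", "AC")
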