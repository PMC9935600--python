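"""Evaluation metrics against independently coded brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spectden import metrics
from spectden.metrics import (PolarMapROIs, bland_altman, default_rois,
                              defect_extent_surrogate, intensity_ratio,
                              joint_regression, nmse, paired_test, polar_map,
                              psnr, ssim, voi_slices)


# ---------------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and loop-based)

def oracle_nmse(a, b):
    num = den = 0.0
    for x, y in zip(a.ravel(), b.ravel()):
        num += (x - y) ** 2
        den += y ** 2
    return num / den


def oracle_ssim(a, b, c1=0.01, c2=0.02):
    af, bf = a.ravel(), b.ravel()
    n = len(af)
    mu_a = sum(af) / n
    mu_b = sum(bf) / n
    var_a = sum((x - mu_a) ** 2 for x in af) / n
    var_b = sum((x - mu_b) ** 2 for x in bf) / n
    cov = sum((x - mu_a) * (y - mu_b) for x, y in zip(af, bf)) / n
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
            / ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


def oracle_psnr(a, b):
    af, bf = a.ravel(), b.ravel()
    mse = sum((x - y) ** 2 for x, y in zip(af, bf)) / len(af)
    return 10.0 * np.log10(max(bf) / mse)


def test_voxel_metrics_match_oracles_on_random_pairs(rng):
    for _ in range(5):
        a = rng.random((18, 18, 18))
        b = rng.random((18, 18, 18)) + 0.1
        assert nmse(a, b) == pytest.approx(oracle_nmse(a, b), rel=1e-12)
        assert ssim(a, b) == pytest.approx(oracle_ssim(a, b), rel=1e-12)
        assert psnr(a, b) == pytest.approx(oracle_psnr(a, b), rel=1e-12)


def test_identity_inputs_give_reference_values(rng):
    a = rng.random((18, 18, 18))
    assert nmse(a, a) == 0.0
    assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)
    assert psnr(a, a) == np.inf


def test_nmse_closed_forms(rng):
    b = rng.random((10, 10, 10)) + 0.5
    assert nmse(2 * b, b) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        nmse(b, np.zeros_like(b))


@settings(deadline=None, max_examples=20)
@given(st.floats(0.01, 100.0))
def test_nmse_is_scale_covariant(c):
    rng = np.random.default_rng(0)
    a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8)) + 0.1
    assert nmse(c * a, c * b) == pytest.approx(nmse(a, b), rel=1e-9)


def test_ssim_negative_for_anticorrelated_zero_mean():
    """Hand evaluation on a 2-voxel zero-mean pair: I_D = -I_FT."""
    b = np.array([1.0, -1.0])
    a = -b
    # mu = 0, var = 1, cov = -1 -> (c1)(-2 + c2) / (c1)(2 + c2)
    expected = (0.01 * (-2 + 0.02)) / (0.01 * (2 + 0.02))
    assert ssim(a, b) == pytest.approx(expected, rel=1e-12)
    assert ssim(a, b) < 0


def test_psnr_printed_convention_and_standard_switch():
    b = np.full((4, 4, 4), 1.0)
    a = b + 0.1  # mse = 0.01, max = 1
    assert psnr(a, b) == pytest.approx(20.0)
    assert psnr(a, b, convention="standard") == pytest.approx(20.0)  # max 1
    b2 = b * 2
    a2 = b2 + 0.1
    assert (psnr(a2, b2, convention="standard")
            == pytest.approx(psnr(a2, b2) + 10 * np.log10(2)))


def test_halving_mse_raises_psnr_3db(rng):
    b = rng.random((8, 8, 8)) + 0.5
    e = rng.standard_normal(b.shape) * 0.05
    assert (psnr(b + e / np.sqrt(2), b) - psnr(b + e, b)
            == pytest.approx(10 * np.log10(2), abs=1e-9))


def test_noise_monotonically_degrades_nmse_and_psnr(rng):
    b = rng.random((16, 16, 16)) + 0.5
    noise = rng.standard_normal(b.shape)
    nm, ps = [], []
    for sigma in (0.01, 0.05, 0.2):
        a = b + sigma * noise
        nm.append(nmse(a, b))
        ps.append(psnr(a, b))
    assert nm[0] < nm[1] < nm[2]
    assert ps[0] > ps[1] > ps[2]


def test_voi_slices_clamped_and_validated():
    sl = voi_slices((8, 8, 8), 12, (16, 16, 16))
    assert all(s.stop - s.start == 12 for s in sl)
    sl_edge = voi_slices((1, 8, 15), 12, (16, 16, 16))
    assert all(0 <= s.start and s.stop <= 16 for s in sl_edge)
    with pytest.raises(ValueError):
        voi_slices((8, 8, 8), 18, (16, 16, 16))


# ---------------------------------------------------------------------------
# polar map and regional indices

def test_polar_map_uniform_shell_is_uniform():
    n = 32
    x, y, z = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2)
    img = ((r > 6) & (r < 10)).astype(float)
    pmap = polar_map(img, ((n - 1) / 2, (n - 1) / 2, n // 2),
                     z_range=(8, 24), n_angles=24)
    assert pmap.shape == (16, 24)
    assert np.allclose(pmap, 1.0, rtol=0.02)


def test_polar_map_defect_sector_shows_reduced_uptake():
    n = 32
    x, y, z = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3, indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2)
    phi = np.arctan2(y, x)
    img = ((r > 6) & (r < 10)).astype(float)
    img[(phi > 0) & (phi < np.pi / 2) & (img > 0)] = 0.5
    pmap = polar_map(img, ((n - 1) / 2, (n - 1) / 2, n // 2),
                     z_range=(10, 22), n_angles=36)
    in_defect = pmap[:, 2:8].mean()      # angles ~(20, 80) degrees
    normal = pmap[:, 20:34].mean()
    assert in_defect == pytest.approx(0.5 * normal, rel=0.05)


def test_polar_map_deterministic_and_axis_validated(rng):
    img = rng.random((16, 16, 16))
    a = polar_map(img, (8, 8, 8))
    b = polar_map(img, (8, 8, 8))
    assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        polar_map(img, (20, 8, 8))


def test_intensity_ratio_closed_forms():
    pmap = np.ones((8, 12))
    rois = default_rois(pmap, defect_phi0=0.0, defect_extent_frac=0.2)
    assert intensity_ratio(rois) == pytest.approx(1.0)
    pmap2 = np.ones((8, 12))
    pmap2[rois.roi_defect] = 0.5
    rois2 = PolarMapROIs(pmap2, rois.roi_defect, rois.roi_normal)
    assert intensity_ratio(rois2) == pytest.approx(0.5)
    # absolute error of a method against itself is zero
    assert abs(intensity_ratio(rois2) - intensity_ratio(rois2)) == 0.0


def test_intensity_ratio_requires_rois():
    with pytest.raises(ValueError):
        intensity_ratio(PolarMapROIs(np.ones((4, 4))))


def test_defect_extent_surrogate_thresholding():
    assert defect_extent_surrogate(np.ones((10, 10))) == 0.0
    pmap = np.ones((10, 10))
    pmap.ravel()[:10] = 0.0          # exactly 10% of pixels at zero
    assert defect_extent_surrogate(pmap, 0.5) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        defect_extent_surrogate(pmap, 1.5)


def test_defect_extent_surrogate_recovers_ground_truth_extent():
    """Noiseless phantom polar map with a known 7%-of-wall defect: the
    surrogate lands within 2 percentage points."""
    pmap = np.ones((10, 40))
    pmap[2:9, 0:4] = 0.3             # 28 of 400 pixels = 7%
    rois = default_rois(pmap, defect_phi0=0.0, defect_extent_frac=0.1)
    est = defect_extent_surrogate(rois, threshold_fraction=0.6)
    assert abs(est - 7.0) < 2.0


# ---------------------------------------------------------------------------
# agreement / regression / testing

def test_bland_altman_closed_forms():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = bland_altman(a, a)
    assert (res.mean_diff, res.lower95, res.upper95) == (0.0, 0.0, 0.0)
    res2 = bland_altman(a + 1, a)
    assert res2.mean_diff == pytest.approx(1.0)
    assert res2.lower95 == pytest.approx(1.0)
    assert res2.upper95 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bland_altman([1.0], [2.0])


def test_bland_altman_limits_cover_95_percent(rng):
    a = rng.standard_normal(10_000)
    b = rng.standard_normal(10_000)
    res = bland_altman(a, b)
    inside = ((res.diffs > res.lower95) & (res.diffs < res.upper95)).mean()
    assert abs(inside - 0.95) < 0.01


def test_joint_regression_closed_forms(rng):
    x = rng.random(5000)
    res = joint_regression(x, x)
    assert (res.slope, res.intercept, res.r_squared) == pytest.approx((1, 0, 1))
    res2 = joint_regression(x, 2 * x + 3)
    assert res2.slope == pytest.approx(2.0)
    assert res2.intercept == pytest.approx(3.0)
    assert res2.r_squared == pytest.approx(1.0)
    with pytest.raises(ValueError):
        joint_regression(np.ones(10), x[:10])


def test_joint_regression_r2_matches_signal_variance_ratio(rng):
    """y = x + noise: R^2 approaches var(x) / (var(x) + var(noise))."""
    x = rng.standard_normal(200_000)
    sigma = 0.5
    y = x + sigma * rng.standard_normal(x.size)
    expected = 1.0 / (1.0 + sigma ** 2)
    res = joint_regression(x, y)
    assert res.r_squared == pytest.approx(expected, rel=0.02)
    assert res.hist2d.sum() == x.size


def test_paired_test_matches_manual_t_statistic():
    """Classic before/after sample, checked against a hand-computed paired t
    statistic and the t-distribution survival function."""
    before = np.array([72.0, 68.0, 75.0, 71.0, 69.0, 74.0, 70.0, 73.0])
    after = np.array([70.0, 65.0, 73.0, 72.0, 66.0, 71.0, 68.0, 70.0])
    d = before - after
    t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p_manual = 2 * stats.t.sf(abs(t_manual), df=len(d) - 1)
    assert paired_test(before, after) == pytest.approx(p_manual, rel=1e-6)
    # Bonferroni with 3 comparisons triples the raw p, capped at 1
    assert paired_test(before, after, n_comparisons=3) == pytest.approx(
        min(1.0, 3 * p_manual), rel=1e-6)


def test_paired_test_degenerate_cases():
    a = np.array([1.0, 2.0, 3.0])
    with pytest.warns(RuntimeWarning):
        assert paired_test(a, a) == 1.0
    with pytest.warns(RuntimeWarning):
        assert paired_test(a + 1, a) == 0.0
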