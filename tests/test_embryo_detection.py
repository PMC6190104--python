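"""Adaptive-threshold embryo detection: local means, binarization, contours,
ellipse fitting, and the (b, param1) circulation."""

import numpy as np
import pytest

from embryoserv import (
    AdaptiveThresholdParams,
    DetectionConfig,
    IlluminationField,
    SceneParams,
    adaptive_threshold,
    detect_embryo,
    detect_embryo_global_otsu,
    fit_ellipse_lsq,
    largest_closed_contour,
    local_weighted_mean,
    otsu_global_threshold,
    render_scene,
)
from embryoserv.embryo_detection import ContourNotFound

# ---------------------------------------------------------------------------
# local weighted mean


def test_local_mean_of_constant_is_constant():
    img = np.full((16, 16), 77, dtype=np.uint8)
    for weighting in ("uniform", "gaussian"):
        A = local_weighted_mean(img, 5, weighting)
        assert np.allclose(A, 77.0)


def test_local_mean_uniform_hand_value():
    img = np.array([[0, 0, 0], [0, 9, 0], [0, 0, 0]], dtype=np.uint8)
    A = local_weighted_mean(img, 3, "uniform")
    assert A[1, 1] == pytest.approx(1.0)


def test_local_mean_large_block_approximates_global_mean():
    rng = np.random.default_rng(5)
    img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
    A = local_weighted_mean(img, 63, "uniform")
    # interior pixel: the window covers ~97% of the image
    assert abs(A[32, 32] - img.mean()) < 3.0


def test_local_mean_rejects_even_or_oversized_block():
    img = np.zeros((8, 8), dtype=np.uint8)
    with pytest.raises(ValueError):
        local_weighted_mean(img, 4)
    with pytest.raises(ValueError):
        local_weighted_mean(img, 9)


# ---------------------------------------------------------------------------
# adaptive threshold


def test_adaptive_threshold_constant_image_all_white():
    img = np.full((12, 12), 100, dtype=np.uint8)
    out = adaptive_threshold(img, AdaptiveThresholdParams(3, 7.0))
    assert np.all(out == 255)  # 100 > 100 - 7 everywhere


def test_adaptive_threshold_step_edge_hand_values():
    # left columns 0, right columns 200; b=3 uniform, param1=7
    img = np.zeros((9, 10), dtype=np.uint8)
    img[:, 5:] = 200
    out = adaptive_threshold(img, AdaptiveThresholdParams(3, 7.0, "uniform"))
    # dark pixel adjacent to the step: local mean 200/3 > 7 -> 0
    assert np.all(out[:, 4] == 0)
    # pixels far from the step on both sides -> 255
    assert np.all(out[:, :3] == 255) and np.all(out[:, 7:] == 255)


def test_adaptive_threshold_binary_contract():
    rng = np.random.default_rng(2)
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    out = adaptive_threshold(img, AdaptiveThresholdParams(9, 5.0))
    assert set(np.unique(out)) <= {0, 255}


def test_adaptive_threshold_invariant_to_smooth_gain():
    """The detection-relevant dark set barely moves under a smooth gradient."""
    img, _ = render_scene(SceneParams(noise_sigma=0.0))
    shaded = np.asarray(img, float) * IlluminationField(
        "linear", (1.0, 0.8, 0.8, 0.6)
    ).gain_field(*img.shape)
    shaded = np.clip(np.rint(shaded), 0, 255).astype(np.uint8)
    p = AdaptiveThresholdParams(9, 5.0)
    even = adaptive_threshold(img, p) == 0
    uneven = adaptive_threshold(shaded, p) == 0
    # dark masks overlap almost perfectly (Jaccard)
    inter, union = np.sum(even & uneven), np.sum(even | uneven)
    assert inter / union > 0.9


# ---------------------------------------------------------------------------
# Otsu baseline


def test_otsu_separates_bimodal_levels():
    img = np.full((10, 10), 50, dtype=np.uint8)
    img[:, 5:] = 200
    out = otsu_global_threshold(img)
    assert np.all(out[:, :5] == 0) and np.all(out[:, 5:] == 255)


def brute_force_otsu_mask(img):
    """Independent oracle: scan all thresholds, maximize between-class variance."""
    a = np.asarray(img).ravel()
    n = a.size
    best_t, best_var = None, -1.0
    for t in range(256):
        lo, hi = a[a <= t], a[a > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return np.where(np.asarray(img) > best_t, 255, 0).astype(np.uint8), best_var


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_otsu_matches_exhaustive_search(seed):
    rng = np.random.default_rng(seed)
    # bimodal image with noise, the regime Otsu is defined for
    img = np.where(
        rng.random((24, 24)) < 0.4,
        rng.normal(60, 12, (24, 24)),
        rng.normal(190, 12, (24, 24)),
    )
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    mask = otsu_global_threshold(img)
    oracle_mask, oracle_var = brute_force_otsu_mask(img)
    # equal achieved between-class variance (threshold may differ inside a tie)
    a = img.ravel().astype(float)
    t_cls = mask.ravel() == 255
    w1 = t_cls.mean()
    got_var = w1 * (1 - w1) * (a[t_cls].mean() - a[~t_cls].mean()) ** 2
    assert got_var == pytest.approx(oracle_var, rel=1e-12)
    assert np.array_equal(mask, oracle_mask)


def test_otsu_rejects_constant_image():
    with pytest.raises(ValueError):
        otsu_global_threshold(np.full((8, 8), 9, dtype=np.uint8))


# ---------------------------------------------------------------------------
# contours


def test_contour_not_found_on_all_white():
    with pytest.raises(ContourNotFound):
        largest_closed_contour(np.full((16, 16), 255, dtype=np.uint8), 5)


def test_contour_point_count_equals_rectangle_perimeter():
    mask = np.full((20, 20), 255, dtype=np.uint8)
    mask[5:10, 4:14] = 0  # filled 10x5 dark rectangle
    pts = largest_closed_contour(mask, 5)
    assert len(pts) == 2 * (10 + 5) - 4


def test_contour_picks_larger_of_two_blobs():
    mask = np.full((40, 40), 255, dtype=np.uint8)
    mask[4:8, 4:8] = 0       # small blob
    mask[15:30, 15:35] = 0   # large blob
    pts = largest_closed_contour(mask, 5)
    xs, ys = pts[:, 0], pts[:, 1]
    assert xs.min() == 15 and xs.max() == 34 and ys.min() == 15 and ys.max() == 29


def test_contour_excludes_border_touching_regions():
    mask = np.full((30, 30), 255, dtype=np.uint8)
    mask[0:30, 0:6] = 0      # huge region running off the frame
    mask[10:16, 12:18] = 0   # small closed interior region
    pts = largest_closed_contour(mask, 5)
    assert pts[:, 0].min() >= 12


def test_contour_boundary_is_outer_edge_of_annulus():
    # a dark ring is hole-filled, so its contour is the outer edge only
    yy, xx = np.mgrid[0:41, 0:41]
    r = np.hypot(xx - 20, yy - 20)
    mask = np.where((r >= 10) & (r <= 15), 0, 255).astype(np.uint8)
    pts = largest_closed_contour(mask, 5)
    radii = np.hypot(pts[:, 0] - 20, pts[:, 1] - 20)
    assert radii.min() > 13.5  # no inner-edge points


# ---------------------------------------------------------------------------
# ellipse fitting


def _ellipse_points(cx, cy, a, b, angle_deg, n=12):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.deg2rad(angle_deg)
    x = cx + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
    y = cy + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
    return np.column_stack([x, y])


def test_fit_recovers_exact_ellipse():
    fit = fit_ellipse_lsq(_ellipse_points(60, 40, 30, 20, 0.0))
    assert fit.center == pytest.approx((60.0, 40.0), abs=1e-6)
    assert fit.major_axis_length == pytest.approx(60.0, rel=1e-6)
    assert fit.minor_axis_length == pytest.approx(40.0, rel=1e-6)
    assert fit.angle_deg % 180.0 == pytest.approx(0.0, abs=1e-6)


def test_fit_recovers_rotated_ellipse():
    fit = fit_ellipse_lsq(_ellipse_points(10, -5, 50, 35, 25.0))
    assert fit.center == pytest.approx((10.0, -5.0), abs=1e-6)
    assert fit.angle_deg == pytest.approx(25.0, abs=1e-6)


def test_fit_circle_axes_equal():
    fit = fit_ellipse_lsq(_ellipse_points(0, 0, 25, 25, 0.0))
    assert fit.major_axis_length == pytest.approx(fit.minor_axis_length, rel=1e-9)


def test_fit_underdetermined_raises():
    with pytest.raises(ValueError):
        fit_ellipse_lsq(np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float))


def test_fit_collinear_raises():
    pts = np.column_stack([np.arange(8.0), 2.0 * np.arange(8.0)])
    with pytest.raises(ValueError):
        fit_ellipse_lsq(pts)


# ---------------------------------------------------------------------------
# full detection circulation


def test_detect_embryo_clean_scene_recovers_truth():
    params = SceneParams(seed=3)
    img, truth = render_scene(params)
    det = detect_embryo(img)
    assert det.accepted
    cx, cy = det.ellipse.center
    tx, ty = truth.embryo_center
    assert np.hypot(cx - tx, cy - ty) <= 5.0
    assert det.ellipse.major_axis_length == pytest.approx(
        2 * truth.embryo_axes[0], rel=0.05
    )


def test_detect_blank_image_rejected_after_all_combinations():
    cfg = DetectionConfig()
    det = detect_embryo(np.full((128, 128), 180, dtype=np.uint8), cfg)
    assert not det.accepted
    assert det.n_combinations_tried == len(cfg.b_range) * len(cfg.param1_range)


def test_detection_is_deterministic():
    img, _ = render_scene(SceneParams(seed=8))
    d1, d2 = detect_embryo(img), detect_embryo(img)
    assert d1.params_used == d2.params_used
    assert d1.ellipse.center == d2.ellipse.center


def test_min_accepted_block_size_nondecreasing_with_unevenness():
    """More uneven illumination never lets a smaller block size win."""
    params = SceneParams(seed=4)
    img_even, _ = render_scene(params)
    img_uneven, _ = render_scene(
        params, IlluminationField("linear", (1.0, 0.7, 0.7, 0.4))
    )
    b_even = detect_embryo(img_even).params_used[0]
    b_uneven = detect_embryo(img_uneven).params_used[0]
    assert b_uneven >= b_even


def test_adaptive_and_otsu_agree_under_even_illumination():
    img, _ = render_scene(SceneParams(seed=6))
    da = detect_embryo(img)
    do = detect_embryo_global_otsu(img)
    assert da.accepted and do.accepted
    dx = da.ellipse.center[0] - do.ellipse.center[0]
    dy = da.ellipse.center[1] - do.ellipse.center[1]
    assert np.hypot(dx, dy) <= 2.0


def test_otsu_baseline_fails_under_strong_gradient():
    img, truth = render_scene(
        SceneParams(seed=6), IlluminationField("linear", (1.0, 0.7, 0.7, 0.4))
    )
    do = detect_embryo_global_otsu(img)
    if do.accepted:
        err = np.hypot(
            do.ellipse.center[0] - truth.embryo_center[0],
            do.ellipse.center[1] - truth.embryo_center[1],
        )
        assert err > 20.0
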