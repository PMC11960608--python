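import numpy as np
import pytest
from sklearn.base import clone

from relpatlak.kinetics import (FrameSchedule, InputFunction, KineticParams,
                                TissueCurve, tissue_curve)
from relpatlak.patlak import (ParametricImage, PatlakImager, default_mask,
                              estimate_alpha, fit_parametric, fit_patlak,
                              patlak_xy, suv_image, suvr_image)
from relpatlak.phantom import DynamicImage, late_schedule, simulate_dynamic


def _exact_curve(f, sched, t_star, method, slope, intercept):
    """TissueCurve whose Patlak plot is the exact line y = slope*x + b."""
    mids = sched.mid
    cp = f(mids)
    lower = 0.0 if method == "standard" else t_star
    x = np.array([f.integral(lower, t) for t in mids]) / cp
    return TissueCurve(times=mids, values=(slope * x + intercept) * cp,
                       schedule=sched), x


# ---------------------------------------------------------------------- #
# single-curve fits

@pytest.mark.parametrize("method", ["standard", "relative"])
def test_exact_line_recovery(feng, late_sched, method):
    curve, _ = _exact_curve(feng, late_sched, 40.0, method, 0.05, 0.7)
    fit = fit_patlak(curve, feng, 40.0, method=method)
    assert fit.slope == pytest.approx(0.05, rel=1e-12)
    assert fit.intercept == pytest.approx(0.7, rel=1e-12)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    assert fit.n_points == 4 and fit.method == method


def test_patlak_xy_definitions(feng, late_sched):
    curve = tissue_curve(feng, KineticParams(0.3, 0.6, 0.15), late_sched)
    x, y = patlak_xy(curve, feng, 40.0, method="relative")
    cp = feng(late_sched.mid)
    assert np.allclose(y, curve.values / cp)
    assert np.allclose(
        x, [feng.integral(40.0, t) for t in late_sched.mid] / cp)
    # relative abscissa starts near zero and grows
    assert x[0] < x[-1] and x[0] >= 0
    with pytest.raises(ValueError):
        patlak_xy(curve, feng, 59.0)        # < 2 frames after t*
    with pytest.raises(ValueError):
        fit_patlak(curve, feng, 40.0, method="bogus")
    with pytest.raises(ValueError):
        fit_patlak(curve, feng, 40.0, weights="bogus")


def test_late_time_linearity(feng, late_sched):
    """Patlak linearity at t* = 40 min for an irreversible tracer."""
    curve = tissue_curve(feng, KineticParams(0.3, 0.6, 0.15, 0.0), late_sched)
    fit = fit_patlak(curve, feng, 40.0, method="standard")
    assert fit.r2 > 0.9999


def test_early_frames_are_dropped(feng):
    sched = FrameSchedule(starts=[30.0, 40.0, 45.0, 50.0, 55.0],
                          ends=[40.0, 45.0, 50.0, 55.0, 60.0])
    curve = tissue_curve(feng, KineticParams(0.3, 0.6, 0.15), sched)
    fit = fit_patlak(curve, feng, 40.0)
    assert fit.n_points == 4


def test_duration_weighting_changes_nothing_for_exact_data(feng, late_sched):
    curve, _ = _exact_curve(feng, late_sched, 40.0, "relative", 0.04, 0.5)
    a = fit_patlak(curve, feng, 40.0, weights="none")
    b = fit_patlak(curve, feng, 40.0, weights="duration")
    assert a.slope == pytest.approx(b.slope, rel=1e-12)


# ---------------------------------------------------------------------- #
# parametric images

def test_fit_parametric_matches_per_voxel_loop(feng, late_sched):
    rng = np.random.default_rng(1)
    data = rng.uniform(5.0, 50.0, size=(5, 5, 4, 4))
    img = DynamicImage(data=data, schedule=late_sched)
    mask = np.ones(img.shape, dtype=bool)
    pimg = fit_parametric(img, feng, 40.0, method="relative", mask=mask)
    for idx in np.ndindex(img.shape):
        curve = TissueCurve(times=late_sched.mid, values=data[idx],
                            schedule=late_sched)
        fit = fit_patlak(curve, feng, 40.0, method="relative")
        assert pimg.slope_vol[idx] == pytest.approx(fit.slope, rel=1e-10)
        assert pimg.intercept_vol[idx] == pytest.approx(fit.intercept,
                                                        rel=1e-10, abs=1e-12)


def test_fit_parametric_organ_values(small_spec, small_noise_free, feng):
    pimg = fit_parametric(small_noise_free, feng, 40.0, method="relative")
    # all voxels of one organ share a TAC, hence a slope
    for name in ("liver", "lesion_2"):
        vox = pimg.slope_vol[small_spec.labels == small_spec.label_of(name)]
        assert vox.std() < 1e-9 * abs(vox.mean())
    lab = small_spec.label_of("lesion_2")
    curve_fit = fit_patlak(
        tissue_curve(feng, small_spec.organ_params[lab], late_schedule()),
        feng, 40.0, method="relative")
    assert pimg.slope_vol[small_spec.labels == lab][0] == pytest.approx(
        curve_fit.slope, rel=1e-9)


def test_fit_parametric_mask_and_errors(small_noise_free, feng):
    with pytest.raises(ValueError):
        fit_parametric(small_noise_free, feng, 40.0,
                       mask=np.ones((2, 2, 2), bool))
    with pytest.raises(ValueError):
        fit_parametric(small_noise_free, feng, 59.0)
    mask = default_mask(small_noise_free)
    assert mask.any() and not mask.all()
    pimg = fit_parametric(small_noise_free, feng, 40.0)
    assert np.all(pimg.slope_vol[~pimg.mask] == 0.0)


def test_parametric_image_validation(late_sched):
    with pytest.raises(ValueError):
        ParametricImage(slope_vol=np.zeros((2, 2, 2)),
                        intercept_vol=np.zeros((3, 2, 2)),
                        method="relative", t_star=40.0,
                        mask=np.ones((2, 2, 2), bool))


# ---------------------------------------------------------------------- #
# SUV / SUVr

def test_suv_image_default_window(small_noise_free):
    suv = suv_image(small_noise_free)
    assert np.allclose(suv, small_noise_free.data[..., -1])
    with pytest.raises(ValueError):
        suv_image(small_noise_free, window=(10.0, 12.0))


def test_suv_image_duration_weighting():
    sched = FrameSchedule(starts=[50.0, 52.0], ends=[52.0, 60.0])
    data = np.zeros((2, 2, 2, 2))
    data[..., 0], data[..., 1] = 10.0, 20.0
    img = DynamicImage(data=data, schedule=sched)
    suv = suv_image(img, window=(50.0, 60.0))
    assert np.allclose(suv, (10.0 * 2 + 20.0 * 8) / 10.0)


def test_suvr_image_interp_and_nearest(small_noise_free, feng):
    interp = suvr_image(small_noise_free, feng, 40.0)
    # t* = 40 precedes the first mid-time (42.5): linear extrapolation from
    # the first two frames
    d = small_noise_free.data
    ct = d[..., 0] + (40.0 - 42.5) / 5.0 * (d[..., 1] - d[..., 0])
    assert np.allclose(interp, ct / feng(40.0))
    nearest = suvr_image(small_noise_free, feng, 40.0, frame_select="nearest")
    assert np.allclose(nearest, d[..., 0] / feng(42.5))
    with pytest.raises(ValueError):
        suvr_image(small_noise_free, feng, 39.0)
    with pytest.raises(ValueError):
        suvr_image(small_noise_free, feng, 45.0, frame_select="bogus")


# ---------------------------------------------------------------------- #
# alpha

def test_estimate_alpha_exact_scaling():
    rng = np.random.default_rng(0)
    ki_vals = rng.uniform(0.001, 0.06, size=(6, 6, 6))
    mask = np.ones(ki_vals.shape, bool)
    ki = ParametricImage(slope_vol=ki_vals, intercept_vol=np.zeros_like(ki_vals),
                         method="standard", t_star=40.0, mask=mask)
    kip = ParametricImage(slope_vol=1.7 * ki_vals,
                          intercept_vol=np.zeros_like(ki_vals),
                          method="relative", t_star=40.0, mask=mask)
    alpha, intercept, r = estimate_alpha(ki, kip)
    assert alpha == pytest.approx(1.7, rel=1e-12)
    assert abs(intercept) < 1e-12
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError):
        estimate_alpha(ki, kip, mask=np.zeros(ki_vals.shape, bool))


# ---------------------------------------------------------------------- #
# estimator interface

def test_patlak_imager_estimator(small_noise_free, feng):
    est = PatlakImager(method="relative", t_star=40.0)
    params = est.get_params()
    assert params["method"] == "relative" and params["t_star"] == 40.0
    est2 = clone(est).set_params(method="standard")
    assert est2.get_params()["method"] == "standard"
    est.fit(small_noise_free, input_function=feng)
    ref = fit_parametric(small_noise_free, feng, 40.0, method="relative")
    assert np.array_equal(est.slope_vol_, ref.slope_vol)
    assert np.array_equal(est.mask_, ref.mask)
    with pytest.raises(ValueError):
        PatlakImager().fit(small_noise_free)
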