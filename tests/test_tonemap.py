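import numpy as np
import pytest
from scipy.optimize import minimize

from wtm import (
    ControlPointSet,
    SlopeBounds,
    WeibullParams,
    clhe_proxy,
    clhe_tonecurve,
    compute_pdf,
    curve_slopes,
    extract_brightness,
    fit_weibull,
    he_tonecurve,
    identity_curve,
    mean_delta_e,
    pchip_tonecurve,
    wtm_approximate,
    wtm_enhance,
    wtm_tonecurve,
)
from wtm.synth import SceneSpec, generate_seafloor_image, generate_user_adjustment
from wtm.weibull import weibull_cdf

from conftest import random_pdf


def qp_projection(h, m, M):
    """Least-squares projection onto the box∩simplex via generic SLSQP."""
    n = len(h)
    res = minimize(
        lambda x: np.sum((x - h) ** 2),
        x0=np.full(n, 1.0 / n),
        jac=lambda x: 2 * (x - h),
        bounds=[(m / n, M / n)] * n,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    assert res.success
    return res.x


def fritsch_carlson_pchip(x, y, xq):
    """Independent monotone-PCHIP oracle (Fritsch–Carlson derivative limiting)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    h = np.diff(x)
    delta = np.diff(y) / h
    n = len(x)
    d = np.zeros(n)
    for i in range(1, n - 1):
        if delta[i - 1] * delta[i] <= 0:
            d[i] = 0.0
        else:
            w1 = 2 * h[i] + h[i - 1]
            w2 = h[i] + 2 * h[i - 1]
            d[i] = (w1 + w2) / (w1 / delta[i - 1] + w2 / delta[i])

    def endpoint(h0, h1, d0, d1):
        slope = ((2 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
        if np.sign(slope) != np.sign(d0):
            return 0.0
        if np.sign(d0) != np.sign(d1) and abs(slope) > 3 * abs(d0):
            return 3 * d0
        return slope

    d[0] = endpoint(h[0], h[1], delta[0], delta[1])
    d[-1] = endpoint(h[-1], h[-2], delta[-1], delta[-2])

    out = np.empty_like(np.asarray(xq, float))
    for j, xv in enumerate(np.atleast_1d(xq)):
        i = min(np.searchsorted(x, xv, side="right") - 1, n - 2)
        i = max(i, 0)
        t = (xv - x[i]) / h[i]
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[j] = h00 * y[i] + h10 * h[i] * d[i] + h01 * y[i + 1] + h11 * h[i] * d[i + 1]
    return out


class TestHE:
    def test_flat_histogram_is_null_operation(self):
        assert np.allclose(he_tonecurve(np.full(256, 1 / 256)), identity_curve(256))

    def test_delta_histogram_saturates(self):
        h = np.zeros(256)
        h[0] = 1.0
        assert np.all(he_tonecurve(h) == 1.0)

    def test_slopes_recover_histogram(self, rng):
        h = random_pdf(rng)
        assert np.allclose(curve_slopes(he_tonecurve(h)), 256 * h, atol=1e-12)


class TestCLHE:
    def test_feasible_histogram_unchanged(self):
        h = np.full(256, 1 / 256)
        assert np.allclose(clhe_proxy(h), h, atol=1e-15)

    def test_delta_matches_qp_oracle_small_n(self):
        h = np.zeros(8)
        h[3] = 1.0
        proxy = clhe_proxy(h, SlopeBounds(0.5, 2.0))
        oracle = qp_projection(h, 0.5, 2.0)
        assert np.max(np.abs(proxy - oracle)) <= 1e-6
        assert proxy[3] == pytest.approx(2.0 / 8)

    def test_random_small_n_matches_qp_oracle(self, rng):
        for _ in range(10):
            h = random_pdf(rng, 8)
            proxy = clhe_proxy(h, SlopeBounds(0.5, 2.0))
            assert np.max(np.abs(proxy - qp_projection(h, 0.5, 2.0))) <= 1e-6

    def test_slope_bounds_met(self, rng):
        for _ in range(25):
            curve = clhe_tonecurve(random_pdf(rng))
            slopes = curve_slopes(curve)
            assert slopes.min() >= 0.5 - 1e-9 and slopes.max() <= 2.0 + 1e-9

    def test_idempotent(self, rng):
        h = random_pdf(rng)
        once = clhe_proxy(h)
        assert np.max(np.abs(clhe_proxy(once) - once)) <= 1e-12

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            SlopeBounds(1.2, 2.0)
        with pytest.raises(ValueError):
            SlopeBounds(0.5, 0.9)


class TestWTMCurve:
    def test_self_composition_near_identity(self):
        p = WeibullParams(1.2, 4.0)
        assert np.max(np.abs(wtm_tonecurve(p, p) - identity_curve(256))) <= 2 / 256

    def test_higher_target_scale_brightens(self):
        p_in = WeibullParams(1.0, 3.0)
        curve = wtm_tonecurve(p_in, WeibullParams(1.6, 3.0))
        assert curve.mean() >= identity_curve(256).mean()

    def test_against_dense_tabulation_oracle(self):
        p_in, p_out = WeibullParams(0.9, 2.5), WeibullParams(1.4, 5.0)
        curve = wtm_tonecurve(p_in, p_out)
        # tabulate the target CDF on 65536 points and invert by bisection
        grid = np.linspace(0.0, 1.0, 65_536)
        table = weibull_cdf(grid, p_out)
        probs = weibull_cdf(np.arange(1, 257) / 256, p_in)
        inverted = np.interp(probs, table, grid)
        assert np.max(np.abs(curve - inverted)) <= 1e-7

    def test_monotone_over_random_pairs(self, rng):
        for _ in range(50):
            lam_i, lam_o = rng.uniform(0.1, 3.0, 2)
            k_i, k_o = rng.uniform(0.1, 15.0, 2)
            curve = wtm_tonecurve(WeibullParams(lam_i, k_i), WeibullParams(lam_o, k_o))
            assert np.all(np.diff(curve) >= 0.0)
            assert curve.min() >= 0.0 and curve.max() <= 1.0
            assert curve[-1] == pytest.approx(1.0, abs=1e-9)

    def test_composition_associativity(self):
        a, b, c = WeibullParams(0.8, 2.0), WeibullParams(1.2, 4.0), WeibullParams(1.8, 6.0)
        ab = wtm_tonecurve(a, b)
        bc = wtm_tonecurve(b, c)
        ac = wtm_tonecurve(a, c)
        # compose node-wise: push each ab node through the b→c map
        composed = np.interp(
            ab, np.concatenate(([0.0], np.arange(1, 257) / 256)), np.concatenate(([0.0], bc))
        )
        assert np.max(np.abs(composed - ac)) <= 2 / 256


class TestWTMEnhance:
    def test_identity_target_is_noop(self, scene_image_small):
        pdf = compute_pdf(extract_brightness(scene_image_small))
        fit = fit_weibull(pdf)
        out, _, _ = wtm_enhance(scene_image_small, fit.params)
        change = np.abs(
            extract_brightness(out) - extract_brightness(scene_image_small)
        )
        assert change.mean() <= 2 / 256

    def test_lower_shape_increases_contrast(self, scene_image_small):
        _, _, fit = wtm_enhance(scene_image_small, WeibullParams(1.0, 3.0))
        lower_k = WeibullParams(fit.params.lam, max(fit.params.k - 1.5, 0.5))
        out, _, _ = wtm_enhance(scene_image_small, lower_k)
        assert extract_brightness(out).std() > extract_brightness(scene_image_small).std()

    def test_target_fit_roundtrip(self):
        img = generate_seafloor_image(SceneSpec(seed=21))
        target = WeibullParams(1.0, 2.5)
        out, _, _ = wtm_enhance(img, target)
        refit = fit_weibull(compute_pdf(extract_brightness(out)))
        assert abs(refit.params.lam - target.lam) <= 0.1 + 1e-9
        assert abs(refit.params.k - target.k) <= 0.1 + 1e-9


class TestWTMApproximate:
    def test_identity_pair(self, scene_image_small):
        approx, _, _, _ = wtm_approximate(scene_image_small, scene_image_small)
        assert mean_delta_e(approx, scene_image_small).mean_delta_e <= 1.0

    def test_roundtrip_recovers_target(self):
        img = generate_seafloor_image(SceneSpec(seed=5))
        target = WeibullParams(1.3, 2.0)
        enhanced, _, _ = wtm_enhance(img, target)
        approx, _, _, fit_out = wtm_approximate(img, enhanced)
        assert abs(fit_out.params.lam - target.lam) <= 0.1 + 1e-9
        assert abs(fit_out.params.k - target.k) <= 0.1 + 1e-9
        assert mean_delta_e(approx, enhanced).mean_delta_e <= 5.0

    def test_gentle_pchip_adjustment_is_wtm_like(self):
        img = generate_seafloor_image(SceneSpec(seed=13))
        adjusted = generate_user_adjustment(img, "pchip", seed=13)
        approx, _, _, _ = wtm_approximate(img, adjusted)
        assert mean_delta_e(approx, adjusted).mean_delta_e < 5.0

    def test_dimension_mismatch_rejected(self, scene_image_small, scene_image):
        with pytest.raises(ValueError):
            wtm_approximate(scene_image_small, scene_image)


class TestPCHIP:
    def test_identity_knots_reproduce_identity(self):
        cps = ControlPointSet((0.0, 0.2, 0.4, 0.6, 0.8, 1.0))
        assert np.max(np.abs(pchip_tonecurve(cps) - identity_curve(256))) <= 1e-12

    def test_matches_fritsch_carlson_oracle(self):
        y = (0.0, 0.1, 0.5, 0.7, 0.9, 1.0)
        curve = pchip_tonecurve(ControlPointSet(y))
        xs = np.arange(1, 257) / 256
        oracle = fritsch_carlson_pchip([0, 0.2, 0.4, 0.6, 0.8, 1.0], y, xs)
        assert np.max(np.abs(curve - oracle)) <= 1e-9
        # spot value at b = 0.3: oracle agrees with the library interpolant
        from scipy.interpolate import PchipInterpolator

        direct = PchipInterpolator([0, 0.2, 0.4, 0.6, 0.8, 1.0], y)(0.3)
        assert fritsch_carlson_pchip([0, 0.2, 0.4, 0.6, 0.8, 1.0], y, [0.3])[0] == pytest.approx(
            direct, abs=1e-9
        )

    def test_monotone_no_overshoot(self, rng):
        for _ in range(20):
            y = np.sort(rng.random(6))
            if np.any(np.diff(y) <= 0):
                continue
            curve = pchip_tonecurve(ControlPointSet(tuple(y)))
            assert np.all(np.diff(curve) >= -1e-12)
            assert curve.min() >= 0.0 and curve.max() <= 1.0

    def test_passes_through_control_points(self):
        y = (0.05, 0.3, 0.45, 0.6, 0.85, 1.0)
        curve = pchip_tonecurve(ControlPointSet(y))
        # abscissae 0.2..1.0 land exactly on nodes 51.2 -> not integer; check 0.4*256
        for frac, val in zip((0.4, 0.6, 0.8, 1.0), y[2:]):
            # evaluate through the interpolant at exact knot positions
            from wtm.core import _eval_curve

            assert _eval_curve(np.array([frac]), curve)[0] == pytest.approx(val, abs=2e-3)

    def test_non_increasing_ordinates_rejected(self):
        with pytest.raises(ValueError):
            ControlPointSet((0.0, 0.5, 0.4, 0.6, 0.8, 1.0))
        with pytest.raises(ValueError):
            ControlPointSet((0.0, 0.2, 0.2, 0.6, 0.8, 1.0))
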