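import json

import numpy as np
import pytest

from sludgecolor import (
    CalibrationModel,
    DegenerateDataError,
    GrayCoefficients,
    InputDataError,
    RGBMean,
    build_model,
    fit_channel,
    fit_exponential,
    gray_coefficients,
    to_grayscale,
)

from conftest import make_samples


def ols_oracle(x, y):
    """Closed-form simple OLS via explicit sums, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - ybar) ** 2)
    return slope, intercept, r2


class TestFitChannel:
    def test_collinear_points_exact(self):
        samples = make_samples([0, 1, 2], b=[10, 8, 6])
        fit = fit_channel(samples, "B")
        assert fit.slope == pytest.approx(-2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(10.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n == 3 and fit.mlss_range == (0.0, 2.0)

    def test_hand_computed_noncollinear(self):
        # SS_res = 1.5, SS_tot = 2 for these three points
        fit = fit_channel(make_samples([0, 1, 2], g=[1, 3, 2]), "G")
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(1.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.25, abs=1e-12)

    def test_matches_closed_form_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.uniform(0, 15, size=n)
            while np.unique(x).size < 2:
                x = rng.uniform(0, 15, size=n)
            y = rng.uniform(1, 254, size=n)
            fit = fit_channel(make_samples(x, r=y), "R")
            slope, intercept, r2 = ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2, abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(InputDataError, match="insufficient"):
            fit_channel(make_samples([0, 1], r=[1, 2]), "R")

    def test_identical_mlss_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_channel(make_samples([2, 2, 2], r=[1, 2, 3]), "R")


class TestGrayCoefficients:
    def test_published_slopes(self):
        k = gray_coefficients(-5.3117, -8.9099, -14.404)
        assert k.k_r == pytest.approx(0.18556, abs=1e-5)
        assert k.k_g == pytest.approx(0.31126, abs=1e-5)
        assert k.k_b == pytest.approx(0.50318, abs=1e-5)

    def test_symmetric_slopes_give_thirds(self):
        k = gray_coefficients(-1, -1, -1)
        assert k.as_tuple() == pytest.approx((1 / 3, 1 / 3, 1 / 3), abs=1e-15)

    def test_mixed_signs_rejected(self):
        with pytest.raises(DegenerateDataError, match="mixed signs"):
            gray_coefficients(2, -1, -1)

    def test_zero_slope_rejected(self):
        with pytest.raises(DegenerateDataError, match="zero"):
            gray_coefficients(0, -1, -1)

    def test_sum_to_one_and_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = -rng.uniform(0.01, 50, size=3)
            k = gray_coefficients(*m)
            assert abs(sum(k.as_tuple()) - 1.0) < 1e-9
            assert all(0 < v < 1 for v in k.as_tuple())
            kp = gray_coefficients(m[1], m[2], m[0])
            assert kp.as_tuple() == pytest.approx(
                (k.k_g, k.k_b, k.k_r), abs=1e-15
            )


class TestToGrayscale:
    K = GrayCoefficients(0.18556, 0.31126, 0.50318)

    def test_flat_pixel_preserved(self):
        assert to_grayscale(RGBMean(233.6, 233.6, 233.6), self.K) == pytest.approx(
            233.6, abs=1e-3
        )

    def test_direct_arithmetic(self):
        gray = to_grayscale(RGBMean(232.08, 232.09, 233.6), self.K)
        assert gray == pytest.approx(232.85, abs=0.01)

    def test_black_maps_to_zero(self):
        assert to_grayscale(RGBMean(0, 0, 0), self.K) == 0.0

    def test_linearity_under_weight_preserving_mixes(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            x = RGBMean(*rng.uniform(0, 255, 3))
            y = RGBMean(*rng.uniform(0, 255, 3))
            a = rng.uniform(0, 1)
            mix = RGBMean(
                a * x.r + (1 - a) * y.r,
                a * x.g + (1 - a) * y.g,
                a * x.b + (1 - a) * y.b,
            )
            assert to_grayscale(mix, self.K) == pytest.approx(
                a * to_grayscale(x, self.K) + (1 - a) * to_grayscale(y, self.K),
                abs=1e-9,
            )


class TestFitExponential:
    def test_exact_recovery_on_model_true_data(self):
        m = np.arange(8)
        v = 230 * np.exp(-0.18 * m)
        fit = fit_exponential(make_samples(m, b=v), "B", mlss_max=8)
        assert fit.v0 == pytest.approx(230, abs=1e-9)
        assert fit.kappa == pytest.approx(0.18, abs=1e-12)
        assert fit.r_squared_log == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared_linear == pytest.approx(1.0, abs=1e-12)

    def test_recovery_for_random_positive_kappa(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            kappa = rng.uniform(0.01, 0.5)
            v0 = rng.uniform(50, 250)
            m = np.linspace(0, 7, 6)
            v = v0 * np.exp(-kappa * m)
            fit = fit_exponential(make_samples(m, g=v), "G", mlss_max=8)
            assert fit.v0 == pytest.approx(v0, abs=1e-9)
            assert fit.kappa == pytest.approx(kappa, abs=1e-9)

    def test_zero_intensity_rejected(self):
        with pytest.raises(InputDataError, match="non-positive"):
            fit_exponential(make_samples([0, 1, 2], b=[10, 5, 0]), "B", mlss_max=8)

    def test_subset_too_small(self):
        samples = make_samples([0, 1, 9, 10], b=[10, 8, 3, 2])
        with pytest.raises(InputDataError, match="insufficient"):
            fit_exponential(samples, "B", mlss_max=2)


class TestBuildModel:
    def test_reference_gray_coefficients(self, ref_model):
        k = ref_model.gray
        assert k.k_r == pytest.approx(0.185, abs=1e-3)
        assert k.k_g == pytest.approx(0.311, abs=1e-3)
        assert k.k_b == pytest.approx(0.503, abs=1e-3)

    def test_reference_gray_fit_quality(self, ref_model):
        assert ref_model.fits["GRAY"].r_squared == pytest.approx(0.992, abs=1e-3)

    def test_reference_r_squared_ordering(self, ref_model):
        fits = ref_model.fits
        assert fits["B"].r_squared > fits["G"].r_squared > fits["R"].r_squared

    def test_gray_fit_consistent_with_stored_coefficients(self, ref_model, ref_subset):
        grays = [to_grayscale(s.rgb, ref_model.gray) for s in ref_subset]
        mlss = [s.mlss for s in ref_subset]
        slope, intercept, r2 = ols_oracle(mlss, grays)
        assert ref_model.fits["GRAY"].slope == pytest.approx(slope, abs=1e-9)
        assert ref_model.fits["GRAY"].r_squared == pytest.approx(r2, abs=1e-9)

    def test_collinear_samples_give_unit_r_squared(self):
        m = [0.0, 1.0, 2.0, 3.0]
        samples = make_samples(
            m,
            r=[200 - 2 * x for x in m],
            g=[210 - 5 * x for x in m],
            b=[220 - 9 * x for x in m],
        )
        model = build_model(samples)
        for fit in model.fits.values():
            assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_json_round_trip_bit_stable(self, ref_model, tmp_path):
        p = tmp_path / "model.json"
        ref_model.to_json(p)
        back = CalibrationModel.from_json(p)
        for c, f in ref_model.fits.items():
            g = back.fits[c]
            assert (g.slope, g.intercept, g.r_squared, g.n) == (
                f.slope, f.intercept, f.r_squared, f.n,
            )
            assert g.mlss_range == f.mlss_range
        assert back.gray == ref_model.gray
        for c, e in ref_model.exponential.items():
            b = back.exponential[c]
            assert (b.v0, b.kappa, b.r_squared_log, b.r_squared_linear, b.mlss_max) == (
                e.v0, e.kappa, e.r_squared_log, e.r_squared_linear, e.mlss_max,
            )
        # and the file is plain JSON
        assert "channels" in json.loads(p.read_text())
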