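"""ROI color extraction, HCL conversion, hue statistics, and ratiometrics."""

import numpy as np
import pandas as pd
import pytest

from best4pipe.colorimetry import (
    background_shift,
    calibrate_hue_to_ph,
    ctcf,
    extract_roi_color,
    fit_hue_polynomials,
    fit_relaxation,
    hue_shift,
    hue_timeseries,
    phluorin_ratio,
    rgb_to_hcl,
    series_to_hue,
)
from best4pipe.synthetic_data import simulate_ph_series, simulate_ph_standards


class TestExtractROI:
    def test_uniform_image(self):
        img = np.tile(np.array([10.0, 20.0, 30.0]), (8, 8, 1))
        roi, bg = extract_roi_color(img, (0, 0, 4, 4), (4, 4, 4, 4))
        assert np.allclose(roi, [10, 20, 30]) and np.allclose(bg, [10, 20, 30])

    def test_zero_background_rectangle(self):
        img = np.zeros((6, 6, 3))
        img[:3] = 50.0
        _, bg = extract_roi_color(img, (0, 0, 3, 6), (3, 0, 3, 6))
        assert np.allclose(bg, 0.0)

    def test_checkerboard_mean(self):
        img = np.zeros((4, 4, 3))
        img[::2, ::2] = 2.0
        img[1::2, 1::2] = 2.0
        roi, _ = extract_roi_color(img, (0, 0, 4, 4), (0, 0, 2, 2))
        assert np.allclose(roi, 1.0)

    def test_out_of_bounds_rejected(self):
        img = np.zeros((4, 4, 3))
        with pytest.raises(ValueError, match="outside image"):
            extract_roi_color(img, (2, 2, 4, 4), (0, 0, 2, 2))


def series_frame(rows):
    return pd.DataFrame(
        rows, columns=["animal", "time", "R", "G", "B", "bgR", "bgG", "bgB", "condition"]
    )


class TestBackgroundShift:
    def test_equal_backgrounds_identity_on_roi(self):
        s = series_frame(
            [["a", 0, 100, 110, 120, 10, 10, 10, "x"], ["b", 0, 90, 95, 99, 10, 10, 10, "x"]]
        )
        out = background_shift(s)
        assert np.allclose(out[["R", "G", "B"]], s[["R", "G", "B"]])

    def test_additive_shift_rule(self):
        s = series_frame(
            [["a", 0, 100, 100, 100, 10, 10, 10, "x"], ["b", 0, 100, 100, 100, 14, 18, 22, "x"]]
        )
        out = background_shift(s)
        # targets are (12,14,16); record a shifted by (+2,+4,+6)
        assert np.allclose(out.loc[0, ["R", "G", "B"]].astype(float), [102, 104, 106])
        assert np.allclose(out.loc[0, ["bgR", "bgG", "bgB"]].astype(float), [12, 14, 16])

    def test_mean_background_preserved_and_differences_exact(self):
        rng = np.random.default_rng(0)
        rows = [
            ["a", t, *rng.uniform(50, 200, 3), *rng.uniform(0, 30, 3), "x"]
            for t in range(12)
        ]
        s = series_frame(rows)
        out = background_shift(s)
        before = s[["bgR", "bgG", "bgB"]].mean(axis=0).to_numpy()
        after = out[["bgR", "bgG", "bgB"]].mean(axis=0).to_numpy()
        assert np.allclose(before, after, atol=1e-10)
        diff_before = s[["R", "G", "B"]].to_numpy() - s[["bgR", "bgG", "bgB"]].to_numpy()
        diff_after = out[["R", "G", "B"]].to_numpy() - out[["bgR", "bgG", "bgB"]].to_numpy()
        assert np.allclose(diff_before, diff_after, atol=1e-10)


class TestRgbToHcl:
    def test_gray_is_near_achromatic(self):
        # the tabulated matrix and white point disagree in the 4th decimal,
        # so the gray axis lands at C ~ 0.005, not exactly 0 (the reference
        # conversion shares this property)
        _, C, _ = rgb_to_hcl((128, 128, 128))
        assert C < 0.05

    def test_exact_neutral_axis_gets_hue_zero(self):
        # a color exactly on the dialect's own white axis is achromatic by
        # the C < 1e-6 convention and gets H = 0
        import best4pipe.colorimetry as cm

        lin = np.linalg.solve(cm._RGB_TO_XYZ, cm._WHITE * 0.18)
        srgb = 255.0 * np.where(
            lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055
        )
        _, C, H = rgb_to_hcl(srgb)
        assert C == pytest.approx(0.0, abs=1e-6)
        assert H == 0.0

    def test_white_point(self):
        L, C, _ = rgb_to_hcl((255, 255, 255))
        assert L == pytest.approx(100.0, abs=1e-2)
        assert C < 0.05

    def test_red_matches_reference_conversion(self):
        skimage_color = pytest.importorskip("skimage.color")
        L, C, H = rgb_to_hcl((255, 0, 0))
        luv = skimage_color.rgb2luv(np.array([[[1.0, 0.0, 0.0]]]))[0, 0]
        assert L == pytest.approx(luv[0], abs=1e-3)
        assert C == pytest.approx(np.hypot(luv[1], luv[2]), abs=1e-3)
        assert H == pytest.approx(np.degrees(np.arctan2(luv[2], luv[1])) % 360, abs=1e-3)

    def test_random_grid_matches_reference(self):
        skimage_color = pytest.importorskip("skimage.color")
        rng = np.random.default_rng(0)
        rgb = rng.uniform(0, 255, size=(200, 3))
        luv = skimage_color.rgb2luv((rgb / 255.0)[None, :, :])[0]
        for row, ref in zip(rgb, luv):
            L, C, H = rgb_to_hcl(row)
            assert L == pytest.approx(ref[0], abs=1e-3)
            assert C == pytest.approx(np.hypot(ref[1], ref[2]), abs=1e-3)


class TestHueShift:
    @pytest.mark.parametrize("h,expect", [(350.0, 170.0), (170.0, 350.0), (0.0, 180.0)])
    def test_examples(self, h, expect):
        assert hue_shift(h) == pytest.approx(expect)

    def test_involution(self):
        for h in np.linspace(0, 359.9, 25):
            assert hue_shift(hue_shift(h)) == pytest.approx(h)


class TestHuePolynomials:
    def _records(self, hue, chroma, lum):
        return pd.DataFrame({"hue_shifted": hue, "chroma": chroma, "luminance": lum})

    def test_exact_quartic_recovered(self):
        rng = np.random.default_rng(1)
        chroma = rng.uniform(10, 60, 30)
        coef = np.array([1e-4, -2e-3, 0.05, 1.2, 40.0])
        hue = np.polyval(coef, chroma)
        fits = fit_hue_polynomials(self._records(hue, chroma, chroma * 0.5))
        assert np.allclose(fits["hue~chroma"]["coef"], coef, atol=1e-6)
        assert fits["hue~chroma"]["r2"] == pytest.approx(1.0)

    def test_constant_hue_convention(self):
        fits = fit_hue_polynomials(
            self._records(np.full(10, 200.0), np.linspace(1, 10, 10), np.linspace(1, 10, 10))
        )
        assert fits["hue~chroma"]["r2"] == 1.0
        assert fits["hue~chroma"]["note"] == "zero-variance response"

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 50, 40)
        hue = rng.uniform(100, 300, 40)
        fits = fit_hue_polynomials(self._records(hue, x, rng.uniform(0, 100, 40)))
        V = np.vander(x, 5)
        beta = np.linalg.solve(V.T @ V, V.T @ hue)
        assert np.allclose(fits["hue~chroma"]["coef"], beta, atol=1e-8)

    def test_insufficient_records_rejected(self):
        with pytest.raises(ValueError, match="records"):
            fit_hue_polynomials(self._records([1, 2, 3], [1, 2, 3], [1, 2, 3]))


class TestHueTimeseries:
    def test_identical_animals_zero_width(self):
        rec = pd.DataFrame({"time": [0, 0, 0], "hue_shifted": [200.0] * 3})
        out = hue_timeseries(rec)
        assert out.loc[0, "ci_lo"] == out.loc[0, "ci_hi"] == 200.0

    def test_two_animal_closed_form(self):
        rec = pd.DataFrame({"time": [0, 0], "hue_shifted": [10.0, 20.0]})
        out = hue_timeseries(rec)
        half = 12.706204736 * (7.0710678 / np.sqrt(2))
        assert out.loc[0, "mean_hue"] == pytest.approx(15.0)
        assert out.loc[0, "ci_hi"] - out.loc[0, "mean_hue"] == pytest.approx(half, abs=1e-3)

    def test_missing_timepoint_omitted(self, caplog):
        rec = pd.DataFrame({"time": [0, 0], "hue_shifted": [10.0, 20.0]})
        with caplog.at_level("WARNING", logger="best4pipe"):
            out = hue_timeseries(rec, times=[0, 5])
        assert list(out["time"]) == [0]


class TestPhRecovery:
    def test_hue_trace_monotone_and_crosses_midpoint_at_pka(self):
        times = np.arange(0.0, 30.1, 0.5)
        series = simulate_ph_series(4.0, 7.5, 5.0, list(times), noise_sd=0.0, n_animals=1, seed=0)
        hue = series_to_hue(series)
        trace = hue_timeseries(hue)["mean_hue"].to_numpy()
        diffs = np.diff(trace)
        assert (diffs <= 1e-9).all() or (diffs >= -1e-9).all()
        std = simulate_ph_standards([4.0, 6.0, 7.5])
        std[["bgR", "bgG", "bgB"]] = 0.0
        mid_hue = series_to_hue(std, shift_background=False)["hue_shifted"].iloc[1]
        cross = times[np.argmin(np.abs(trace - mid_hue))]
        t_pka = 5.0 * np.log(3.5 / 1.5)  # pH(t) = 6 = pKa
        assert abs(cross - t_pka) <= 0.5

    def test_relaxation_time_recovered_from_hue(self):
        series = simulate_ph_series(4.0, 7.5, 5.0, list(np.arange(0.0, 31.0)), seed=3)
        ts = hue_timeseries(series_to_hue(series))
        fit = fit_relaxation(ts["time"], ts["mean_hue"])
        assert fit["tau"] == pytest.approx(5.0, rel=0.1)

    def test_calibration_maps_hue_back_to_ph(self):
        std = simulate_ph_standards(np.arange(4.0, 8.01, 0.25))
        std[["bgR", "bgG", "bgB"]] = 0.0
        hue = series_to_hue(std, shift_background=False)
        cal = calibrate_hue_to_ph(hue)
        recovered = cal(hue["hue_shifted"].to_numpy())
        mid = (std["ph"] > 4.5) & (std["ph"] < 7.5)  # inside the responsive range
        assert np.allclose(recovered[mid], std.loc[mid, "ph"], atol=0.05)


class TestRatiometrics:
    def test_phluorin_example(self):
        assert phluorin_ratio(200, 100, 50, 25) == pytest.approx(2.0)

    def test_phluorin_zero_numerator(self):
        assert phluorin_ratio(50, 100, 50, 25) == 0.0

    def test_phluorin_nonpositive_denominator_is_nan(self):
        assert np.isnan(phluorin_ratio(200, 10, 50, 25))

    def test_phluorin_gain_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            f405, f488, b405, b488 = rng.uniform(10, 100, 4)
            f488 += b488  # keep denominator positive
            g = rng.uniform(0.1, 10)
            assert phluorin_ratio(f405 * g, f488 * g, b405 * g, b488 * g) == pytest.approx(
                phluorin_ratio(f405, f488, b405, b488)
            )

    def test_ctcf_example(self):
        assert ctcf(1000, 10, 5) == 950.0

    def test_ctcf_uniform_image_is_zero(self):
        img = np.full((5, 5), 7.0)
        intden = img.sum()
        assert ctcf(intden, img.size, img.mean()) == pytest.approx(0.0)

    def test_ctcf_linear_in_integrated_density(self):
        assert ctcf(1001, 10, 5) - ctcf(1000, 10, 5) == pytest.approx(1.0)
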