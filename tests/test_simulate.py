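"""Synthetic sensor-frame generator: determinism, noise model, pipeline identity."""

import dataclasses
import math

import numpy as np
import pytest

from rawphot import (
    IspModel,
    ReactionModel,
    SpotModel,
    absorbance,
    crop,
    dark_frame,
    develop_rgb,
    dilution_series,
    end_point,
    intensity_from_planes,
    reaction_curve,
    render_mosaic,
    render_rgb,
    split_channels,
    two_point_delta,
    RoiSpec,
)
from rawphot.errors import ContractError


def measure_raw(mosaic, ref, dark, half=15):
    """Reference chain: split -> crop at the spot -> green means -> absorbance."""
    center = (60, 80)  # mosaic coords of the fixture spot
    spec = RoiSpec(center, half, half).halved()

    def green(m):
        p = split_channels(m)
        return intensity_from_planes(
            crop(p.red, spec), crop(p.green1, spec), crop(p.green2, spec), crop(p.blue, spec)
        ).mean_green

    return absorbance(green(ref), green(dark), green(mosaic)).A


class TestRenderMosaic:
    def test_zero_peak_gives_exact_dark_frame(self, quiet_small_spot):
        frame = dark_frame(quiet_small_spot)
        assert np.all(frame.values == round(quiet_small_spot.dark_level))

    def test_center_green_value_matches_formula(self, quiet_small_spot):
        spot = quiet_small_spot
        mosaic = render_mosaic(spot, true_A=1.0)
        # green1 site one column right of the (blue) centre pixel
        r, c = 60, 81
        d2 = (r - spot.center[0]) ** 2 + (c - spot.center[1]) ** 2
        gauss = math.exp(-d2 / (2 * spot.sigma**2))
        wg = spot.channel_weights[1]
        expected = round(spot.dark_level + wg * spot.peak * 10**-1.0 * gauss)
        assert mosaic.values[r, c] == expected

    def test_same_seed_renders_identical_frames(self, small_spot):
        a = render_mosaic(small_spot, 0.5)
        b = render_mosaic(small_spot, 0.5)
        assert np.array_equal(a.values, b.values)

    def test_shot_noise_variance_grows_with_mean(self, small_spot):
        noisy = dataclasses.replace(small_spot, read_noise_sd=0.0, shot_noise=True)
        clean = dataclasses.replace(small_spot, read_noise_sd=0.0, shot_noise=False)

        def residual_var(true_A):
            resid = (
                render_mosaic(noisy, true_A).values.astype(float)
                - render_mosaic(clean, true_A).values.astype(float)
            )
            return resid[50:70:2, 71:91:2].var()  # green1 sites near the spot

        assert residual_var(0.0) > residual_var(1.0)

    def test_negative_absorbance_rejected(self, small_spot):
        with pytest.raises(ContractError):
            render_mosaic(small_spot, -0.1)

    def test_invalid_spot_rejected(self):
        with pytest.raises(ContractError):
            SpotModel(peak=2000)
        with pytest.raises(ContractError):
            SpotModel(sigma=0)
        with pytest.raises(ContractError):
            SpotModel(dark_level=100, peak=50)


class TestNoiseFreeChainIdentity:
    @pytest.mark.parametrize("true_A", [0.0, 0.3, 0.9, 1.4, 1.8])
    def test_raw_chain_returns_truth_within_quantization(self, quiet_small_spot, true_A):
        ref = render_mosaic(quiet_small_spot, 0.0)
        dark = dark_frame(quiet_small_spot)
        sample = render_mosaic(quiet_small_spot, true_A)
        measured = measure_raw(sample, ref, dark)
        assert measured == pytest.approx(true_A, abs=0.02)

    def test_blank_is_exactly_zero(self, quiet_small_spot):
        ref = render_mosaic(quiet_small_spot, 0.0)
        dark = dark_frame(quiet_small_spot)
        assert measure_raw(render_mosaic(quiet_small_spot, 0.0), ref, dark) == 0.0


class TestProcessedPath:
    def test_identity_isp_is_proportional_to_mosaic(self, quiet_small_spot):
        mosaic = render_mosaic(quiet_small_spot, 0.2)
        rgb = develop_rgb(mosaic, IspModel(gamma=1.0, gains=(1, 1, 1)))
        planes = split_channels(mosaic)
        expected_red = np.rint(255.0 * planes.red / 1023.0)
        assert np.array_equal(rgb.values[:, :, 0], expected_red.astype(np.uint8))

    def test_saturated_spot_clips_to_255(self, quiet_small_spot):
        spot = dataclasses.replace(quiet_small_spot, peak=1023.0)
        rgb = develop_rgb(render_mosaic(spot, 0.0), IspModel(gamma=2.2, gains=(1, 4, 1)))
        assert rgb.values[30, 40, 1] == 255

    def test_gamma_path_deviates_more_than_raw_path(self, quiet_small_spot):
        spot = quiet_small_spot
        ref, dark = render_mosaic(spot, 0.0), dark_frame(spot)
        isp = IspModel(gamma=2.2)

        def measure_rgb(mosaic):
            def green(m):
                img = develop_rgb(m, isp)
                return crop(img.values, RoiSpec((30, 40), 8, 8))[:, :, 1].mean()
            return absorbance(green(ref), green(dark), green(mosaic)).A

        true_A = 0.6
        sample = render_mosaic(spot, true_A)
        err_raw = abs(measure_raw(sample, ref, dark) - true_A)
        err_rgb = abs(measure_rgb(sample) - true_A)
        assert err_rgb > err_raw


class TestScenarios:
    def test_dilution_series_shapes_and_determinism(self, small_spot):
        s1 = dilution_series(small_spot, [0.1, 0.5], replicates=2, seed=9)
        s2 = dilution_series(small_spot, [0.1, 0.5], replicates=2, seed=9)
        assert len(s1.samples) == 2 and len(s1.samples[0][1]) == 2
        assert np.array_equal(s1.reference.values, s2.reference.values)
        for (a1, f1), (a2, f2) in zip(s1.samples, s2.samples):
            for m1, m2 in zip(f1, f2):
                assert np.array_equal(m1.values, m2.values)

    def test_noiseless_single_replicate_matches_truth(self, quiet_small_spot):
        series = dilution_series(quiet_small_spot, [0.3, 0.8], replicates=1)
        for a, (frame,) in series.samples:
            measured = measure_raw(frame, series.reference, series.dark)
            assert measured == pytest.approx(a, abs=0.01)

    def test_empty_level_list_rejected(self, small_spot):
        with pytest.raises(ContractError):
            dilution_series(small_spot, [])

    def test_steep_logistic_reaches_plateau(self):
        model = ReactionModel(plateau=1.2, rate=50.0, t_mid=5.0)
        assert model.true_absorbance(40.0) == pytest.approx(1.2, abs=1e-6)
        assert model.true_absorbance(0.0) == pytest.approx(0.0, abs=1e-6)

    def test_decreasing_variant_has_negative_delta(self, quiet_small_spot):
        model = ReactionModel(plateau=1.0, rate=0.3, t_mid=10.0, direction="down")
        run = reaction_curve(quiet_small_spot, model, np.arange(0, 25, 5))
        assert two_point_delta(run.truth, 0, 20) < 0

    def test_noiseless_curve_recovered_through_pipeline(self, quiet_small_spot):
        model = ReactionModel(plateau=1.0, rate=0.2, t_mid=8.0)
        schedule = [0, 5, 10, 20, 40]
        run = reaction_curve(quiet_small_spot, model, schedule)
        for t, truth_a, frame in zip(run.truth.times, run.truth.absorbances, run.frames):
            measured = measure_raw(frame, run.reference, run.dark)
            assert measured == pytest.approx(truth_a, abs=0.02)
        assert end_point(run.truth, 40) == pytest.approx(model.true_absorbance(40))

    def test_unsorted_schedule_rejected(self, small_spot):
        with pytest.raises(ContractError):
            reaction_curve(small_spot, ReactionModel(), [0, 10, 5])
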