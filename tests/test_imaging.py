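"""Ratio computation, OPA, smoothing, calibration inversion and extraction."""

import numpy as np
import pytest

from conftest import noisy_acquisition, quiet_acquisition, uniform_scene
from optoflux import imaging
from optoflux.errors import DataError, GeometryError
from optoflux.imaging import (AnalyteMap, FrameStack, PlateLayout, RatioMap,
                              RoiMask)
from optoflux.simulate import render_frames, simulate_fields


def make_stack(sens, ref, pixel_size_mm=0.1):
    frames = np.stack([np.asarray(sens, float), np.asarray(ref, float)], axis=-1)[None]
    return FrameStack(frames=frames, timestamps_s=np.array([0.0]),
                      channel_roles={"sensitive": 0, "reference": 1},
                      pixel_size_mm=pixel_size_mm)


def const_map(value, shape=(10, 10), analyte="O2_percent_airsat", t=0.0):
    return AnalyteMap(values=np.full(shape, float(value)), analyte=analyte,
                      pixel_size_mm=0.1, timestamp_s=t)


class TestComputeRatio:
    def test_proportional_channels(self):
        stack = make_stack(2 * np.ones((8, 8)) * 500, np.ones((8, 8)) * 500)
        assert np.allclose(imaging.compute_ratio(stack, 0).values, 2.0)

    def test_common_mode_cancellation(self):
        """Scaling both channels by the same field leaves the ratio unchanged."""
        rng = np.random.default_rng(0)
        sens, ref = 800 * rng.random((8, 8)) + 100, 900 * rng.random((8, 8)) + 100
        L = 0.5 + rng.random((8, 8))
        r1 = imaging.compute_ratio(make_stack(sens, ref), 0).values
        r2 = imaging.compute_ratio(make_stack(sens * L, ref * L), 0, eps=1e-9).values
        assert np.allclose(r1, r2, rtol=1e-12)

    def test_zero_reference_yields_nan(self):
        ref = np.ones((5, 5)) * 1000.0
        ref[2, 2] = 0.0
        r = imaging.compute_ratio(make_stack(np.ones((5, 5)) * 500, ref), 0).values
        assert np.isnan(r[2, 2])
        assert np.isfinite(np.delete(r.ravel(), 12)).all()

    def test_time_index_out_of_range(self):
        with pytest.raises(DataError):
            imaging.compute_ratio(make_stack(np.ones((4, 4)), np.ones((4, 4))), 1)


class TestSmooth:
    def test_constant_map_unchanged(self):
        m = const_map(7.0)
        assert np.allclose(imaging.smooth(m, 3.0).values, 7.0)

    def test_impulse_mass_preserved(self):
        v = np.zeros((41, 41))
        v[20, 20] = 5.0
        m = RatioMap(values=v, pixel_size_mm=0.1, timestamp_s=0.0)
        out = imaging.smooth(m, 2.0)
        assert out.values.sum() == pytest.approx(5.0, abs=1e-6)

    def test_factor_zero_is_identity(self):
        rng = np.random.default_rng(1)
        m = RatioMap(values=rng.random((9, 9)), pixel_size_mm=0.1, timestamp_s=0.0)
        assert np.array_equal(imaging.smooth(m, 0.0).values, m.values)

    def test_nan_pixels_do_not_bleed(self):
        v = np.full((15, 15), 4.0)
        v[7, 7] = np.nan
        m = RatioMap(values=v, pixel_size_mm=0.1, timestamp_s=0.0)
        out = imaging.smooth(m, 2.0).values
        assert np.allclose(out[np.isfinite(out)], 4.0)

    def test_negative_factor_rejected(self):
        with pytest.raises(DataError):
            imaging.smooth(const_map(1.0), -1.0)


class TestApplyCalibration:
    def test_anchor_ratio_maps_to_zero(self, o2_cal):
        m = RatioMap(values=np.full((6, 6), o2_cal.R0), pixel_size_mm=0.1, timestamp_s=0.0)
        out = imaging.apply_calibration(m, o2_cal)
        assert np.allclose(out.values, 0.0)
        assert out.analyte == "O2_percent_airsat"

    def test_end_to_end_round_trip(self, o2_cal):
        """simulate -> render (noise off) -> ratio -> calibrate reproduces the
        simulated field to 1e-6 everywhere."""
        sc = uniform_scene(grid=(24, 24), d_eff=1e-3)
        acq = quiet_acquisition(duration_s=200)
        maps = simulate_fields(sc, acq, "O2")
        stack = render_frames(maps, o2_cal, acq)
        for t, truth in enumerate(maps):
            rec = imaging.apply_calibration(imaging.compute_ratio(stack, t), o2_cal)
            assert np.allclose(rec.values, truth.values, atol=1e-6)

    def test_nan_propagates_invalid(self, o2_cal):
        v = np.full((4, 4), 0.8)
        v[0, 0] = np.nan
        out = imaging.apply_calibration(
            RatioMap(values=v, pixel_size_mm=0.1, timestamp_s=0.0), o2_cal)
        assert np.isnan(out.values[0, 0]) and out.flags[0, 0] == 2

    def test_batch_mismatch_warns(self, o2_cal):
        m = RatioMap(values=np.full((4, 4), 0.8), pixel_size_mm=0.1, timestamp_s=0.0)
        with pytest.warns(UserWarning, match="batch"):
            imaging.apply_calibration(m, o2_cal, batch_id="other-batch")


class TestOpa:
    def test_uniform_plate_gives_unit_factors(self):
        m = RatioMap(values=np.full((12, 12), 0.4), pixel_size_mm=0.1, timestamp_s=0.0)
        field = imaging.fit_illumination(m, 0.4)
        assert np.allclose(field.correction, 1.0)

    def test_identity_field_leaves_map_unchanged(self):
        rng = np.random.default_rng(0)
        m = RatioMap(values=0.3 + rng.random((8, 8)), pixel_size_mm=0.1, timestamp_s=0.0)
        field = imaging.IlluminationField(correction=np.ones((8, 8)), reference_value=1.0)
        assert np.allclose(imaging.apply_opa(m, field).values, m.values)

    def test_bias_then_correct_recovers_truth(self, o2_cal):
        """Noise-free biased plate, corrected with a field fitted on the same
        bias, equals the unbiased plate to 1e-6."""
        rng = np.random.default_rng(3)
        bias = 1.0 + 0.2 * rng.random((16, 16))
        true_ratio = float(o2_cal.ratio(100.0))
        biased = RatioMap(values=true_ratio * bias, pixel_size_mm=0.1, timestamp_s=0.0)
        field = imaging.fit_illumination(biased, true_ratio)
        corrected = imaging.apply_opa(biased, field)
        assert np.allclose(corrected.values, true_ratio, atol=1e-6)

    def test_median_anchor(self):
        rng = np.random.default_rng(4)
        v = 0.5 + 0.1 * rng.random((11, 11))
        m = RatioMap(values=v, pixel_size_mm=0.1, timestamp_s=0.0)
        field = imaging.fit_illumination(m, float(np.median(v)))
        assert np.median(field.correction) == pytest.approx(1.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        m = RatioMap(values=np.ones((4, 4)), pixel_size_mm=0.1, timestamp_s=0.0)
        field = imaging.IlluminationField(correction=np.ones((5, 5)), reference_value=1.0)
        with pytest.raises(DataError):
            imaging.apply_opa(m, field)

    def test_plate_mode_scalar_per_well(self):
        """Plate mode fits one factor per well from the well-mean ratio and
        corrects each disc back to the expected value."""
        layout = PlateLayout.regular((80, 120), n_rows=2, n_cols=3)
        v = np.full((80, 120), 0.4)
        biases = [1.0, 1.1, 0.9, 1.05, 0.95, 1.2]
        for i, b in enumerate(biases):
            v[layout.well_mask(i, (80, 120))] = 0.4 * b
        m = RatioMap(values=v, pixel_size_mm=0.1, timestamp_s=0.0)
        field = imaging.fit_illumination(m, 0.4, layout=layout)
        assert np.allclose(field.correction, 1.0 / np.array(biases))
        corrected = imaging.apply_opa(m, field)
        for i in range(6):
            assert np.allclose(corrected.values[layout.well_mask(i, (80, 120))], 0.4)


class TestRoiExtraction:
    def test_constant_maps_give_constant_series(self):
        maps = [const_map(42.0, t=10.0 * i) for i in range(5)]
        roi = RoiMask(np.ones((10, 10), dtype=bool))
        ts = imaging.extract_roi_timeseries(maps, roi)
        assert np.allclose(ts.values, 42.0) and not ts.gaps.any()

    def test_mean_over_half_map(self):
        v = np.zeros((10, 10))
        v[:, :5] = 3.0
        v[:, 5:] = 9.0
        m = AnalyteMap(values=v, analyte="pH", pixel_size_mm=0.1, timestamp_s=0.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :5] = True
        ts = imaging.extract_roi_timeseries([m], RoiMask(mask))
        assert ts.values[0] == pytest.approx(3.0)

    def test_mean_is_permutation_invariant(self):
        rng = np.random.default_rng(5)
        v = rng.random((8, 8))
        perm = rng.permutation(64)
        m1 = AnalyteMap(values=v, analyte="pH", pixel_size_mm=0.1, timestamp_s=0.0)
        m2 = AnalyteMap(values=v.ravel()[perm].reshape(8, 8), analyte="pH",
                        pixel_size_mm=0.1, timestamp_s=0.0)
        roi = RoiMask(np.ones((8, 8), dtype=bool))
        assert imaging.extract_roi_timeseries([m1], roi).values[0] == pytest.approx(
            imaging.extract_roi_timeseries([m2], roi).values[0])

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            RoiMask(np.zeros((5, 5), dtype=bool))

    def test_invalid_timepoint_is_flagged_gap(self):
        good = const_map(10.0, t=0.0)
        bad = const_map(10.0, t=10.0)
        bad.flags[:] = 2  # everything invalid at t=10
        ts = imaging.extract_roi_timeseries([good, bad], RoiMask(np.ones((10, 10), bool)))
        assert list(ts.gaps) == [False, True]
        assert ts.n_valid[1] == 0


class TestWells:
    def test_per_well_constants_recovered(self):
        layout = PlateLayout.regular((80, 120), n_rows=2, n_cols=3)
        v = np.zeros((80, 120))
        for i in range(6):
            v[layout.well_mask(i, (80, 120))] = 10.0 * (i + 1)
        m = AnalyteMap(values=v, analyte="pH", pixel_size_mm=0.1, timestamp_s=0.0)
        df = imaging.extract_wells(m, layout)
        assert list(df["well"]) == ["A1", "A2", "A3", "B1", "B2", "B3"]
        assert np.allclose(df["value"], [10, 20, 30, 40, 50, 60])

    def test_fully_invalid_well_is_nan(self):
        layout = PlateLayout.regular((80, 120), n_rows=2, n_cols=3)
        m = const_map(5.0, shape=(80, 120))
        m.flags[layout.well_mask(0, (80, 120))] = 2
        df = imaging.extract_wells(m, layout)
        assert np.isnan(df["value"][0]) and df["n_valid"][0] == 0
        assert np.isfinite(df["value"][1:]).all()

    def test_out_of_bounds_layout_rejected(self):
        layout = PlateLayout(n_rows=1, n_cols=1, centers_px=np.array([[2.0, 2.0]]),
                             radius_px=10.0)
        with pytest.raises(GeometryError):
            imaging.extract_wells(const_map(1.0, shape=(20, 20)), layout)


class TestStackIo:
    def test_tiff_round_trip(self, tmp_path, o2_cal):
        sc = uniform_scene(grid=(16, 16))
        acq = noisy_acquisition(duration_s=60, seed=9)
        stack = render_frames(simulate_fields(sc, acq, "O2"), o2_cal, acq)
        path = imaging.write_frame_stack(stack, tmp_path)
        loaded = imaging.load_frame_stack(path)
        assert np.allclose(loaded.frames, stack.frames, atol=1e-5)
        assert np.array_equal(loaded.timestamps_s, stack.timestamps_s)
        assert loaded.batch_id == stack.batch_id


def test_heatmap_bytes_deterministic(tmp_path):
    m = const_map(50.0, shape=(20, 20))
    m.values[5:10, 5:10] = 20.0
    p1 = imaging.render_heatmap(m, tmp_path / "a.png", value_range=(0, 100))
    p2 = imaging.render_heatmap(m, tmp_path / "b.png", value_range=(0, 100))
    assert p1.read_bytes() == p2.read_bytes()
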