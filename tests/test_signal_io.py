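"""Trace I/O, background subtraction, ratioing, ROI extraction, detrending."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calwave.signal_io import (RoiGeometrySpec, RoiTraceSet, compute_ratio,
                               detrend, extract_roi_traces, load_traces,
                               save_traces, subtract_background)


def make_set(values, dt=1.0, **kw):
    return RoiTraceSet(values=np.asarray(values, dtype=float), dt=dt, **kw)


class TestRoiTraceSet:
    def test_shape_and_defaults(self):
        ts = make_set(np.ones((10, 3)))
        assert ts.n_frames == 10 and ts.n_rois == 3
        assert ts.roi_ids.tolist() == [1, 2, 3]
        assert np.allclose(ts.times, np.arange(10))

    @pytest.mark.parametrize("bad", [
        dict(values=np.ones((10, 1))),          # < 2 ROIs
        dict(values=np.ones((5, 3))),           # < 8 frames
        dict(values=np.full((10, 2), np.nan)),  # non-finite
        dict(values=np.ones((10, 2)), dt=0.0),  # bad dt
        dict(values=np.ones((10, 2)), roi_ids=[2, 1]),  # not increasing
        dict(values=np.ones((10, 2)), roi_ids=[0, 1]),  # background label
        dict(values=np.ones((10, 2)), channel="f999"),
    ])
    def test_invariants_rejected(self, bad):
        kw = dict(dt=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            RoiTraceSet(**kw)


class TestLoadSave:
    def test_three_column_csv(self, tmp_path):
        p = tmp_path / "traces.csv"
        p.write_text("t,roi1,roi2\n" + "\n".join(
            f"{i},{i * 0.5},{i * 2.0}" for i in range(10)))
        ts = load_traces(p, dt=1.0)
        assert ts.n_frames == 10 and ts.n_rois == 2
        assert ts.values[3, 0] == pytest.approx(1.5)

    def test_nan_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,roi1,roi2\n0,1.0,NaN\n" + "\n".join(
            f"{i},1,1" for i in range(1, 10)))
        with pytest.raises(ValueError, match="non-numeric"):
            load_traces(p, dt=1.0)

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("t,roi1\n" + "\n".join(f"{i},1" for i in range(10)))
        with pytest.raises(ValueError, match="at least 2"):
            load_traces(p, dt=1.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_traces(tmp_path / "nope.csv", dt=1.0)

    def test_nonpositive_dt(self, tmp_path):
        with pytest.raises(ValueError):
            load_traces(tmp_path / "x.csv", dt=-1.0)

    def test_round_trip_lossless(self, tmp_path, small_cell):
        _, (ratio, _, _, _, _) = small_cell
        p = tmp_path / "rt.csv"
        save_traces(ratio, p)
        back = load_traces(p, dt=ratio.dt, background_subtracted=True)
        np.testing.assert_allclose(back.values, ratio.values, rtol=1e-15)
        assert back.roi_ids.tolist() == ratio.roi_ids.tolist()


class TestBackgroundSubtraction:
    def test_cancellation_and_identity(self):
        bg = np.linspace(10, 11, 12)
        ts = make_set(np.tile(bg[:, None], (1, 3)), channel="f380")
        out = subtract_background(ts, bg)
        assert np.allclose(out.values, 0.0)
        assert out.background_subtracted
        ts2 = make_set(np.random.default_rng(0).normal(size=(12, 3)))
        out2 = subtract_background(ts2, np.zeros(12))
        np.testing.assert_array_equal(out2.values, ts2.values)

    def test_constant_arithmetic(self):
        out = subtract_background(make_set(np.full((10, 2), 7.0)),
                                  np.full(10, 3.0))
        assert np.allclose(out.values, 4.0)

    def test_double_subtraction_rejected(self):
        ts = make_set(np.ones((10, 2)))
        once = subtract_background(ts, np.zeros(10))
        with pytest.raises(ValueError, match="already"):
            subtract_background(once, np.zeros(10))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            subtract_background(make_set(np.ones((10, 2))), np.zeros(9))


class TestComputeRatio:
    def _pair(self, a, b):
        kw = dict(background_subtracted=True)
        return (make_set(a, channel="f340", **kw),
                make_set(b, channel="f380", **kw))

    def test_identity_and_scaling(self):
        f380 = np.full((10, 2), 5.0)
        f340, f380s = self._pair(f380, f380)
        assert np.allclose(compute_ratio(f340, f380s).values, 1.0)
        f340b, f380b = self._pair(2 * f380, f380)
        assert np.allclose(compute_ratio(f340b, f380b).values, 2.0)

    def test_guarded_denominator(self):
        a = np.ones((10, 2))
        b = np.ones((10, 2))
        b[4, 1] = 0.0
        f340, f380 = self._pair(a, b)
        out = compute_ratio(f340, f380, eps=1e-9)
        assert np.all(np.isfinite(out.values))
        assert out.n_guarded == 1
        assert out.channel == "ratio"

    def test_requires_background_subtraction(self):
        f340 = make_set(np.ones((10, 2)), channel="f340")
        f380 = make_set(np.ones((10, 2)), channel="f380",
                        background_subtracted=True)
        with pytest.raises(ValueError, match="background"):
            compute_ratio(f340, f380)

    def test_offset_commutation(self):
        """Subtracting a per-frame constant offset before ratioing equals
        ratioing offset-free channels directly."""
        rng = np.random.default_rng(5)
        a = rng.uniform(1, 2, (12, 4))
        b = rng.uniform(1, 2, (12, 4))
        off = rng.uniform(0.1, 0.5, 12)
        direct = compute_ratio(*self._pair(a, b))
        via_sub = compute_ratio(
            subtract_background(make_set(a + off[:, None], channel="f340"),
                                off),
            subtract_background(make_set(b + off[:, None], channel="f380"),
                                off))
        np.testing.assert_allclose(via_sub.values, direct.values, rtol=1e-12)


class TestExtractRoiTraces:
    SPEC = RoiGeometrySpec(centers=[(5.0, 5.0), (12.0, 5.0)], radius_px=3)

    def test_uniform_image(self):
        stack = np.full((8, 16, 20), 3.5)
        ts = extract_roi_traces(stack, self.SPEC, dt=1.0)
        assert np.allclose(ts.values, 3.5)

    def test_radius_zero_single_pixel(self):
        rng = np.random.default_rng(1)
        stack = rng.normal(size=(9, 12, 12))
        spec = RoiGeometrySpec(centers=[(4, 7), (8, 2)], radius_px=0)
        ts = extract_roi_traces(stack, spec, dt=1.0)
        np.testing.assert_array_equal(ts.values[:, 0], stack[:, 7, 4])
        np.testing.assert_array_equal(ts.values[:, 1], stack[:, 2, 8])

    def test_painted_disk_means(self):
        """A stack painted with known values inside each disk yields
        exactly those values as traces."""
        from calwave.signal_io import circle_mask
        stack = np.zeros((8, 16, 24))
        for i, (c, v) in enumerate(zip(self.SPEC.centers, (2.0, 5.0))):
            m = circle_mask((16, 24), tuple(c), self.SPEC.radius_px)
            for t in range(8):
                frame = stack[t]
                frame[m] = v * (t + 1)
        ts = extract_roi_traces(stack, self.SPEC, dt=0.5)
        np.testing.assert_allclose(ts.values[:, 0], 2.0 * np.arange(1, 9))
        np.testing.assert_allclose(ts.values[:, 1], 5.0 * np.arange(1, 9))

    def test_linearity_in_the_image(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(8, 16, 20))
        B = rng.normal(size=(8, 16, 20))
        ta = extract_roi_traces(A, self.SPEC, dt=1.0).values
        tb = extract_roi_traces(B, self.SPEC, dt=1.0).values
        tab = extract_roi_traces(2 * A + 3 * B, self.SPEC, dt=1.0).values
        np.testing.assert_allclose(tab, 2 * ta + 3 * tb, rtol=1e-12)

    def test_out_of_bounds_circle(self):
        stack = np.zeros((8, 10, 10))
        spec = RoiGeometrySpec(centers=[(1.0, 5.0), (5.0, 5.0)], radius_px=3)
        with pytest.raises(ValueError, match="outside"):
            extract_roi_traces(stack, spec, dt=1.0)


class TestLoadStack:
    def test_tiff_round_trip_and_extraction(self, tmp_path):
        import tifffile
        from calwave.signal_io import load_stack
        rng = np.random.default_rng(6)
        stack = rng.uniform(0, 100, (8, 16, 20)).astype(np.float32)
        p = tmp_path / "stack.tif"
        tifffile.imwrite(p, stack)
        loaded = load_stack(p)
        np.testing.assert_allclose(loaded, stack, rtol=1e-6)
        spec = RoiGeometrySpec(centers=[(5.0, 5.0), (12.0, 8.0)], radius_px=2)
        ts = extract_roi_traces(loaded, spec, dt=1.0)
        assert ts.n_frames == 8 and ts.n_rois == 2


class TestDetrend:
    def test_modes(self):
        const = np.full(20, 4.2)
        assert np.allclose(detrend(const, "mean"), 0.0)
        t = np.arange(30, dtype=float)
        line = 2.5 + 0.3 * t
        assert np.max(np.abs(detrend(line, "linear"))) < 1e-10
        x = np.sin(t)
        np.testing.assert_array_equal(detrend(x, "none"), x)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            detrend(np.ones(5), "fourier")

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    def test_mean_mode_zero_mean(self, xs):
        out = detrend(np.array(xs), "mean")
        assert abs(out.mean()) < 1e-9 * max(1.0, np.abs(xs).max())
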