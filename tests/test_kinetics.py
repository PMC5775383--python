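"""Background-subtracted traces, Delta I, and per-cell linear fits."""

import numpy as np
import pytest

from anchortrack import kinetics as kin
from anchortrack import segmentation as seg
from anchortrack.chip_model import build_layout
from anchortrack.errors import InvalidInputError
from anchortrack.segmentation import CellTrack, DetectedCell
from anchortrack.synthetic_timelapse import CellTruth, ImagingParams, render_frame


@pytest.fixture(scope="module")
def layout():
    return build_layout(rows=2, cols=2)


def disk_detection(layout, anchor_id, radius_px=7):
    """A detection whose mask is a centred disk in the anchor."""
    cx, cy = layout.centers_um[anchor_id]
    yy, xx = np.mgrid[0 : int(layout.fov_um[1]), 0 : int(layout.fov_um[0])]
    inside = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius_px**2
    coords = np.argwhere(inside)
    return DetectedCell(
        frame=0,
        x_um=cx,
        y_um=cy,
        area_um2=float(coords.shape[0]),
        eq_diameter_um=2 * radius_px,
        anchor_id=anchor_id,
        mask=coords,
    )


class TestMeasureIntensities:
    def test_uniform_frame_gives_zero_signal(self, layout):
        det = disk_detection(layout, 0)
        frame = np.full((int(layout.fov_um[1]), int(layout.fov_um[0])), 137.0)
        kin.measure_intensities([det], frame, layout)
        assert det.i_cell - det.i_back == pytest.approx(0.0)

    def test_cell_above_background(self, layout):
        det = disk_detection(layout, 0)
        frame = np.full((int(layout.fov_um[1]), int(layout.fov_um[0])), 100.0)
        frame[det.mask[:, 0], det.mask[:, 1]] = 250.0
        kin.measure_intensities([det], frame, layout)
        assert det.i_cell == pytest.approx(250.0)
        assert det.i_back == pytest.approx(100.0)
        assert det.i_cell - det.i_back == pytest.approx(150.0)


class TestDelta:
    def test_examples(self):
        np.testing.assert_allclose(
            kin.delta_trace([10.0, 30.0, 70.0]), [0.0, 20.0, 60.0]
        )
        np.testing.assert_allclose(kin.delta_trace([5.0, 5.0, 5.0]), 0.0)

    def test_starts_at_zero(self):
        rng = np.random.default_rng(0)
        assert kin.delta_trace(rng.normal(size=20))[0] == 0.0


class TestFitLinear:
    def test_exact_line(self):
        t = np.arange(0, 63, 2, dtype=float)
        slope, intercept, r2 = kin.fit_linear(t, 5.0 * t)
        assert slope == pytest.approx(5.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_series_convention(self):
        slope, _, r2 = kin.fit_linear(np.array([0.0, 2.0, 4.0]), np.zeros(3))
        assert slope == 0.0 and r2 == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            kin.fit_linear(np.array([0.0, 2.0]), np.array([0.0, 1.0]))


class TestBackgroundInvariance:
    def test_constant_offset_cancels(self, layout):
        """Adding a constant to every green pixel leaves I and Delta I
        unchanged: the measurement is purely differential."""
        cx, cy = layout.centers_um[0]
        cell = CellTruth(0, 0, cx, cy, 14.0, False, 4.0, 15.0, True)
        params = ImagingParams(
            read_noise_sd=0.0, quantize=False, time_grid_h=(0.0, 2.0, 4.0, 6.0)
        )
        tracks = None
        results = []
        for offset in (0.0, 500.0):
            dets_per_frame = []
            for k in range(4):
                red = render_frame([cell], layout, k, "red_tracker", params)
                green = np.asarray(
                    render_frame([cell], layout, k, "green_gfp", params), dtype=float
                )
                green += offset
                dets = seg.detect_cells(red, layout, frame=k)
                kin.measure_intensities(dets, green, layout)
                dets_per_frame.append(dets)
            track = seg.track_cells(dets_per_frame)[0]
            results.append(kin.extract_trace(track, params.time_grid_h))
        np.testing.assert_allclose(results[0].intensity, results[1].intensity, atol=1e-9)
        np.testing.assert_allclose(results[0].delta, results[1].delta, atol=1e-9)
        assert results[0].slope == pytest.approx(results[1].slope, abs=1e-12)


class TestExtractTrace:
    def test_zero_noise_cell_recovers_generator_line(self, layout):
        cx, cy = layout.centers_um[3]
        cell = CellTruth(0, 3, cx, cy, 16.0, False, 7.0, 25.0, True)
        params = ImagingParams(
            read_noise_sd=0.0,
            blur_sigma_px=0.0,
            quantize=False,
            antialias=False,
            time_grid_h=tuple(float(t) for t in range(0, 13, 2)),
        )
        dets_per_frame = []
        for k in range(len(params.time_grid_h)):
            red = render_frame([cell], layout, k, "red_tracker", params)
            green = render_frame([cell], layout, k, "green_gfp", params)
            dets = seg.detect_cells(red, layout, frame=k)
            kin.measure_intensities(dets, green, layout)
            dets_per_frame.append(dets)
        track = seg.track_cells(dets_per_frame)[0]
        trace = kin.extract_trace(track, params.time_grid_h)
        # I(t) - I(0) = slope * t exactly
        np.testing.assert_allclose(
            trace.delta, 7.0 * np.asarray(params.time_grid_h), rtol=1e-12, atol=1e-9
        )
        assert trace.slope == pytest.approx(7.0, rel=1e-9)
        assert trace.delta[0] == 0.0

    def test_missing_frame_interpolated(self, layout):
        det0 = disk_detection(layout, 0)
        det2 = disk_detection(layout, 0)
        det0.i_cell, det0.i_back = 110.0, 100.0
        det2.i_cell, det2.i_back = 130.0, 100.0
        track = CellTrack(0, 0, {0: det0, 2: det2}, n_frames=3)
        trace = kin.extract_trace(track, (0.0, 2.0, 4.0))
        assert trace.intensity[1] == pytest.approx(20.0)  # midpoint of 10 and 30


class TestPopulationSummary:
    def _trace(self, deltas):
        d = np.asarray(deltas, dtype=float)
        t = np.arange(d.size, dtype=float) * 2
        return kin.CellTrace(
            track_id=0, anchor_id=0, time_h=t, i_cell=d, i_back=np.zeros_like(d),
            intensity=d, delta=d,
        )

    def test_single_trace(self):
        tr = self._trace([0.0, 10.0, 20.0])
        summary = kin.summarize_population([tr])
        np.testing.assert_allclose(summary.mean_delta, tr.delta)
        np.testing.assert_allclose(summary.mean_deviation, 0.0)

    def test_two_trace_mean_and_md(self):
        summary = kin.summarize_population(
            [self._trace([0.0, 10.0]), self._trace([0.0, 30.0])]
        )
        np.testing.assert_allclose(summary.mean_delta, [0.0, 20.0])
        np.testing.assert_allclose(summary.mean_deviation, [0.0, 10.0])

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            kin.summarize_population([])
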