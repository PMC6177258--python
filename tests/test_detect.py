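"""Baseline, dF/F0, ROI tiling and trace-level event calling."""

import numpy as np
import pytest

from sparklet.detect import (
    CandidateEvent,
    DffStack,
    Roi,
    RoiTrace,
    compute_baseline,
    compute_dff,
    detect_events,
    detect_steps,
    extract_trace,
    localize_sites,
    tile_rois,
)
from sparklet.movie import MovieStack


def movie_from(frames, pixel_um=0.27, rate=40.0):
    frames = np.asarray(frames, dtype=float)
    return MovieStack(
        frames=frames, pixel_um=pixel_um, timestamps=np.arange(frames.shape[0]) / rate
    )


def trace_from(values, rate=40.0, pixel_um=0.27, side=20):
    values = np.asarray(values, dtype=float)
    roi = Roi(y0=0, x0=0, side_px=side, pixel_um=pixel_um)
    return RoiTrace(roi=roi, dff=values, timestamps=np.arange(values.size) / rate)


class TestBaseline:
    def test_constant_frames(self):
        m = movie_from(np.full((12, 4, 4), 100.0))
        b = compute_baseline(m)
        assert np.all(b.f0 == 100.0) and b.n_frames_used == 10

    def test_arithmetic_mean_of_first_ten(self):
        frames = np.zeros((10, 2, 2))
        frames[:, 0, 0] = np.arange(1, 11)
        b = compute_baseline(movie_from(frames))
        assert b.f0[0, 0] == pytest.approx(5.5)

    def test_later_frames_never_influence_f0(self):
        frames = np.full((1000, 2, 2), 500.0)
        frames[:10] = 50.0
        b = compute_baseline(movie_from(frames))
        assert np.all(b.f0 == 50.0)

    def test_too_few_frames_names_the_shortfall(self):
        with pytest.raises(ValueError, match="3 frames"):
            compute_baseline(movie_from(np.zeros((3, 2, 2)) + 1))


class TestDff:
    def test_identity_and_doubling(self):
        frames = np.full((12, 2, 2), 100.0)
        m = movie_from(frames)
        b = compute_baseline(m)
        d = compute_dff(m, b)
        assert np.all(d.data == 0.0)
        frames2 = frames.copy()
        frames2[11] = 200.0
        d2 = compute_dff(movie_from(frames2), b)
        assert np.all(d2.data[11] == pytest.approx(1.0))

    def test_zero_baseline_pixel_masked_not_infinite(self):
        frames = np.full((12, 2, 2), 100.0)
        frames[:, 0, 0] = 0.0
        m = movie_from(frames)
        b = compute_baseline(m)
        d = compute_dff(m, b)
        assert d.invalid[0, 0]
        assert np.all(np.isfinite(d.data))
        assert np.all(d.data[:, 0, 0] == 0.0)

    def test_all_invalid_baseline_is_an_error(self):
        frames = np.zeros((12, 2, 2))
        m = movie_from(frames)
        with pytest.raises(ValueError, match="no valid pixels"):
            compute_dff(m, compute_baseline(m))


class TestRoiGrid:
    def test_reference_roi_is_20_pixels(self):
        rois = tile_rois((512, 512), pixel_um=0.27)
        assert rois[0].side_px == 20  # round(5.3 / 0.27)
        assert rois[0].side_um == pytest.approx(5.4, abs=0.2)

    def test_grid_count_matches_arithmetic(self):
        rois = tile_rois((512, 512), pixel_um=0.27)  # stride 10 at 50% overlap
        per_axis = (512 - 20) // 10 + 1
        assert len(rois) == per_axis**2

    def test_missing_pixel_size_is_an_error(self):
        with pytest.raises(ValueError, match="pixel size"):
            tile_rois((64, 64), pixel_um=None)

    def test_roi_larger_than_fov_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            tile_rois((16, 16), pixel_um=0.27)


class TestExtractTrace:
    def test_uniform_frame_value(self):
        data = np.full((5, 20, 20), 0.3, dtype=np.float32)
        d = DffStack(data=data, invalid=np.zeros((20, 20), bool), pixel_um=0.27,
                     timestamps=np.arange(5) / 40)
        tr = extract_trace(d, Roi(0, 0, 20, 0.27))
        assert np.allclose(tr.dff, 0.3)

    def test_half_high_half_zero_averages(self):
        data = np.zeros((2, 20, 20), dtype=np.float32)
        data[:, :10, :] = 2.0
        d = DffStack(data=data, invalid=np.zeros((20, 20), bool), pixel_um=0.27,
                     timestamps=np.arange(2) / 40)
        tr = extract_trace(d, Roi(0, 0, 20, 0.27))
        assert np.allclose(tr.dff, 1.0)

    def test_fully_masked_roi_is_an_error(self):
        d = DffStack(data=np.zeros((2, 20, 20), np.float32),
                     invalid=np.ones((20, 20), bool), pixel_um=0.27,
                     timestamps=np.arange(2) / 40)
        with pytest.raises(ValueError, match="no valid pixels"):
            extract_trace(d, Roi(0, 0, 20, 0.27))


def brute_force_steps(segment, unit, min_frames=2):
    """Independent change-point oracle: scan every frame for a sustained
    quantal level change."""
    levels = [int(round(max(v, 0) / unit)) for v in segment]
    # sustained level at each index (>= min_frames run), forward fill
    runs = []
    i = 0
    while i < len(levels):
        j = i
        while j + 1 < len(levels) and levels[j + 1] == levels[i]:
            j += 1
        runs.append((levels[i], i, j - i + 1))
        i = j + 1
    sustained = []
    for lev, start, length in runs:
        if length >= min_frames or not sustained:
            sustained.append((lev, start))
    changes = []
    for k in range(1, len(sustained)):
        if sustained[k][0] != sustained[k - 1][0]:
            changes.append((sustained[k - 1][0], sustained[k][0]))
    return changes


class TestDetectEvents:
    def test_flat_trace_has_no_events(self):
        assert detect_events(trace_from(np.zeros(100))) == []

    def test_rectangular_pulse(self):
        y = np.zeros(60)
        y[20:30] = 1.1
        events = detect_events(trace_from(y), threshold_dff=0.55)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(1.1)
        assert events[0].core_start == 20 and events[0].core_end == 29

    def test_staircase_records_two_ascending_steps(self):
        y = np.concatenate([
            np.zeros(10), np.full(10, 1.1), np.full(10, 2.2),
            np.full(10, 1.1), np.zeros(10),
        ])
        events = detect_events(trace_from(y), threshold_dff=0.55, step_amp=1.1)
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude == pytest.approx(2.2)
        ups = [(a, b) for _, a, b in ev.steps if b > a]
        downs = [(a, b) for _, a, b in ev.steps if b < a]
        assert len(ups) == 2 and len(downs) == 2
        # cross-check against the brute-force change-point oracle
        oracle = brute_force_steps(ev.segment, 1.1)
        assert [(a, b) for _, a, b in ev.steps] == oracle

    def test_single_frame_spike_rejected(self):
        y = np.zeros(50)
        y[25] = 2.0
        assert detect_events(trace_from(y), threshold_dff=0.55) == []

    def test_brief_subthreshold_gap_does_not_split_event(self):
        y = np.zeros(60)
        y[20:30] = 1.1
        y[24] = 0.3  # single-frame dropout, below the 2-frame debounce
        events = detect_events(trace_from(y), threshold_dff=0.55)
        assert len(events) == 1

    def test_two_separated_pulses_are_two_events(self):
        y = np.zeros(100)
        y[20:30] = 1.1
        y[60:70] = 1.1
        assert len(detect_events(trace_from(y), threshold_dff=0.55)) == 2

    def test_nonmonotonic_timestamps_rejected(self):
        tr = trace_from(np.zeros(10))
        tr.timestamps = tr.timestamps[::-1].copy()
        with pytest.raises(ValueError, match="increasing"):
            detect_events(tr)

    def test_threshold_k_times_noise(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.01, size=400)
        y[100:110] += 1.0
        events = detect_events(trace_from(y), noise_sd=0.01, threshold_k=10)
        assert len(events) == 1


class TestDetectSteps:
    def test_short_blips_are_absorbed(self):
        seg = np.array([0, 0, 1.1, 2.2, 1.1, 1.1, 0, 0])  # 1-frame excursion to 2.2
        steps = detect_steps(seg, 1.1, min_frames=2)
        assert [(a, b) for _, a, b in steps] == [(0, 1), (1, 0)]


def make_event(t0, t1, x_um, y_um, amp=1.0, rate=40.0):
    n = t1 - t0 + 1
    seg = np.full(n, amp)
    return CandidateEvent(
        start_frame=t0, peak_frame=t0, end_frame=t1,
        times=np.arange(t0, t1 + 1) / rate, segment=seg, amplitude=amp,
        threshold=0.5, core_start=t0, core_end=t1, x_um=x_um, y_um=y_um,
    )


class TestLocalizeSites:
    def test_nearby_events_share_a_site(self):
        evs = [make_event(0, 5, 10.0, 10.0), make_event(50, 55, 10.4, 10.3)]
        kept, sites = localize_sites(evs, merge_radius_um=2.0)
        assert len(kept) == 2 and len(sites) == 1

    def test_distant_events_are_two_sites(self):
        evs = [make_event(0, 5, 10.0, 10.0), make_event(50, 55, 60.0, 10.0)]
        _, sites = localize_sites(evs, merge_radius_um=2.0)
        assert len(sites) == 2

    def test_duplicate_event_from_overlapping_rois_collapses(self):
        # same physical event seen by two overlapping ROIs: same time span,
        # positions well within the merge radius
        a = make_event(10, 20, 10.0, 10.0, amp=1.1)
        b = make_event(10, 20, 10.2, 10.1, amp=1.0)
        kept, sites = localize_sites([a, b], merge_radius_um=2.0)
        assert len(kept) == 1 and kept[0].amplitude == pytest.approx(1.1)
        # oracle: exhaustive pairwise centroid distance + time overlap
        assert np.hypot(a.x_um - b.x_um, a.y_um - b.y_um) < 2.0

    def test_same_site_sequential_events_not_merged(self):
        a = make_event(10, 20, 10.0, 10.0)
        b = make_event(40, 50, 10.0, 10.0)
        kept, sites = localize_sites([a, b], merge_radius_um=2.0)
        assert len(kept) == 2 and len(sites) == 1 and sites[0].n_events == 2
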