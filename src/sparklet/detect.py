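"""Sparklet event detection on dF/F0 movies.

The stage follows the optical patch-clamp workflow: baseline fluorescence
F0 is the pixel-wise mean of the first frames acquired before stimulation;
dF/F0 = (F - F0)/F0; traces are spatial means over 5.3 x 5.3 um regions of
interest tiled across the field with 50% overlap; candidate events are
contiguous supra-threshold excursions of a trace.

Detection is two-stage.  Candidate runs are found on the ROI-mean traces
with a sensitive threshold (a noise multiple with an absolute floor):
averaging a ~17 um^2 Gaussian footprint over a ~28 um^2 ROI that may be
mis-centred by up to half a tile stride dilutes the peak well below the
unitary amplitude, so the trace itself is deliberately not held to the
quantal threshold.  Each candidate is then refined against the pixel data
(2-D Gaussian fit at the peak frame, then per-frame projection of the
fitted footprint) which restores the amplitude on the true dF/F0 scale;
acceptance applies the quantal threshold (default 0.5 x unitary amplitude)
to that refined amplitude.  Duplicates from overlapping ROIs are collapsed
by spatio-temporal proximity and surviving events are clustered into
sparklet sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter

from .movie import MovieStack

__all__ = [
    "BaselineImage",
    "DffStack",
    "Roi",
    "RoiTrace",
    "CandidateEvent",
    "SparkletSite",
    "DetectionResult",
    "compute_baseline",
    "compute_dff",
    "tile_rois",
    "extract_trace",
    "detect_events",
    "detect_steps",
    "localize_sites",
    "detect_movie",
    "estimate_noise_sd",
]

ROI_SIDE_UM = 5.3  # side of the analysis region of interest


@dataclass
class BaselineImage:
    """Pixel-wise baseline fluorescence F0 and its invalid-pixel mask."""

    f0: np.ndarray
    n_frames_used: int
    invalid: np.ndarray  # True where F0 <= 0 or non-finite

    @property
    def all_invalid(self) -> bool:
        return bool(self.invalid.all())


@dataclass
class DffStack:
    """dF/F0 values per pixel and frame, with geometry and timing."""

    data: np.ndarray        # (t, y, x) float32; 0 on invalid pixels
    invalid: np.ndarray     # (y, x) bool
    pixel_um: float
    timestamps: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class Roi:
    """A square region of interest in pixel coordinates."""

    y0: int
    x0: int
    side_px: int
    pixel_um: float

    @property
    def side_um(self) -> float:
        return self.side_px * self.pixel_um

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.y0 + self.side_px / 2.0, self.x0 + self.side_px / 2.0)

    @property
    def center_um(self) -> tuple[float, float]:
        cy, cx = self.center_px
        return (cy * self.pixel_um, cx * self.pixel_um)


@dataclass
class RoiTrace:
    """Spatial-mean dF/F0 of one ROI across all frames."""

    roi: Roi
    dff: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if self.dff.shape != self.timestamps.shape:
            raise ValueError("trace and timestamps lengths differ")


@dataclass
class CandidateEvent:
    """One supra-threshold excursion, possibly refined against pixel data.

    Frame indices are global movie indices; ``start/end`` span the event
    segment extended down to the local baseline, ``core_*`` the
    supra-threshold run itself.  ``segment`` holds the per-frame amplitude
    (ROI-mean for raw candidates, template-projected dF/F0 after
    refinement) and ``amplitude`` its sub-frame-interpolated peak.
    """

    start_frame: int
    peak_frame: int
    end_frame: int
    times: np.ndarray
    segment: np.ndarray
    amplitude: float
    threshold: float
    core_start: int
    core_end: int
    roi: Roi | None = None
    x_um: float = math.nan
    y_um: float = math.nan
    sigma_px: float = math.nan
    steps: list[tuple[int, int, int]] = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.start_frame <= self.peak_frame <= self.end_frame:
            raise ValueError("event requires start <= peak <= end")

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_peak(self) -> float:
        return float(self.times[self.peak_frame - self.start_frame])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])


@dataclass
class SparkletSite:
    """A spatial cluster of events attributed to one channel site."""

    site_id: int
    x_um: float
    y_um: float
    events: list[CandidateEvent]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def frequency_hz(self, duration_s: float) -> float:
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        return self.n_events / duration_s


# -- baseline and dF/F0 ----------------------------------------------------

def compute_baseline(movie: MovieStack, n: int = 10) -> BaselineImage:
    """Average the first ``n`` frames (acquired before stimulation) as F0.

    Later frames never influence F0, so stimulated activity cannot
    contaminate the baseline.
    """
    if n < 1:
        raise ValueError("baseline needs at least one frame")
    if movie.n_frames < n:
        raise ValueError(
            f"movie has {movie.n_frames} frames; baseline requires the first {n}"
        )
    f0 = movie.frames[:n].mean(axis=0, dtype=np.float64)
    invalid = ~np.isfinite(f0) | (f0 <= 0)
    return BaselineImage(f0=f0, n_frames_used=n, invalid=invalid)


def compute_dff(movie: MovieStack, baseline: BaselineImage) -> DffStack:
    """(F - F0)/F0 per pixel and frame; invalid-baseline pixels masked."""
    if movie.frame_shape != baseline.f0.shape:
        raise ValueError(
            f"movie frames {movie.frame_shape} and baseline {baseline.f0.shape} differ"
        )
    if baseline.all_invalid:
        raise ValueError("baseline has no valid pixels; cannot form dF/F0")
    f0 = np.where(baseline.invalid, 1.0, baseline.f0)
    dff = (movie.frames.astype(np.float32) - f0.astype(np.float32)) / f0.astype(np.float32)
    dff[:, baseline.invalid] = 0.0
    return DffStack(
        data=dff,
        invalid=baseline.invalid,
        pixel_um=movie.pixel_um,
        timestamps=movie.timestamps,
    )


# -- ROI grid --------------------------------------------------------------

def tile_rois(
    frame_shape: tuple[int, int],
    pixel_um: float | None,
    roi_um: float = ROI_SIDE_UM,
    overlap: float = 0.5,
) -> list[Roi]:
    """Tile the field of view with square ROIs.

    The ROI side is ``round(roi_um / pixel_um)`` pixels (20 px for the
    0.27-um pixels of the reference optics) and consecutive ROIs overlap
    by ``overlap`` of their side, giving ``floor((fov - side)/stride) + 1``
    positions per axis.
    """
    if pixel_um is None or not pixel_um > 0:
        raise ValueError("pixel size (um) is required to tile ROIs")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    side = int(round(roi_um / pixel_um))
    ny, nx = frame_shape
    if side > min(ny, nx):
        raise ValueError(
            f"ROI side {side} px exceeds the {ny}x{nx} px field of view"
        )
    stride = max(1, round(side * (1.0 - overlap)))
    return [
        Roi(y0=y, x0=x, side_px=side, pixel_um=pixel_um)
        for y in range(0, ny - side + 1, stride)
        for x in range(0, nx - side + 1, stride)
    ]


def extract_trace(dff: DffStack, roi: Roi) -> RoiTrace:
    """Per-frame spatial mean of dF/F0 over the ROI's valid pixels."""
    sl = (slice(roi.y0, roi.y0 + roi.side_px), slice(roi.x0, roi.x0 + roi.side_px))
    valid = ~dff.invalid[sl]
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("ROI contains no valid pixels")
    block = dff.data[(slice(None),) + sl]
    trace = block.reshape(dff.n_frames, -1)[:, valid.ravel()].mean(axis=1)
    return RoiTrace(roi=roi, dff=trace.astype(np.float64), timestamps=dff.timestamps)


def _all_roi_traces(dff: DffStack, rois: list[Roi]) -> np.ndarray:
    """Vectorized ROI means via per-frame integral images.

    Returns an array (n_rois, n_frames).  Invalid pixels contribute 0 to
    the sums and are excluded from the per-ROI divisor.
    """
    if not rois:
        return np.empty((0, dff.n_frames))
    side = rois[0].side_px
    y0 = np.array([r.y0 for r in rois])
    x0 = np.array([r.x0 for r in rois])
    valid = (~dff.invalid).astype(np.float64)
    cval = np.pad(valid, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    counts = (
        cval[y0 + side, x0 + side] - cval[y0, x0 + side]
        - cval[y0 + side, x0] + cval[y0, x0]
    )
    traces = np.empty((len(rois), dff.n_frames))
    chunk = max(1, int(4e7 // (dff.data.shape[1] * dff.data.shape[2])))
    for t0 in range(0, dff.n_frames, chunk):
        block = dff.data[t0 : t0 + chunk].astype(np.float64)
        c = np.pad(block, ((0, 0), (1, 0), (1, 0))).cumsum(1).cumsum(2)
        sums = (
            c[:, y0 + side, x0 + side] - c[:, y0, x0 + side]
            - c[:, y0 + side, x0] + c[:, y0, x0]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            traces[:, t0 : t0 + chunk] = (sums / counts).T
    traces[counts == 0, :] = np.nan
    return traces


# -- trace-level event calling --------------------------------------------

def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise sd of a trace (1.4826 x median absolute deviation)."""
    x = np.asarray(trace, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _quadratic_peak(seg: np.ndarray, i: int) -> float:
    """Sub-frame peak estimate: parabola through the top three samples.

    At finite frame rates the sampled maximum of a rise/decay waveform
    systematically underestimates the instantaneous peak; a clamped
    quadratic interpolation recovers most of the loss.
    """
    if i <= 0 or i >= len(seg) - 1:
        return float(seg[i])
    if seg[i - 1] >= seg[i] or seg[i + 1] >= seg[i]:
        return float(seg[i])  # flat top (plateau): the sample is the peak
    denom = seg[i - 1] - 2.0 * seg[i] + seg[i + 1]
    if denom >= 0:
        return float(seg[i])
    delta = 0.5 * (seg[i - 1] - seg[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = seg[i] - 0.25 * (seg[i - 1] - seg[i + 1]) * delta
    return float(min(value, 1.2 * seg[i]))


def detect_steps(
    segment: np.ndarray, step_amp: float, min_frames: int = 2
) -> list[tuple[int, int, int]]:
    """Quantal level transitions within an event segment.

    Frames are rounded to the nearest multiple of ``step_amp``; runs
    shorter than ``min_frames`` are absorbed into the preceding level
    (they are noise, not gating).  Returns ``(frame_index, from_level,
    to_level)`` tuples, index relative to the segment.
    """
    if step_amp <= 0:
        raise ValueError("step amplitude must be positive")
    levels = np.rint(np.clip(np.asarray(segment, float), 0, None) / step_amp).astype(int)
    # run-length encode, absorbing short runs
    runs: list[list[int]] = []  # [level, start, length]
    for i, lev in enumerate(levels):
        if runs and runs[-1][0] == lev:
            runs[-1][2] += 1
        else:
            runs.append([int(lev), i, 1])
    merged: list[list[int]] = []
    for lev, start, length in runs:
        if length < min_frames and merged:
            merged[-1][2] += length
        else:
            merged.append([lev, start, length])
    # adjacent equal levels may appear after absorption; fuse them
    fused: list[list[int]] = []
    for lev, start, length in merged:
        if fused and fused[-1][0] == lev:
            fused[-1][2] += length
        else:
            fused.append([lev, start, length])
    return [
        (fused[k][1], fused[k - 1][0], fused[k][0]) for k in range(1, len(fused))
    ]


def detect_events(
    trace: RoiTrace,
    noise_sd: float | None = None,
    threshold_k: float | None = None,
    threshold_dff: float | None = None,
    min_duration_frames: int = 2,
    end_debounce_frames: int = 2,
    step_amp: float | None = None,
) -> list[CandidateEvent]:
    """Call contiguous supra-threshold excursions of a dF/F0 trace.

    The threshold is ``threshold_dff`` if given, else ``threshold_k *
    noise_sd`` (noise estimated robustly from the trace when not
    supplied), else an absolute default of 0.55 dF/F0 -- half the unitary
    sparklet amplitude.  An event ends at the first frame below threshold
    sustained for ``end_debounce_frames``; single-frame spikes are
    rejected.  Segments are extended outward to the local baseline so that
    kinetic half-times can be measured from the true event onset.
    """
    y = np.asarray(trace.dff, dtype=float)
    t = np.asarray(trace.timestamps, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("trace timestamps must be strictly increasing")
    if np.any(~np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(y)
    elif noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if threshold_dff is None:
        threshold_dff = 0.55 if threshold_k is None else threshold_k * noise_sd
    above = y >= threshold_dff

    # supra-threshold runs, merging gaps shorter than the debounce window
    runs: list[tuple[int, int]] = []
    i = 0
    n = y.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n:
                if above[j + 1]:
                    j += 1
                    continue
                gap_end = j + 1
                while gap_end < n and not above[gap_end]:
                    gap_end += 1
                if gap_end < n and (gap_end - (j + 1)) < end_debounce_frames:
                    j = gap_end
                else:
                    break
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    onset_floor = max(noise_sd, 0.02 * threshold_dff)
    events: list[CandidateEvent] = []
    prev_end = -1
    for r, (i0, i1) in enumerate(runs):
        if i1 - i0 + 1 < min_duration_frames:
            continue
        next_start = runs[r + 1][0] if r + 1 < len(runs) else n
        peak_idx = i0 + int(np.argmax(y[i0 : i1 + 1]))
        # extend to the local baseline on both sides, never crossing into
        # a neighbouring event's run
        s = i0
        while s - 1 > prev_end and y[s - 1] > onset_floor:
            s -= 1
        # include a short sub-onset lead/tail so onset back-extrapolation
        # and half-crossing interpolation have samples to work with
        s = min(max(prev_end + 1, s - 2), i0)
        e = i1
        while e + 1 < next_start and y[e + 1] > onset_floor:
            e += 1
        e = min(next_start - 1, e + 2, n - 1)
        seg = y[s : e + 1].copy()
        ev = CandidateEvent(
            start_frame=s,
            peak_frame=peak_idx,
            end_frame=e,
            times=t[s : e + 1].copy(),
            segment=seg,
            amplitude=_quadratic_peak(y, peak_idx),
            threshold=threshold_dff,
            core_start=i0,
            core_end=i1,
            roi=trace.roi,
            truncated=(peak_idx == 0),
        )
        if step_amp is not None:
            ev.steps = detect_steps(seg, step_amp)
        events.append(ev)
        prev_end = e
    return events


# -- spatial refinement ----------------------------------------------------

def _gauss2d(coords, amp, cy, cx, sigma):
    yy, xx = coords
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))


def _refine_event(
    dff: DffStack, event: CandidateEvent, window_px: int, sigma_guess_px: float
) -> CandidateEvent | None:
    """Fit a 2-D Gaussian at the peak frame and project it through time.

    Returns the event with sub-pixel position, footprint sd, and a
    template-projected amplitude segment on the true dF/F0 scale, or
    ``None`` when no coherent spatial peak exists in the window.
    """
    ny, nx = dff.data.shape[1:]
    cy0, cx0 = event.roi.center_px
    half = window_px
    y0 = int(np.clip(round(cy0) - half, 0, ny - 1))
    y1 = int(np.clip(round(cy0) + half + 1, 1, ny))
    x0 = int(np.clip(round(cx0) - half, 0, nx - 1))
    x1 = int(np.clip(round(cx0) + half + 1, 1, nx))
    frame = dff.data[event.peak_frame, y0:y1, x0:x1].astype(np.float64)
    smoothed = gaussian_filter(frame, sigma=1.5)
    py, px = np.unravel_index(int(np.argmax(smoothed)), smoothed.shape)
    peak_val = float(frame[py, px])
    if peak_val <= 0:
        return None
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    p0 = (peak_val, float(py), float(px), sigma_guess_px)
    bounds = (
        [0.0, -2.0, -2.0, 0.8],
        [50.0, frame.shape[0] + 2.0, frame.shape[1] + 2.0, 6.0 * sigma_guess_px],
    )
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (yy.ravel(), xx.ravel()),
            frame.ravel(),
            p0=p0,
            bounds=bounds,
            maxfev=2000,
        )
        amp_fit, cy, cx, sigma = map(float, popt)
    except (RuntimeError, ValueError):
        amp_fit, cy, cx, sigma = peak_val, float(py), float(px), sigma_guess_px
    template = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
    norm = float((template**2).sum())
    if norm <= 0:
        return None
    block = dff.data[event.start_frame : event.end_frame + 1, y0:y1, x0:x1]
    projected = (block.astype(np.float64) * template).sum(axis=(1, 2)) / norm
    peak_rel = int(np.argmax(projected))
    event.segment = projected
    event.peak_frame = event.start_frame + peak_rel
    event.amplitude = _quadratic_peak(projected, peak_rel)
    event.y_um = (y0 + cy) * dff.pixel_um
    event.x_um = (x0 + cx) * dff.pixel_um
    event.sigma_px = sigma
    return event


# -- duplicate merging and site clustering ---------------------------------

def _time_overlap(a: CandidateEvent, b: CandidateEvent) -> bool:
    return a.start_frame <= b.end_frame and b.start_frame <= a.end_frame


def localize_sites(
    events: list[CandidateEvent], merge_radius_um: float = 4.0
) -> tuple[list[CandidateEvent], list[SparkletSite]]:
    """Collapse duplicate detections and cluster events into sites.

    Events whose positions lie within ``merge_radius_um`` *and* whose
    frame spans overlap are the same physical event seen from overlapping
    ROIs; the highest-amplitude copy is kept.  Surviving events are then
    single-linkage clustered by position into sites.
    """
    if merge_radius_um <= 0:
        raise ValueError("merge radius must be positive")
    order = sorted(events, key=lambda e: -e.amplitude)
    kept: list[CandidateEvent] = []
    for ev in order:
        dup = any(
            _time_overlap(ev, k)
            and (ev.x_um - k.x_um) ** 2 + (ev.y_um - k.y_um) ** 2 <= merge_radius_um**2
            for k in kept
        )
        if not dup:
            kept.append(ev)
    kept.sort(key=lambda e: e.start_frame)

    # single-linkage clustering by position (union-find)
    parent = list(range(len(kept)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            dx = kept[i].x_um - kept[j].x_um
            dy = kept[i].y_um - kept[j].y_um
            if dx * dx + dy * dy <= merge_radius_um**2:
                parent[find(i)] = find(j)
    clusters: dict[int, list[CandidateEvent]] = {}
    for i, ev in enumerate(kept):
        clusters.setdefault(find(i), []).append(ev)
    sites = [
        SparkletSite(
            site_id=k,
            x_um=float(np.mean([e.x_um for e in evs])),
            y_um=float(np.mean([e.y_um for e in evs])),
            events=evs,
        )
        for k, evs in enumerate(clusters.values())
    ]
    return kept, sites


@dataclass
class DetectionResult:
    """Everything the downstream quantal analysis needs from one movie."""

    events: list[CandidateEvent]
    sites: list[SparkletSite]
    baseline: BaselineImage
    dff: DffStack
    rois: list[Roi]
    params: dict


def detect_movie(
    movie: MovieStack,
    *,
    baseline_frames: int = 10,
    roi_um: float = ROI_SIDE_UM,
    overlap: float = 0.5,
    unitary_dff: float = 1.10,
    amp_threshold_dff: float | None = None,
    candidate_k: float = 5.0,
    candidate_floor_dff: float = 0.02,
    merge_radius_um: float = 4.0,
    halfmax_area_um2: float = 17.2,
    min_duration_frames: int = 2,
    end_debounce_frames: int = 2,
) -> DetectionResult:
    """Run the full detection stage on one movie.

    ``amp_threshold_dff`` (default half the unitary amplitude) is applied
    to the refined, template-projected amplitude of each candidate.
    """
    if amp_threshold_dff is None:
        amp_threshold_dff = 0.5 * unitary_dff
    baseline = compute_baseline(movie, n=baseline_frames)
    dff = compute_dff(movie, baseline)
    rois = tile_rois(movie.frame_shape, movie.pixel_um, roi_um=roi_um, overlap=overlap)
    traces = _all_roi_traces(dff, rois)

    from .simulate import halfmax_sigma_um  # local import avoids a cycle

    sigma_guess_px = halfmax_sigma_um(halfmax_area_um2) / movie.pixel_um
    window_px = max(rois[0].side_px, int(math.ceil(3.0 * sigma_guess_px)))

    candidates: list[CandidateEvent] = []
    for roi, y in zip(rois, traces):
        if np.any(~np.isfinite(y)):
            continue  # fully invalid ROI
        noise = estimate_noise_sd(y)
        thr = max(candidate_k * noise, candidate_floor_dff)
        trace = RoiTrace(roi=roi, dff=y, timestamps=dff.timestamps)
        candidates.extend(
            detect_events(
                trace,
                noise_sd=max(noise, 1e-9),
                threshold_dff=thr,
                min_duration_frames=min_duration_frames,
                end_debounce_frames=end_debounce_frames,
            )
        )

    refined: list[CandidateEvent] = []
    for ev in candidates:
        out = _refine_event(dff, ev, window_px=window_px, sigma_guess_px=sigma_guess_px)
        if out is None or out.amplitude < amp_threshold_dff:
            continue
        # a much-broader-than-expected footprint at sub-unitary amplitude
        # is the superposition of tails from simultaneously active
        # neighbouring sites, not a channel opening of its own
        if out.sigma_px > 2.5 * sigma_guess_px and out.amplitude < 0.8 * unitary_dff:
            continue
        out.steps = detect_steps(out.segment, unitary_dff)
        refined.append(out)

    events, sites = localize_sites(refined, merge_radius_um=merge_radius_um)
    params = {
        "baseline_frames": baseline_frames,
        "roi_um": roi_um,
        "overlap": overlap,
        "unitary_dff": unitary_dff,
        "amp_threshold_dff": amp_threshold_dff,
        "candidate_k": candidate_k,
        "candidate_floor_dff": candidate_floor_dff,
        "merge_radius_um": merge_radius_um,
    }
    return DetectionResult(
        events=events, sites=sites, baseline=baseline, dff=dff, rois=rois, params=params
    )
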