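"""Synthetic en face GCaMP6f movie generator with channel-gating ground truth.

The generator emulates wide-field recordings of the cerebral-artery
endothelium expressing a genetically encoded Ca2+ biosensor: a mosaic of
endothelial cells (mean area ~462 um^2) forms the baseline image, discrete
sparklet sites gate stochastically as homogeneous Poisson processes, and
every channel opening renders as a separable spatio-temporal profile

    dF/F0(x, y, t) = level * unitary_dff * amp(t) * G(x, y)

with a linear rise and exponential decay parameterised by half-times, and
an isotropic Gaussian footprint whose half-max contour encloses a
configured area.  Because fluorescence is proportional to local sensor
expression, the signal multiplies the baseline: F = F0 * (1 + dF/F0).

Every stochastic choice derives from ``SimConfig.seed`` through fixed
:class:`numpy.random.SeedSequence` spawn keys (gating, mosaic, noise), so a
fixed config yields byte-identical movies while the three stages stay
statistically independent.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .movie import MovieStack

__all__ = [
    "SimConfig",
    "TruthSite",
    "ChannelOpening",
    "GroundTruth",
    "simulate_gating",
    "render_movie",
    "make_baseline",
    "simulate_movie",
    "write_truth",
    "read_truth",
    "halfmax_sigma_um",
]

# SeedSequence spawn keys: one independent stream per stochastic stage.
_STREAM_GATING = 0
_STREAM_MOSAIC = 1
_STREAM_NOISE = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def halfmax_sigma_um(halfmax_area_um2: float) -> float:
    """Gaussian sd whose half-max contour encloses the given area.

    The half-max contour of ``exp(-r^2 / 2 sigma^2)`` is the circle of
    radius ``sigma * sqrt(2 ln 2)``, so area = 2 pi ln2 sigma^2.
    """
    return math.sqrt(halfmax_area_um2 / (2.0 * math.pi * math.log(2.0)))


@dataclass
class SimConfig:
    """Study conditions for one simulated recording.

    Defaults reproduce the stimulated (4-HNE-like) condition of the en
    face preparation: 512x512 px at 0.27 um/px, 40 frames/s for 1000
    frames, unitary amplitude 1.10 dF/F0 with attack/decay half-times of
    87/84 ms and a 17.2 um^2 half-max footprint, sites firing at 0.13 Hz
    with ~0.108 active sites per 462-um^2 cell.  Intensity units are
    EMCCD-scale counts; the noise statistics are stated here as config
    values (baseline 1000 counts, read noise 50 counts = 0.05 dF/F0,
    shot noise approximated as Gaussian with variance = shot_gain * F).
    """

    fov_px: int = 512
    pixel_um: float = 0.27
    frame_rate_hz: float = 40.0
    n_frames: int = 1000
    mean_cell_area_um2: float = 462.0
    n_sites: int | None = None          # default: derived from sites_per_cell
    sites_per_cell: float = 0.108
    site_rate_hz: float = 0.13
    unitary_dff: float = 1.10
    max_channels_per_site: int = 3
    extra_channel_prob: float = 0.15    # P(level k+1)/P(level k), truncated
    attack_half_ms: float = 87.0
    decay_half_ms: float = 84.0
    plateau_mean_ms: float = 0.0        # exponential full-open dwell past the rise
    halfmax_area_um2: float = 17.2
    baseline_mean: float = 1000.0
    cell_brightness_cv: float = 0.15
    read_noise_sd: float = 50.0
    shot_noise: bool = True
    shot_gain: float = 1.0
    quiescent_frames: int = 10          # pre-stimulation window used for F0
    site_margin_um: float = 5.0
    min_site_separation_um: float = 8.0
    transient_mode: bool = False
    transient_sites_per_cell: float = 0.26
    transient_rate_hz: float = 0.12
    transient_halfmax_area_um2: float = 60.0
    transient_attack_half_ms: float = 200.0
    transient_decay_half_ms: float = 600.0
    seed: int = 0
    condition: str = "simulated"
    extra_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = [
            ("fov_px", self.fov_px), ("pixel_um", self.pixel_um),
            ("frame_rate_hz", self.frame_rate_hz),
            ("mean_cell_area_um2", self.mean_cell_area_um2),
            ("unitary_dff", self.unitary_dff),
            ("max_channels_per_site", self.max_channels_per_site),
            ("attack_half_ms", self.attack_half_ms),
            ("decay_half_ms", self.decay_half_ms),
            ("halfmax_area_um2", self.halfmax_area_um2),
            ("baseline_mean", self.baseline_mean),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        nonneg = [
            ("n_frames", self.n_frames), ("site_rate_hz", self.site_rate_hz),
            ("sites_per_cell", self.sites_per_cell),
            ("plateau_mean_ms", self.plateau_mean_ms),
            ("read_noise_sd", self.read_noise_sd),
            ("cell_brightness_cv", self.cell_brightness_cv),
            ("quiescent_frames", self.quiescent_frames),
            ("transient_rate_hz", self.transient_rate_hz),
        ]
        for name, value in nonneg:
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.n_sites is not None and self.n_sites < 0:
            raise ValueError(f"n_sites must be non-negative, got {self.n_sites}")
        if not 0 <= self.extra_channel_prob < 1:
            raise ValueError("extra_channel_prob must be in [0, 1)")

    # -- derived quantities ----------------------------------------------
    @property
    def fov_um(self) -> float:
        return self.fov_px * self.pixel_um

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def n_cells(self) -> float:
        """Expected number of cells in the field of view."""
        return self.fov_um**2 / self.mean_cell_area_um2

    def resolved_n_sites(self, kind: str = "sparklet") -> int:
        if kind == "sparklet":
            if self.n_sites is not None:
                return self.n_sites
            return max(1, round(self.sites_per_cell * self.n_cells))
        return max(1, round(self.transient_sites_per_cell * self.n_cells))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TruthSite:
    """A sparklet site: position in micrometres and its channel complement."""

    x_um: float
    y_um: float
    n_channels: int
    event_class: str = "sparklet"


@dataclass
class ChannelOpening:
    """One gating episode at a site.

    ``t_open``..``t_close`` is the channel-open interval (rise plus any
    full-open dwell); fluorescence decays back to baseline after
    ``t_close``.  ``level`` is the number of simultaneously open channels
    represented by this opening.
    """

    site: int
    t_open: float
    t_close: float
    level: int

    def __post_init__(self) -> None:
        if not self.t_open < self.t_close:
            raise ValueError("opening must have t_open < t_close")
        if self.level < 1:
            raise ValueError("opening level must be >= 1")


@dataclass
class GroundTruth:
    """Simulator sidecar: true sites, gating intervals and render params."""

    sites: list[TruthSite]
    openings: list[ChannelOpening]
    config: SimConfig

    def openings_at(self, site: int) -> list[ChannelOpening]:
        return [o for o in self.openings if o.site == site]


def _place_sites(
    rng: np.random.Generator, config: SimConfig, n: int, existing: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Uniform site positions with a margin and a minimum pair separation."""
    lo = config.site_margin_um
    hi = config.fov_um - config.site_margin_um
    if hi <= lo:
        raise ValueError(
            f"field of view {config.fov_um:.1f} um too small for site margin "
            f"{config.site_margin_um} um"
        )
    placed = list(existing)
    out: list[tuple[float, float]] = []
    for _ in range(n):
        for _attempt in range(10000):
            x, y = rng.uniform(lo, hi, size=2)
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= config.min_site_separation_um**2
                for px, py in placed
            ):
                placed.append((x, y))
                out.append((float(x), float(y)))
                break
        else:
            raise ValueError(
                f"could not place {n} sites {config.min_site_separation_um} um apart "
                f"in a {config.fov_um:.0f} um field"
            )
    return out


def _draw_levels(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Opening levels: truncated geometric, P(level k+1) = p * P(level k)."""
    if config.max_channels_per_site == 1 or config.extra_channel_prob == 0:
        return np.ones(n, dtype=int)
    extra = rng.geometric(1.0 - config.extra_channel_prob, size=n) - 1
    return 1 + np.minimum(extra, config.max_channels_per_site - 1)


def simulate_gating(config: SimConfig) -> GroundTruth:
    """Draw stochastic channel gating for every site.

    Opening start times follow a homogeneous Poisson process at
    ``site_rate_hz`` per site over the post-baseline window; open dwell is
    the deterministic rise (2 x attack half-time) plus an exponential
    plateau with mean ``plateau_mean_ms``.  Sites are quiescent during the
    first ``quiescent_frames`` frames, mirroring the pre-stimulation
    period used to define baseline fluorescence.
    """
    rng = _rng(config.seed, _STREAM_GATING)
    t_total = config.duration_s
    t_start = min(config.quiescent_frames / config.frame_rate_hz, t_total)
    if config.n_frames == 0 or t_total <= t_start:
        warnings.warn("zero-duration recording window: empty ground truth", stacklevel=2)
        return GroundTruth(sites=[], openings=[], config=config)

    sites: list[TruthSite] = []
    openings: list[ChannelOpening] = []

    classes: list[tuple[str, int, float, float, float]] = [
        (
            "sparklet",
            config.resolved_n_sites("sparklet"),
            config.site_rate_hz,
            config.attack_half_ms,
            config.plateau_mean_ms,
        )
    ]
    if config.transient_mode:
        classes.append(
            (
                "transient",
                config.resolved_n_sites("transient"),
                config.transient_rate_hz,
                config.transient_attack_half_ms,
                config.plateau_mean_ms,
            )
        )

    positions: list[tuple[float, float]] = []
    for event_class, n_sites, rate, attack_ms, plateau_ms in classes:
        coords = _place_sites(rng, config, n_sites, positions)
        positions.extend(coords)
        rise_s = 2.0 * attack_ms / 1000.0
        window = t_total - t_start
        for x, y in coords:
            site_id = len(sites)
            sites.append(
                TruthSite(
                    x_um=x, y_um=y,
                    n_channels=config.max_channels_per_site,
                    event_class=event_class,
                )
            )
            n_open = rng.poisson(rate * window)
            t_opens = np.sort(rng.uniform(t_start, t_total, size=n_open))
            levels = _draw_levels(rng, n_open, config)
            if config.plateau_mean_ms > 0:
                plateaus = rng.exponential(plateau_ms / 1000.0, size=n_open)
            else:
                plateaus = np.zeros(n_open)
            for t0, level, plateau in zip(t_opens, levels, plateaus):
                openings.append(
                    ChannelOpening(
                        site=site_id,
                        t_open=float(t0),
                        t_close=float(t0 + rise_s + plateau),
                        level=int(level),
                    )
                )
    return GroundTruth(sites=sites, openings=openings, config=config)


def make_baseline(config: SimConfig) -> np.ndarray:
    """Baseline cell-mosaic image (float counts, shape (fov_px, fov_px)).

    A seeded nearest-neighbour (Voronoi) tessellation with the configured
    mean cell area; per-cell brightness is lognormal around
    ``baseline_mean`` and cell borders are softened by a 1-px Gaussian
    blur to mimic optical blur.
    """
    rng = _rng(config.seed, _STREAM_MOSAIC)
    n = config.fov_px
    n_cells = max(1, round(config.n_cells))
    centers = rng.uniform(0, n, size=(n_cells, 2))
    yy, xx = np.mgrid[0:n, 0:n]
    pix = np.column_stack([yy.ravel(), xx.ravel()]) + 0.5
    _, label = cKDTree(centers).query(pix)
    if config.cell_brightness_cv > 0:
        s2 = math.log1p(config.cell_brightness_cv**2)
        brightness = rng.lognormal(
            mean=math.log(config.baseline_mean) - s2 / 2.0, sigma=math.sqrt(s2), size=n_cells
        )
    else:
        brightness = np.full(n_cells, config.baseline_mean)
    f0 = brightness[label].reshape(n, n)
    return gaussian_filter(f0, sigma=1.0)


def _opening_params(config: SimConfig, event_class: str) -> tuple[float, float, float]:
    """(rise_s, decay_half_s, sigma_px) for one event class."""
    if event_class == "transient":
        attack, decay, area = (
            config.transient_attack_half_ms,
            config.transient_decay_half_ms,
            config.transient_halfmax_area_um2,
        )
    else:
        attack, decay, area = (
            config.attack_half_ms, config.decay_half_ms, config.halfmax_area_um2
        )
    sigma_px = halfmax_sigma_um(area) / config.pixel_um
    return 2.0 * attack / 1000.0, decay / 1000.0, sigma_px


def _amplitude_profile(
    t: np.ndarray, t_open: float, t_close: float, rise_s: float, decay_half_s: float
) -> np.ndarray:
    """Normalized temporal envelope: linear rise, full-open hold, exp decay."""
    amp = np.zeros_like(t)
    rise_end = t_open + rise_s
    rising = (t >= t_open) & (t < rise_end)
    amp[rising] = (t[rising] - t_open) / rise_s
    hold = (t >= rise_end) & (t <= t_close)
    amp[hold] = 1.0
    falling = t > t_close
    amp[falling] = np.exp2(-(t[falling] - t_close) / decay_half_s)
    return amp


def render_movie(truth: GroundTruth, config: SimConfig) -> MovieStack:
    """Render a ground truth into a noisy 16-bit fluorescence movie.

    Each opening contributes ``level * unitary_dff * amp(t) * G(x, y)`` to
    the dF/F0 field; overlapping openings at one site sum, which is what
    makes multi-channel amplitude levels appear in the traces.
    """
    n = config.fov_px
    fov_um = config.fov_um
    for s in truth.sites:
        if not (0 <= s.x_um < fov_um and 0 <= s.y_um < fov_um):
            raise ValueError(
                f"site at ({s.x_um:.1f}, {s.y_um:.1f}) um lies outside the "
                f"{fov_um:.1f} um field of view"
            )

    f0 = make_baseline(config)
    timestamps = np.arange(config.n_frames) / config.frame_rate_hz

    # Pre-compute, per opening: the spatial patch, its pixel window, and
    # the temporal envelope over the frames it spans.  Rendering then adds
    # small patches frame by frame, keeping memory independent of FOV.
    patches = []
    amp_floor = 1e-3
    for op in truth.openings:
        site = truth.sites[op.site]
        rise_s, decay_half_s, sigma_px = _opening_params(config, site.event_class)
        peak = op.level * config.unitary_dff
        t_tail = op.t_close + decay_half_s * math.log2(max(peak, amp_floor) / amp_floor)
        i0 = max(0, int(math.floor(op.t_open * config.frame_rate_hz)))
        i1 = min(config.n_frames, int(math.ceil(t_tail * config.frame_rate_hz)) + 1)
        if i1 <= i0:
            continue
        env = peak * _amplitude_profile(
            timestamps[i0:i1], op.t_open, op.t_close, rise_s, decay_half_s
        )
        cx = site.x_um / config.pixel_um
        cy = site.y_um / config.pixel_um
        half = int(math.ceil(4.0 * sigma_px))
        x0, x1 = max(0, int(cx) - half), min(n, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(n, int(cy) + half + 1)
        ys = np.arange(y0, y1) + 0.5
        xs = np.arange(x0, x1) + 0.5
        g = np.exp(
            -((ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2) / (2.0 * sigma_px**2)
        )
        patches.append((i0, i1, y0, y1, x0, x1, g.astype(np.float32), env.astype(np.float32)))

    rng = _rng(config.seed, _STREAM_NOISE)
    out = np.empty((config.n_frames, n, n), dtype=np.uint16)
    max_count = float(np.iinfo(np.uint16).max)
    for i in range(config.n_frames):
        frame = f0.copy()
        for i0, i1, y0, y1, x0, x1, g, env in patches:
            if i0 <= i < i1 and env[i - i0] > 0:
                frame[y0:y1, x0:x1] += f0[y0:y1, x0:x1] * (g * env[i - i0])
        if config.shot_noise:
            frame = frame + rng.standard_normal(frame.shape) * np.sqrt(
                config.shot_gain * np.clip(frame, 0.0, None)
            )
        if config.read_noise_sd > 0:
            frame = frame + rng.standard_normal(frame.shape) * config.read_noise_sd
        out[i] = np.clip(np.rint(frame), 0.0, max_count).astype(np.uint16)

    metadata = {
        "condition": config.condition,
        "frame_rate_hz": config.frame_rate_hz,
        "seed": config.seed,
        **config.extra_metadata,
    }
    return MovieStack(
        frames=out, pixel_um=config.pixel_um, timestamps=timestamps, metadata=metadata
    )


def simulate_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Convenience: gate then render, returning the movie and its truth."""
    truth = simulate_gating(config)
    return render_movie(truth, config), truth


# -- ground-truth serialization -------------------------------------------

def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "sites": [asdict(s) for s in truth.sites],
        "openings": [asdict(o) for o in truth.openings],
        "config": truth.config.to_dict(),
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
        return GroundTruth(
            sites=[TruthSite(**s) for s in doc["sites"]],
            openings=[ChannelOpening(**o) for o in doc["openings"]],
            config=SimConfig.from_dict(doc["config"]),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"malformed ground-truth file {path}: {exc}") from exc
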