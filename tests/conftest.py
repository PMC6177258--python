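"""Shared fixtures: tiny configs and noiseless rendering helpers."""

import numpy as np
import pytest

from sparklet.simulate import ChannelOpening, GroundTruth, SimConfig, TruthSite


def noiseless_config(**overrides) -> SimConfig:
    """A small, flat-baseline, noise-free configuration for exact checks."""
    defaults = dict(
        fov_px=96,
        n_frames=200,
        frame_rate_hz=40.0,
        shot_noise=False,
        read_noise_sd=0.0,
        cell_brightness_cv=0.0,
        n_sites=1,
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def manual_truth(config: SimConfig, openings, sites=None) -> GroundTruth:
    """Ground truth with hand-placed sites/openings for targeted renders.

    ``openings`` is a list of (site, t_open, level) or (site, t_open,
    t_close, level) tuples; the default close time ends the rise exactly
    at the configured attack half-time.
    """
    if sites is None:
        c = config.fov_um / 2.0
        sites = [TruthSite(x_um=c, y_um=c, n_channels=config.max_channels_per_site)]
    ops = []
    rise = 2.0 * config.attack_half_ms / 1000.0
    for item in openings:
        if len(item) == 3:
            site, t0, level = item
            ops.append(ChannelOpening(site=site, t_open=t0, t_close=t0 + rise, level=level))
        else:
            site, t0, t1, level = item
            ops.append(ChannelOpening(site=site, t_open=t0, t_close=t1, level=level))
    return GroundTruth(sites=sites, openings=ops, config=config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
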