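"""Gating statistics, rendering geometry and ground-truth serialization."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from sparklet.simulate import (
    ChannelOpening,
    SimConfig,
    TruthSite,
    halfmax_sigma_um,
    make_baseline,
    read_truth,
    render_movie,
    simulate_gating,
    simulate_movie,
    write_truth,
)

from conftest import manual_truth, noiseless_config


class TestGating:
    def test_zero_rate_yields_no_openings(self):
        truth = simulate_gating(noiseless_config(site_rate_hz=0.0, n_sites=3))
        assert truth.openings == []
        assert len(truth.sites) == 3

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(site_rate_hz=-0.1)

    def test_zero_duration_recording_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            truth = simulate_gating(noiseless_config(n_frames=0))
        assert truth.openings == [] and truth.sites == []

    def test_opening_counts_match_poisson_mean(self):
        """One site at 0.1 Hz for 1000 s: the mean count over 200 seeds
        must fall inside the exact Poisson 95% interval around 100."""
        lam, t_s = 0.1, 1000.0
        n_seeds = 200
        counts = []
        for seed in range(n_seeds):
            cfg = noiseless_config(
                n_frames=int(t_s * 40), site_rate_hz=lam, seed=seed,
                quiescent_frames=0,
            )
            counts.append(len(simulate_gating(cfg).openings))
        total = sum(counts)
        lo, hi = sps.poisson.interval(0.95, n_seeds * lam * t_s)
        assert lo <= total <= hi

    def test_counts_follow_poisson_distribution(self):
        """Chi-square goodness of fit of per-seed counts vs Poisson(lam*T)."""
        lam, t_s, n_seeds = 0.2, 100.0, 300
        counts = np.array([
            len(simulate_gating(noiseless_config(
                n_frames=int(t_s * 40), site_rate_hz=lam, seed=s, quiescent_frames=0,
            )).openings)
            for s in range(n_seeds)
        ])
        mu = lam * t_s
        kmax = int(sps.poisson.ppf(0.999, mu))
        observed = np.bincount(np.clip(counts, 0, kmax), minlength=kmax + 1)
        expected = sps.poisson.pmf(np.arange(kmax + 1), mu) * n_seeds
        expected[-1] += (1 - sps.poisson.cdf(kmax, mu)) * n_seeds
        # pool bins with small expectation
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        p = sps.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
        assert p > 0.01

    def test_same_seed_reproduces_ground_truth(self):
        cfg = noiseless_config(site_rate_hz=0.5, n_sites=4, seed=11)
        t1 = simulate_gating(cfg)
        t2 = simulate_gating(cfg)
        assert [vars(o) for o in t1.openings] == [vars(o) for o in t2.openings]
        assert [vars(s) for s in t1.sites] == [vars(s) for s in t2.sites]

    def test_openings_respect_invariants(self):
        cfg = noiseless_config(site_rate_hz=1.0, n_sites=3, seed=5, plateau_mean_ms=30)
        truth = simulate_gating(cfg)
        assert truth.openings
        for op in truth.openings:
            assert op.t_open < op.t_close
            assert 1 <= op.level <= cfg.max_channels_per_site
            assert 0 <= op.site < len(truth.sites)

    def test_sites_respect_margin_and_separation(self):
        cfg = noiseless_config(n_sites=5, fov_px=192, seed=3)
        truth = simulate_gating(cfg)
        pos = [(s.x_um, s.y_um) for s in truth.sites]
        for x, y in pos:
            assert cfg.site_margin_um <= x <= cfg.fov_um - cfg.site_margin_um
            assert cfg.site_margin_um <= y <= cfg.fov_um - cfg.site_margin_um
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = math.dist(pos[i], pos[j])
                assert d >= cfg.min_site_separation_um


class TestRendering:
    def test_no_openings_and_no_noise_gives_constant_baseline(self):
        cfg = noiseless_config()
        truth = manual_truth(cfg, openings=[])
        movie = render_movie(truth, cfg)
        assert np.all(movie.frames == movie.frames[0])
        expected = np.clip(np.rint(make_baseline(cfg)), 0, 65535).astype(np.uint16)
        assert np.array_equal(movie.frames[0], expected)

    def test_center_pixel_peak_amplitude_is_unitary(self):
        """A level-1 opening with unitary 1.1 peaks at dF/F0 = 1.1 at the
        site centre, up to rendering quantization."""
        cfg = noiseless_config(unitary_dff=1.1, baseline_mean=2000.0)
        truth = manual_truth(cfg, openings=[(0, 1.0, 1)])
        movie = render_movie(truth, cfg)
        f0 = movie.frames[:10].mean(axis=0)
        dff = movie.frames / f0 - 1.0
        # centre pixel, maximum over time; frames sample the rise/decay so
        # allow one-frame-interval kinetic loss plus quantization
        cpx = cfg.fov_px // 2
        peak = dff[:, cpx, cpx].max()
        assert peak == pytest.approx(1.1, rel=0.02)

    def test_rendering_is_linear_in_level(self):
        cfg = noiseless_config()
        t_open = 10 / cfg.frame_rate_hz + 0.5  # aligned rise for exact peak frames
        m1 = render_movie(manual_truth(cfg, openings=[(0, t_open, 1)]), cfg)
        m2 = render_movie(manual_truth(cfg, openings=[(0, t_open, 2)]), cfg)
        f0 = make_baseline(cfg)
        d1 = (m1.frames.astype(float) - f0) / f0
        d2 = (m2.frames.astype(float) - f0) / f0
        assert d2.max() == pytest.approx(2 * d1.max(), rel=0.01)

    def test_halfmax_footprint_area_matches_closed_form(self):
        """The half-max contour of an isotropic Gaussian of sd sigma
        encloses 2 pi ln2 sigma^2; measured pixel count agrees within one
        pixel ring at the boundary."""
        for sigma_px in (2.0, 4.0, 8.0):
            cfg = noiseless_config(
                fov_px=128,
                halfmax_area_um2=2 * math.pi * math.log(2) * (sigma_px * 0.27) ** 2,
                baseline_mean=5000.0,
            )
            # close at a frame instant so one frame samples the full peak
            t_open = 0.5
            t_close = t_open + 2 * cfg.attack_half_ms / 1000.0
            truth = manual_truth(cfg, openings=[(0, t_open, t_close, 1)])
            peak_frame = int(round(t_close * cfg.frame_rate_hz))
            movie = render_movie(truth, cfg)
            f0 = make_baseline(cfg)
            dff = (movie.frames[peak_frame] - f0) / f0
            area_px = np.count_nonzero(dff >= 0.5 * dff.max())
            expected = 2 * math.pi * math.log(2) * sigma_px**2
            radius = sigma_px * math.sqrt(2 * math.log(2))
            ring = 2 * math.pi * radius  # one-pixel boundary ring
            assert abs(area_px - expected) <= ring

    def test_site_outside_fov_rejected(self):
        cfg = noiseless_config()
        bad = manual_truth(
            cfg, openings=[(0, 1.0, 1)],
            sites=[TruthSite(x_um=2 * cfg.fov_um, y_um=1.0, n_channels=1)],
        )
        with pytest.raises(ValueError, match="outside"):
            render_movie(bad, cfg)

    def test_same_seed_gives_identical_movie(self):
        cfg = SimConfig(fov_px=64, n_frames=80, n_sites=1, seed=9)
        m1, _ = simulate_movie(cfg)
        m2, _ = simulate_movie(cfg)
        assert np.array_equal(m1.frames, m2.frames)


class TestTruthSerialization:
    def test_empty_truth_round_trips(self, tmp_path):
        truth = simulate_gating(noiseless_config(site_rate_hz=0.0))
        p = write_truth(truth, tmp_path / "truth.json")
        back = read_truth(p)
        assert back.openings == [] and len(back.sites) == 1
        assert back.config == truth.config

    def test_many_openings_round_trip(self, tmp_path):
        cfg = noiseless_config(site_rate_hz=2.0, n_sites=3, seed=21)
        truth = simulate_gating(cfg)
        assert len(truth.openings) > 20
        back = read_truth(write_truth(truth, tmp_path / "t.json"))
        assert [vars(o) for o in back.openings] == [vars(o) for o in truth.openings]
        assert [vars(s) for s in back.sites] == [vars(s) for s in truth.sites]

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_truth(p)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("pixel_um", 0.0), ("unitary_dff", -1.0), ("frame_rate_hz", 0.0),
            ("halfmax_area_um2", -5.0), ("n_frames", -1), ("extra_channel_prob", 1.0),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_dict({"not_a_field": 1})
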