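"""Bearing-crossing localization geometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strikewatch import localization as loc


def bearings_to(track: loc.VesselTrack, xw, yw, rng=None, noise_deg=0.0,
                whale_id="w"):
    """Noise-free (or noisy) unsigned bearings from every track sample."""
    s = track.samples
    dx = xw - s["x_km"].to_numpy()
    dy = yw - s["y_km"].to_numpy()
    los = np.degrees(np.arctan2(dy, dx))
    rel = np.abs((los - s["heading_deg"].to_numpy() + 180.0) % 360.0 - 180.0)
    if noise_deg:
        rel = np.clip(rel + rng.normal(0, noise_deg, rel.size), 0.0, 180.0)
    return loc.BearingSeries(whale_id, pd.DataFrame(
        {"t_s": s["t_s"], "bearing_deg": rel}))


def straight_track(length_km=10.0, n=40):
    t = np.linspace(0.0, 3600.0, n)
    return loc.VesselTrack(pd.DataFrame({
        "t_s": t, "x_km": np.linspace(0, length_km, n), "y_km": 0.0,
        "heading_deg": 0.0}))


def curved_track(n=40):
    # gentle dog-leg so the port/starboard hypotheses are distinguishable
    t = np.linspace(0.0, 3600.0, n)
    x = np.linspace(0.0, 10.0, n)
    y = 0.3 * np.sin(x / 10.0 * np.pi)
    heading = np.degrees(np.arctan2(np.gradient(y), np.gradient(x)))
    return loc.VesselTrack(pd.DataFrame(
        {"t_s": t, "x_km": x, "y_km": y, "heading_deg": heading}))


class TestCrossBearings:
    def test_noiseless_whale_recovered_to_1m(self):
        track = straight_track()
        fx = loc.cross_bearings(track, bearings_to(track, 5.0, 2.0))
        assert np.hypot(fx.position[0] - 5.0, fx.position[1] - 2.0) < 1e-3
        assert abs(fx.perp_distance_km - 2.0) < 1e-3

    def test_mirror_whale_swaps_side(self):
        track = curved_track()
        fx_a = loc.cross_bearings(track, bearings_to(track, 5.0, 2.0))
        # reflect the whole geometry across y = 0
        s = track.samples.copy()
        s["y_km"] *= -1.0
        s["heading_deg"] *= -1.0
        mirror = loc.VesselTrack(s)
        fx_b = loc.cross_bearings(mirror, bearings_to(mirror, 5.0, -2.0))
        assert fx_a.chosen_side != fx_b.chosen_side
        assert abs(fx_a.perp_distance_km - fx_b.perp_distance_km) < 1e-3

    def test_correct_side_wins_on_curved_track(self):
        track = curved_track()
        fx = loc.cross_bearings(track, bearings_to(track, 5.0, 2.5))
        assert fx.chosen_side == "port"
        assert (fx.residual_port < fx.residual_starboard)

    def test_noisy_bearing_error_is_small(self):
        # whale 3 km abeam, ~20 bearings spanning a wide aperture, sd 2 deg
        errs = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            t = np.linspace(0, 3600, 20)
            x = np.linspace(2.0, 8.0, 20)
            track = loc.VesselTrack(pd.DataFrame(
                {"t_s": t, "x_km": x, "y_km": 0.0, "heading_deg": 0.0}))
            bs = bearings_to(track, 5.0, 3.0, rng=rng, noise_deg=2.0)
            if bs.samples["bearing_deg"].max() - bs.samples["bearing_deg"].min() < 15:
                continue
            fx = loc.cross_bearings(track, bs)
            errs.append(abs(fx.perp_distance_km - 3.0))
        assert np.median(errs) < 0.15

    def test_aperture_gate(self):
        track = straight_track()
        far = bearings_to(track, 200.0, 2.0)  # nearly constant bearing
        with pytest.raises(loc.NoFixError):
            loc.cross_bearings(track, far)

    def test_too_few_bearings(self):
        track = straight_track()
        bs = loc.BearingSeries("w", pd.DataFrame(
            {"t_s": [0.0], "bearing_deg": [45.0]}))
        with pytest.raises(loc.NoFixError):
            loc.cross_bearings(track, bs)

    def test_error_shrinks_with_aperture(self):
        # position error decreases as the bearing aperture grows (the
        # along-track component is poorly constrained by narrow fans)
        med_errs = []
        for span in (0.5, 2.0, 6.0):  # km of track either side of the beam
            errs = []
            for seed in range(100):
                rng = np.random.default_rng(1000 + seed)
                t = np.linspace(0, 3600, 15)
                x = np.linspace(5.0 - span, 5.0 + span, 15)
                track = loc.VesselTrack(pd.DataFrame(
                    {"t_s": t, "x_km": x, "y_km": 0.0, "heading_deg": 0.0}))
                bs = bearings_to(track, 5.0, 3.0, rng=rng, noise_deg=2.0)
                try:
                    fx = loc.cross_bearings(track, bs, min_aperture_deg=5.0)
                except loc.NoFixError:
                    continue
                errs.append(np.hypot(fx.position[0] - 5.0,
                                     abs(fx.position[1]) - 3.0))
            med_errs.append(np.median(errs))
        assert med_errs[0] > med_errs[1] > med_errs[2]


class TestPerpendicularDistance:
    def test_point_on_line(self):
        assert loc.perpendicular_distance((3.0, 0.0), ((0, 0), (10, 0))) == 0.0

    def test_offset_point(self):
        assert loc.perpendicular_distance((0.0, 3.0), ((0, 0), (10, 0))) == 3.0

    def test_against_dense_sampling_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(-10, 10, 2)
            a, b = rng.uniform(-10, 10, 2), rng.uniform(-10, 10, 2)
            if np.hypot(*(b - a)) < 0.1:
                continue
            d = loc.perpendicular_distance(tuple(p), (tuple(a), tuple(b)))
            # densely sample the infinite line far beyond the segment
            s = np.linspace(-100, 100, 2_000_001)[:, None]
            pts = a + s * (b - a) / np.hypot(*(b - a))
            brute = np.min(np.hypot(*(pts - p).T))
            assert abs(d - brute) < 1e-6

    def test_zero_length_segment(self):
        with pytest.raises(ValueError):
            loc.perpendicular_distance((1, 1), ((2, 2), (2, 2)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-5, 5),
           dy=st.floats(-5, 5))
    def test_rigid_transform_invariance(self, angle, dx, dy):
        p = np.array([1.3, -2.1])
        a, b = np.array([0.0, 0.0]), np.array([4.0, 1.0])
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        t = np.array([dx, dy])
        d0 = loc.perpendicular_distance(tuple(p), (tuple(a), tuple(b)))
        d1 = loc.perpendicular_distance(
            tuple(R @ p + t), (tuple(R @ a + t), tuple(R @ b + t)))
        assert abs(d0 - d1) < 1e-6


class TestSurfaceAssumptionBias:
    def test_zero_depth_zero_bias(self):
        assert loc.surface_assumption_bias(0.0, 4.0) == 0.0

    def test_closed_form_value(self):
        # depth 600 m, 4 km abeam: sqrt(16.36)/4 - 1
        want = np.sqrt(16.36) / 4.0 - 1.0
        assert abs(loc.surface_assumption_bias(600.0, 4.0) - want) < 1e-12

    def test_monotone_decreasing_in_distance(self):
        xs = np.linspace(0.5, 10, 40)
        b = [loc.surface_assumption_bias(600.0, x) for x in xs]
        assert np.all(np.diff(b) < 0)
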