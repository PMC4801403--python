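"""Monte Carlo availability g(0) and its renewal-theory oracle."""

import numpy as np
import pytest

from strikewatch import g0 as g0m
from strikewatch.tags import PhaseDurationSet


def small_cfg(phases, **kw):
    kw.setdefault("n_runs", 200)
    kw.setdefault("seed", 0)
    return g0m.G0SimConfig(phase_source=phases, **kw)


class TestPhaseSources:
    def test_empirical_means(self):
        ph = g0m.EmpiricalPhases([10.0, 20.0], [5.0, 15.0])
        assert ph.mean_echo == 15.0 and ph.mean_silent == 10.0

    def test_length_biased_mean_is_second_moment_ratio(self):
        # E[length-biased X] = E[X^2] / E[X]
        rng = np.random.default_rng(1)
        for ph in (g0m.EmpiricalPhases([10.0] * 3 + [60.0], [2.0, 4.0, 30.0]),
                   g0m.ExponentialPhases(34.0, 24.0),
                   g0m.LognormalMixturePhases()):
            d = ph.sample_silent(np.random.default_rng(2), 200_000)
            want = np.mean(d**2) / np.mean(d)
            got = ph.sample_length_biased_silent(rng, 200_000).mean()
            assert abs(got - want) / want < 0.03

    def test_lognormal_mixture_calibration(self):
        ph = g0m.LognormalMixturePhases()
        assert abs(ph.mean_echo - 34.0) < 2.0
        assert abs(ph.mean_silent - 24.0) < 2.0
        d = ph.sample_silent(np.random.default_rng(3), 50_000)
        assert d.max() > 120.0  # heavy surface-rest tail is present


class TestSimulate:
    def test_always_vocal_gives_exactly_one(self):
        ph = g0m.EmpiricalPhases([30.0, 40.0], [0.0, 0.0])
        est = g0m.simulate_g0(small_cfg(ph))
        assert est.g0_mean == 1.0 and est.g0_sd == 0.0

    def test_all_silent_shorter_than_window_gives_one(self):
        # no silent phase can cover the window, so every whale is heard
        ph = g0m.EmpiricalPhases([30.0, 35.0], [5.0, 10.0, 20.0])
        est = g0m.simulate_g0(small_cfg(ph, eshw_km=4.168, speed_kmh=11.8))
        assert est.window_min > 20.0
        assert est.g0_mean == 1.0

    def test_matches_exponential_closed_form(self):
        ph = g0m.ExponentialPhases(34.0, 24.0)
        cfg = g0m.G0SimConfig(phase_source=ph, eshw_km=4.168, speed_kmh=11.8,
                              n_runs=2000, seed=4)
        est = g0m.simulate_g0(cfg)
        want = g0m.analytic_g0_exponential(34.0, 24.0, cfg.window_min)
        mc_se = est.g0_sd / np.sqrt(cfg.n_runs)
        assert abs(est.g0_mean - want) < 3 * mc_se

    def test_per_run_in_unit_interval_and_sd_consistent(self):
        ph = g0m.LognormalMixturePhases()
        est = g0m.simulate_g0(small_cfg(ph))
        assert np.all(est.per_run >= 0) and np.all(est.per_run <= 1)
        assert np.isclose(est.g0_sd, est.per_run.std(ddof=1))

    def test_zero_echo_mass_warns(self):
        ph = g0m.EmpiricalPhases([1.0], [10.0])
        ph.mean_echo = 0.0
        with pytest.warns(UserWarning):
            est = g0m.simulate_g0(small_cfg(ph))
        assert est.g0_mean == 0.0

    def test_seed_reproducibility(self):
        ph = g0m.LognormalMixturePhases()
        a = g0m.simulate_g0(small_cfg(ph, seed=9))
        b = g0m.simulate_g0(small_cfg(ph, seed=9))
        assert np.array_equal(a.per_run, b.per_run)

    def test_empirical_phase_source_from_tag_truth(self, calibrated_phases):
        est = g0m.simulate_g0(g0m.G0SimConfig(
            phase_source=g0m.EmpiricalPhases.from_phase_set(calibrated_phases),
            n_runs=500, seed=5))
        assert 0.85 <= est.g0_mean <= 0.98


class TestEventDrivenVsTimestep:
    def test_timeline_detection_matches_vectorised_rule_and_brute_force(self):
        # ten small runs: the interval-overlap detector, the collapsed
        # initial-state rule used by simulate_g0, and a 1-second scan must
        # all agree per whale (brute force to within boundary discretisation)
        ph = g0m.LognormalMixturePhases()
        window = g0m.G0SimConfig(phase_source=ph).window_min
        rng = np.random.default_rng(6)
        for _ in range(10):
            N = int(rng.integers(5, 25))
            is_echo, dur, elapsed = g0m._stationary_init(rng, ph, N)
            fast = is_echo | ((dur - elapsed) < window)
            n_mismatch = 0
            for k in range(N):
                tl = g0m.whale_timeline(rng, ph,
                                        (is_echo[k], dur[k], elapsed[k]),
                                        window + 1.0)
                ev = g0m.detected_from_timeline(tl, window)
                bf = g0m.detected_by_timestep(tl, window)
                assert ev == fast[k]
                n_mismatch += int(ev != bf)
            assert n_mismatch <= 1


class TestAnalyticOracle:
    def test_no_silence_limit(self):
        assert g0m.analytic_g0_exponential(34.0, 0.0, 10.0) == 1.0

    def test_zero_window_is_availability_fraction(self):
        got = g0m.analytic_g0_exponential(34.0, 24.0, 0.0)
        assert np.isclose(got, 34.0 / 58.0)

    def test_printed_configuration_value(self):
        # mean phases 34/24 min, 42.4-min window -> ~0.929
        got = g0m.analytic_g0_exponential(34.0, 24.0, 42.4)
        assert abs(got - 0.929) < 0.001


@pytest.fixture(scope="module")
def grid():
    ph = g0m.LognormalMixturePhases()
    return g0m.g0_grid(ph, eshw_list=[2.0, 4.168, 8.0],
                       speed_list=[6.0, 11.8, 20.0], n_runs=400, seed=7)


class TestGrid:
    def test_monotone_in_eshw_and_speed(self, grid):
        df, flags = grid
        assert flags["nondecreasing_in_eshw"]
        assert flags["nonincreasing_in_speed"]

    def test_centre_cell_consistent_with_simulate(self, grid):
        df, _ = grid
        cell = df[(df.eshw_km == 4.168) & (df.speed_kmh == 11.8)].iloc[0]
        assert abs(cell.g0_mean - 0.92) < 0.04
        assert np.isclose(cell.window_min, 2 * 4.168 / 11.8 * 60.0)
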