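import numpy as np
import pytest

from hemaclone import (
    DAYS_PER_YEAR,
    ScenarioConfig,
    SimulationError,
    SystemState,
    Trajectory,
    detect_manifestation,
    euler_oracle,
    healthy_steady_state,
    scaled_mds_params,
    simulate,
)


class TestSimulate:
    def test_healthy_equilibrium_is_stationary_over_55_years(self, healthy, healthy_traj):
        ss = healthy_steady_state(healthy)
        drift = np.abs(healthy_traj.counts - ss.counts) / ss.counts
        assert drift.max() < 1e-6

    def test_default_scenario_shows_mature_decline_near_year_17(self, disease_traj):
        t_m = disease_traj.events["manifestation_years"]
        assert 15.0 <= t_m <= 19.0
        # the decline is sharp: output drops from 75% to 25% of baseline
        # within a few years around manifestation
        mature = disease_traj.series("normal", "mature")
        frac = mature / mature[0]
        years = disease_traj.times_years
        t75 = years[np.argmax(frac < 0.75)]
        t25 = years[np.argmax(frac < 0.25)]
        assert t25 - t75 < 5.0

    def test_neutral_clone_stays_at_seed_level(self, baseline):
        params = scaled_mds_params(baseline, a_mds_stem=0.7, p_scale=1.0)
        traj = simulate(ScenarioConfig(params=params, horizon_years=55.0))
        stem = traj.series("mds", "MDS-LT-HSC")
        assert np.all(np.abs(stem - 1.0) < 0.01)

    def test_tolerance_halving_changes_little(self, baseline):
        kw = dict(params=baseline, horizon_years=30.0, output_interval_days=365.0)
        a = simulate(ScenarioConfig(rtol=1e-8, atol=1e-8, **kw))
        b = simulate(ScenarioConfig(rtol=5e-9, atol=5e-9, **kw))
        scale = np.maximum(np.abs(b.counts), 1.0)
        assert np.max(np.abs(a.counts - b.counts) / scale) < 1e-6

    def test_nonnegative_everywhere(self, disease_traj):
        assert disease_traj.counts.min() >= 0.0
        assert np.all((disease_traj.s_p > 0) & (disease_traj.s_p <= 1))
        assert np.all((disease_traj.s_a > 0) & (disease_traj.s_a <= 1))

    def test_frame_export_has_all_columns(self, disease_traj):
        frame = disease_traj.to_frame()
        assert len(frame) == len(disease_traj.times)
        for lin, name in disease_traj.params.labels():
            assert f"{lin}:{name}" in frame.columns
        assert {"s_p", "s_a", "t_days", "t_years"} <= set(frame.columns)


class TestEulerOracle:
    def test_constant_at_equilibrium(self, healthy):
        ss = healthy_steady_state(healthy)
        cfg = ScenarioConfig(params=healthy, initial=ss, horizon_years=0.5,
                             output_interval_days=10.0)
        traj = euler_oracle(cfg, step=0.25)
        drift = np.abs(traj.counts - ss.counts) / ss.counts
        assert drift.max() < 1e-9

    def test_first_order_error_decay(self, baseline):
        # start away from equilibrium so the solution actually moves
        ss = healthy_steady_state(baseline)
        y0 = SystemState(t=0.0, counts=0.5 * ss.counts)
        cfg = ScenarioConfig(params=baseline, initial=y0,
                             horizon_years=200.0 / DAYS_PER_YEAR,
                             output_interval_days=200.0,
                             rtol=1e-10, atol=1e-10)
        ref = simulate(cfg).counts[-1]
        j = baseline.index("normal", "mature")
        errors = [abs(euler_oracle(cfg, step=h).counts[-1][j] - ref[j])
                  for h in (0.5, 0.25)]
        ratio = errors[0] / errors[1]
        assert 1.6 < ratio < 2.4  # Richardson: halving the step halves the error

    def test_agrees_with_adaptive_solver(self, baseline):
        cfg = ScenarioConfig(params=baseline, horizon_years=5.0,
                             output_interval_days=365.0)
        adaptive = simulate(cfg)
        euler = euler_oracle(cfg, step=0.1)
        assert np.allclose(euler.times, adaptive.times, atol=1e-6)
        scale = np.maximum(adaptive.counts, 1e-12)
        rel = np.abs(euler.counts - adaptive.counts) / scale
        assert rel.max() < 5e-3

    def test_unstable_step_is_rejected(self, healthy):
        ss = healthy_steady_state(healthy)
        y0 = SystemState(t=0.0, counts=0.1 * ss.counts)
        cfg = ScenarioConfig(params=healthy, initial=y0, horizon_years=1.0,
                             output_interval_days=30.0)
        with pytest.raises(SimulationError, match="smaller step"):
            euler_oracle(cfg, step=5.0)  # far beyond 1/d of the mature pool


class TestManifestationDetection:
    def test_healthy_only_never_manifests(self, healthy_traj):
        assert detect_manifestation(healthy_traj) is None
        assert "manifestation_years" not in healthy_traj.events

    def test_interpolates_synthetic_crossing_exactly(self, healthy):
        # piecewise-linear mature decline crossing 50% exactly at t = 3 y
        n = healthy.n_compartments
        times = np.array([0.0, 2.0, 4.0]) * DAYS_PER_YEAR
        counts = np.tile(healthy_steady_state(healthy).counts, (3, 1))
        j = healthy.index("normal", "mature")
        counts[:, j] = np.array([1.0, 0.75, 0.25]) * counts[0, j]
        traj = Trajectory(params=healthy, times=times, counts=counts,
                          s_p=np.ones(3), s_a=np.ones(3))
        t = detect_manifestation(traj, threshold_fraction=0.5)
        assert t == pytest.approx(3.0, abs=1e-9)

    def test_threshold_fraction_is_respected(self, disease_traj):
        t30 = detect_manifestation(disease_traj, threshold_fraction=0.3)
        t70 = detect_manifestation(disease_traj, threshold_fraction=0.7)
        assert t70 < t30
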