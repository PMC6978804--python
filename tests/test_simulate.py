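"""Simulation driver: configuration round-trip, determinism, cycle
detection, and file output."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ratloco import (SimConfig, load_config, save_config, simulate,
                     detect_cycles, analyze, run_io, sweep_io)
from ratloco.params import config_from_dict, config_to_dict
from ratloco.simulate import (build_muscle_arrays, initial_state,
                              joint_limit_arrays, sweep_duration, Trajectory)
from ratloco.skeleton import build_skeleton


@pytest.fixture(scope="module")
def short_walk():
    """A brief nominal-walk run shared across tests (compile-once)."""
    return simulate(SimConfig(duration=0.6))


class TestConfig:
    def test_dict_round_trip(self):
        cfg = SimConfig(duration=1.5, seed=7)
        again = config_from_dict(config_to_dict(cfg))
        assert config_to_dict(again) == config_to_dict(cfg)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(duration=0.2)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        loaded = load_config(path)
        assert config_to_dict(loaded) == config_to_dict(cfg)

    def test_delay_steps(self):
        assert SimConfig().delay_steps == 750


class TestMuscleArrays:
    def test_layout(self, config):
        mus = build_muscle_arrays(config)
        assert len(mus.names) == 26
        # left and right instances mirror each other
        assert mus.names[0] == "SSP_L" and mus.names[13] == "SSP_R"
        np.testing.assert_array_equal(mus.fmax[:13], mus.fmax[13:])
        # forelimb muscles read the fore oscillators, hindlimb the hind
        for m, name in enumerate(mus.names):
            side = 0 if name.endswith("_L") else 1
            fore = name.split("_")[0] in ("SSP", "SPD", "BR", "TRIL", "BIC", "TRI")
            assert mus.osc_of[m] == (0 if fore else 2) + side

    def test_joint_limits_in_q_layout(self, config):
        lo, hi, k, c = joint_limit_arrays(config)
        assert np.all(np.isinf(lo[:3])) and np.all(np.isinf(hi[:3]))
        assert hi[4] == pytest.approx(math.pi)  # elbow straight
        assert k > 0


class TestInitialState:
    def test_posed_on_ground_at_reference_heights(self, config):
        model = build_skeleton(config.skeleton)
        y = initial_state(config, model, config.gait.beta_hat)
        st = model.__class__  # noqa: keep simple
        from ratloco.skeleton import SkeletonState
        state = SkeletonState(y[:13], y[13:26])
        hs = model.shoulder_height(state)
        hh = model.hip_height(state)
        assert hs == pytest.approx(config.regulator.h0_shoulder, abs=1e-6)
        assert hh == pytest.approx(config.regulator.h0_hip, abs=1e-6)
        # stance tips on the ground, swing tips clear of it
        pos, _ = model.tip_states(state)
        assert np.min(pos[:, 1]) > -1e-9
        assert state.qd[0] == pytest.approx(config.start_speed)

    def test_random_phases_seeded(self, config):
        cfg = dataclasses.replace(config, random_phases=True, seed=3)
        model = build_skeleton(cfg.skeleton)
        y1 = initial_state(cfg, model, 0.62)
        y2 = initial_state(cfg, model, 0.62)
        np.testing.assert_array_equal(y1, y2)


class TestSimulate:
    def test_monotone_time_no_nan(self, short_walk):
        assert short_walk.status == "ok"
        assert np.all(np.diff(short_walk.t) > 0)
        assert np.all(np.isfinite(short_walk.rec))

    def test_determinism(self, short_walk):
        """Identical configs give bit-identical trajectories."""
        again = simulate(SimConfig(duration=0.6))
        np.testing.assert_array_equal(short_walk.rec, again.rec)
        pd.testing.assert_frame_equal(short_walk.events, again.events)

    def test_events_logged(self, short_walk):
        ev = short_walk.events
        assert {"touchdown", "liftoff"} >= set(ev.event.unique())
        assert (ev.event == "touchdown").sum() >= 4
        assert ev.time.is_monotonic_increasing

    def test_activations_bounded(self, short_walk):
        for block in (short_walk.activation, short_walk.activation_syn,
                      short_walk.activation_height, short_walk.activation_speed):
            assert block.min() >= 0.0 and block.max() <= 1.0

    def test_contact_forces_sane(self, short_walk):
        fz = short_walk.contact_fz
        assert np.all(fz >= 0.0)
        assert fz.max() > 0.1  # the model is actually standing on the ground

    def test_passive_mode_silences_muscles(self):
        from ratloco.params import ContactParams
        cfg = SimConfig(passive=True, duration=0.05,
                        contact=ContactParams(ground_height=-10.0))
        traj = simulate(cfg)
        assert np.all(traj.tension == 0.0)
        assert np.all(traj.activation == 0.0)


class TestDetectCycles:
    def synthetic_trajectory(self, td_times):
        """Trajectory stub with a fabricated right-hind touchdown log."""
        import ratloco._engine as E
        t = np.arange(0.0, 2.0, 1e-3)
        rec = np.zeros((t.size, E.REC_W))
        rec[:, E.REC_T] = t
        rec[:, E.REC_Q] = 0.2 * t  # constant forward speed
        rec[:, E.REC_ST:E.REC_ST + 4] = 1.0
        events = pd.DataFrame({
            "time": td_times, "tip": ["RH"] * len(td_times),
            "event": ["touchdown"] * len(td_times)})
        cfg = SimConfig(duration=2.0)
        return Trajectory(cfg, build_skeleton(cfg.skeleton),
                          build_muscle_arrays(cfg), rec, events, "ok", 0.62)

    def test_windows_between_touchdowns(self):
        traj = self.synthetic_trajectory([1.00, 1.26, 1.52])
        info = detect_cycles(traj)
        assert info.windows == [(1.00, 1.26), (1.26, 1.52)]
        np.testing.assert_allclose(info.durations, 0.26)

    def test_too_few_touchdowns(self):
        traj = self.synthetic_trajectory([1.00])
        with pytest.raises(ValueError, match="no steady gait"):
            detect_cycles(traj)

    def test_walk_cycle_durations_match_cpg_period(self, short_walk):
        info = detect_cycles(short_walk)
        assert len(info.windows) >= 1
        # cycle durations track T = T_fl / (1 - beta)
        T = short_walk.config.gait.cycle_duration
        assert info.durations[-1] == pytest.approx(T, rel=0.1)


class TestIO:
    def test_run_io_files(self, short_walk, tmp_path):
        paths = run_io(short_walk, tmp_path)
        for p in paths.values():
            assert p.exists()
        df = pd.read_csv(paths["trajectory"])
        assert df.t.is_monotonic_increasing
        reloaded = load_config(paths["config"])
        assert config_to_dict(reloaded) == config_to_dict(short_walk.config)

    def test_sweep_io(self, tmp_path):
        df = pd.DataFrame({"beta": [0.6, 0.62], "mean_speed": [0.21, 0.20],
                           "cot": [0.9, 1.0], "status": ["ok", "ok"]})
        paths = sweep_io(df, tmp_path)
        assert paths["csv"].exists()
        import json
        payload = json.loads(paths["json"].read_text())
        assert payload["columns"] == list(df.columns)
        assert len(payload["rows"]) == 2

    def test_sweep_duration_covers_ramp_and_hold(self):
        cfg = SimConfig()
        d = sweep_duration(cfg, 0.58)
        # 8 ramp cycles + 18 hold cycles, each at least T_fl long
        assert d > 26 * 0.10
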