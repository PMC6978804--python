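"""Hill-type muscle model: geometry, tension, activation, torques."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratloco import (MuscleCurves, activation_step, default_muscles,
                     joint_torques_from_muscles, muscle_length,
                     muscle_tension, muscle_velocity)
from ratloco.params import (ConfigurationError, MuscleCurveParams,
                            NEUTRAL_POSTURE_DEG)

MUS = {m.name: m for m in default_muscles()}
NEUTRAL = dict(NEUTRAL_POSTURE_DEG)
CURVES = MuscleCurves()


class TestGeometry:
    @pytest.mark.parametrize("name", list(MUS))
    def test_neutral_lengths(self, name):
        """85 % of maximum length for uniarticular muscles, 75 % for
        biarticular muscles, at the neutral posture."""
        want = 0.75 if MUS[name].biarticular else 0.85
        assert muscle_length(MUS[name], NEUTRAL) == pytest.approx(want)

    def test_flexor_lengthens_with_extension(self):
        ang = dict(NEUTRAL, ankle=110.0)
        # TA flexes the ankle: +10 deg extension at 2 deg/1% -> +5%
        assert muscle_length(MUS["TA"], ang) == pytest.approx(0.90)

    def test_extensor_shortens_with_extension(self):
        ang = dict(NEUTRAL, ankle=110.0)
        # SO extends the ankle and has the GA-independent 2 deg/1% map
        assert muscle_length(MUS["SO"], ang) == pytest.approx(0.80)

    def test_special_excursion_coefficients(self):
        # BIC at the shoulder: 4.5 deg per 1%
        ang = dict(NEUTRAL, shoulder=60.0 + 4.5)
        assert muscle_length(MUS["BIC"], ang) == pytest.approx(0.75 - 0.01)
        # GA at the ankle: 1.5 deg per 1%
        ang = dict(NEUTRAL, ankle=100.0 + 1.5)
        assert muscle_length(MUS["GA"], ang) == pytest.approx(0.75 - 0.01)

    def test_missing_joint_errors(self):
        with pytest.raises(KeyError, match="ankle"):
            muscle_length(MUS["TA"], {"knee": 90.0})

    def test_velocity_chain_rule(self):
        rates = {"ankle": 2.0}
        v = muscle_velocity(MUS["TA"], NEUTRAL, rates)
        assert v == pytest.approx(-0.01 / 1.8)
        v2 = muscle_velocity(MUS["TA"], NEUTRAL, {"ankle": -2.0})
        assert v2 == pytest.approx(-v)

    def test_zero_rates_zero_velocity(self):
        rates = {j: 0.0 for j in NEUTRAL}
        for m in MUS.values():
            assert muscle_velocity(m, NEUTRAL, rates) == 0.0


class TestCurves:
    def test_normalization_points(self):
        assert CURVES.force_length(1.0) == pytest.approx(1.0)
        assert CURVES.force_velocity(0.0) == pytest.approx(1.0)
        assert CURVES.passive(1.0) == 0.0
        assert CURVES.passive(0.8) == 0.0

    def test_nonnegative_and_shapes(self):
        l = np.linspace(0.3, 1.7, 50)
        v = np.linspace(-3.0, 3.0, 50)
        assert np.all(CURVES.force_length(l) >= 0.0)
        assert np.all(CURVES.force_velocity(v) >= 0.0)
        assert np.all(CURVES.passive(l) >= 0.0)
        # concentric cutoff and eccentric cap
        assert CURVES.force_velocity(1.5) == 0.0
        assert CURVES.force_velocity(-5.0) <= 1.5 + 1e-12

    def test_bad_normalization_rejected(self):
        with pytest.raises(ConfigurationError):
            MuscleCurves(MuscleCurveParams(fl_width=-0.1))


class TestTension:
    def test_zero_activation_below_optimum(self):
        assert muscle_tension(MUS["SO"], CURVES, 0.0, 0.85, 0.0) == 0.0

    def test_isometric_optimum_equals_fmax(self):
        assert muscle_tension(MUS["SO"], CURVES, 1.0, 1.0, 0.0) == pytest.approx(3.5)

    def test_linear_in_activation(self):
        f1 = muscle_tension(MUS["GM"], CURVES, 1.0, 0.9, 0.1)
        f5 = muscle_tension(MUS["GM"], CURVES, 0.5, 0.9, 0.1)
        assert f5 == pytest.approx(0.5 * f1)

    def test_monotone_in_activation(self):
        f = [muscle_tension(MUS["VL"], CURVES, a, 0.95, -0.2)
             for a in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(f, f[1:]))

    def test_activation_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            muscle_tension(MUS["SO"], CURVES, 1.2, 1.0, 0.0)


class TestActivation:
    def test_rise_time_constant(self):
        """Under u = 1 the ODE reduces to da/dt = (1-a)/tau_act."""
        a, dt = 0.0, 2e-5
        for _ in range(int(round(0.011 / dt))):
            a = activation_step(a, 1.0, dt)
        assert a == pytest.approx(1.0 - math.exp(-1.0), abs=1e-4)

    def test_decay_time_constant(self):
        """Under u = 0 the ODE reduces to da/dt = -a/tau_deact."""
        a, dt = 1.0, 2e-5
        for _ in range(int(round(0.018 / dt))):
            a = activation_step(a, 0.0, dt)
        assert a == pytest.approx(math.exp(-1.0), abs=1e-4)

    def test_zero_fixed_point(self):
        assert activation_step(0.0, 0.0, 1e-3) == 0.0

    def test_step_convergence_order(self):
        """Error against the closed form decreases at least linearly in dt."""
        errs = []
        for dt in (1e-3, 5e-4, 2.5e-4):
            a = 0.0
            for _ in range(int(round(0.011 / dt))):
                a = activation_step(a, 1.0, dt)
            errs.append(abs(a - (1.0 - math.exp(-1.0))))
        assert errs[1] <= errs[0] / 1.9 + 1e-15
        assert errs[2] <= errs[1] / 1.9 + 1e-15

    def test_dt_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            activation_step(0.5, 0.5, 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50),
           st.floats(0.0, 1.0))
    def test_activation_stays_in_unit_interval(self, us, a0):
        """For any command trajectory in [0,1], a remains in [0,1]."""
        a = a0
        for u in us:
            a = activation_step(a, u, 2e-3)
            assert 0.0 <= a <= 1.0


class TestTorques:
    def tensions(self, **forces):
        mus = list(MUS.values())
        return mus, [forces.get(m.name, 0.0) for m in mus]

    def test_uniarticular_extensor(self):
        tau = joint_torques_from_muscles(*self.tensions(TRIL=1.0))
        assert tau["elbow"] == pytest.approx(0.0059)
        assert tau["shoulder"] == 0.0 and tau["knee"] == 0.0

    def test_biarticular_both_joints(self):
        tau = joint_torques_from_muscles(*self.tensions(BF=1.0))
        assert tau["hip"] == pytest.approx(0.0025)
        assert tau["knee"] == pytest.approx(-0.0125)

    def test_all_zero(self):
        tau = joint_torques_from_muscles(*self.tensions())
        assert all(v == 0.0 for v in tau.values())

    def test_every_joint_has_antagonist_pair(self):
        """Each joint is spanned by at least one extensor and one flexor."""
        actions = {}
        for m in MUS.values():
            for ja in m.joints:
                actions.setdefault(ja.joint, set()).add(ja.action)
        for joint in ("shoulder", "elbow", "hip", "knee", "ankle"):
            assert actions[joint] == {"ext", "flex"}
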