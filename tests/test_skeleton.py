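"""Skeleton model: construction, kinematics, dynamics, contact, energy."""

import dataclasses
import math

import numpy as np
import pytest

from ratloco import ConfigurationError, build_skeleton
from ratloco.params import ContactParams, LinkParams, SimConfig, SkeletonParams
from ratloco.skeleton import SkeletonState, neutral_q, posture_q, reference_q

from conftest import oracle_accelerations


def test_total_mass_sums_link_table(model):
    # trunk once, each limb link twice
    assert model.params.total_mass == pytest.approx(0.1252, abs=1e-9)


def test_zero_mass_rejected():
    with pytest.raises(ConfigurationError, match="brachium"):
        SkeletonParams(brachium=LinkParams("brachium", 0.0, 0.0161, 5.7e-8))


def test_nonpositive_inertia_rejected():
    with pytest.raises(ConfigurationError, match="foot"):
        SkeletonParams(foot=LinkParams("foot", 1.5e-3, 0.0177, -1e-9))


def test_reference_configuration_tip_heights(model):
    """All limb segments collinear and perpendicular to the trunk: each
    tip hangs its full limb length below the girdle joint."""
    st = SkeletonState(reference_q((0.0, 0.1)), np.zeros(13))
    pos, _ = model.tip_states(st)
    p = model.params
    fore = p.brachium.length + p.antebrachium.length
    hind = p.thigh.length + p.shank.length + p.foot.length
    assert pos[0, 1] == pytest.approx(0.1 - fore, abs=1e-12)
    assert pos[1, 1] == pytest.approx(0.1 - fore, abs=1e-12)
    assert pos[2, 1] == pytest.approx(0.1 - hind, abs=1e-12)
    assert pos[3, 1] == pytest.approx(0.1 - hind, abs=1e-12)


def test_translation_invariance(model):
    q1 = neutral_q((0.0, 0.08))
    q2 = neutral_q((1.0, 0.08))
    s1 = SkeletonState(q1, np.zeros(13))
    s2 = SkeletonState(q2, np.zeros(13))
    k1 = model.kinematic_queries(s1)
    k2 = model.kinematic_queries(s2)
    assert k1["shoulder_height"] == pytest.approx(k2["shoulder_height"])
    assert k1["hip_height"] == pytest.approx(k2["hip_height"])
    np.testing.assert_allclose(k2["tip_positions"][:, 0],
                               k1["tip_positions"][:, 0] + 1.0)
    np.testing.assert_allclose(k2["tip_positions"][:, 1],
                               k1["tip_positions"][:, 1])


def test_posed_standing_matches_reference_heights(model):
    st = model.pose_standing(0.033, 0.054)
    assert model.shoulder_height(st) == pytest.approx(0.033, abs=1e-9)
    assert model.hip_height(st) == pytest.approx(0.054, abs=1e-9)
    pos, _ = model.tip_states(st)
    np.testing.assert_allclose(pos[:, 1], 0.0, atol=1e-12)


def test_unforced_zero_gravity_equilibrium():
    m0 = build_skeleton(dataclasses.replace(SkeletonParams(), gravity=0.0))
    st = SkeletonState(neutral_q((0.0, 0.1)), np.zeros(13))
    qdd = m0.generalized_accelerations(st)
    np.testing.assert_allclose(qdd, 0.0, atol=1e-12)


def test_free_fall(model):
    st = SkeletonState(reference_q((0.0, 0.5)), np.zeros(13))
    qdd = model.generalized_accelerations(st)
    assert qdd[1] == pytest.approx(-model.params.gravity, rel=1e-12)
    assert abs(qdd[0]) < 1e-9
    np.testing.assert_allclose(qdd[2:], 0.0, atol=1e-9)


def test_nan_state_rejected(model):
    q = neutral_q()
    q[3] = math.nan
    with pytest.raises(ValueError, match="NaN"):
        model.generalized_accelerations(SkeletonState(q, np.zeros(13)))


def test_accelerations_match_lagrangian_oracle(model):
    """Forward dynamics vs finite differences of an independently coded
    Lagrangian on 100 random states."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        q = neutral_q((0.0, 0.08)) + rng.uniform(-0.3, 0.3, 13)
        qd = rng.uniform(-2.0, 2.0, 13)
        tau = rng.uniform(-0.02, 0.02, 10)
        Q = np.zeros(13)
        Q[3:] = tau
        ours = model.generalized_accelerations(SkeletonState(q, qd), tau)
        ref = oracle_accelerations(model.params, q, qd, Q)
        worst = max(worst, np.linalg.norm(ours - ref) / np.linalg.norm(ref))
    assert worst < 1e-5


def test_passive_energy_conservation():
    """Muscle-free, contact-free swing conserves mechanical energy to
    better than 1e-4 relative over 1 s at the nominal time step."""
    from ratloco import simulate

    cfg = dataclasses.replace(
        SimConfig(passive=True, duration=1.0,
                  contact=ContactParams(ground_height=-10.0)))
    traj = simulate(cfg)
    assert traj.status == "ok"
    e = [traj.model.total_mechanical_energy(traj.state_at(i))
         for i in range(0, len(traj.t), 50)]
    e0 = e[0]
    assert max(abs(v - e0) for v in e) / abs(e0) < 1e-4


def test_kinetic_energy_quadratic_in_rates(model):
    q = neutral_q((0.0, 0.07))
    qd = np.linspace(-1.0, 1.0, 13)
    e1 = model.total_mechanical_energy(SkeletonState(q, qd))
    e0 = model.total_mechanical_energy(SkeletonState(q, np.zeros(13)))
    e2 = model.total_mechanical_energy(SkeletonState(q, 2.0 * qd))
    assert e2 - e0 == pytest.approx(4.0 * (e1 - e0), rel=1e-10)


class TestContact:
    cp = ContactParams(vertical_stiffness=1000.0, vertical_damping=5.0,
                       horizontal_stiffness=1000.0, horizontal_damping=5.0)

    def hover_state(self, model, dz):
        """Standing pose shifted vertically by dz."""
        st = model.pose_standing(0.033, 0.054)
        st.q[1] += dz
        return st

    def test_zero_force_above_ground(self, model):
        st = self.hover_state(model, +0.001)
        F = model.contact_forces(st, self.cp)
        np.testing.assert_allclose(F, 0.0)

    def test_linear_spring_penetration(self, model):
        st = self.hover_state(model, -0.001)
        F = model.contact_forces(st, self.cp)
        np.testing.assert_allclose(F[:, 1], 1.0, rtol=1e-9)

    def test_never_adhesive(self, model):
        st = self.hover_state(model, -0.001)
        st.qd[1] = 1.0  # rapid upward motion: damper would pull down
        F = model.contact_forces(st, self.cp)
        assert np.all(F[:, 1] >= 0.0)
        np.testing.assert_allclose(F[:, 1], 0.0)

    def test_friction_cone_caps_horizontal(self, model):
        st = self.hover_state(model, -0.001)
        anchors = np.full(4, -1.0)  # far-away anchors demand a huge force
        F = model.contact_forces(st, self.cp, anchors=anchors,
                                 in_contact=np.ones(4, bool))
        np.testing.assert_allclose(np.abs(F[:, 0]), self.cp.friction * F[:, 1])
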