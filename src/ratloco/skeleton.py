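"""Planar 11-link rat skeleton: model building, forward dynamics, contact,
and kinematic queries.

Coordinate conventions
----------------------
x forward, z up, trunk pitch positive nose-up.  Joint angles are
extensor-positive.  In the reference configuration (all limb segments
collinear and perpendicular to the trunk) the shoulder is at 120 deg, the
elbow at 180 deg, the hip at 120 deg, and the knee and ankle at 180 deg.

Generalized coordinates (13):
    0 x, 1 z, 2 pitch,
    3 L shoulder, 4 L elbow, 5 R shoulder, 6 R elbow,
    7 L hip, 8 L knee, 9 L ankle, 10 R hip, 11 R knee, 12 R ankle

Limb tips (4): 0 LF, 1 RF, 2 LH, 3 RH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kin
from .params import (ConfigurationError, ContactParams, SkeletonParams,
                     NEUTRAL_POSTURE_DEG, REFERENCE_POSTURE_DEG)

NQ = _kin.NQ
NTIP = _kin.NTIP

#: q-vector index of each (side, joint) pair
JOINT_INDEX = {
    ("L", "shoulder"): 3, ("L", "elbow"): 4,
    ("R", "shoulder"): 5, ("R", "elbow"): 6,
    ("L", "hip"): 7, ("L", "knee"): 8, ("L", "ankle"): 9,
    ("R", "hip"): 10, ("R", "knee"): 11, ("R", "ankle"): 12,
}

JOINT_ORDER = tuple(sorted(JOINT_INDEX, key=JOINT_INDEX.get))

TIP_NAMES = ("LF", "RF", "LH", "RH")


@dataclass
class SkeletonState:
    """Generalized coordinates and rates of the 13-DOF linkage."""

    q: np.ndarray
    qd: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qd = np.asarray(self.qd, dtype=float)
        if self.q.shape != (NQ,) or self.qd.shape != (NQ,):
            raise ValueError(f"state vectors must have shape ({NQ},)")

    def copy(self) -> "SkeletonState":
        return SkeletonState(self.q.copy(), self.qd.copy())


def posture_q(joint_angles_deg: dict, trunk_xz=(0.0, 0.0), pitch=0.0) -> np.ndarray:
    """Build a q vector from per-joint angles in degrees (both sides equal
    unless a ('L'/'R', joint) key overrides)."""
    q = np.zeros(NQ)
    q[0], q[1] = trunk_xz
    q[2] = pitch
    for (side, joint), idx in JOINT_INDEX.items():
        if (side, joint) in joint_angles_deg:
            q[idx] = math.radians(joint_angles_deg[(side, joint)])
        elif joint in joint_angles_deg:
            q[idx] = math.radians(joint_angles_deg[joint])
        else:
            raise ConfigurationError(f"missing joint angle for {joint!r}")
    return q


def reference_q(trunk_xz=(0.0, 0.0), pitch=0.0) -> np.ndarray:
    return posture_q(REFERENCE_POSTURE_DEG, trunk_xz, pitch)


def neutral_q(trunk_xz=(0.0, 0.0), pitch=0.0) -> np.ndarray:
    return posture_q(NEUTRAL_POSTURE_DEG, trunk_xz, pitch)


def _build_tables(p: SkeletonParams):
    """Static kinematic tables: angle map alpha = A q + b, CoM and tip paths."""
    A = np.zeros((_kin.NL, NQ))
    b = np.zeros(_kin.NL)
    pi = math.pi

    def row(i, cols, const):
        for c, w in cols:
            A[i, c] = w
        b[i] = const

    # Offsets place every limb segment at absolute angle -pi/2 (straight
    # down) in the reference configuration (120/180 deg joint angles).
    # trunk
    row(0, [(2, 1.0)], 0.0)
    # forelimbs: brachium rotates forward with shoulder extension,
    # antebrachium folds backward relative to it as the elbow flexes
    for i0, sh, el in ((1, 3, 4), (3, 5, 6)):
        row(i0, [(2, 1.0), (sh, 1.0)], -7.0 * pi / 6.0)
        row(i0 + 1, [(2, 1.0), (sh, 1.0), (el, -1.0)], -pi / 6.0)
    # hindlimbs: thigh rotates backward with hip extension, shank folds
    # forward at the knee, foot folds backward at the ankle
    for i0, hip, knee, ank in ((5, 7, 8, 9), (8, 10, 11, 12)):
        row(i0, [(2, 1.0), (hip, -1.0)], pi / 6.0)
        row(i0 + 1, [(2, 1.0), (hip, -1.0), (knee, 1.0)], -5.0 * pi / 6.0)
        row(i0 + 2, [(2, 1.0), (hip, -1.0), (knee, 1.0), (ank, -1.0)], pi / 6.0)

    d_sh = p.shoulder_offset
    d_hip = p.hip_offset
    lb, la = p.brachium.length, p.antebrachium.length
    lt, ls, lf = p.thigh.length, p.shank.length, p.foot.length
    cb, ca_ = p.brachium.com, p.antebrachium.com
    ct, cs, cf = p.thigh.com, p.shank.com, p.foot.com

    com_paths = [
        [],                                                # trunk (CoM = reference point)
        [(0, d_sh), (1, cb)],                              # L brachium
        [(0, d_sh), (1, lb), (2, ca_)],                    # L antebrachium
        [(0, d_sh), (3, cb)],                              # R brachium
        [(0, d_sh), (3, lb), (4, ca_)],                    # R antebrachium
        [(0, d_hip), (5, ct)],                             # L thigh
        [(0, d_hip), (5, lt), (6, cs)],                    # L shank
        [(0, d_hip), (5, lt), (6, ls), (7, cf)],           # L foot
        [(0, d_hip), (8, ct)],                             # R thigh
        [(0, d_hip), (8, lt), (9, cs)],                    # R shank
        [(0, d_hip), (8, lt), (9, ls), (10, cf)],          # R foot
    ]
    tip_paths = [
        [(0, d_sh), (1, lb), (2, la)],                     # LF
        [(0, d_sh), (3, lb), (4, la)],                     # RF
        [(0, d_hip), (5, lt), (6, ls), (7, lf)],           # LH
        [(0, d_hip), (8, lt), (9, ls), (10, lf)],          # RH
    ]

    def pack(paths, n):
        idx = -np.ones((n, _kin.MAXSEG), dtype=np.int64)
        ln = np.zeros((n, _kin.MAXSEG))
        for i, path in enumerate(paths):
            for s, (ai, r) in enumerate(path):
                idx[i, s] = ai
                ln[i, s] = r
        return idx, ln

    com_idx, com_len = pack(com_paths, _kin.NL)
    tip_idx, tip_len = pack(tip_paths, NTIP)

    link_cols = np.zeros((_kin.NL, _kin.MAXCOL), dtype=np.int64)
    link_ncols = np.zeros(_kin.NL, dtype=np.int64)
    for i in range(_kin.NL):
        cols = [0, 1] + sorted(c for c in range(2, NQ) if A[i, c] != 0.0)
        link_ncols[i] = len(cols)
        link_cols[i, :len(cols)] = cols

    masses = np.array([p.trunk.mass,
                       p.brachium.mass, p.antebrachium.mass,
                       p.brachium.mass, p.antebrachium.mass,
                       p.thigh.mass, p.shank.mass, p.foot.mass,
                       p.thigh.mass, p.shank.mass, p.foot.mass])
    inertias = np.array([p.trunk.inertia,
                         p.brachium.inertia, p.antebrachium.inertia,
                         p.brachium.inertia, p.antebrachium.inertia,
                         p.thigh.inertia, p.shank.inertia, p.foot.inertia,
                         p.thigh.inertia, p.shank.inertia, p.foot.inertia])
    return A, b, masses, inertias, com_idx, com_len, link_cols, link_ncols, tip_idx, tip_len


@dataclass(frozen=True)
class SkeletonModel:
    """Immutable compiled form of the skeleton: kinematic tables plus
    mass/inertia arrays consumed by the numba kernels."""

    params: SkeletonParams
    A: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    masses: np.ndarray = field(repr=False)
    inertias: np.ndarray = field(repr=False)
    com_idx: np.ndarray = field(repr=False)
    com_len: np.ndarray = field(repr=False)
    link_cols: np.ndarray = field(repr=False)
    link_ncols: np.ndarray = field(repr=False)
    tip_idx: np.ndarray = field(repr=False)
    tip_len: np.ndarray = field(repr=False)

    # -- dynamics -----------------------------------------------------------

    def mass_matrix(self, state: SkeletonState) -> np.ndarray:
        return _kin.mass_matrix(state.q, self.A, self.b, self.masses,
                                self.inertias, self.com_idx, self.com_len,
                                self.link_cols, self.link_ncols)

    def generalized_accelerations(self, state: SkeletonState,
                                  joint_torques=None,
                                  tip_forces=None) -> np.ndarray:
        """Solve M(q) qdd = Q for the generalized accelerations.

        joint_torques: 10-vector (extensor-positive), ordered as q[3:].
        tip_forces: (4, 2) planar forces at the limb tips, columns (Fx, Fz).
        """
        if np.any(~np.isfinite(state.q)) or np.any(~np.isfinite(state.qd)):
            raise ValueError("NaN/Inf in skeleton state")
        tau = np.zeros(10) if joint_torques is None else np.asarray(joint_torques, float)
        F = np.zeros((NTIP, 2)) if tip_forces is None else np.asarray(tip_forces, float)
        if tau.shape != (10,):
            raise ValueError("joint_torques must have one entry per joint (10)")
        if F.shape != (NTIP, 2):
            raise ValueError("tip_forces must have shape (4, 2)")
        return _kin.generalized_accel(
            state.q, state.qd, tau, F, self.A, self.b, self.masses,
            self.inertias, self.com_idx, self.com_len, self.link_cols,
            self.link_ncols, self.tip_idx, self.tip_len, self.params.gravity)

    def total_mechanical_energy(self, state: SkeletonState) -> float:
        """Kinetic + gravitational potential energy (J), datum at z = 0."""
        return _kin.mechanical_energy(state.q, state.qd, self.A, self.b,
                                      self.masses, self.inertias,
                                      self.com_idx, self.com_len,
                                      self.params.gravity)

    # -- contact ------------------------------------------------------------

    def contact_forces(self, state: SkeletonState, cparams: ContactParams,
                       anchors=None, in_contact=None) -> np.ndarray:
        """Ground forces at the four limb tips, shape (4, 2) = (Fx, Fz).

        ``anchors``/``in_contact`` carry the horizontal sticking state; when
        omitted, every penetrating tip is anchored at its current x (pure
        vertical response plus damping-free horizontal equilibrium).
        """
        pos, vel = self.tip_states(state)
        if anchors is None:
            anchors = pos[:, 0].copy()
        if in_contact is None:
            in_contact = np.ones(NTIP, dtype=np.bool_)
        return _kin.contact_forces_kernel(
            pos, vel, np.asarray(anchors, float),
            np.asarray(in_contact, np.bool_),
            cparams.vertical_stiffness, cparams.vertical_damping,
            cparams.horizontal_stiffness, cparams.horizontal_damping,
            cparams.friction, cparams.ground_height)

    # -- kinematic queries ---------------------------------------------------

    def tip_states(self, state: SkeletonState):
        """Positions and velocities of the limb tips, two (4, 2) arrays."""
        return _kin.tip_states(state.q, state.qd, self.A, self.b,
                               self.tip_idx, self.tip_len)

    def link_alphas(self, state: SkeletonState) -> np.ndarray:
        return _kin.link_alphas(self.A, self.b, state.q)

    def shoulder_height(self, state: SkeletonState) -> float:
        return state.q[1] + self.params.shoulder_offset * math.sin(state.q[2])

    def hip_height(self, state: SkeletonState) -> float:
        return state.q[1] + self.params.hip_offset * math.sin(state.q[2])

    def shoulder_height_rate(self, state: SkeletonState) -> float:
        return state.qd[1] + self.params.shoulder_offset * math.cos(state.q[2]) * state.qd[2]

    def hip_height_rate(self, state: SkeletonState) -> float:
        return state.qd[1] + self.params.hip_offset * math.cos(state.q[2]) * state.qd[2]

    def kinematic_queries(self, state: SkeletonState) -> dict:
        """Sensed quantities: girdle heights (+rates), tip positions, trunk
        CoM position/velocity, forward speed.  SI units."""
        pos, vel = self.tip_states(state)
        return {
            "shoulder_height": self.shoulder_height(state),
            "hip_height": self.hip_height(state),
            "shoulder_height_rate": self.shoulder_height_rate(state),
            "hip_height_rate": self.hip_height_rate(state),
            "tip_positions": pos,
            "tip_velocities": vel,
            "trunk_com": state.q[:2].copy(),
            "trunk_com_velocity": state.qd[:2].copy(),
            "forward_speed": state.qd[0],
        }

    # -- posing -------------------------------------------------------------

    def limb_drop(self, q: np.ndarray, limb: str) -> float:
        """Vertical distance from the girdle joint to the limb tip (m);
        positive when the tip is below the joint.  Uses the left side."""
        state = SkeletonState(q, np.zeros(NQ))
        pos, _ = self.tip_states(state)
        if limb == "fore":
            return self.shoulder_height(state) - pos[0, 1]
        return self.hip_height(state) - pos[2, 1]

    def pose_standing(self, h_shoulder: float, h_hip: float, x=0.0,
                      forward_speed=0.0) -> SkeletonState:
        """Pose the model standing at the given girdle heights.

        The trunk pitch follows from the two heights; each limb's extension
        is interpolated between the neutral and reference postures and
        solved by bisection so the tips touch the ground.
        """
        L = self.params.shoulder_offset - self.params.hip_offset
        pitch = math.asin((h_shoulder - h_hip) / L)

        def pose(s_fore, s_hind):
            ang = {}
            for joint in ("shoulder", "elbow"):
                n, r = NEUTRAL_POSTURE_DEG[joint], REFERENCE_POSTURE_DEG[joint]
                ang[joint] = n + s_fore * (r - n)
            for joint in ("hip", "knee", "ankle"):
                n, r = NEUTRAL_POSTURE_DEG[joint], REFERENCE_POSTURE_DEG[joint]
                ang[joint] = n + s_hind * (r - n)
            return posture_q(ang, (x, 0.0), pitch)

        def solve(limb, target):
            lo, hi = 0.0, 1.0
            f = lambda s: self.limb_drop(pose(s, s), limb) - target
            if f(1.0) < 0.0:
                raise ConfigurationError(
                    f"target {limb} height {target} m exceeds limb length")
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if f(mid) < 0.0:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        s_f = solve("fore", h_shoulder)
        s_h = solve("hind", h_hip)
        q = pose(s_f, s_h)
        # drop the trunk so both tip pairs rest exactly on the ground
        state = SkeletonState(q, np.zeros(NQ))
        pos, _ = self.tip_states(state)
        q[1] -= 0.5 * (pos[0, 1] + pos[2, 1])
        qd = np.zeros(NQ)
        qd[0] = forward_speed
        return SkeletonState(q, qd)


def build_skeleton(params: SkeletonParams = None) -> SkeletonModel:
    """Validate parameters and assemble the immutable skeleton model."""
    if params is None:
        params = SkeletonParams()
    for link in params.links:
        # LinkParams validates at construction; re-check to catch mutation
        if not (link.mass > 0 and link.length > 0 and link.inertia > 0):
            raise ConfigurationError(
                f"link {link.name!r}: mass, length and inertia must be positive")
    tables = _build_tables(params)
    return SkeletonModel(params, *tables)
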