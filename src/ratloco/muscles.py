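"""Hill-type muscle model: geometry, tension generation, activation
dynamics, and joint-torque assembly.

Each of the 26 muscles (6 per forelimb, 7 per hindlimb) produces tension

    F_m = F_max * (a_m * F^l(lbar) * F^v(vbar) + F^p(lbar))

from its activation a_m, normalized length lbar and normalized contraction
velocity vbar (positive shortening, in maximum lengths per second divided
by 1.8).  Muscle length is a linear function of the spanned joint angles:
each muscle is calibrated so a fixed joint excursion (2 deg for most
muscles) corresponds to 1 % of maximum length, with uniarticular muscles at
85 % and biarticular muscles at 75 % of maximum length in the neutral
posture.  Moment arms are constant.

Activation follows the first-order dynamics

    tau_act * da/dt + {tau_act/tau_deact + (1 - tau_act/tau_deact) u} a = u

which rises with time constant tau_act (11 ms) under u = 1 and decays with
tau_deact (18 ms) under u = 0, keeping a in [0, 1] for u in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (ConfigurationError, MuscleCurveParams, MuscleParams,
                     NEUTRAL_POSTURE_DEG, VELOCITY_NORM, default_muscles)


# ---------------------------------------------------------------------------
# Contraction curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleCurves:
    """Force-length, force-velocity, and passive curves.

    The default family satisfies the normalization F^l(1) = 1, F^v(0) = 1,
    and F^p = 0 at or below the optimum length; all curves are nonnegative.
    Custom parameterizations are accepted as long as they keep those
    normalization points (validated here).
    """

    params: MuscleCurveParams = MuscleCurveParams()

    def __post_init__(self):
        for name, val, want in (("F^l(1)", self.force_length(1.0), 1.0),
                                ("F^v(0)", self.force_velocity(0.0), 1.0),
                                ("F^p(1)", self.passive(1.0), 0.0)):
            if abs(val - want) > 1e-9:
                raise ConfigurationError(f"curve normalization violated: {name} = {val}")

    def force_length(self, lbar):
        p = self.params
        return np.exp(-(((np.asarray(lbar) - 1.0) / p.fl_width) ** 2))

    def force_velocity(self, vbar):
        p = self.params
        v = np.asarray(vbar, dtype=float)
        conc = np.where(v < 1.0, (1.0 - v) / (1.0 + v / p.fv_shape), 0.0)
        ecc = np.minimum(p.fv_ecc_cap,
                         1.5 - 0.5 * (1.0 + v) / (1.0 - p.fv_ecc_slope * v))
        out = np.where(v >= 0.0, conc, ecc)
        return out if out.ndim else float(out)

    def passive(self, lbar):
        p = self.params
        l = np.asarray(lbar, dtype=float)
        out = np.where(l > 1.0, p.fp_scale * (np.exp(p.fp_rate * (l - 1.0)) - 1.0), 0.0)
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def muscle_length(muscle: MuscleParams, joint_angles_deg: dict) -> float:
    """Normalized muscle length at the given joint angles (degrees).

    lbar = neutral + sum over spanned joints of
           sign * (angle - neutral_angle) / deg_per_pct * 0.01,
    where extensors shorten (sign -1) and flexors lengthen (sign +1) as the
    joint angle increases.
    """
    lbar = muscle.neutral_norm_length
    for ja in muscle.joints:
        if ja.joint not in joint_angles_deg:
            raise KeyError(f"muscle {muscle.name}: missing joint angle {ja.joint!r}")
        dev = joint_angles_deg[ja.joint] - NEUTRAL_POSTURE_DEG[ja.joint]
        lbar += ja.length_sign * dev / ja.deg_per_pct * 0.01
    return lbar


def muscle_velocity(muscle: MuscleParams, joint_angles_deg: dict,
                    joint_rates_deg: dict) -> float:
    """Normalized contraction velocity (positive shortening).

    vbar = -(d lbar/dt) / 1.8, with rates in deg/s.
    """
    dldt = 0.0
    for ja in muscle.joints:
        if ja.joint not in joint_rates_deg:
            raise KeyError(f"muscle {muscle.name}: missing joint rate {ja.joint!r}")
        dldt += ja.length_sign * joint_rates_deg[ja.joint] / ja.deg_per_pct * 0.01
    return -dldt / VELOCITY_NORM


def max_length(muscle: MuscleParams) -> float:
    """Absolute maximum muscle length l_max (m), calibrated from the moment
    arm / excursion-coefficient consistency at each spanned joint.

    1 % of l_max per ``deg_per_pct`` degrees and a constant moment arm MA
    imply l_max = MA * deg_per_pct * (pi/180) / 0.01 per joint; biarticular
    muscles use the mean over their joints.  Used only to convert
    normalized contraction velocity to m/s for the energetics.
    """
    vals = [ja.moment_arm * ja.deg_per_pct * (math.pi / 180.0) / 0.01
            for ja in muscle.joints]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Tension and activation
# ---------------------------------------------------------------------------

def muscle_tension(muscle: MuscleParams, curves: MuscleCurves,
                   a: float, lbar: float, vbar: float) -> float:
    """Muscle tension (N): F_max (a F^l F^v + F^p), always nonnegative."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activation must lie in [0, 1], got {a}")
    F = muscle.f_max * (a * float(curves.force_length(lbar))
                        * float(curves.force_velocity(vbar))
                        + float(curves.passive(lbar)))
    return max(F, 0.0)


def activation_rate(a: float, u: float, tau_act: float, tau_deact: float) -> float:
    """da/dt of the activation ODE (u assumed clamped to [0, 1] upstream)."""
    r = tau_act / tau_deact
    return (u - (r + (1.0 - r) * u) * a) / tau_act


def activation_step(a: float, u: float, dt: float,
                    tau_act: float = 0.011, tau_deact: float = 0.018) -> float:
    """Advance the activation ODE one RK4 step; the result stays in [0, 1]."""
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    k1 = activation_rate(a, u, tau_act, tau_deact)
    k2 = activation_rate(a + 0.5 * dt * k1, u, tau_act, tau_deact)
    k3 = activation_rate(a + 0.5 * dt * k2, u, tau_act, tau_deact)
    k4 = activation_rate(a + dt * k3, u, tau_act, tau_deact)
    a_new = a + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return min(max(a_new, 0.0), 1.0)


def joint_torques_from_muscles(muscles, tensions) -> dict:
    """Net joint torques (N m, extensor-positive) from per-muscle tensions.

    tau_joint = sum over muscles of s * MA * F with s = +1 for extensor
    action and -1 for flexor action; biarticular muscles contribute at both
    spanned joints.
    """
    tau = {}
    for muscle, F in zip(muscles, tensions):
        for ja in muscle.joints:
            tau[ja.joint] = tau.get(ja.joint, 0.0) + ja.torque_sign * ja.moment_arm * F
    return tau


def neutral_lengths_pct(muscles=None) -> dict:
    """Normalized lengths (%) of every muscle at the neutral posture."""
    if muscles is None:
        muscles = default_muscles()
    return {m.name: 100.0 * muscle_length(m, NEUTRAL_POSTURE_DEG) for m in muscles}
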