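"""Mechanical work, stride length, and cost of transport (CoT).

Over one gait cycle the muscles perform positive work eta_+ (concentric)
and negative work eta_- (eccentric, down-weighted by 1/4 to reflect the
lower metabolic cost of lengthening contractions):

    eta_+ = int sum_m F_m [v_m]^+ dt
    eta_- = 1/4 int sum_m F_m [-v_m]^+ dt
    W = eta_+ + eta_-,     epsilon = W / D

with v_m the muscle contraction velocity (m/s, positive shortening) and D
the stride length (trunk CoM displacement over the cycle).

The CoT is decomposed by command source: the synergy pulses and the
posture/speed regulator components each drive their own copy of the
activation dynamics; component tensions use the active term only
(F_max a^comp F^l F^v on the realized lengths/velocities), since the
passive term is command-independent.  The decomposition is approximate
(epsilon ~ eps_syn + eps_height + eps_speed) because the activation ODE is
nonlinear in the command.

Contraction velocities in m/s are recovered from the normalized record as
v_m = vbar * 1.8 * l_max, with per-muscle l_max calibrated from the moment
arm / joint-excursion consistency (see muscles.max_length); absolute CoT
values therefore carry that calibration, while curve shapes and orderings
do not depend on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .muscles import MuscleCurves
from .params import VELOCITY_NORM


@dataclass(frozen=True)
class EnergeticsReport:
    """Per-cycle energetics summary (SI units)."""

    cycle_index: int
    t_start: float
    t_end: float
    eta_plus: float      # J
    eta_minus: float     # J, already divided by 4
    work: float          # J, eta_plus + eta_minus
    stride: float        # m
    cot: float           # J/m
    cot_syn: float
    cot_height: float
    cot_speed: float
    cot_active: float    # CoT from the active term with the full command
    mean_speed: float    # m/s


def _pos_work(t, power):
    return float(np.trapezoid(np.maximum(power, 0.0), t))


def mechanical_work(tension, velocity, t):
    """(eta_+, eta_-, W) from tension (n, M) in N and contraction velocity
    (n, M) in m/s over the window t (n,) in s; trapezoidal quadrature."""
    t = np.asarray(t, float)
    if t.size < 2:
        raise ValueError("empty cycle window")
    F = np.asarray(tension, float)
    v = np.asarray(velocity, float)
    eta_p = _pos_work(t, np.sum(F * np.maximum(v, 0.0), axis=1))
    eta_m = 0.25 * _pos_work(t, np.sum(F * np.maximum(-v, 0.0), axis=1))
    return eta_p, eta_m, eta_p + eta_m


def stride_length(t, x, window):
    """Horizontal trunk-CoM displacement over the cycle window (m)."""
    t0, t1 = window
    x0 = float(np.interp(t0, t, x))
    x1 = float(np.interp(t1, t, x))
    D = x1 - x0
    if D < 0.0:
        warnings.warn("backward drift over cycle window: stride negative, "
                      "CoT undefined", stacklevel=2)
    return D


def cot(work, stride):
    """epsilon = W / D (J/m); flagged NaN for nonpositive stride."""
    if stride <= 0.0:
        return float("nan")
    return work / stride


def component_tensions(a_comp, lbar, vbar, fmax, curves: MuscleCurves):
    """Active-term tensions F_max a^comp F^l F^v on realized lengths."""
    a_comp = np.asarray(a_comp, float)
    if a_comp.shape != np.asarray(lbar).shape:
        raise ValueError("mismatched component series lengths")
    return (fmax[None, :] * a_comp
            * curves.force_length(lbar) * curves.force_velocity(vbar))


def cot_decomposition(t, window_mask, stride, lbar, vbar,
                      a_syn, a_height, a_speed, fmax, lmax,
                      curves: MuscleCurves):
    """Component CoTs (eps_syn, eps_height, eps_speed) for one cycle."""
    tw = t[window_mask]
    v_m = vbar[window_mask] * VELOCITY_NORM * lmax[None, :]
    out = []
    for a_comp in (a_syn, a_height, a_speed):
        Fc = component_tensions(a_comp[window_mask], lbar[window_mask],
                                vbar[window_mask], fmax, curves)
        _, _, Wc = mechanical_work(Fc, v_m, tw)
        out.append(cot(Wc, stride))
    return tuple(out)


def cycle_report(index, window, t, x, tension, lbar, vbar,
                 a, a_syn, a_height, a_speed, fmax, lmax,
                 curves: MuscleCurves) -> EnergeticsReport:
    """Full energetics for one detected gait cycle."""
    t0, t1 = window
    mask = (t >= t0) & (t < t1)
    if mask.sum() < 2:
        raise ValueError(f"cycle window [{t0}, {t1}) contains fewer than 2 samples")
    tw = t[mask]
    v_m = vbar[mask] * VELOCITY_NORM * lmax[None, :]
    eta_p, eta_m, W = mechanical_work(tension[mask], v_m, tw)
    D = stride_length(t, x, window)
    eps = cot(W, D)
    eps_syn, eps_h, eps_v = cot_decomposition(
        t, mask, D, lbar, vbar, a_syn, a_height, a_speed, fmax, lmax, curves)
    F_act = component_tensions(a[mask], lbar[mask], vbar[mask], fmax, curves)
    _, _, W_act = mechanical_work(F_act, v_m, tw)
    speed = D / (t1 - t0)
    return EnergeticsReport(
        cycle_index=index, t_start=t0, t_end=t1,
        eta_plus=eta_p, eta_minus=eta_m, work=W, stride=D, cot=eps,
        cot_syn=eps_syn, cot_height=eps_h, cot_speed=eps_v,
        cot_active=cot(W_act, D), mean_speed=speed)
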