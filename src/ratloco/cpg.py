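"""Spinal two-layer CPG: rhythm generator (four coupled phase oscillators)
and pattern formation (rectangular synergy pulses).

Rhythm generator.  One phase oscillator per limb, order (LF, RF, LH, RH):

    dphi/dt = 2 pi / T
              - K1 sin(phi_self - phi_contra - pi)
              - K2 sin(phi_self - phi_ipsi +/- Delta)

with +Delta for the forelimb equations and -Delta for the hindlimbs, so
left/right limbs lock in antiphase and the hind oscillator leads its
ipsilateral fore oscillator by Delta (pi/2 walking, pi trotting).

Pattern formation.  Four rectangular pulses per limb cycle,
p_i(phi) = 1 on the half-open interval [Phi_i, Psi_i); pulses 1-2 span the
extension (stance) phase [0, 2 pi beta), pulses 3-4 the flexion phase.  The
feedforward command of muscle m is u^Syn_m = sum_i w_{m,i} p_i(phi) of its
own limb's oscillator phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import SynergySchedule

TWO_PI = 2.0 * math.pi

#: oscillator order
OSC_NAMES = ("LF", "RF", "LH", "RH")
#: contralateral partner of each oscillator
_CONTRA = np.array([1, 0, 3, 2])
#: ipsilateral partner
_IPSI = np.array([2, 3, 0, 1])
#: sign of Delta in each oscillator's ipsilateral coupling term
_DSIGN = np.array([1.0, 1.0, -1.0, -1.0])


def fixed_point_phases(delta: float) -> np.ndarray:
    """Phase-locked configuration: contralateral offset pi, hind leading
    fore by Delta: (0, pi, Delta, pi + Delta)."""
    return np.array([0.0, math.pi, delta, math.pi + delta]) % TWO_PI


def phase_rates(phases: np.ndarray, T: float, k1: float, k2: float,
                delta: float) -> np.ndarray:
    """Right-hand side of the four oscillator ODEs (rad/s)."""
    p = np.asarray(phases, dtype=float)
    return (TWO_PI / T
            - k1 * np.sin(p - p[_CONTRA] - math.pi)
            - k2 * np.sin(p - p[_IPSI] + _DSIGN * delta))


@dataclass
class OscillatorNetworkState:
    """Four limb phases plus the coupling parameters."""

    phases: np.ndarray = field(default_factory=lambda: np.zeros(4))
    T: float = 0.10 / (1.0 - 0.62)   # cycle duration (s)
    k1: float = 20.0
    k2: float = 10.0
    delta: float = math.pi / 2.0

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float) % TWO_PI
        if self.T <= 0.0:
            raise ValueError("cycle duration T must be > 0")


def oscillator_step(state: OscillatorNetworkState, dt: float) -> OscillatorNetworkState:
    """Advance the oscillator network one RK4 step and wrap to [0, 2 pi)."""
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    if state.T <= 0.0:
        raise ValueError("cycle duration T must be > 0")
    p = state.phases
    args = (state.T, state.k1, state.k2, state.delta)
    k1 = phase_rates(p, *args)
    k2 = phase_rates(p + 0.5 * dt * k1, *args)
    k3 = phase_rates(p + 0.5 * dt * k2, *args)
    k4 = phase_rates(p + dt * k3, *args)
    new = (p + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)) % TWO_PI
    return OscillatorNetworkState(new, state.T, state.k1, state.k2, state.delta)


def integrate_phases(phases0, duration: float, dt: float, T: float,
                     k1: float = 20.0, k2: float = 10.0,
                     delta: float = math.pi / 2.0) -> np.ndarray:
    """Integrate the network for ``duration`` seconds; returns final phases."""
    state = OscillatorNetworkState(np.asarray(phases0, float), T, k1, k2, delta)
    for _ in range(int(round(duration / dt))):
        state = oscillator_step(state, dt)
    return state.phases


def relative_phases(phases) -> dict:
    """Steady-state circular phase differences used to classify the gait."""
    p = np.asarray(phases, dtype=float)
    wrap = lambda x: (x + math.pi) % TWO_PI - math.pi
    return {
        "contralateral_fore": wrap(p[0] - p[1]),
        "contralateral_hind": wrap(p[2] - p[3]),
        "ipsilateral_left": wrap(p[2] - p[0]),    # hind minus fore = Delta at lock
        "ipsilateral_right": wrap(p[3] - p[1]),
    }


def pulse_values(schedule: SynergySchedule, phi: float) -> np.ndarray:
    """The four rectangular pulses at phase phi: p_i = 1 iff
    Phi_i <= phi < Psi_i (half-open)."""
    phi = float(phi) % TWO_PI
    return np.array([1.0 if on <= phi < off else 0.0
                     for on, off in zip(schedule.onsets, schedule.ends)])


def synergy_command(schedule: SynergySchedule, phi: float) -> dict:
    """Feedforward command u^Syn per muscle name at oscillator phase phi."""
    p = pulse_values(schedule, phi)
    return {name: float(sum(w * p[i - 1] for i, w in wd.items()))
            for name, wd in schedule.weights.items()}
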