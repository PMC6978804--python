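"""Brainstem/cerebellar movement regulator: posture (girdle height) and
forward-speed feedback for stance limbs, delivered with a fixed
sensorimotor delay.

Height loops: BR and TRIL hold the shoulder height of a stance forelimb,
VL, TA and SO hold the hip height of a stance hindlimb,

    p^height_m = -K^height_m (h - h0) - D^height_m hdot    (stance, else 0)

Speed loop: SSP, SPD (fore) and IP, GM, TA, SO (hind) hold the forward
trunk speed,

    p^speed_m = -K^speed_m (v - v0)                        (stance, else 0)

The commands are evaluated on the sensed state (stance gating included) and
then delayed: u^Reg_m(t) = p^height_m(t - tau) + p^speed_m(t - tau) with
tau = 15 ms, zero while the delay line is still filling.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .params import RegulatorParams

HEIGHT_MUSCLES = ("BR", "TRIL", "VL", "TA", "SO")
SPEED_MUSCLES = ("SSP", "SPD", "IP", "GM", "TA", "SO")
SHOULDER_MUSCLES = ("BR", "TRIL")
HIP_MUSCLES = ("VL", "TA", "SO")


def height_command(params: RegulatorParams, sensed: dict,
                   limb_in_stance: bool, muscle: str) -> float:
    """Posture command p^height for one muscle of one limb.

    ``sensed`` holds {'h': height m, 'hdot': rate m/s} of the muscle's own
    girdle (shoulder for BR/TRIL, hip for VL/TA/SO).
    """
    if muscle not in HEIGHT_MUSCLES:
        raise KeyError(f"{muscle!r} is not a height-regulating muscle "
                       f"(expected one of {HEIGHT_MUSCLES})")
    if not limb_in_stance:
        return 0.0
    h0 = params.h0_shoulder if muscle in SHOULDER_MUSCLES else params.h0_hip
    return (-params.k_height[muscle] * (sensed["h"] - h0)
            - params.d_height[muscle] * sensed["hdot"])


def speed_command(params: RegulatorParams, v: float,
                  limb_in_stance: bool, muscle: str) -> float:
    """Speed command p^speed for one muscle of one limb."""
    if muscle not in SPEED_MUSCLES:
        raise KeyError(f"{muscle!r} is not a speed-regulating muscle "
                       f"(expected one of {SPEED_MUSCLES})")
    if not limb_in_stance:
        return 0.0
    return -params.k_speed[muscle] * (v - params.v0)


class DelayBuffer:
    """Fixed-latency delay line for per-muscle command samples.

    Written once per control step; reading at time t returns the sample
    written at t - delay (an exact integer number of steps), and zeros
    until the line has filled.
    """

    def __init__(self, delay: float, dt: float, n_channels: int):
        if delay < 0 or dt <= 0:
            raise ValueError("need delay >= 0 and dt > 0")
        self.steps = int(round(delay / dt))
        self.n_channels = n_channels
        # keep steps + 1 samples so that, right after writing sample n,
        # the oldest entry is sample n - steps
        self._ring = deque(maxlen=self.steps + 1)

    def write(self, sample) -> None:
        sample = np.asarray(sample, dtype=float)
        if sample.shape != (self.n_channels,):
            raise ValueError(f"sample must have shape ({self.n_channels},)")
        self._ring.append(sample.copy())

    def read(self) -> np.ndarray:
        """Sample written exactly ``steps`` writes before the latest one;
        zeros while the line is still filling."""
        if len(self._ring) <= self.steps:
            return np.zeros(self.n_channels)
        return self._ring[0].copy()


def regulator_output(buffer: DelayBuffer) -> np.ndarray:
    """u^Reg for the current step: the delayed p^height + p^speed samples."""
    return buffer.read()
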