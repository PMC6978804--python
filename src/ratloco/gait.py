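"""Gait selection and quasi-static speed modulation.

The gait is chosen solely by the ipsilateral phase offset Delta (pi/2 for
walking, pi for trotting).  Speed is modulated by the extension fraction
beta while the flexion duration T_fl stays fixed, T = T_fl / (1 - beta):

* the pulse schedule is rescaled so extension pulses (1, 2) stretch with
  beta and flexion pulses (3, 4) keep their duration, the extension/
  flexion boundary sitting at phase 2 pi beta for every beta;
* the extension-pulse weights are scaled by (1 - beta)/(1 - beta_hat) so
  that shorter stance comes with stronger drive;
* the regulator references shift linearly in beta - beta_hat.

Beta changes are ramped quasi-statically, a bounded step per gait cycle.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ConfigurationError, GaitParams, SynergySchedule

TWO_PI = 2.0 * math.pi


def _check_beta(beta: float) -> None:
    if not 0.0 < beta < 1.0:
        raise ConfigurationError(f"beta must lie in (0, 1), got {beta}")


def scaled_pulse_phases(beta: float, schedule: SynergySchedule,
                        beta_hat: float = 0.62):
    """Pulse onset/end phases at extension fraction beta.

    Extension pulses (i = 1, 2) scale as (beta/beta_hat) * nominal;
    flexion pulses (i = 3, 4) as ((1-beta)/(1-beta_hat)) * nominal
    + 2 pi (beta - beta_hat)/(1 - beta_hat).
    """
    _check_beta(beta)
    ext = beta / beta_hat
    flx = (1.0 - beta) / (1.0 - beta_hat)
    shift = TWO_PI * (beta - beta_hat) / (1.0 - beta_hat)
    onsets = tuple(ext * v if i < 2 else flx * v + shift
                   for i, v in enumerate(schedule.onsets))
    ends = tuple(ext * v if i < 2 else flx * v + shift
                 for i, v in enumerate(schedule.ends))
    return onsets, ends


def scaled_weights(beta: float, schedule: SynergySchedule,
                   beta_hat: float = 0.62) -> dict:
    """Synergy weights at beta: extension pulses (1, 2) scaled by
    (1 - beta)/(1 - beta_hat), flexion pulses unchanged."""
    _check_beta(beta)
    s = (1.0 - beta) / (1.0 - beta_hat)
    return {name: {i: (s * w if i <= 2 else w) for i, w in wd.items()}
            for name, wd in schedule.weights.items()}


def scaled_schedule(beta: float, schedule: SynergySchedule,
                    beta_hat: float = 0.62) -> SynergySchedule:
    onsets, ends = scaled_pulse_phases(beta, schedule, beta_hat)
    return SynergySchedule(onsets, ends, scaled_weights(beta, schedule, beta_hat))


def scaled_references(beta: float, gait: GaitParams,
                      nominal_refs=(0.033, 0.054, 0.4)):
    """Regulator references (h0_shoulder, h0_hip, v0) at beta:
    each nominal value shifted by alpha * (beta - beta_hat)."""
    _check_beta(beta)
    db = beta - gait.beta_hat
    h0s, h0h, v0 = nominal_refs
    return (h0s + gait.alpha_shoulder * db,
            h0h + gait.alpha_hip * db,
            v0 + gait.alpha_speed * db)


def beta_ramp(current: float, target: float, rate_per_cycle: float,
              beta_bounds=(0.0, 1.0)) -> np.ndarray:
    """Per-cycle beta schedule ramping from current to target.

    Returns the beta value at each successive gait cycle, changing by at
    most ``rate_per_cycle`` per cycle, never overshooting the target.
    """
    if rate_per_cycle <= 0.0:
        raise ConfigurationError("ramp rate must be > 0")
    lo, hi = beta_bounds
    if not lo <= target <= hi:
        raise ConfigurationError(
            f"target beta {target} outside configured bounds [{lo}, {hi}]")
    _check_beta(target)
    _check_beta(current)
    n = int(math.ceil(abs(target - current) / rate_per_cycle - 1e-9))
    if n == 0:
        return np.array([current])
    sgn = math.copysign(1.0, target - current)
    vals = current + sgn * rate_per_cycle * np.arange(n + 1)
    vals[-1] = target
    if sgn > 0:
        vals = np.minimum(vals, target)
    else:
        vals = np.maximum(vals, target)
    return vals
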