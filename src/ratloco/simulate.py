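"""Simulation driver: couples skeleton, muscles, CPG and regulators in a
single RK4 loop, detects gait cycles, and runs the speed-sweep experiments.

The heavy lifting happens in the compiled loop (``_engine``); this module
builds the flat parameter arrays, poses the initial condition, and wraps
the raw record matrix in a friendly :class:`Trajectory`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine, gait as gait_mod
from .energetics import EnergeticsReport, cycle_report
from .muscles import MuscleCurves, max_length
from .params import (SimConfig, config_to_dict, default_muscles, save_config,
                     NEUTRAL_POSTURE_DEG)
from .skeleton import JOINT_INDEX, SkeletonModel, SkeletonState, build_skeleton

NM = _engine.NM
TIP_NAMES = ("LF", "RF", "LH", "RH")


# ---------------------------------------------------------------------------
# Flat muscle arrays for the engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleArrays:
    """The 26 muscle instances (13 types x left/right) in engine layout."""

    names: tuple
    fmax: np.ndarray
    nj: np.ndarray
    jq: np.ndarray        # q index per spanned joint
    dldq: np.ndarray      # d lbar / d q (1/rad), flexor-positive
    matq: np.ndarray      # signed moment arm (m), extensor-positive
    lnat: np.ndarray      # neutral normalized length
    lmax: np.ndarray      # absolute maximum length (m), for energetics
    qneutral: np.ndarray  # neutral joint angles in q layout (rad)
    osc_of: np.ndarray    # oscillator/tip index per muscle (LF RF LH RH)
    W_hat: np.ndarray     # nominal synergy weights (26, 4)
    kh: np.ndarray
    dh: np.ndarray
    kv: np.ndarray
    is_fore: np.ndarray
    tau_act: float
    tau_deact: float


def build_muscle_arrays(config: SimConfig) -> MuscleArrays:
    types = default_muscles()
    sched = config.schedule
    reg = config.regulator
    names, rows = [], []
    fmax = np.zeros(NM)
    nj = np.zeros(NM, dtype=np.int64)
    jq = np.zeros((NM, 2), dtype=np.int64)
    dldq = np.zeros((NM, 2))
    matq = np.zeros((NM, 2))
    lnat = np.zeros(NM)
    lmax = np.zeros(NM)
    osc_of = np.zeros(NM, dtype=np.int64)
    W = np.zeros((NM, 4))
    kh = np.zeros(NM)
    dh = np.zeros(NM)
    kv = np.zeros(NM)
    is_fore = np.zeros(NM, dtype=np.bool_)
    deg2rad = math.pi / 180.0
    for s, side in enumerate(("L", "R")):
        for k, mu in enumerate(types):
            m = s * len(types) + k
            names.append(f"{mu.name}_{side}")
            fmax[m] = mu.f_max
            nj[m] = len(mu.joints)
            for j, ja in enumerate(mu.joints):
                jq[m, j] = JOINT_INDEX[(side, ja.joint)]
                dldq[m, j] = ja.length_sign * 0.01 / (ja.deg_per_pct * deg2rad)
                matq[m, j] = ja.torque_sign * ja.moment_arm
            lnat[m] = mu.neutral_norm_length
            lmax[m] = max_length(mu)
            osc_of[m] = (0 if mu.limb == "fore" else 2) + s
            for i, w in sched.weights.get(mu.name, {}).items():
                W[m, i - 1] = w
            kh[m] = reg.k_height.get(mu.name, 0.0)
            dh[m] = reg.d_height.get(mu.name, 0.0)
            kv[m] = reg.k_speed.get(mu.name, 0.0)
            is_fore[m] = mu.limb == "fore"
    qneutral = np.zeros(13)
    for (side, joint), idx in JOINT_INDEX.items():
        qneutral[idx] = math.radians(NEUTRAL_POSTURE_DEG[joint])
    return MuscleArrays(tuple(names), fmax, nj, jq, dldq, matq, lnat, lmax,
                        qneutral, osc_of, W, kh, dh, kv, is_fore,
                        types[0].tau_act, types[0].tau_deact)


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

STATUS_NAMES = {_engine.STATUS_OK: "ok",
                _engine.STATUS_FELL: "fell",
                _engine.STATUS_BLOWUP: "blowup"}


@dataclass
class Trajectory:
    """Recorded simulation output on a uniform time grid plus the
    touchdown/liftoff event log."""

    config: SimConfig
    model: SkeletonModel
    muscles: MuscleArrays
    rec: np.ndarray
    events: pd.DataFrame
    status: str
    final_beta: float

    def _col(self, start, n):
        return self.rec[:, start:start + n]

    @property
    def t(self):
        return self.rec[:, _engine.REC_T]

    @property
    def q(self):
        return self._col(_engine.REC_Q, 13)

    @property
    def qd(self):
        return self._col(_engine.REC_QD, 13)

    @property
    def phi(self):
        return self._col(_engine.REC_PHI, 4)

    @property
    def beta(self):
        return self.rec[:, _engine.REC_BETA]

    @property
    def contact_fz(self):
        return self._col(_engine.REC_FZ, 4)

    @property
    def contact_fx(self):
        return self._col(_engine.REC_FX, 4)

    @property
    def stance(self):
        return self._col(_engine.REC_ST, 4) > 0.5

    @property
    def activation(self):
        return self._col(_engine.REC_A, NM)

    @property
    def activation_syn(self):
        return self._col(_engine.REC_AS, NM)

    @property
    def activation_height(self):
        return self._col(_engine.REC_AH, NM)

    @property
    def activation_speed(self):
        return self._col(_engine.REC_AV, NM)

    @property
    def lbar(self):
        return self._col(_engine.REC_LB, NM)

    @property
    def vbar(self):
        return self._col(_engine.REC_VB, NM)

    @property
    def tension(self):
        return self._col(_engine.REC_F, NM)

    @property
    def ok(self):
        return self.status == "ok"

    def state_at(self, i: int) -> SkeletonState:
        return SkeletonState(self.q[i].copy(), self.qd[i].copy())

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "beta": self.beta}
        qn = ["x", "z", "pitch", "shoulder_L", "elbow_L", "shoulder_R",
              "elbow_R", "hip_L", "knee_L", "ankle_L", "hip_R", "knee_R",
              "ankle_R"]
        for i, n in enumerate(qn):
            cols[f"q_{n}"] = self.q[:, i]
            cols[f"qd_{n}"] = self.qd[:, i]
        for i, n in enumerate(TIP_NAMES):
            cols[f"phi_{n}"] = self.phi[:, i]
            cols[f"fz_{n}"] = self.contact_fz[:, i]
            cols[f"fx_{n}"] = self.contact_fx[:, i]
            cols[f"stance_{n}"] = self.stance[:, i].astype(int)
        for j, n in enumerate(self.muscles.names):
            cols[f"a_{n}"] = self.activation[:, j]
            cols[f"F_{n}"] = self.tension[:, j]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Initial condition
# ---------------------------------------------------------------------------

def joint_limit_arrays(config: SimConfig):
    """Per-coordinate joint bounds (rad) in q layout; trunk coordinates are
    unbounded.  Returns (lo, hi, stiffness, damping) with stiffness 0 when
    limits are disabled."""
    lo = np.full(13, -np.inf)
    hi = np.full(13, np.inf)
    jl = config.joint_limits
    for (side, joint), idx in JOINT_INDEX.items():
        b = jl.bounds_deg.get(joint)
        if b is not None:
            lo[idx] = math.radians(b[0])
            hi[idx] = math.radians(b[1])
    k = jl.stiffness if jl.enabled else 0.0
    return lo, hi, k, jl.damping


def _fore_ik(pitch, h_girdle, x_off, l1, l2):
    """Shoulder/elbow angles (rad) placing the forelimb tip at horizontal
    offset ``x_off`` from the shoulder, on the ground.  The elbow bend sign
    follows the anatomical convention (antebrachium rotated CCW from the
    brachium, i.e. elbow apex caudal); over-long targets are brought within
    reach by straightening."""
    reach = math.hypot(x_off, h_girdle)
    reach = min(reach, 0.999 * (l1 + l2))
    c = (reach * reach - l1 * l1 - l2 * l2) / (2.0 * l1 * l2)
    delta = math.acos(min(1.0, max(-1.0, c)))
    ang_r = math.atan2(-h_girdle, x_off)
    a1 = ang_r - math.atan2(l2 * math.sin(delta), l1 + l2 * math.cos(delta))
    theta_sh = a1 - pitch + 7.0 * math.pi / 6.0
    theta_el = math.pi - delta
    return theta_sh, theta_el


def _hind_ik(pitch, h_girdle, x_off, l1, ls, lf, theta_ankle):
    """Hip/knee angles (rad) placing the hindlimb tip at horizontal offset
    ``x_off`` from the hip with the ankle angle held fixed (the shank+foot
    pair is treated as one virtual link)."""
    v = complex(ls + lf * math.cos(-(theta_ankle - math.pi)),
                lf * math.sin(-(theta_ankle - math.pi)))
    l2 = abs(v)
    off = math.atan2(v.imag, v.real)
    reach = math.hypot(x_off, h_girdle)
    reach = min(reach, 0.999 * (l1 + l2))
    c = (reach * reach - l1 * l1 - l2 * l2) / (2.0 * l1 * l2)
    # knee bend branch: virtual link rotated clockwise from the thigh
    delta = -math.acos(min(1.0, max(-1.0, c)))
    ang_r = math.atan2(-h_girdle, x_off)
    a_th = ang_r - math.atan2(l2 * math.sin(delta), l1 + l2 * math.cos(delta))
    theta_hip = pitch + math.pi / 6.0 - a_th
    theta_knee = delta - off + math.pi
    return theta_hip, theta_knee


def initial_state(config: SimConfig, model: SkeletonModel, beta0: float):
    """Initial condition close to the gait's limit cycle.

    The trunk is posed at the beta-scaled reference heights; each limb is
    placed according to its oscillator phase (stance limbs swept in
    proportion to their stance progress, swing limbs at the crouched
    neutral posture), activations are preloaded to the current synergy
    commands, and the trunk moves forward at ``start_speed``.
    """
    from .cpg import fixed_point_phases

    p = model.params
    reg = config.regulator
    g = config.gait
    h0s, h0h, v0 = gait_mod.scaled_references(
        beta0, g, (reg.h0_shoulder, reg.h0_hip, reg.v0))
    pitch = math.asin((h0s - h0h) / (p.shoulder_offset - p.hip_offset))

    if config.random_phases:
        rng = np.random.default_rng(config.seed)
        phases = rng.uniform(0.0, 2.0 * math.pi, 4)
    else:
        phases = (fixed_point_phases(g.delta) + config.start_phase) % (2 * math.pi)

    v_init = config.start_speed
    t_ex = beta0 * g.t_flex / (1.0 - beta0)
    ext_end = 2.0 * math.pi * beta0

    # ankle angle of a statically posed standing hindlimb (held fixed by the IK)
    standing = model.pose_standing(h0s, h0h)
    theta_ankle = standing.q[9]

    q = np.zeros(13)
    q[2] = pitch
    q[1] = h0s - p.shoulder_offset * math.sin(pitch)
    neutral = {j: math.radians(a) for j, a in NEUTRAL_POSTURE_DEG.items()}
    for side, s in (("L", 0), ("R", 1)):
        for limb, osc in (("fore", 0 + s), ("hind", 2 + s)):
            phi = phases[osc]
            in_stance = phi < ext_end
            if limb == "fore":
                h_g, l1, l2 = h0s, p.brachium.length, p.antebrachium.length
                jidx = (JOINT_INDEX[(side, "shoulder")], JOINT_INDEX[(side, "elbow")])
            else:
                h_g, l1 = h0h, p.thigh.length
                jidx = (JOINT_INDEX[(side, "hip")], JOINT_INDEX[(side, "knee")])
            if in_stance:
                xi = phi / ext_end
                x_off = (0.5 - xi) * v_init * t_ex
                lmax_limb = l1 + l2 if limb == "fore" else \
                    l1 + p.shank.length + p.foot.length
                x_reach = math.sqrt(max(lmax_limb ** 2 - h_g ** 2, 0.0)) * 0.97
                x_off = max(-x_reach, min(x_reach, x_off))
                if limb == "fore":
                    th1, th2 = _fore_ik(pitch, h_g, x_off, l1, l2)
                    q[jidx[0]], q[jidx[1]] = th1, th2
                else:
                    th1, th2 = _hind_ik(pitch, h_g, x_off, l1,
                                        p.shank.length, p.foot.length,
                                        theta_ankle)
                    q[jidx[0]], q[jidx[1]] = th1, th2
                    q[JOINT_INDEX[(side, "ankle")]] = theta_ankle
            else:
                if limb == "fore":
                    q[jidx[0]] = neutral["shoulder"]
                    q[jidx[1]] = neutral["elbow"]
                else:
                    q[jidx[0]] = neutral["hip"]
                    q[jidx[1]] = neutral["knee"]
                    q[JOINT_INDEX[(side, "ankle")]] = neutral["ankle"]

    qd = np.zeros(13)
    qd[0] = v_init

    y = np.zeros(_engine.NY)
    y[0:13] = q
    y[13:26] = qd
    y[130:134] = phases

    if config.passive:
        return y

    # preload activations with the current synergy commands
    mus = build_muscle_arrays(config)
    on, off = config.schedule.onsets, config.schedule.ends
    for m in range(NM):
        ph = phases[mus.osc_of[m]]
        u_syn = sum(mus.W_hat[m, i] for i in range(4) if on[i] <= ph < off[i])
        u_syn = min(u_syn, 1.0)
        y[26 + m] = u_syn
        y[52 + m] = u_syn
    return y


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------

def simulate(config: SimConfig = None) -> Trajectory:
    """Integrate the coupled neuromusculoskeletal system.

    If ``config.gait.beta`` differs from ``beta_hat``, the run starts at
    ``beta_hat`` and ramps quasi-statically to the target.
    """
    if config is None:
        config = SimConfig()
    model = build_skeleton(config.skeleton)
    mus = build_muscle_arrays(config)
    g = config.gait
    beta0 = g.beta_hat
    y = initial_state(config, model, beta0)

    n_steps = int(round(config.duration / config.dt))
    n_rec_cap = n_steps // config.record_stride + 2
    rec = np.zeros((n_rec_cap, _engine.REC_W))
    t_min = g.t_flex / (1.0 - min(beta0, g.beta))
    ev_cap = int(16 * config.duration / t_min) + 64
    ev_time = np.zeros(ev_cap)
    ev_tip = np.zeros(ev_cap, dtype=np.int64)
    ev_kind = np.zeros(ev_cap, dtype=np.int64)

    c = config.contact
    cur = config.curves
    status, n_rec, n_ev, final_beta = _engine.run(
        model.A, model.b, model.masses, model.inertias, model.com_idx,
        model.com_len, model.link_cols, model.link_ncols, model.tip_idx,
        model.tip_len, model.params.gravity,
        model.params.shoulder_offset, model.params.hip_offset,
        c.vertical_stiffness, c.vertical_damping,
        c.horizontal_stiffness, c.horizontal_damping, c.friction,
        c.ground_height,
        mus.fmax, mus.nj, mus.jq, mus.dldq, mus.matq, mus.lnat, mus.qneutral,
        mus.tau_act, mus.tau_deact,
        cur.fl_width, cur.fv_shape, cur.fv_ecc_slope, cur.fv_ecc_cap,
        cur.fp_scale, cur.fp_rate,
        *joint_limit_arrays(config), config.skeleton.joint_viscosity,
        mus.osc_of, mus.W_hat,
        mus.kh, mus.dh, mus.kv, mus.is_fore,
        config.regulator.h0_shoulder, config.regulator.h0_hip,
        config.regulator.v0,
        g.alpha_shoulder, g.alpha_hip, g.alpha_speed, config.delay_steps,
        config.oscillator.k1, config.oscillator.k2, g.delta,
        np.asarray(config.schedule.onsets), np.asarray(config.schedule.ends),
        g.beta_hat, g.t_flex,
        config.dt, n_steps, beta0, g.beta, g.ramp_rate, config.record_stride,
        config.passive, config.fall_pitch, config.fall_height_fraction,
        y, rec, ev_time, ev_tip, ev_kind)

    events = pd.DataFrame({
        "time": ev_time[:n_ev],
        "tip": [TIP_NAMES[i] for i in ev_tip[:n_ev]],
        "event": ["touchdown" if k == _engine.EV_TOUCHDOWN else "liftoff"
                  for k in ev_kind[:n_ev]],
    })
    return Trajectory(config, model, mus, rec[:n_rec], events,
                      STATUS_NAMES[status], final_beta)


# ---------------------------------------------------------------------------
# Gait-cycle detection and steady-state analysis
# ---------------------------------------------------------------------------

@dataclass
class CycleInfo:
    """Gait cycles delimited by successive right-hindlimb touchdowns."""

    windows: list                 # [(t0, t1), ...), half-open
    durations: np.ndarray
    duty_factors: np.ndarray      # (n_cycles, 4), order LF RF LH RH
    ipsilateral_lag: np.ndarray   # RF touchdown within the RH cycle, in cycles


def detect_cycles(traj: Trajectory) -> CycleInfo:
    """Cycle windows between successive right-hindlimb touchdowns, with
    per-limb duty factors and the fore-hind footfall lag."""
    ev = traj.events
    td = ev[(ev.tip == "RH") & (ev.event == "touchdown")].time.to_numpy()
    if td.size < 2:
        raise ValueError("no steady gait: fewer than 2 right-hindlimb touchdowns")
    windows = [(td[i], td[i + 1]) for i in range(td.size - 1)]
    t = traj.t
    stance = traj.stance
    duty = np.zeros((len(windows), 4))
    lag = np.full(len(windows), np.nan)
    rf_td = ev[(ev.tip == "RF") & (ev.event == "touchdown")].time.to_numpy()
    for i, (t0, t1) in enumerate(windows):
        mask = (t >= t0) & (t < t1)
        if mask.any():
            duty[i] = stance[mask].mean(axis=0)
        hits = rf_td[(rf_td >= t0) & (rf_td < t1)]
        if hits.size:
            lag[i] = (hits[0] - t0) / (t1 - t0)
    return CycleInfo(windows, np.diff(td), duty, lag)


@dataclass
class SteadyMetrics:
    """Averages over the measured steady cycles of one run."""

    n_cycles: int
    mean_speed: float
    cycle_duration: float
    stride: float
    work: float
    eta_plus: float
    eta_minus: float
    cot: float
    cot_syn: float
    cot_height: float
    cot_speed: float
    cot_active: float
    duty_factors: np.ndarray
    ipsilateral_lag: float
    reports: list


def analyze(traj: Trajectory, discard: int = None, measure: int = None) -> SteadyMetrics:
    """Per-cycle energetics over the last ``measure`` cycles after
    discarding the transient."""
    cfg = traj.config
    discard = cfg.discard_cycles if discard is None else discard
    measure = cfg.measure_cycles if measure is None else measure
    info = detect_cycles(traj)
    usable = info.windows[discard:]
    if not usable:
        raise ValueError(f"only {len(info.windows)} cycles detected, "
                         f"{discard} discarded: nothing to measure")
    sel = usable[-measure:] if measure < len(usable) else usable
    first = info.windows.index(sel[0])
    curves = MuscleCurves(cfg.curves)
    t = traj.t
    x = traj.q[:, 0]
    reports = []
    for k, win in enumerate(sel):
        reports.append(cycle_report(
            k, win, t, x, traj.tension, traj.lbar, traj.vbar,
            traj.activation, traj.activation_syn, traj.activation_height,
            traj.activation_speed, traj.muscles.fmax, traj.muscles.lmax,
            curves))
    t0 = sel[0][0]
    t1 = sel[-1][1]
    x0 = float(np.interp(t0, t, x))
    x1 = float(np.interp(t1, t, x))
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    return SteadyMetrics(
        n_cycles=len(sel),
        mean_speed=(x1 - x0) / (t1 - t0),
        cycle_duration=float(np.mean([w[1] - w[0] for w in sel])),
        stride=mean("stride"), work=mean("work"),
        eta_plus=mean("eta_plus"), eta_minus=mean("eta_minus"),
        cot=mean("cot"), cot_syn=mean("cot_syn"),
        cot_height=mean("cot_height"), cot_speed=mean("cot_speed"),
        cot_active=mean("cot_active"),
        duty_factors=info.duty_factors[first:first + len(sel)].mean(axis=0),
        ipsilateral_lag=float(np.nanmean(info.ipsilateral_lag[first:first + len(sel)])),
        reports=reports)


# ---------------------------------------------------------------------------
# Beta sweeps
# ---------------------------------------------------------------------------

def sweep_duration(config: SimConfig, beta: float) -> float:
    """Simulated time needed to ramp from beta_hat to beta and then hold
    for the discard + measure cycles (plus margin)."""
    g = config.gait
    ramp = gait_mod.beta_ramp(g.beta_hat, beta, g.ramp_rate,
                              (g.beta_min, g.beta_max))
    ramp_time = float(np.sum(g.t_flex / (1.0 - ramp)))
    hold = (config.discard_cycles + config.measure_cycles + 3) \
        * g.t_flex / (1.0 - beta)
    return ramp_time + hold


def sweep_beta(config: SimConfig, betas, gait: str = None) -> pd.DataFrame:
    """Quasi-static speed sweep: one steady run per beta.

    Each run ramps beta from beta_hat to the target, holds, and averages
    the energetics over the final cycles.  Failed runs (fall/blow-up) are
    kept as rows with status set and NaN metrics.
    """
    rows = []
    for beta in betas:
        g = replace(config.gait, beta=float(beta),
                    **({"gait": gait} if gait else {}))
        cfg = replace(config, gait=g, duration=sweep_duration(
            replace(config, gait=g), float(beta)))
        traj = simulate(cfg)
        row = {"beta": float(beta), "gait": g.gait, "status": traj.status,
               "T": g.cycle_duration}
        if traj.ok:
            try:
                m = analyze(traj)
            except ValueError:
                row["status"] = "no_cycles"
                m = None
        else:
            m = None
        for attr in ("mean_speed", "stride", "work", "eta_plus", "eta_minus",
                     "cot", "cot_syn", "cot_height", "cot_speed",
                     "cot_active", "ipsilateral_lag"):
            row[attr] = getattr(m, attr) if m is not None else float("nan")
        if m is not None:
            for i, n in enumerate(TIP_NAMES):
                row[f"duty_{n}"] = m.duty_factors[i]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def run_io(traj: Trajectory, outdir, metrics: SteadyMetrics = None,
           downsample: int = 10) -> dict:
    """Write trajectory, events, per-cycle energetics, and the resolved
    configuration; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    frame = traj.to_frame().iloc[::downsample]
    paths["trajectory"] = outdir / "trajectory.csv"
    frame.to_csv(paths["trajectory"], index=False)
    paths["events"] = outdir / "events.csv"
    traj.events.to_csv(paths["events"], index=False)
    if metrics is not None:
        per_cycle = pd.DataFrame([dataclasses.asdict(r) for r in metrics.reports])
        paths["energetics"] = outdir / "energetics.csv"
        per_cycle.to_csv(paths["energetics"], index=False)
    paths["config"] = outdir / "config_resolved.yaml"
    save_config(traj.config, paths["config"])
    return paths


def sweep_io(df: pd.DataFrame, outdir) -> dict:
    """Write the sweep table as CSV plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"csv": outdir / "sweep.csv", "json": outdir / "sweep.json"}
    df.to_csv(paths["csv"], index=False)
    payload = {"columns": list(df.columns),
               "rows": json.loads(df.to_json(orient="records"))}
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
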