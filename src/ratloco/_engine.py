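"""Fused numba simulation loop.

One RK4 step advances the 134-dimensional continuous state

    y = [q (13), qd (13), a (26), a_syn (26), a_height (26), a_speed (26),
         phi (4)]

with motor commands held constant over the step (zero-order hold).  Per
step: sense girdle heights / speed and stance -> regulator commands into
the delay line -> read delayed commands -> synergy commands from the
oscillator phases with the beta-scaled schedule -> clamp -> RK4 -> wrap
phases, update contact anchors, log touchdown/liftoff events, ramp beta.

The three component activation sets (a_syn, a_height, a_speed) integrate
the same activation ODE driven by the individual command components; they
do not feed back on the dynamics and exist only for the cost-of-transport
decomposition.

Discrete contact state (anchor points, in-contact flags) is updated at step
boundaries; within a step the contact force is a smooth function of the
state, so the RK4 stages see a consistent vector field.
"""

import math

import numpy as np
from numba import njit

from ._kin import generalized_accel, tip_states

NM = 26      # muscles
NQ = 13
NY = 134     # continuous state dimension

# record column layout
REC_T = 0
REC_Q = 1
REC_QD = 14
REC_PHI = 27
REC_BETA = 31
REC_FZ = 32
REC_FX = 36
REC_ST = 40
REC_A = 44
REC_AS = 70
REC_AH = 96
REC_AV = 122
REC_LB = 148
REC_VB = 174
REC_F = 200
REC_W = 226

STATUS_OK = 0
STATUS_FELL = 1
STATUS_BLOWUP = 2

EV_LIFTOFF = 0
EV_TOUCHDOWN = 1

_CONTRA = np.array([1, 0, 3, 2], dtype=np.int64)
_IPSI = np.array([2, 3, 0, 1], dtype=np.int64)
_DSIGN = np.array([1.0, 1.0, -1.0, -1.0])

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def _muscle_kin(q, qd, nj, jq, dldq, lnat, qneutral, lbar, vbar):
    """Normalized lengths and contraction velocities of all muscles."""
    for m in range(NM):
        l = lnat[m]
        dl = 0.0
        for j in range(nj[m]):
            c = jq[m, j]
            l += dldq[m, j] * (q[c] - qneutral[c])
            dl += dldq[m, j] * qd[c]
        lbar[m] = l
        vbar[m] = -dl / 1.8


@njit(cache=True, inline="always")
def _fl(l, fl_width):
    x = (l - 1.0) / fl_width
    return math.exp(-x * x)


@njit(cache=True, inline="always")
def _fv(v, fv_shape, fv_ecc_slope, fv_ecc_cap):
    if v >= 0.0:
        if v >= 1.0:
            return 0.0
        return (1.0 - v) / (1.0 + v / fv_shape)
    e = 1.5 - 0.5 * (1.0 + v) / (1.0 - fv_ecc_slope * v)
    return e if e < fv_ecc_cap else fv_ecc_cap


@njit(cache=True, inline="always")
def _fp(l, fp_scale, fp_rate):
    if l <= 1.0:
        return 0.0
    return fp_scale * (math.exp(fp_rate * (l - 1.0)) - 1.0)


@njit(cache=True)
def _tensions(a, lbar, vbar, fmax,
              fl_width, fv_shape, fv_ecc_slope, fv_ecc_cap, fp_scale, fp_rate,
              out):
    for m in range(NM):
        am = a[m]
        if am < 0.0:
            am = 0.0
        elif am > 1.0:
            am = 1.0
        F = fmax[m] * (am * _fl(lbar[m], fl_width)
                       * _fv(vbar[m], fv_shape, fv_ecc_slope, fv_ecc_cap)
                       + _fp(lbar[m], fp_scale, fp_rate))
        out[m] = F if F > 0.0 else 0.0


@njit(cache=True, inline="always")
def _act_rate(a, u, tau_act, ratio):
    return (u - (ratio + (1.0 - ratio) * u) * a) / tau_act


@njit(cache=True)
def _deriv(y, u, uS, uH, uV, anchors, in_contact, T_cycle,
           # skeleton
           A, bvec, masses, inertias, com_idx, com_len, link_cols, link_ncols,
           tip_idx, tip_len, gravity,
           # contact
           kz, cz, kx, cx, mu, ground,
           # muscles
           fmax, nj, jq, dldq, matq, lnat, qneutral, tau_act, tau_ratio,
           fl_width, fv_shape, fv_ecc_slope, fv_ecc_cap, fp_scale, fp_rate,
           passive,
           # joint limits and passive joint viscosity
           qlim_lo, qlim_hi, k_lim, c_lim, b_visc,
           # cpg
           k1g, k2g, delta,
           dy):
    q = y[0:13]
    qd = y[13:26]
    a = y[26:52]
    aS = y[52:78]
    aH = y[78:104]
    aV = y[104:130]
    phi = y[130:134]

    tau = np.zeros(10)
    if not passive:
        lbar = np.empty(NM)
        vbar = np.empty(NM)
        F = np.empty(NM)
        _muscle_kin(q, qd, nj, jq, dldq, lnat, qneutral, lbar, vbar)
        _tensions(a, lbar, vbar, fmax, fl_width, fv_shape, fv_ecc_slope,
                  fv_ecc_cap, fp_scale, fp_rate, F)
        for m in range(NM):
            for j in range(nj[m]):
                tau[jq[m, j] - 3] += matq[m, j] * F[m]

    # passive joint viscosity (velocity-dependent passive tissue component)
    if b_visc > 0.0:
        for jj in range(3, 13):
            tau[jj - 3] -= b_visc * qd[jj]

    # one-sided viscoelastic joint limits (restoring torques only)
    if k_lim > 0.0:
        for jj in range(3, 13):
            if q[jj] > qlim_hi[jj]:
                tl = -k_lim * (q[jj] - qlim_hi[jj]) - c_lim * qd[jj]
                if tl < 0.0:
                    tau[jj - 3] += tl
            elif q[jj] < qlim_lo[jj]:
                tl = k_lim * (qlim_lo[jj] - q[jj]) - c_lim * qd[jj]
                if tl > 0.0:
                    tau[jj - 3] += tl

    pos, vel = tip_states(q, qd, A, bvec, tip_idx, tip_len)
    Ft = np.zeros((4, 2))
    for t in range(4):
        pen = ground - pos[t, 1]
        if pen > 0.0:
            fz = kz * pen - cz * vel[t, 1]
            if fz < 0.0:
                fz = 0.0
            Ft[t, 1] = fz
            if in_contact[t]:
                fx = kx * (anchors[t] - pos[t, 0]) - cx * vel[t, 0]
                cap = mu * fz
                if fx > cap:
                    fx = cap
                elif fx < -cap:
                    fx = -cap
                Ft[t, 0] = fx

    qdd = generalized_accel(q, qd, tau, Ft, A, bvec, masses, inertias,
                            com_idx, com_len, link_cols, link_ncols,
                            tip_idx, tip_len, gravity)

    for i in range(13):
        dy[i] = qd[i]
        dy[13 + i] = qdd[i]
    for m in range(NM):
        dy[26 + m] = _act_rate(a[m], u[m], tau_act, tau_ratio)
        dy[52 + m] = _act_rate(aS[m], uS[m], tau_act, tau_ratio)
        dy[78 + m] = _act_rate(aH[m], uH[m], tau_act, tau_ratio)
        dy[104 + m] = _act_rate(aV[m], uV[m], tau_act, tau_ratio)
    for o in range(4):
        dy[130 + o] = (TWO_PI / T_cycle
                       - k1g * math.sin(phi[o] - phi[_CONTRA[o]] - math.pi)
                       - k2g * math.sin(phi[o] - phi[_IPSI[o]] + _DSIGN[o] * delta))


@njit(cache=True)
def run(# skeleton tables
        A, bvec, masses, inertias, com_idx, com_len, link_cols, link_ncols,
        tip_idx, tip_len, gravity, d_sh, d_hip,
        # contact
        kz, cz, kx, cx, mu, ground,
        # muscles
        fmax, nj, jq, dldq, matq, lnat, qneutral, tau_act, tau_deact,
        fl_width, fv_shape, fv_ecc_slope, fv_ecc_cap, fp_scale, fp_rate,
        qlim_lo, qlim_hi, k_lim, c_lim, b_visc,
        osc_of, W_hat,
        # regulator
        kh, dh, kv, is_fore, h0s_hat, h0h_hat, v0_hat,
        alpha_sh, alpha_hip, alpha_spd, delay_steps,
        # cpg / gait
        k1g, k2g, delta, phi_hat, psi_hat, beta_hat, t_flex,
        # run control
        dt, n_steps, beta0, beta_target, ramp_rate, record_stride,
        passive, fall_pitch, fall_frac,
        # state and outputs (mutated in place)
        y, rec, ev_time, ev_tip, ev_kind):
    """Advance the coupled system n_steps; returns
    (status, n_records, n_events, final_beta)."""
    tau_ratio = tau_act / tau_deact
    beta = beta0
    n_rec = 0
    n_ev = 0
    ev_cap = ev_time.shape[0]

    anchors = np.zeros(4)
    in_contact = np.zeros(4, dtype=np.bool_)

    u = np.zeros(NM)
    uS = np.zeros(NM)
    uH = np.zeros(NM)
    uV = np.zeros(NM)

    D = delay_steps
    ring_ph = np.zeros((D + 1, NM))
    ring_pv = np.zeros((D + 1, NM))

    dy1 = np.empty(NY)
    dy2 = np.empty(NY)
    dy3 = np.empty(NY)
    dy4 = np.empty(NY)
    ytmp = np.empty(NY)

    Phi = np.empty(4)
    Psi = np.empty(4)
    lbar = np.empty(NM)
    vbar = np.empty(NM)
    Fmus = np.empty(NM)
    fz = np.empty(4)
    fx = np.empty(4)
    stance = np.zeros(4, dtype=np.bool_)

    status = STATUS_OK

    for step in range(n_steps):
        t = step * dt
        q = y[0:13]
        qd = y[13:26]

        # --- contact bookkeeping and stance detection -----------------------
        pos, vel = tip_states(q, qd, A, bvec, tip_idx, tip_len)
        for tp in range(4):
            pen = ground - pos[tp, 1]
            if pen > 0.0 and not in_contact[tp]:
                in_contact[tp] = True
                anchors[tp] = pos[tp, 0]
                if n_ev < ev_cap:
                    ev_time[n_ev] = t
                    ev_tip[n_ev] = tp
                    ev_kind[n_ev] = EV_TOUCHDOWN
                    n_ev += 1
            elif pen <= 0.0 and in_contact[tp]:
                in_contact[tp] = False
                if n_ev < ev_cap:
                    ev_time[n_ev] = t
                    ev_tip[n_ev] = tp
                    ev_kind[n_ev] = EV_LIFTOFF
                    n_ev += 1
            f = 0.0
            fh = 0.0
            if pen > 0.0:
                f = kz * pen - cz * vel[tp, 1]
                if f < 0.0:
                    f = 0.0
                if in_contact[tp]:
                    fh = kx * (anchors[tp] - pos[tp, 0]) - cx * vel[tp, 0]
                    cap = mu * f
                    if fh > cap or fh < -cap:
                        # friction cone saturated: slide the anchor so the
                        # spring holds exactly the capped force
                        if fh > cap:
                            fh = cap
                        else:
                            fh = -cap
                        if kx > 0.0:
                            anchors[tp] = pos[tp, 0] + (fh + cx * vel[tp, 0]) / kx
            fz[tp] = f
            fx[tp] = fh
            stance[tp] = f > 0.0

        # --- beta-dependent quantities --------------------------------------
        T_cycle = t_flex / (1.0 - beta)
        ext = beta / beta_hat
        flx = (1.0 - beta) / (1.0 - beta_hat)
        shift = TWO_PI * (beta - beta_hat) / (1.0 - beta_hat)
        for i in range(2):
            Phi[i] = ext * phi_hat[i]
            Psi[i] = ext * psi_hat[i]
        for i in range(2, 4):
            Phi[i] = flx * phi_hat[i] + shift
            Psi[i] = flx * psi_hat[i] + shift
        h0s = h0s_hat + alpha_sh * (beta - beta_hat)
        h0h = h0h_hat + alpha_hip * (beta - beta_hat)
        v0 = v0_hat + alpha_spd * (beta - beta_hat)

        # --- regulator: sense, command, delay -------------------------------
        slot = step % (D + 1)
        rd = (step - D) % (D + 1)
        hS = q[1] + d_sh * math.sin(q[2])
        hH = q[1] + d_hip * math.sin(q[2])
        hSd = qd[1] + d_sh * math.cos(q[2]) * qd[2]
        hHd = qd[1] + d_hip * math.cos(q[2]) * qd[2]
        v = qd[0]
        for m in range(NM):
            ph = 0.0
            pv = 0.0
            if stance[osc_of[m]]:
                if kh[m] != 0.0 or dh[m] != 0.0:
                    if is_fore[m]:
                        ph = -kh[m] * (hS - h0s) - dh[m] * hSd
                    else:
                        ph = -kh[m] * (hH - h0h) - dh[m] * hHd
                if kv[m] != 0.0:
                    pv = -kv[m] * (v - v0)
            ring_ph[slot, m] = ph
            ring_pv[slot, m] = pv

        # --- motor commands (zero-order hold over the step) ------------------
        phi = y[130:134]
        for m in range(NM):
            ph_m = phi[osc_of[m]] % TWO_PI
            us = 0.0
            for i in range(4):
                if Phi[i] <= ph_m < Psi[i]:
                    w = W_hat[m, i]
                    if i < 2:
                        w *= flx
                    us += w
            if step >= D:
                uh = ring_ph[rd, m]
                uv = ring_pv[rd, m]
            else:
                uh = 0.0
                uv = 0.0
            if passive:
                us = 0.0
                uh = 0.0
                uv = 0.0
            tot = us + uh + uv
            u[m] = min(max(tot, 0.0), 1.0)
            uS[m] = min(max(us, 0.0), 1.0)
            uH[m] = min(max(uh, 0.0), 1.0)
            uV[m] = min(max(uv, 0.0), 1.0)

        # --- record ----------------------------------------------------------
        if step % record_stride == 0:
            _muscle_kin(q, qd, nj, jq, dldq, lnat, qneutral, lbar, vbar)
            _tensions(y[26:52], lbar, vbar, fmax, fl_width, fv_shape,
                      fv_ecc_slope, fv_ecc_cap, fp_scale, fp_rate, Fmus)
            if passive:
                for m in range(NM):
                    Fmus[m] = 0.0
            r = rec[n_rec]
            r[REC_T] = t
            for i in range(13):
                r[REC_Q + i] = q[i]
                r[REC_QD + i] = qd[i]
            for o in range(4):
                r[REC_PHI + o] = phi[o] % TWO_PI
                r[REC_FZ + o] = fz[o]
                r[REC_FX + o] = fx[o]
                r[REC_ST + o] = 1.0 if stance[o] else 0.0
            r[REC_BETA] = beta
            for m in range(NM):
                r[REC_A + m] = y[26 + m]
                r[REC_AS + m] = y[52 + m]
                r[REC_AH + m] = y[78 + m]
                r[REC_AV + m] = y[104 + m]
                r[REC_LB + m] = lbar[m]
                r[REC_VB + m] = vbar[m]
                r[REC_F + m] = Fmus[m]
            n_rec += 1

        # --- RK4 -------------------------------------------------------------
        _deriv(y, u, uS, uH, uV, anchors, in_contact, T_cycle,
               A, bvec, masses, inertias, com_idx, com_len, link_cols,
               link_ncols, tip_idx, tip_len, gravity, kz, cz, kx, cx, mu,
               ground,
               fmax, nj, jq, dldq, matq, lnat, qneutral, tau_act, tau_ratio,
               fl_width, fv_shape, fv_ecc_slope, fv_ecc_cap, fp_scale,
               fp_rate, passive, qlim_lo, qlim_hi, k_lim, c_lim, b_visc,
               k1g, k2g, delta, dy1)
        for i in range(NY):
            ytmp[i] = y[i] + 0.5 * dt * dy1[i]
        _deriv(ytmp, u, uS, uH, uV, anchors, in_contact, T_cycle,
               A, bvec, masses, inertias, com_idx, com_len, link_cols,
               link_ncols, tip_idx, tip_len, gravity, kz, cz, kx, cx, mu,
               ground,
               fmax, nj, jq, dldq, matq, lnat, qneutral, tau_act, tau_ratio,
               fl_width, fv_shape, fv_ecc_slope, fv_ecc_cap, fp_scale,
               fp_rate, passive, qlim_lo, qlim_hi, k_lim, c_lim, b_visc,
               k1g, k2g, delta, dy2)
        for i in range(NY):
            ytmp[i] = y[i] + 0.5 * dt * dy2[i]
        _deriv(ytmp, u, uS, uH, uV, anchors, in_contact, T_cycle,
               A, bvec, masses, inertias, com_idx, com_len, link_cols,
               link_ncols, tip_idx, tip_len, gravity, kz, cz, kx, cx, mu,
               ground,
               fmax, nj, jq, dldq, matq, lnat, qneutral, tau_act, tau_ratio,
               fl_width, fv_shape, fv_ecc_slope, fv_ecc_cap, fp_scale,
               fp_rate, passive, qlim_lo, qlim_hi, k_lim, c_lim, b_visc,
               k1g, k2g, delta, dy3)
        for i in range(NY):
            ytmp[i] = y[i] + dt * dy3[i]
        _deriv(ytmp, u, uS, uH, uV, anchors, in_contact, T_cycle,
               A, bvec, masses, inertias, com_idx, com_len, link_cols,
               link_ncols, tip_idx, tip_len, gravity, kz, cz, kx, cx, mu,
               ground,
               fmax, nj, jq, dldq, matq, lnat, qneutral, tau_act, tau_ratio,
               fl_width, fv_shape, fv_ecc_slope, fv_ecc_cap, fp_scale,
               fp_rate, passive, qlim_lo, qlim_hi, k_lim, c_lim, b_visc,
               k1g, k2g, delta, dy4)
        for i in range(NY):
            y[i] += dt / 6.0 * (dy1[i] + 2.0 * dy2[i] + 2.0 * dy3[i] + dy4[i])

        # --- post-step housekeeping ------------------------------------------
        for o in range(4):
            y[130 + o] = y[130 + o] % TWO_PI
        for m in range(NM):
            for base in (26, 52, 78, 104):
                am = y[base + m]
                if am < 0.0:
                    y[base + m] = 0.0
                elif am > 1.0:
                    y[base + m] = 1.0

        # beta ramp (quasi-static, bounded change per gait cycle)
        if beta != beta_target:
            db = ramp_rate * dt / T_cycle
            if beta < beta_target:
                beta = min(beta + db, beta_target)
            else:
                beta = max(beta - db, beta_target)

        # failure checks
        bad = False
        for i in range(26):
            if not math.isfinite(y[i]):
                bad = True
                break
        if not bad:
            for i in range(13, 26):
                if abs(y[i]) > 1.0e4:
                    bad = True
                    break
        if bad:
            status = STATUS_BLOWUP
            break
        if not passive:
            hS_new = y[1] + d_sh * math.sin(y[2])
            hH_new = y[1] + d_hip * math.sin(y[2])
            if (abs(y[2]) > fall_pitch
                    or hS_new < fall_frac * h0s
                    or hH_new < fall_frac * h0h):
                status = STATUS_FELL
                break

    return status, n_rec, n_ev, beta
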