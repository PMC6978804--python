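"""Numba kernels for the planar linkage: kinematics, mass matrix, and the
equations of motion.

The 13 generalized coordinates are
    q = [x, z, pitch,
         L shoulder, L elbow, R shoulder, R elbow,
         L hip, L knee, L ankle, R hip, R knee, R ankle]
with (x, z) the trunk centre of mass, pitch positive nose-up, and all
joint angles extensor-positive.

Every link's absolute orientation is an affine function alpha = A q + b of
the coordinates, so the angular Jacobians are constant and the only
velocity-product terms in the equations of motion are centripetal terms of
the translational Jacobians.  The generalized accelerations solve

    M(q) qdd = Q_applied + Q_gravity - C(q, qd)

assembled link by link from Jacobian-transpose projections (equivalent to
the Lagrangian equations; verified against a finite-difference Lagrangian
oracle in the test suite).
"""

import math

import numpy as np
from numba import njit

NQ = 13      # generalized coordinates
NL = 11      # rigid links
NTIP = 4     # limb tips, order LF, RF, LH, RH
MAXSEG = 4   # longest kinematic path (trunk offset + 3 limb links)
MAXCOL = 7   # x, z, pitch + at most 3 joint angles (padded)


@njit(cache=True)
def link_alphas(A, b, q):
    """Absolute link angles (rad), one per link."""
    return A @ q + b


@njit(cache=True)
def _point_path(q, ca, sa, path_idx, path_len):
    """Position of a path endpoint: (x, z) + sum of segment vectors."""
    px = q[0]
    pz = q[1]
    for s in range(MAXSEG):
        ai = path_idx[s]
        if ai < 0:
            break
        px += path_len[s] * ca[ai]
        pz += path_len[s] * sa[ai]
    return px, pz


@njit(cache=True)
def _point_vel_path(qd, ca, sa, ad, path_idx, path_len):
    vx = qd[0]
    vz = qd[1]
    for s in range(MAXSEG):
        ai = path_idx[s]
        if ai < 0:
            break
        vx += -path_len[s] * ad[ai] * sa[ai]
        vz += path_len[s] * ad[ai] * ca[ai]
    return vx, vz


@njit(cache=True)
def tip_states(q, qd, A, b, tip_idx, tip_len):
    """Positions and velocities of the four limb tips: (4,2) arrays."""
    alpha = link_alphas(A, b, q)
    ad = A @ qd
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    pos = np.empty((NTIP, 2))
    vel = np.empty((NTIP, 2))
    for t in range(NTIP):
        px, pz = _point_path(q, ca, sa, tip_idx[t], tip_len[t])
        vx, vz = _point_vel_path(qd, ca, sa, ad, tip_idx[t], tip_len[t])
        pos[t, 0] = px
        pos[t, 1] = pz
        vel[t, 0] = vx
        vel[t, 1] = vz
    return pos, vel


@njit(cache=True)
def link_com_states(q, qd, A, b, com_idx, com_len):
    """CoM positions/velocities of the 11 links plus angles and rates."""
    alpha = link_alphas(A, b, q)
    ad = A @ qd
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    pos = np.empty((NL, 2))
    vel = np.empty((NL, 2))
    for i in range(NL):
        px, pz = _point_path(q, ca, sa, com_idx[i], com_len[i])
        vx, vz = _point_vel_path(qd, ca, sa, ad, com_idx[i], com_len[i])
        pos[i, 0] = px
        pos[i, 1] = pz
        vel[i, 0] = vx
        vel[i, 1] = vz
    return pos, vel, alpha, ad


@njit(cache=True)
def _cholesky_solve(M, rhs):
    """Solve M x = rhs for symmetric positive-definite M (in place copy)."""
    n = M.shape[0]
    L = M.copy()
    x = rhs.copy()
    for j in range(n):
        d = L[j, j]
        for k in range(j):
            d -= L[j, k] * L[j, k]
        d = math.sqrt(d)
        L[j, j] = d
        inv = 1.0 / d
        for i in range(j + 1, n):
            s = L[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            L[i, j] = s * inv
    for i in range(n):
        s = x[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, n):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def mass_matrix(q, A, b, masses, inertias, com_idx, com_len, link_cols, link_ncols):
    """Joint-space inertia matrix M(q), 13 x 13, symmetric positive definite."""
    alpha = A @ q + b
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    M = np.zeros((NQ, NQ))
    jx = np.zeros(MAXCOL)
    jz = np.zeros(MAXCOL)
    for i in range(NL):
        nc = link_ncols[i]
        # translational Jacobian, compact over this link's support columns
        for k in range(nc):
            c = link_cols[i, k]
            if c == 0:
                jx[k] = 1.0
                jz[k] = 0.0
            elif c == 1:
                jx[k] = 0.0
                jz[k] = 1.0
            else:
                gx = 0.0
                gz = 0.0
                for s in range(MAXSEG):
                    ai = com_idx[i, s]
                    if ai < 0:
                        break
                    w = A[ai, c]
                    if w != 0.0:
                        gx += -com_len[i, s] * w * sa[ai]
                        gz += com_len[i, s] * w * ca[ai]
                jx[k] = gx
                jz[k] = gz
        mi = masses[i]
        Ii = inertias[i]
        for a_ in range(nc):
            cA = link_cols[i, a_]
            for b_ in range(a_, nc):
                cB = link_cols[i, b_]
                v = mi * (jx[a_] * jx[b_] + jz[a_] * jz[b_])
                if cA >= 2 and cB >= 2:
                    v += Ii * A[i, cA] * A[i, cB]
                M[cA, cB] += v
    for r in range(NQ):
        for c in range(r + 1, NQ):
            M[c, r] = M[r, c]
    return M


@njit(cache=True)
def generalized_accel(q, qd, joint_torques, tip_forces,
                      A, b, masses, inertias, com_idx, com_len,
                      link_cols, link_ncols, tip_idx, tip_len, gravity):
    """Forward dynamics: solve M qdd = Q for the 13 accelerations.

    joint_torques: 10 entries (extensor-positive), ordered as q[3:].
    tip_forces: (4, 2) planar forces applied at the limb tips.
    """
    alpha = A @ q + b
    ad = A @ qd
    ca = np.cos(alpha)
    sa = np.sin(alpha)
    M = np.zeros((NQ, NQ))
    rhs = np.zeros(NQ)
    jx = np.zeros(MAXCOL)
    jz = np.zeros(MAXCOL)
    for i in range(NL):
        nc = link_ncols[i]
        for k in range(nc):
            c = link_cols[i, k]
            if c == 0:
                jx[k] = 1.0
                jz[k] = 0.0
            elif c == 1:
                jx[k] = 0.0
                jz[k] = 1.0
            else:
                gx = 0.0
                gz = 0.0
                for s in range(MAXSEG):
                    ai = com_idx[i, s]
                    if ai < 0:
                        break
                    w = A[ai, c]
                    if w != 0.0:
                        gx += -com_len[i, s] * w * sa[ai]
                        gz += com_len[i, s] * w * ca[ai]
                jx[k] = gx
                jz[k] = gz
        mi = masses[i]
        Ii = inertias[i]
        # centripetal acceleration of the CoM with qdd = 0
        ax = 0.0
        az = 0.0
        for s in range(MAXSEG):
            ai = com_idx[i, s]
            if ai < 0:
                break
            w2 = ad[ai] * ad[ai]
            ax -= com_len[i, s] * w2 * ca[ai]
            az -= com_len[i, s] * w2 * sa[ai]
        for a_ in range(nc):
            cA = link_cols[i, a_]
            for b_ in range(a_, nc):
                cB = link_cols[i, b_]
                v = mi * (jx[a_] * jx[b_] + jz[a_] * jz[b_])
                if cA >= 2 and cB >= 2:
                    v += Ii * A[i, cA] * A[i, cB]
                M[cA, cB] += v
            # bias (Coriolis/centrifugal) and gravity projections
            rhs[cA] += -mi * (jx[a_] * ax + jz[a_] * az) - mi * gravity * jz[a_]
    for r in range(NQ):
        for c in range(r + 1, NQ):
            M[c, r] = M[r, c]
    for j in range(10):
        rhs[3 + j] += joint_torques[j]
    # external tip forces through the tip Jacobians
    for t in range(NTIP):
        fx = tip_forces[t, 0]
        fz = tip_forces[t, 1]
        if fx == 0.0 and fz == 0.0:
            continue
        rhs[0] += fx
        rhs[1] += fz
        for c in range(2, NQ):
            gx = 0.0
            gz = 0.0
            for s in range(MAXSEG):
                ai = tip_idx[t, s]
                if ai < 0:
                    break
                w = A[ai, c]
                if w != 0.0:
                    gx += -tip_len[t, s] * w * sa[ai]
                    gz += tip_len[t, s] * w * ca[ai]
            rhs[c] += gx * fx + gz * fz
    return _cholesky_solve(M, rhs)


@njit(cache=True)
def contact_forces_kernel(tip_pos, tip_vel, anchors, in_contact,
                          kz, cz, kx, cx, mu, ground):
    """Per-tip planar ground forces: (4,2) array, columns (Fx, Fz).

    Vertical: spring-damper on penetration, clamped nonnegative (never
    adhesive).  Horizontal: spring-damper to the touchdown anchor, capped
    by the Coulomb cone |Fx| <= mu * Fz; only while the tip penetrates and
    an anchor is planted.
    """
    F = np.zeros((NTIP, 2))
    for t in range(NTIP):
        pen = ground - tip_pos[t, 1]
        if pen <= 0.0:
            continue
        fz = kz * pen - cz * tip_vel[t, 1]
        if fz < 0.0:
            fz = 0.0
        F[t, 1] = fz
        if in_contact[t]:
            fx = kx * (anchors[t] - tip_pos[t, 0]) - cx * tip_vel[t, 0]
            cap = mu * fz
            if fx > cap:
                fx = cap
            elif fx < -cap:
                fx = -cap
            F[t, 0] = fx
    return F


@njit(cache=True)
def mechanical_energy(q, qd, A, b, masses, inertias, com_idx, com_len, gravity):
    """Kinetic plus gravitational potential energy of all links (J)."""
    pos, vel, alpha, ad = link_com_states(q, qd, A, b, com_idx, com_len)
    e = 0.0
    for i in range(NL):
        e += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2)
        e += 0.5 * inertias[i] * ad[i] ** 2
        e += masses[i] * gravity * pos[i, 1]
    return e
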