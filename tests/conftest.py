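"""Shared fixtures and the independent Lagrangian oracle.

The oracle computes generalized accelerations purely from finite
differences of an independently coded Lagrangian (complex-number forward
kinematics), never touching the package's dynamics tables.
"""

import math

import numpy as np
import pytest

from ratloco import SimConfig, build_skeleton
from ratloco.params import SkeletonParams


@pytest.fixture(scope="session")
def model():
    return build_skeleton(SkeletonParams())


@pytest.fixture(scope="session")
def config():
    return SimConfig()


def independent_link_states(P, q, qd):
    """(mass, inertia, CoM position, CoM velocity, angle, rate) per link,
    from explicit per-limb chain geometry written independently of the
    package's kinematic tables."""
    x, z, th = q[0], q[1], q[2]
    vx, vz, w = qd[0], qd[1], qd[2]
    out = []
    trunk = complex(x, z)
    vtrunk = complex(vx, vz)
    out.append((P.trunk.mass, P.trunk.inertia, trunk, vtrunk, th, w))
    u_t = complex(math.cos(th), math.sin(th))
    sh = trunk + P.shoulder_offset * u_t
    vsh = vtrunk + P.shoulder_offset * w * 1j * u_t
    hp = trunk + P.hip_offset * u_t
    vhp = vtrunk + P.hip_offset * w * 1j * u_t
    for ish, iel in ((3, 4), (5, 6)):
        a1 = th + q[ish] - 7 * math.pi / 6
        a1d = w + qd[ish]
        a2 = a1 - (q[iel] - math.pi)
        a2d = a1d - qd[iel]
        u1 = complex(math.cos(a1), math.sin(a1))
        u2 = complex(math.cos(a2), math.sin(a2))
        c1 = sh + P.brachium.com * u1
        v1 = vsh + P.brachium.com * a1d * 1j * u1
        out.append((P.brachium.mass, P.brachium.inertia, c1, v1, a1, a1d))
        el = sh + P.brachium.length * u1
        vel = vsh + P.brachium.length * a1d * 1j * u1
        c2 = el + P.antebrachium.com * u2
        v2 = vel + P.antebrachium.com * a2d * 1j * u2
        out.append((P.antebrachium.mass, P.antebrachium.inertia, c2, v2, a2, a2d))
    for ihp, ikn, ian in ((7, 8, 9), (10, 11, 12)):
        a1 = th - q[ihp] + math.pi / 6
        a1d = w - qd[ihp]
        a2 = a1 + (q[ikn] - math.pi)
        a2d = a1d + qd[ikn]
        a3 = a2 - (q[ian] - math.pi)
        a3d = a2d - qd[ian]
        u1 = complex(math.cos(a1), math.sin(a1))
        u2 = complex(math.cos(a2), math.sin(a2))
        u3 = complex(math.cos(a3), math.sin(a3))
        c1 = hp + P.thigh.com * u1
        v1 = vhp + P.thigh.com * a1d * 1j * u1
        out.append((P.thigh.mass, P.thigh.inertia, c1, v1, a1, a1d))
        kn = hp + P.thigh.length * u1
        vkn = vhp + P.thigh.length * a1d * 1j * u1
        c2 = kn + P.shank.com * u2
        v2 = vkn + P.shank.com * a2d * 1j * u2
        out.append((P.shank.mass, P.shank.inertia, c2, v2, a2, a2d))
        an = kn + P.shank.length * u2
        van = vkn + P.shank.length * a2d * 1j * u2
        c3 = an + P.foot.com * u3
        v3 = van + P.foot.com * a3d * 1j * u3
        out.append((P.foot.mass, P.foot.inertia, c3, v3, a3, a3d))
    return out


def independent_lagrangian(P, q, qd):
    L = 0.0
    for m, I, pos, vel, a, ad in independent_link_states(P, q, qd):
        L += 0.5 * m * (vel.real ** 2 + vel.imag ** 2) + 0.5 * I * ad * ad \
            - m * P.gravity * pos.imag
    return L


def oracle_accelerations(P, q, qd, Q):
    """Finite-difference Lagrangian accelerations.

    The Lagrangian is quadratic in the rates, so the second differences in
    qd are exact for any step; large steps avoid cancellation against the
    small distal inertias.
    """
    n = 13
    L = lambda qq, dd: independent_lagrangian(P, qq, dd)
    M = np.zeros((n, n))
    hh = 1.0
    for i in range(n):
        for j in range(i, n):
            dp = qd.copy(); dp[i] += hh; dp[j] += hh
            dm = qd.copy(); dm[i] -= hh; dm[j] -= hh
            da = qd.copy(); da[i] += hh; da[j] -= hh
            db = qd.copy(); db[i] -= hh; db[j] += hh
            M[i, j] = M[j, i] = (L(q, dp) + L(q, dm) - L(q, da) - L(q, db)) / (4 * hh * hh)
    hq = 1e-5
    dLdq = np.zeros(n)
    for i in range(n):
        qp = q.copy(); qp[i] += hq
        qm = q.copy(); qm[i] -= hq
        dLdq[i] = (L(qp, qd) - L(qm, qd)) / (2 * hq)
    G = np.zeros((n, n))
    hv = 1.0
    for i in range(n):
        dp = qd.copy(); dp[i] += hv
        dm = qd.copy(); dm[i] -= hv
        for j in range(n):
            qp = q.copy(); qp[j] += hq
            qm = q.copy(); qm[j] -= hq
            G[i, j] = (L(qp, dp) - L(qp, dm) - L(qm, dp) + L(qm, dm)) / (4 * hv * hq)
    return np.linalg.solve(M, Q + dLdq - G @ qd)
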