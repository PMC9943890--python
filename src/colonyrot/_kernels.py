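"""Fused numba kernel for the hybrid LB / finite-difference update.

Implements exactly the step sequence of :func:`colonyrot.simulate.step_once`
(molecular field -> stress divergence -> BGK collide-stream with Guo
forcing -> finite-difference substeps of Q and phi) as one jitted loop
over lattice nodes; a test asserts agreement with the NumPy reference
path.  Only the default 5-point stencil is supported here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .lb import MACH_LIMIT
from .qtensor import Q_BLOWUP_BOUND
from .cahn_hilliard import PHI_BLOWUP_BOUND

_CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
_CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
_W = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9,
               1 / 36, 1 / 36, 1 / 36, 1 / 36])

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_MACH = 2


@njit(cache=True)
def _evolve(f, phi, qxx, qxy, ux, uy, rho, n_steps,
            c_bulk, b_well, k_phi, k_frank, gamma, gamma_phi, lam, zeta,
            tau_lb, n_sub, active_phi):
    nx, ny = phi.shape
    ip = np.empty(nx, np.int64)
    im = np.empty(nx, np.int64)
    jp = np.empty(ny, np.int64)
    jm = np.empty(ny, np.int64)
    for i in range(nx):
        ip[i] = (i + 1) % nx
        im[i] = (i - 1) % nx
    for j in range(ny):
        jp[j] = (j + 1) % ny
        jm[j] = (j - 1) % ny

    hxx = np.empty((nx, ny))
    hxy = np.empty((nx, ny))
    mu = np.empty((nx, ny))
    pxx = np.empty((nx, ny))
    pxy = np.empty((nx, ny))
    pyx = np.empty((nx, ny))
    pyy = np.empty((nx, ny))
    fx = np.empty((nx, ny))
    fy = np.empty((nx, ny))
    exx = np.empty((nx, ny))
    exy = np.empty((nx, ny))
    eyy = np.empty((nx, ny))
    om = np.empty((nx, ny))
    fpost = np.empty_like(f)
    qxx_n = np.empty((nx, ny))
    qxy_n = np.empty((nx, ny))
    phi_n = np.empty((nx, ny))

    dt_sub = 1.0 / n_sub

    for _step in range(n_steps):
        # --- molecular field from current fields ---
        for i in range(nx):
            for j in range(ny):
                lap_qxx = (qxx[ip[i], j] + qxx[im[i], j] + qxx[i, jp[j]]
                           + qxx[i, jm[j]] - 4.0 * qxx[i, j])
                lap_qxy = (qxy[ip[i], j] + qxy[im[i], j] + qxy[i, jp[j]]
                           + qxy[i, jm[j]] - 4.0 * qxy[i, j])
                trqq = 2.0 * (qxx[i, j] ** 2 + qxy[i, j] ** 2)
                amp = c_bulk * (1.0 + 0.5 * trqq)
                hxx[i, j] = -amp * qxx[i, j] + k_frank * lap_qxx
                hxy[i, j] = -amp * qxy[i, j] + k_frank * lap_qxy

        # --- passive elastic + active stress ---
        for i in range(nx):
            for j in range(ny):
                q1 = qxx[i, j]
                q2 = qxy[i, j]
                h1 = hxx[i, j]
                h2 = hxy[i, j]
                zloc = zeta * phi[i, j] if active_phi else zeta
                axx = q1 + 0.5
                axy = q2
                ayy = -q1 + 0.5
                tr_qh = 2.0 * (q1 * h1 + q2 * h2)
                ha_xx = h1 * axx + h2 * axy
                ha_xy = h1 * axy + h2 * ayy
                ha_yx = h2 * axx - h1 * axy
                ha_yy = h2 * axy - h1 * ayy
                ah_xx = axx * h1 + axy * h2
                ah_xy = axx * h2 - axy * h1
                ah_yx = axy * h1 + ayy * h2
                ah_yy = axy * h2 - ayy * h1
                anti_xy = 2.0 * (q1 * h2 - q2 * h1)
                gx_qxx = 0.5 * (qxx[ip[i], j] - qxx[im[i], j])
                gy_qxx = 0.5 * (qxx[i, jp[j]] - qxx[i, jm[j]])
                gx_qxy = 0.5 * (qxy[ip[i], j] - qxy[im[i], j])
                gy_qxy = 0.5 * (qxy[i, jp[j]] - qxy[i, jm[j]])
                er_xx = 2.0 * (gx_qxx * gx_qxx + gx_qxy * gx_qxy)
                er_xy = 2.0 * (gx_qxx * gy_qxx + gx_qxy * gy_qxy)
                er_yy = 2.0 * (gy_qxx * gy_qxx + gy_qxy * gy_qxy)
                pxx[i, j] = (2.0 * lam * axx * tr_qh - lam * (ha_xx + ah_xx)
                             - k_frank * er_xx + zloc * q1)
                pyy[i, j] = (2.0 * lam * ayy * tr_qh - lam * (ha_yy + ah_yy)
                             - k_frank * er_yy - zloc * q1)
                pxy[i, j] = (2.0 * lam * axy * tr_qh - lam * (ha_xy + ah_xy)
                             + anti_xy - k_frank * er_xy + zloc * q2)
                pyx[i, j] = (2.0 * lam * axy * tr_qh - lam * (ha_yx + ah_yx)
                             - anti_xy - k_frank * er_xy + zloc * q2)

        # --- body force F_j = d_i Pi_ij ---
        for i in range(nx):
            for j in range(ny):
                fx[i, j] = (0.5 * (pxx[ip[i], j] - pxx[im[i], j])
                            + 0.5 * (pyx[i, jp[j]] - pyx[i, jm[j]]))
                fy[i, j] = (0.5 * (pxy[ip[i], j] - pxy[im[i], j])
                            + 0.5 * (pyy[i, jp[j]] - pyy[i, jm[j]]))

        # --- Mach guard ---
        for i in range(nx):
            for j in range(ny):
                if abs(ux[i, j]) > MACH_LIMIT or abs(uy[i, j]) > MACH_LIMIT:
                    return STATUS_MACH

        # --- BGK collide + Guo forcing ---
        pref = 1.0 - 0.5 / tau_lb
        for i in range(nx):
            for j in range(ny):
                u1 = ux[i, j]
                u2 = uy[i, j]
                r = rho[i, j]
                usq = u1 * u1 + u2 * u2
                for k in range(9):
                    cu = _CX[k] * u1 + _CY[k] * u2
                    feq = _W[k] * r * (1.0 + 3.0 * cu + 4.5 * cu * cu
                                       - 1.5 * usq)
                    gfx = 3.0 * (_CX[k] - u1) + 9.0 * cu * _CX[k]
                    gfy = 3.0 * (_CY[k] - u2) + 9.0 * cu * _CY[k]
                    src = pref * _W[k] * (gfx * fx[i, j] + gfy * fy[i, j])
                    fpost[k, i, j] = (f[k, i, j]
                                      - (f[k, i, j] - feq) / tau_lb + src)

        # --- streaming (periodic) ---
        for k in range(9):
            cx = _CX[k]
            cy = _CY[k]
            for i in range(nx):
                si = (i - cx) % nx
                for j in range(ny):
                    f[k, i, j] = fpost[k, si, (j - cy) % ny]

        # --- moments with half-force correction ---
        for i in range(nx):
            for j in range(ny):
                r = 0.0
                mx = 0.0
                my = 0.0
                for k in range(9):
                    r += f[k, i, j]
                    mx += _CX[k] * f[k, i, j]
                    my += _CY[k] * f[k, i, j]
                rho[i, j] = r
                ux[i, j] = (mx + 0.5 * fx[i, j]) / r
                uy[i, j] = (my + 0.5 * fy[i, j]) / r

        # --- strain rate and vorticity of the frozen velocity ---
        for i in range(nx):
            for j in range(ny):
                dxux = 0.5 * (ux[ip[i], j] - ux[im[i], j])
                dxuy = 0.5 * (uy[ip[i], j] - uy[im[i], j])
                dyux = 0.5 * (ux[i, jp[j]] - ux[i, jm[j]])
                dyuy = 0.5 * (uy[i, jp[j]] - uy[i, jm[j]])
                exx[i, j] = dxux
                exy[i, j] = 0.5 * (dxuy + dyux)
                eyy[i, j] = dyuy
                om[i, j] = 0.5 * (dxuy - dyux)

        # --- finite-difference substeps of Q and phi ---
        for _sub in range(n_sub):
            for i in range(nx):
                for j in range(ny):
                    q1 = qxx[i, j]
                    q2 = qxy[i, j]
                    # molecular field and chemical potential
                    lap_qxx = (qxx[ip[i], j] + qxx[im[i], j] + qxx[i, jp[j]]
                               + qxx[i, jm[j]] - 4.0 * q1)
                    lap_qxy = (qxy[ip[i], j] + qxy[im[i], j] + qxy[i, jp[j]]
                               + qxy[i, jm[j]] - 4.0 * q2)
                    trqq = 2.0 * (q1 * q1 + q2 * q2)
                    amp = c_bulk * (1.0 + 0.5 * trqq)
                    h1 = -amp * q1 + k_frank * lap_qxx
                    h2 = -amp * q2 + k_frank * lap_qxy
                    ph = phi[i, j]
                    lap_phi = (phi[ip[i], j] + phi[im[i], j] + phi[i, jp[j]]
                               + phi[i, jm[j]] - 4.0 * ph)
                    mu[i, j] = (b_well * ph * (1.0 - ph) * (1.0 - 2.0 * ph)
                                - 2.0 * k_phi * lap_phi)

                    # generalized advection W
                    e1 = exx[i, j]
                    e2 = exy[i, j]
                    e3 = eyy[i, j]
                    w0 = om[i, j]
                    axx = q1 + 0.5
                    axy = q2
                    ayy = -q1 + 0.5
                    le1 = lam * e1
                    le2 = lam * e2
                    le3 = lam * e3
                    m1xx = le1 * axx + (le2 - w0) * axy
                    m1xy = le1 * axy + (le2 - w0) * ayy
                    m1yx = (le2 + w0) * axx + le3 * axy
                    m1yy = (le2 + w0) * axy + le3 * ayy
                    m2xx = axx * le1 + axy * (le2 - w0)
                    m2xy = axx * (le2 + w0) + axy * le3
                    m2yx = axy * le1 + ayy * (le2 - w0)
                    m2yy = axy * (le2 + w0) + ayy * le3
                    tr_qe = q1 * (e1 - e3) + 2.0 * q2 * e2
                    wxx = m1xx + m2xx - 2.0 * lam * axx * tr_qe
                    wyy = m1yy + m2yy - 2.0 * lam * ayy * tr_qe
                    wxy = 0.5 * ((m1xy + m2xy) + (m1yx + m2yx))
                    w_xx = 0.5 * (wxx - wyy)

                    # advection u . grad
                    u1 = ux[i, j]
                    u2 = uy[i, j]
                    adv_qxx = (u1 * 0.5 * (qxx[ip[i], j] - qxx[im[i], j])
                               + u2 * 0.5 * (qxx[i, jp[j]] - qxx[i, jm[j]]))
                    adv_qxy = (u1 * 0.5 * (qxy[ip[i], j] - qxy[im[i], j])
                               + u2 * 0.5 * (qxy[i, jp[j]] - qxy[i, jm[j]]))

                    qxx_n[i, j] = q1 + dt_sub * (-adv_qxx + w_xx + gamma * h1)
                    qxy_n[i, j] = q2 + dt_sub * (-adv_qxy + wxy + gamma * h2)

            for i in range(nx):
                for j in range(ny):
                    lap_mu = (mu[ip[i], j] + mu[im[i], j] + mu[i, jp[j]]
                              + mu[i, jm[j]] - 4.0 * mu[i, j])
                    adv_phi = (ux[i, j] * 0.5 * (phi[ip[i], j] - phi[im[i], j])
                               + uy[i, j] * 0.5 * (phi[i, jp[j]] - phi[i, jm[j]]))
                    phi_n[i, j] = phi[i, j] + dt_sub * (-adv_phi
                                                        + gamma_phi * lap_mu)

            bad = False
            for i in range(nx):
                for j in range(ny):
                    q1 = qxx_n[i, j]
                    q2 = qxy_n[i, j]
                    ph = phi_n[i, j]
                    if (not np.isfinite(q1)) or (not np.isfinite(q2)) \
                            or (not np.isfinite(ph)) \
                            or abs(q1) > Q_BLOWUP_BOUND \
                            or abs(q2) > Q_BLOWUP_BOUND \
                            or abs(ph) > PHI_BLOWUP_BOUND:
                        bad = True
            if bad:
                return STATUS_BLOWUP
            qxx[:, :] = qxx_n
            qxy[:, :] = qxy_n
            phi[:, :] = phi_n

    return STATUS_OK


def evolve(state, params, n_steps: int) -> int:
    """Advance a :class:`~colonyrot.simulate.FieldState` in place.

    Returns the kernel status code (0 ok, 1 blow-up, 2 Mach guard).
    """
    if params.stencil != "5pt":
        raise ValueError("the fused kernel supports only the 5pt stencil")
    lbstate = state.lbstate
    status = _evolve(
        lbstate.f, state.phi, state.q[0], state.q[1],
        lbstate.u[0], lbstate.u[1], lbstate.rho, n_steps,
        params.C, params.B, params.K_phi, params.K, params.gamma,
        params.gamma_phi, params.lam, params.zeta, params.tau_lb,
        params.n_substeps, params.active_coupling == "phi",
    )
    if status == STATUS_OK:
        state.step += n_steps
    return int(status)
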