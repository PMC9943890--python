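"""D2Q9 lattice-Boltzmann solver for the near-incompressible flow.

The momentum balance  rho (d_t + u.grad) u = div(Pi),  with Pi the
sum of viscous, passive elastic and active stresses, is solved with a
single-relaxation-time (BGK) collision operator and Guo's
second-order forcing.  The viscous stress and the isotropic pressure
are produced by the collision operator itself (ideal-gas equation of
state P = rho c_s^2); only the divergence of the deviatoric passive
elastic stress and of the active stress  Pi^a = zeta Q  is applied as
a body force.  In extensile systems zeta < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, check_finite, divergence_tensor, gradient

__all__ = [
    "D2Q9",
    "LBState",
    "equilibrium",
    "lb_step",
    "assemble_stress",
    "stress_divergence",
    "viscosity",
]

# D2Q9 velocity set and weights; c_s^2 = 1/3.
_CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=np.int64)
_CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=np.int64)
_W = np.array(
    [4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36]
)
CS2 = 1.0 / 3.0

#: Mach guard: |u| above this fraction of the lattice speed aborts.
MACH_LIMIT = 0.2


class D2Q9:
    """Constants of the nine-velocity lattice."""

    cx = _CX
    cy = _CY
    w = _W
    cs2 = CS2


def viscosity(rho: float, tau_lb: float, dt: float = 1.0) -> float:
    """Dynamic viscosity implied by the BGK relaxation time."""
    return rho * CS2 * (tau_lb - 0.5) * dt


@dataclass
class LBState:
    """Populations and derived hydrodynamic moments."""

    f: np.ndarray          # (9, nx, ny)
    rho: np.ndarray        # (nx, ny)
    u: np.ndarray          # (2, nx, ny)
    tau_lb: float = 1.0

    @classmethod
    def rest(cls, grid: Grid, rho0: float = 40.0, tau_lb: float = 1.0) -> "LBState":
        """Uniform fluid at rest (global equilibrium)."""
        f = np.empty((9,) + grid.shape)
        for i in range(9):
            f[i] = _W[i] * rho0
        return cls(f=f, rho=np.full(grid.shape, rho0), u=np.zeros((2,) + grid.shape),
                   tau_lb=tau_lb)

    def moments(self, force: np.ndarray | None = None) -> None:
        """Recompute rho and u from the populations (Guo half-force shift)."""
        self.rho = self.f.sum(axis=0)
        mx = np.einsum("i,ixy->xy", _CX.astype(float), self.f)
        my = np.einsum("i,ixy->xy", _CY.astype(float), self.f)
        if force is not None:
            mx = mx + 0.5 * force[0]
            my = my + 0.5 * force[1]
        self.u = np.stack([mx / self.rho, my / self.rho])


def equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order Maxwell-Boltzmann equilibrium populations."""
    feq = np.empty((9,) + rho.shape)
    u2 = u[0] ** 2 + u[1] ** 2
    for i in range(9):
        cu = _CX[i] * u[0] + _CY[i] * u[1]
        feq[i] = _W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * u2)
    return feq


def _guo_force_terms(u: np.ndarray, force: np.ndarray, tau_lb: float) -> np.ndarray:
    pref = 1.0 - 0.5 / tau_lb
    s = np.empty((9,) + u.shape[1:])
    for i in range(9):
        cu = _CX[i] * u[0] + _CY[i] * u[1]
        fx = 3.0 * (_CX[i] - u[0]) + 9.0 * cu * _CX[i]
        fy = 3.0 * (_CY[i] - u[1]) + 9.0 * cu * _CY[i]
        s[i] = pref * _W[i] * (fx * force[0] + fy * force[1])
    return s


def lb_step(state: LBState, force: np.ndarray, grid: Grid) -> LBState:
    """One BGK collide-stream cycle with Guo forcing.

    The input ``state.u`` must already include the half-force moment
    shift (as produced by :meth:`LBState.moments`).  Returns a new
    state with updated populations and moments.
    """
    check_finite(state.f, force)
    umax = float(np.max(np.abs(state.u)))
    if umax > MACH_LIMIT:
        raise FloatingPointError(
            f"Mach guard: max|u| = {umax:.3g} exceeds {MACH_LIMIT} lattice units"
        )
    feq = equilibrium(state.rho, state.u)
    src = _guo_force_terms(state.u, force, state.tau_lb)
    post = state.f - (state.f - feq) / state.tau_lb + grid.dt * src
    # streaming with periodic wrap
    fnew = np.empty_like(post)
    for i in range(9):
        fnew[i] = np.roll(np.roll(post[i], _CX[i], axis=0), _CY[i], axis=1)
    out = LBState(f=fnew, rho=state.rho, u=state.u, tau_lb=state.tau_lb)
    out.moments(force)
    return out


def assemble_stress(q: np.ndarray, h: np.ndarray, phi: np.ndarray,
                    k_frank: float, lam: float, zeta: float,
                    grid: Grid, active_phi: bool = True
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deviatoric passive elastic plus active stress, full 2x2 components.

    Pi = 2 lam (Q + I/2) Tr(Q.H) - lam H (Q + I/2) - lam (Q + I/2) H
         + Q.H - H.Q - K (d_i Q_kl)(d_j Q_kl) + zeta_eff Q

    with zeta_eff = zeta * phi when ``active_phi`` (default: the
    dipolar force density is exerted by the cells, so it vanishes in
    the cell-free background) and zeta_eff = zeta otherwise.

    The pressure -P delta_ij and the viscous stress are supplied by
    the lattice-Boltzmann equation of state and collision operator and
    must not be duplicated here.  Returns (xx, xy, yx, yy); the
    antisymmetric part Q.H - H.Q makes Pi generally non-symmetric.
    """
    check_finite(q, h, phi)
    qxx, qxy = q[0], q[1]
    hxx, hxy = h[0], h[1]
    zeta = zeta * phi if active_phi else zeta

    axx, axy, ayy = qxx + 0.5, qxy, -qxx + 0.5
    tr_qh = 2.0 * (qxx * hxx + qxy * hxy)

    # H.A and A.H (both symmetric inputs, products generally not)
    ha_xx = hxx * axx + hxy * axy
    ha_xy = hxx * axy + hxy * ayy
    ha_yx = hxy * axx - hxx * axy
    ha_yy = hxy * axy - hxx * ayy

    ah_xx = axx * hxx + axy * hxy
    ah_xy = axx * hxy - axy * hxx
    ah_yx = axy * hxx + ayy * hxy
    ah_yy = axy * hxy - ayy * hxx

    # antisymmetric part Q.H - H.Q : only xy = -(yx) component in 2D
    anti_xy = qxx * hxy - qxy * hxx - (hxx * qxy - hxy * qxx)

    gqxx = gradient(qxx, grid)
    gqxy = gradient(qxy, grid)
    # Ericksen: (d_i Q_kl)(d_j Q_kl) = 2(d_i Qxx d_j Qxx + d_i Qxy d_j Qxy)
    er_xx = 2.0 * (gqxx[0] ** 2 + gqxy[0] ** 2)
    er_xy = 2.0 * (gqxx[0] * gqxx[1] + gqxy[0] * gqxy[1])
    er_yy = 2.0 * (gqxx[1] ** 2 + gqxy[1] ** 2)

    p_xx = (2.0 * lam * axx * tr_qh - lam * (ha_xx + ah_xx)
            - k_frank * er_xx + zeta * qxx)
    p_yy = (2.0 * lam * ayy * tr_qh - lam * (ha_yy + ah_yy)
            - k_frank * er_yy - zeta * qxx)
    p_xy = (2.0 * lam * axy * tr_qh - lam * (ha_xy + ah_xy)
            + anti_xy - k_frank * er_xy + zeta * qxy)
    p_yx = (2.0 * lam * axy * tr_qh - lam * (ha_yx + ah_yx)
            - anti_xy - k_frank * er_xy + zeta * qxy)
    return p_xx, p_xy, p_yx, p_yy


def stress_divergence(q: np.ndarray, h: np.ndarray, phi: np.ndarray,
                      k_frank: float, lam: float, zeta: float,
                      grid: Grid, active_phi: bool = True) -> np.ndarray:
    """Body force F_j = d_i Pi_ij driving the LB fluid."""
    p_xx, p_xy, p_yx, p_yy = assemble_stress(q, h, phi, k_frank, lam, zeta,
                                             grid, active_phi)
    return divergence_tensor(p_xx, p_xy, p_yx, p_yy, grid)
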