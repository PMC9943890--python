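"""Free-energy functional of the phase-field active nematic.

The free-energy density couples the cell concentration ``phi`` (phi=1
tissue, phi=0 cell-free background) and the nematic order tensor Q:

    f = f_bulk(Q) + (B/2) phi^2 (1-phi)^2 + K_phi |grad phi|^2
        + (K/2) |grad Q|^2

with, under the default sign convention,

    f_bulk(Q) = +(C/2) (1 + Tr(Q.Q)/2)^2 ,

which makes the isotropic state Q=0 the bulk minimum, so that any
nematic order must be generated by activity.  The double well has
minima at phi=0 and phi=1; K_phi penalises concentration gradients
(interface tension) and K is the single Frank elastic constant.

Functional derivatives drive the dynamics: the molecular field
H = -df/dQ + div(df/d(grad Q)) relaxes Q, and the chemical potential
mu = df/dphi - div(df/d(grad phi)) drives the conserved phi dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid, check_finite, laplacian

__all__ = [
    "FreeEnergyParams",
    "free_energy_density",
    "total_free_energy",
    "molecular_field",
    "chemical_potential",
]


@dataclass(frozen=True)
class FreeEnergyParams:
    """Material parameters of the free-energy density.

    Attributes
    ----------
    C : float
        Bulk nematic coefficient.  With ``stabilizing_bulk=True``
        (default) the bulk term is +(C/2)(1+Tr(Q.Q)/2)^2 and C>0
        stabilises the isotropic phase.
    B : float
        Depth of the phi double well (minima at phi=0 and phi=1).
    K_phi : float
        Concentration gradient stiffness; enters f with coefficient
        K_phi (not K_phi/2), so mu carries a factor 2 on the Laplacian.
    K : float
        Frank elastic constant (single-constant approximation).
    stabilizing_bulk : bool
        If False, use the opposite (destabilising) sign of the bulk Q
        term, exposed only for sensitivity checks.
    """

    C: float = 0.001
    B: float = 0.01
    K_phi: float = 0.1
    K: float = 0.02
    stabilizing_bulk: bool = True

    def __post_init__(self) -> None:
        if self.B <= 0 or self.K <= 0 or self.K_phi <= 0 or self.C <= 0:
            raise ValueError("C, B, K_phi and K must all be positive")


def _tr_qq(q: np.ndarray) -> np.ndarray:
    """Tr(Q.Q) = 2(Qxx^2 + Qxy^2) for a traceless symmetric 2D tensor."""
    return 2.0 * (q[0] ** 2 + q[1] ** 2)


def _forward_grad_sq(f: np.ndarray, grid: Grid) -> np.ndarray:
    """|grad f|^2 with forward differences and periodic wrap."""
    dfx = (np.roll(f, -1, axis=0) - f) / grid.dx
    dfy = (np.roll(f, -1, axis=1) - f) / grid.dx
    return dfx**2 + dfy**2


def free_energy_density(phi: np.ndarray, q: np.ndarray, p: FreeEnergyParams,
                        grid: Grid) -> np.ndarray:
    """Pointwise free-energy density f(phi, Q)."""
    if phi.shape != grid.shape or q.shape[1:] != grid.shape:
        raise ValueError("phi/Q shapes do not match the grid")
    check_finite(phi, q)
    sign = 1.0 if p.stabilizing_bulk else -1.0
    f_bulk = sign * 0.5 * p.C * (1.0 + 0.5 * _tr_qq(q)) ** 2
    f_well = 0.5 * p.B * phi**2 * (1.0 - phi) ** 2
    # forward differences: the discretisation conjugate to the compact
    # 5-point Laplacian, making mu and H exact discrete functional
    # derivatives of the total energy (gradient-flow consistency)
    gphi2 = _forward_grad_sq(phi, grid)
    f_grad_phi = p.K_phi * gphi2
    # |grad Q|^2 = sum_m (dQij/dxm)^2 = 2[(dQxx)^2 + (dQxy)^2]
    f_grad_q = p.K * (_forward_grad_sq(q[0], grid)
                      + _forward_grad_sq(q[1], grid))
    return f_bulk + f_well + f_grad_phi + f_grad_q


def total_free_energy(phi: np.ndarray, q: np.ndarray, p: FreeEnergyParams,
                      grid: Grid) -> float:
    """Grid integral of the free-energy density."""
    return float(np.sum(free_energy_density(phi, q, p, grid)) * grid.dx**2)


def molecular_field(phi: np.ndarray, q: np.ndarray, p: FreeEnergyParams,
                    grid: Grid, stencil: str = "5pt") -> np.ndarray:
    """Molecular field H = -df/dQ + div(df/d grad Q).

    H = -C (1 + Tr(Q.Q)/2) Q + K lap(Q) under the default convention;
    traceless and symmetric by construction (components xx, xy).
    """
    check_finite(phi, q)
    sign = 1.0 if p.stabilizing_bulk else -1.0
    amp = sign * p.C * (1.0 + 0.5 * _tr_qq(q))
    h = np.empty_like(q)
    h[0] = -amp * q[0] + p.K * laplacian(q[0], grid, stencil)
    h[1] = -amp * q[1] + p.K * laplacian(q[1], grid, stencil)
    return h


def chemical_potential(phi: np.ndarray, q: np.ndarray, p: FreeEnergyParams,
                       grid: Grid, stencil: str = "5pt") -> np.ndarray:
    """Chemical potential mu = df/dphi - div(df/d grad phi).

    mu = B phi (1-phi)(1-2 phi) - 2 K_phi lap(phi).  The factor 2
    follows from the gradient term carrying coefficient K_phi.
    """
    check_finite(phi, q)
    well = p.B * phi * (1.0 - phi) * (1.0 - 2.0 * phi)
    return well - 2.0 * p.K_phi * laplacian(phi, grid, stencil)
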