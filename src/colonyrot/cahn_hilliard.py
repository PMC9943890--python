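"""Advected Cahn-Hilliard dynamics of the cell concentration.

    d_t phi + u.grad phi = Gamma_phi lap(mu)

with mu the chemical potential from the free-energy module.  The
right-hand side is conservative on the periodic lattice (the grid sum
of any Laplacian telescopes to zero), so total concentration is
preserved to round-off when u = 0 and monitored under advection.
"""

from __future__ import annotations

import numpy as np

from .grid import Grid, check_finite, laplacian
from .qtensor import advect

__all__ = ["step_phi"]

#: |phi| beyond which the explicit scheme is declared blown up.
PHI_BLOWUP_BOUND = 50.0


def step_phi(phi: np.ndarray, u: np.ndarray, mu: np.ndarray,
             gamma_phi: float, grid: Grid, dt: float | None = None,
             stencil: str = "5pt") -> np.ndarray:
    """One explicit Euler step: phi' = phi + dt(-u.grad phi + Gamma lap mu)."""
    check_finite(phi, u, mu)
    if gamma_phi <= 0:
        raise ValueError("Gamma_phi must be positive")
    if dt is None:
        dt = grid.dt
    out = phi + dt * (-advect(phi, u, grid)
                      + gamma_phi * laplacian(mu, grid, stencil))
    mx = float(np.max(np.abs(out)))
    if not np.isfinite(mx) or mx > PHI_BLOWUP_BOUND:
        raise FloatingPointError(
            f"concentration step blew up: max|phi| = {mx:.3g}"
        )
    return out
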