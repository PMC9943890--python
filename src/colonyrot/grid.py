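"""Periodic-grid field containers and finite-difference operators.

All continuum fields live on a rectangular grid with periodic boundary
conditions in both directions.  Scalar fields are ``(nx, ny)`` arrays,
vector fields are ``(2, nx, ny)`` and symmetric traceless 2x2 tensor
fields store only their two independent components ``(xx, xy)`` as
``(2, nx, ny)`` (``yy = -xx``, ``yx = xy``).

Derivatives are second-order central differences with periodic wrap;
an isotropic 9-point Laplacian is available to reduce lattice
anisotropy of diffuse interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Grid",
    "gradient",
    "laplacian",
    "divergence",
    "divergence_tensor",
    "gradient_vector",
    "check_finite",
]


@dataclass(frozen=True)
class Grid:
    """Periodic rectangular lattice.

    Parameters
    ----------
    nx, ny : int
        Number of lattice nodes along x and y (each >= 8).
    dx, dt : float
        Lattice spacing and time step.  The simulator works in lattice
        units where both are 1; physical rescaling is applied only when
        comparing observables with experiment.
    """

    nx: int
    ny: int
    dx: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError(f"grid must be at least 8x8, got {self.nx}x{self.ny}")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def scalar(self, fill: float = 0.0) -> np.ndarray:
        return np.full(self.shape, fill, dtype=np.float64)

    def vector(self) -> np.ndarray:
        return np.zeros((2, self.nx, self.ny), dtype=np.float64)

    def tensor(self) -> np.ndarray:
        """Symmetric traceless tensor field, components (xx, xy)."""
        return np.zeros((2, self.nx, self.ny), dtype=np.float64)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.arange(self.nx) * self.dx
        y = np.arange(self.ny) * self.dx
        return np.meshgrid(x, y, indexing="ij")


def check_finite(*fields: np.ndarray) -> None:
    """Raise with a diagnostic if any field contains NaN or Inf."""
    for i, f in enumerate(fields):
        if not np.all(np.isfinite(f)):
            bad = int(np.count_nonzero(~np.isfinite(f)))
            raise FloatingPointError(
                f"field argument {i} contains {bad} non-finite values"
            )


def _dx(f: np.ndarray, dx: float) -> np.ndarray:
    # axis 0 is x; np.roll(f, -1) brings f[i+1] to position i
    return (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2.0 * dx)


def _dy(f: np.ndarray, dx: float) -> np.ndarray:
    return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2.0 * dx)


def gradient(f: np.ndarray, grid: Grid) -> np.ndarray:
    """Central-difference gradient of a scalar field -> vector field."""
    check_finite(f)
    g = np.empty((2,) + f.shape)
    g[0] = _dx(f, grid.dx)
    g[1] = _dy(f, grid.dx)
    return g


def laplacian(f: np.ndarray, grid: Grid, stencil: str = "5pt") -> np.ndarray:
    """Periodic Laplacian of a scalar field.

    ``stencil="5pt"`` is the standard second-order cross;
    ``stencil="9pt"`` is the isotropic nine-point form
    (weights 2/3 edge, 1/6 corner, -10/3 centre).
    """
    check_finite(f)
    dx2 = grid.dx * grid.dx
    xp = np.roll(f, -1, axis=0)
    xm = np.roll(f, 1, axis=0)
    yp = np.roll(f, -1, axis=1)
    ym = np.roll(f, 1, axis=1)
    if stencil == "5pt":
        return (xp + xm + yp + ym - 4.0 * f) / dx2
    if stencil == "9pt":
        xpyp = np.roll(xp, -1, axis=1)
        xpym = np.roll(xp, 1, axis=1)
        xmyp = np.roll(xm, -1, axis=1)
        xmym = np.roll(xm, 1, axis=1)
        # grouped so constants are annihilated exactly
        return (
            (2.0 / 3.0) * (xp + xm + yp + ym - 4.0 * f)
            + (1.0 / 6.0) * (xpyp + xpym + xmyp + xmym - 4.0 * f)
        ) / dx2
    raise ValueError(f"unknown stencil {stencil!r}")


def divergence(v: np.ndarray, grid: Grid) -> np.ndarray:
    """Divergence of a vector field -> scalar field."""
    check_finite(v)
    return _dx(v[0], grid.dx) + _dy(v[1], grid.dx)


def gradient_vector(u: np.ndarray, grid: Grid) -> np.ndarray:
    """Velocity gradient tensor du_j/dx_i, shape (2, 2, nx, ny).

    Index convention: result[i, j] = d u_j / d x_i.
    """
    check_finite(u)
    g = np.empty((2, 2) + u.shape[1:])
    g[0, 0] = _dx(u[0], grid.dx)
    g[0, 1] = _dx(u[1], grid.dx)
    g[1, 0] = _dy(u[0], grid.dx)
    g[1, 1] = _dy(u[1], grid.dx)
    return g


def divergence_tensor(t_xx: np.ndarray, t_xy: np.ndarray, t_yx: np.ndarray,
                      t_yy: np.ndarray, grid: Grid) -> np.ndarray:
    """Divergence (d_i T_ij) of a general 2x2 tensor field -> vector field.

    Accepts the four components separately so both symmetric-traceless
    fields (pass ``xx, xy, xy, -xx``) and full stress tensors can be used.
    """
    check_finite(t_xx, t_xy, t_yx, t_yy)
    f = np.empty((2,) + t_xx.shape)
    f[0] = _dx(t_xx, grid.dx) + _dy(t_yx, grid.dx)
    f[1] = _dx(t_xy, grid.dx) + _dy(t_yy, grid.dx)
    return f


def divergence_symtensor(t: np.ndarray, grid: Grid) -> np.ndarray:
    """Divergence of a symmetric traceless tensor stored as (xx, xy)."""
    return divergence_tensor(t[0], t[1], t[1], -t[0], grid)
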