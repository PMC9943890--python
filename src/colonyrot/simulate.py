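"""Colony simulation driver.

Initialises a circular tissue droplet (phi = 1 inside, 0 outside,
tanh-smoothed edge) with a weak random director field, evolves the
coupled Q-tensor / lattice-Boltzmann / Cahn-Hilliard model, and
records colony observables: area, mean angular velocity about the
colony centroid, mean speed, nematic order and total free energy.

Two numerically equivalent backends are provided: a composable
NumPy reference path built from the public module operations, and a
fused numba kernel used for production runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import cahn_hilliard, free_energy, lb, qtensor
from .grid import Grid

__all__ = [
    "ModelParams",
    "FieldState",
    "ColonyObservables",
    "init_droplet",
    "run",
    "measure_angular_velocity",
    "colony_centroid",
    "rescale_to_experiment",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical constants of the continuum model.

    Physical defaults are the study's lattice-unit parameter set;
    ``zeta`` is negative (extensile) by default, the convention for
    epithelial monolayers.  ``tau_lb`` (BGK relaxation time, setting
    the viscosity eta = rho c_s^2 (tau_lb - 1/2)) and the
    finite-difference substep count are numerical choices.
    """

    rho: float = 40.0
    gamma_phi: float = 0.2     # concentration mobility Gamma_phi
    gamma: float = 0.3         # rotational diffusivity
    zeta: float = -0.01        # active stress amplitude; < 0 extensile
    lam: float = 0.7           # flow-aligning parameter
    K: float = 0.02            # Frank elastic constant
    K_phi: float = 0.1         # concentration gradient stiffness
    B: float = 0.01            # double-well depth
    C: float = 0.001           # bulk nematic coefficient
    nx: int = 300
    ny: int = 300
    radius: float = 30.0       # droplet radius (lattice units)
    seed: int = 0
    s0: float = 0.05           # initial nematic order magnitude
    director_mode: str = "per-node"   # or "global"
    tau_lb: float = 0.6
    n_substeps: int = 2        # FD substeps per LB step (phi/Q stability)
    stencil: str = "5pt"
    active_coupling: str = "phi"   # "phi": Pi_a = zeta*phi*Q; "uniform": zeta*Q

    def __post_init__(self) -> None:
        if self.active_coupling not in ("phi", "uniform"):
            raise ValueError("active_coupling must be 'phi' or 'uniform'")
        if self.tau_lb <= 0.5:
            raise ValueError("tau_lb must exceed 1/2 (positive viscosity)")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")

    def free_energy_params(self) -> free_energy.FreeEnergyParams:
        return free_energy.FreeEnergyParams(C=self.C, B=self.B,
                                            K_phi=self.K_phi, K=self.K)

    def grid(self) -> Grid:
        return Grid(self.nx, self.ny)

    def params_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FieldState:
    """Coupled simulation fields on the periodic grid."""

    grid: Grid
    phi: np.ndarray
    q: np.ndarray              # (2, nx, ny): Qxx, Qxy
    lbstate: lb.LBState
    step: int = 0

    @property
    def u(self) -> np.ndarray:
        return self.lbstate.u

    def save_hdf5(self, path, params: ModelParams | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("phi", data=self.phi)
            fh.create_dataset("Qxx", data=self.q[0])
            fh.create_dataset("Qxy", data=self.q[1])
            fh.create_dataset("ux", data=self.u[0])
            fh.create_dataset("uy", data=self.u[1])
            fh.attrs["step"] = self.step
            if params is not None:
                fh.attrs["params_hash"] = params.params_hash()

    @classmethod
    def load_hdf5(cls, path) -> "FieldState":
        import h5py

        with h5py.File(path, "r") as fh:
            phi = fh["phi"][...]
            q = np.stack([fh["Qxx"][...], fh["Qxy"][...]])
            u = np.stack([fh["ux"][...], fh["uy"][...]])
            step = int(fh.attrs.get("step", 0))
        grid = Grid(*phi.shape)
        state = lb.LBState.rest(grid)
        state.u = u
        return cls(grid=grid, phi=phi, q=q, lbstate=state, step=step)


@dataclass
class ColonyObservables:
    """Time series of colony-level measurements."""

    steps: np.ndarray
    area: np.ndarray
    omega: np.ndarray
    speed: np.ndarray
    s_mean: np.ndarray
    f_total: np.ndarray
    phi_total: np.ndarray
    params: ModelParams | None = None
    final_state: FieldState | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "step": self.steps, "area": self.area, "omega": self.omega,
            "speed": self.speed, "S_mean": self.s_mean,
            "F_total": self.f_total, "phi_total": self.phi_total,
        })


def init_droplet(params: ModelParams) -> FieldState:
    """Circular droplet with tanh edge and a weak random director.

    phi = 1 inside radius R, 0 outside, smoothed over the equilibrium
    interface width; inside the droplet Q = S0 (nn - I/2) with the
    director angle drawn uniformly on [0, 2*pi) (per node, or one
    global angle); fluid at rest.  Deterministic given ``params.seed``.
    """
    grid = params.grid()
    delta = float(np.sqrt(2.0 * params.K_phi / params.B))  # profile scale
    width = float(np.sqrt(params.K_phi / params.B))        # interface width
    if params.radius < 1.0:
        raise ValueError("droplet radius below one lattice cell")
    if params.radius + 5.0 * width > min(grid.nx, grid.ny) / 2.0:
        raise ValueError(
            f"droplet radius {params.radius} too large for {grid.nx}x{grid.ny} "
            f"box (needs margin of 5 interface widths = {5 * width:.1f})"
        )
    rng = np.random.default_rng(params.seed)
    x, y = grid.meshgrid()
    cx, cy = grid.nx / 2.0, grid.ny / 2.0
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    phi = 0.5 * (1.0 - np.tanh((r - params.radius) / (2.0 * delta)))

    if params.director_mode == "per-node":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=grid.shape)
    elif params.director_mode == "global":
        theta = np.full(grid.shape, rng.uniform(0.0, 2.0 * np.pi))
    else:
        raise ValueError(f"unknown director_mode {params.director_mode!r}")
    inside = phi > 0.5
    q = grid.tensor()
    q[0][inside] = 0.5 * params.s0 * np.cos(2.0 * theta[inside])
    q[1][inside] = 0.5 * params.s0 * np.sin(2.0 * theta[inside])

    state = lb.LBState.rest(grid, rho0=params.rho, tau_lb=params.tau_lb)
    return FieldState(grid=grid, phi=phi, q=q, lbstate=state, step=0)


def colony_centroid(phi: np.ndarray, grid: Grid) -> tuple[float, float]:
    """phi-weighted centre of mass, periodic-aware (circular mean)."""
    total = float(phi.sum())
    if total <= 0:
        raise ValueError("empty colony: phi sums to zero")
    out = []
    for axis, n in ((0, grid.nx), (1, grid.ny)):
        coord = np.arange(n) * (2.0 * np.pi / n)
        w = phi.sum(axis=1 - axis)
        c = float(np.sum(w * np.cos(coord))) / total
        s = float(np.sum(w * np.sin(coord))) / total
        ang = np.arctan2(s, c) % (2.0 * np.pi)
        out.append(ang * n / (2.0 * np.pi) * grid.dx)
    return out[0], out[1]


def measure_angular_velocity(state: FieldState, r_min: float = 2.0,
                             phi_threshold: float = 0.5) -> float:
    """Mean angular velocity of the colony about its centroid.

    omega = mean over colony nodes with r > r_min of (r_hat x u).z / r,
    counterclockwise positive.  Raises on an empty colony.
    """
    grid = state.grid
    cx, cy = colony_centroid(state.phi, grid)
    x, y = grid.meshgrid()
    # periodic minimal-image displacement from centroid
    dxv = (x - cx + grid.nx * grid.dx / 2) % (grid.nx * grid.dx) - grid.nx * grid.dx / 2
    dyv = (y - cy + grid.ny * grid.dx / 2) % (grid.ny * grid.dx) - grid.ny * grid.dx / 2
    r2 = dxv**2 + dyv**2
    mask = (state.phi > phi_threshold) & (r2 > r_min**2)
    if not np.any(mask):
        raise ValueError("empty colony: no nodes above phi threshold")
    u = state.u
    omega_local = (dxv[mask] * u[1][mask] - dyv[mask] * u[0][mask]) / r2[mask]
    return float(np.mean(omega_local))


def _measure(state: FieldState, params: ModelParams
             ) -> tuple[float, float, float, float, float, float]:
    grid = state.grid
    mask = state.phi > 0.5
    area = float(np.count_nonzero(mask)) * grid.dx**2
    omega = measure_angular_velocity(state) if np.any(mask) else 0.0
    u = state.u
    speed = float(np.mean(np.sqrt(u[0] ** 2 + u[1] ** 2)[mask])) if np.any(mask) else 0.0
    s = 2.0 * np.sqrt(state.q[0] ** 2 + state.q[1] ** 2)
    s_mean = float(np.mean(s[mask])) if np.any(mask) else 0.0
    ftot = free_energy.total_free_energy(state.phi, state.q,
                                         params.free_energy_params(), grid)
    return area, omega, speed, s_mean, ftot, float(state.phi.sum())


def step_once(state: FieldState, params: ModelParams) -> FieldState:
    """One full hybrid step (reference NumPy path).

    Sequence: molecular field and stress from the current fields; one
    LB collide-stream with the stress-divergence body force; then
    ``n_substeps`` explicit finite-difference substeps of Q and phi
    with the updated (frozen) velocity.
    """
    grid = state.grid
    fe = params.free_energy_params()
    h = free_energy.molecular_field(state.phi, state.q, fe, grid, params.stencil)
    force = lb.stress_divergence(state.q, h, state.phi, params.K, params.lam,
                                 params.zeta, grid,
                                 active_phi=params.active_coupling == "phi")
    lbstate = lb.lb_step(state.lbstate, force, grid)
    u = lbstate.u
    q, phi = state.q, state.phi
    dt_sub = grid.dt / params.n_substeps
    for _ in range(params.n_substeps):
        h = free_energy.molecular_field(phi, q, fe, grid, params.stencil)
        mu = free_energy.chemical_potential(phi, q, fe, grid, params.stencil)
        q = qtensor.step_q(q, u, h, params.gamma, params.lam, grid, dt=dt_sub)
        phi = cahn_hilliard.step_phi(phi, u, mu, params.gamma_phi, grid,
                                     dt=dt_sub, stencil=params.stencil)
    return FieldState(grid=grid, phi=phi, q=q, lbstate=lbstate,
                      step=state.step + 1)


def run(params: ModelParams, n_steps: int, sample_every: int = 200,
        backend: str = "numba", state: FieldState | None = None,
        progress: bool = False) -> ColonyObservables:
    """Evolve the model and record colony observables.

    Deterministic given ``params.seed``.  ``backend="numba"`` uses the
    fused kernel; ``backend="numpy"`` the composable reference path.
    Numerical blow-up or a Mach-guard violation raises
    ``FloatingPointError`` annotated with the step index.
    """
    if state is None:
        state = init_droplet(params)
    samples: list[tuple[float, ...]] = []
    steps: list[int] = []

    def record(st: FieldState) -> None:
        samples.append(_measure(st, params))
        steps.append(st.step)

    record(state)
    if backend == "numpy":
        for _ in range(n_steps):
            try:
                state = step_once(state, params)
            except FloatingPointError as err:
                raise FloatingPointError(f"step {state.step + 1}: {err}") from err
            if state.step % sample_every == 0:
                record(state)
    elif backend == "numba":
        from . import _kernels

        n_done = 0
        while n_done < n_steps:
            chunk = min(sample_every - (state.step % sample_every) or sample_every,
                        n_steps - n_done)
            status = _kernels.evolve(state, params, chunk)
            if status != 0:
                raise FloatingPointError(
                    f"step {state.step}: numerical instability "
                    f"({'blow-up' if status == 1 else 'Mach guard'})"
                )
            n_done += chunk
            if state.step % sample_every == 0 or n_done == n_steps:
                record(state)
            if progress:
                print(f"  step {state.step}/{steps[0] + n_steps}", end="\r")
    else:
        raise ValueError(f"unknown backend {backend!r}")

    arr = np.array(samples)
    return ColonyObservables(
        steps=np.array(steps), area=arr[:, 0], omega=arr[:, 1],
        speed=arr[:, 2], s_mean=arr[:, 3], f_total=arr[:, 4],
        phi_total=arr[:, 5], params=params, final_state=state,
    )


def plateau_omega(obs: ColonyObservables, frac: float = 0.25) -> float:
    """Mean angular velocity over the last ``frac`` of the samples."""
    n = max(int(np.ceil(len(obs.omega) * frac)), 1)
    return float(np.mean(obs.omega[-n:]))


def rotation_sign(params: ModelParams, max_steps: int = 20000,
                  threshold: float = 1e-4, chunk: int = 2000,
                  confirm: int = 2, backend: str = "numba") -> int:
    """Sign of the emergent rotation for one seed (adaptive early stop).

    Evolves the droplet until the colony angular velocity exceeds
    ``threshold`` with a consistent sign over ``confirm`` consecutive
    samples, or ``max_steps`` is reached.  Returns +1 / -1, or 0 when
    no rotation above threshold developed.
    """
    state = init_droplet(params)
    recent: list[float] = []
    done = 0
    while done < max_steps:
        obs = run(params, n_steps=min(chunk, max_steps - done),
                  sample_every=chunk, backend=backend, state=state)
        state = obs.final_state
        done = state.step
        om = float(obs.omega[-1])
        recent.append(om)
        tail = recent[-confirm:]
        if len(tail) == confirm and all(abs(v) > threshold for v in tail):
            signs = {np.sign(v) for v in tail}
            if len(signs) == 1:
                return int(signs.pop())
    return 0


def rescale_to_experiment(obs: ColonyObservables, a0_exp: float,
                          omega0_exp: float) -> dict[str, np.ndarray]:
    """Affine rescaling of the area and omega axes to experimental units.

    Matches the first recorded area and angular velocity to the
    experimental reference values: s_A = A0_exp / A0_sim and
    s_omega = omega0_exp / omega0_sim.
    """
    if obs.area.size == 0:
        raise ValueError("empty observable series")
    if obs.omega[0] == 0.0:
        raise ValueError("initial angular velocity is zero: rescaling undefined")
    s_a = a0_exp / obs.area[0]
    s_w = omega0_exp / obs.omega[0]
    return {"area": obs.area * s_a, "omega": obs.omega * s_w,
            "scale_area": s_a, "scale_omega": s_w}
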