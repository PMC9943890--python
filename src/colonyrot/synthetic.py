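"""Seeded synthetic-data generators emulating the time-lapse study.

The analysis pipeline consumes tracked cell positions and colony
growth curves.  These generators produce such tables with known
ground truth so every stage is testable end to end:

* coherently rotating near-circular clusters (rigid rotation with a
  slow homothetic radial expansion, tracking noise added per frame);
* an incoherent negative control with per-cell random-walk angular
  and radial increments of matched displacement variance;
* exponential cell-count series and confluence-versus-time curves.

Each generator returns ``(data, truth)`` and is deterministic given
its spec and seed.  The positional noise model is isotropic Gaussian
error (manual-tracking jitter), default 1 um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RotatingClusterSpec",
    "GrowthSpec",
    "ConfluenceSpec",
    "gen_rotating_cluster",
    "gen_incoherent_cluster",
    "gen_growth_counts",
    "gen_confluence_curves",
]


@dataclass(frozen=True)
class RotatingClusterSpec:
    """A near-circular cluster of rigidly co-rotating cells.

    Defaults follow the tracked reference cluster: ~52 cells, 84 um
    average radius, aspect ratio 0.83, 2 h sampling over 12 h.  The
    angular speed magnitude (0.05 rad/h by default) keeps the per-
    interval angular step far inside the unwrapping Nyquist bound.
    ``inner_quota`` optionally pins the exact number of cells placed
    within ``r_split_um`` of the centre.
    """

    n_cells: int = 52
    radius_um: float = 84.0
    aspect_ratio: float = 0.83
    omega0_rad_h: float = 0.05          # signed
    v_rho_um_min: float = 0.04
    noise_um: float = 1.0
    dt_h: float = 2.0
    duration_h: float = 12.0
    drift_um_h: tuple[float, float] = (0.0, 0.0)
    center_um: tuple[float, float] = (0.0, 0.0)
    cluster_id: object = 0
    inner_quota: tuple[int, float] | None = None   # (n_inner, r_split_um)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")
        if self.radius_um <= 0 or self.noise_um < 0:
            raise ValueError("radius must be positive and noise non-negative")
        if not 0 < self.aspect_ratio <= 1:
            raise ValueError("aspect ratio must lie in (0, 1]")
        if self.inner_quota is not None:
            n_in, r_split = self.inner_quota
            if not 0 <= n_in <= self.n_cells or r_split <= 0:
                raise ValueError("invalid inner_quota")


def _place_in_ellipse(rng: np.random.Generator, spec: RotatingClusterSpec
                      ) -> np.ndarray:
    """Uniform positions in the ellipse, optionally with an exact
    inner/outer split quota, recentred on their mean."""
    a = spec.radius_um / np.sqrt(spec.aspect_ratio)   # semi-major
    b = spec.radius_um * np.sqrt(spec.aspect_ratio)   # semi-minor

    def sample(n: int, accept) -> np.ndarray:
        pts = np.empty((0, 2))
        while len(pts) < n:
            cand = rng.uniform(-1, 1, size=(4 * n, 2)) * (a, b)
            ok = (cand[:, 0] / a) ** 2 + (cand[:, 1] / b) ** 2 <= 1.0
            cand = cand[ok]
            cand = cand[accept(cand)]
            pts = np.vstack([pts, cand])
        return pts[:n]

    if spec.inner_quota is None:
        return _recenter(sample(spec.n_cells, lambda p: np.ones(len(p), bool)))
    n_in, r_split = spec.inner_quota
    rr = lambda p: np.hypot(p[:, 0], p[:, 1])
    # sample with a guard band so that recentring on the sample mean
    # cannot move any cell across the split radius
    margin = 0.15 * r_split
    for _ in range(100):
        inner = sample(n_in, lambda p: rr(p) <= r_split - margin)
        outer = sample(spec.n_cells - n_in, lambda p: rr(p) > r_split + margin)
        pts = _recenter(np.vstack([inner, outer]))
        if np.all(np.hypot(*pts[:n_in].T) <= r_split) and np.all(
                np.hypot(*pts[n_in:].T) > r_split):
            return pts
    raise RuntimeError("could not satisfy inner/outer placement quota")


def _recenter(pts: np.ndarray) -> np.ndarray:
    return pts - pts.mean(axis=0)


def _to_table(spec, positions: dict[float, np.ndarray]) -> pd.DataFrame:
    rows = []
    for t, xy in sorted(positions.items()):
        rows.append(pd.DataFrame({
            "track_id": np.arange(len(xy)),
            "cluster_id": spec.cluster_id,
            "t_h": t,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
        }))
    return pd.concat(rows, ignore_index=True)


def gen_rotating_cluster(spec: RotatingClusterSpec
                         ) -> tuple[pd.DataFrame, dict]:
    """Rigidly rotating cluster trajectories with ground truth.

    Cells are placed uniformly in an ellipse (mean position exactly at
    the origin), rotated rigidly at ``omega0`` about the possibly
    drifting centre, and expanded homothetically so the population-
    mean radial speed equals ``v_rho``; isotropic Gaussian noise is
    added independently per frame.  With zero noise the kinematic
    decomposition recovers omega0 and the mean radial speed exactly.
    """
    rng = np.random.default_rng(spec.seed)
    p0 = _place_in_ellipse(rng, spec)
    r0 = np.hypot(p0[:, 0], p0[:, 1])
    v_h = spec.v_rho_um_min * 60.0
    alpha = v_h / float(np.mean(r0)) if v_h != 0 else 0.0
    times = np.arange(0.0, spec.duration_h + 0.5 * spec.dt_h, spec.dt_h)
    positions = {}
    for t in times:
        c, s = np.cos(spec.omega0_rad_h * t), np.sin(spec.omega0_rad_h * t)
        rot = np.array([[c, -s], [s, c]])
        center = (np.asarray(spec.center_um)
                  + np.asarray(spec.drift_um_h) * t)
        xy = center + (1.0 + alpha * t) * (p0 @ rot.T)
        if spec.noise_um > 0:
            xy = xy + rng.normal(0.0, spec.noise_um, size=xy.shape)
        positions[float(t)] = xy
    truth = {
        "omega0_rad_h": spec.omega0_rad_h,
        "v_rho_um_min": spec.v_rho_um_min,
        "per_cell_v_rho_um_min": alpha * r0 / 60.0,
        "center_um": np.asarray(spec.center_um),
        "drift_um_h": np.asarray(spec.drift_um_h),
        "initial_offsets_um": p0,
    }
    return _to_table(spec, positions), truth


def gen_incoherent_cluster(spec: RotatingClusterSpec
                           ) -> tuple[pd.DataFrame, dict]:
    """Negative control: uncoordinated cell motility.

    Each cell performs an independent random walk in its own polar
    coordinates about the cluster centre: zero-mean Gaussian angular
    and radial increments per frame, with variances matched to the
    per-interval displacements of the coherent generator
    (|omega0| dt and v_rho dt), plus the same positional noise.
    """
    rng = np.random.default_rng(spec.seed)
    p0 = _place_in_ellipse(rng, spec)
    theta = np.arctan2(p0[:, 1], p0[:, 0])
    r = np.hypot(p0[:, 0], p0[:, 1])
    sig_theta = abs(spec.omega0_rad_h) * spec.dt_h
    sig_r = spec.v_rho_um_min * 60.0 * spec.dt_h
    times = np.arange(0.0, spec.duration_h + 0.5 * spec.dt_h, spec.dt_h)
    positions = {}
    for i, t in enumerate(times):
        if i > 0:
            theta = theta + rng.normal(0.0, sig_theta, size=theta.shape)
            r = np.abs(r + rng.normal(0.0, sig_r, size=r.shape))
        xy = np.asarray(spec.center_um) + np.column_stack(
            [r * np.cos(theta), r * np.sin(theta)])
        if spec.noise_um > 0:
            xy = xy + rng.normal(0.0, spec.noise_um, size=xy.shape)
        positions[float(t)] = xy
    truth = {"omega0_rad_h": 0.0, "v_rho_um_min": 0.0,
             "sigma_theta_per_frame": sig_theta, "sigma_r_per_frame": sig_r}
    return _to_table(spec, positions), truth


@dataclass(frozen=True)
class GrowthSpec:
    """Exponential cell-count series for a set of clusters."""

    n_clusters: int = 50
    n0_range: tuple[int, int] = (5, 50)
    t_d_h: float = 71.0
    noise_sigma: float = 0.15           # lognormal multiplicative
    t_max_h: float = 144.0
    dt_h: float = 12.0
    a_cell_um2: float = 500.0           # inverse density for areas
    small_cluster_spread: bool = False  # rising A_cell at small areas
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_d_h <= 0 or self.n_clusters < 1:
            raise ValueError("t_d and n_clusters must be positive")
        if self.n0_range[0] < 1 or self.n0_range[1] < self.n0_range[0]:
            raise ValueError("invalid n0_range")


def gen_growth_counts(spec: GrowthSpec) -> tuple[pd.DataFrame, dict]:
    """Cell-count and cluster-area series N(t) = round(N0 2^(t/t_d) eps).

    eps is lognormal with log-sd ``noise_sigma``.  Areas are
    A = N * A_cell; with ``small_cluster_spread`` the effective area
    per cell rises with cluster area toward the plateau (boundary-cell
    spreading in small clusters), giving the rising-then-flat density
    profile.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.t_max_h + 0.5 * spec.dt_h, spec.dt_h)
    rows = []
    n0s = rng.integers(spec.n0_range[0], spec.n0_range[1] + 1,
                       size=spec.n_clusters)
    for cid in range(spec.n_clusters):
        n0 = int(n0s[cid])
        eps = rng.lognormal(0.0, spec.noise_sigma, size=times.shape) \
            if spec.noise_sigma > 0 else np.ones_like(times)
        n = np.maximum(1, np.round(n0 * 2.0 ** (times / spec.t_d_h) * eps))
        area0 = n * spec.a_cell_um2
        if spec.small_cluster_spread:
            half = 0.5 * FREE_SPREAD_SCALE_UM2
            a_cell = spec.a_cell_um2 * (area0 / (area0 + half))
            area = n * a_cell
        else:
            area = area0
        rows.append(pd.DataFrame({
            "cluster_id": cid, "t_h": times,
            "n_cells": n.astype(int), "area_um2": area,
        }))
    truth = {"t_d_h": spec.t_d_h, "n0": n0s,
             "a_cell_um2": spec.a_cell_um2}
    return pd.concat(rows, ignore_index=True), truth


#: area scale of the boundary-spreading regime in small clusters
FREE_SPREAD_SCALE_UM2 = 2.0e4


@dataclass(frozen=True)
class ConfluenceSpec:
    """Confluence-versus-time curves at several seeding densities."""

    a_s0: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)
    tau_h: float = 50.8
    noise_sigma: float = 0.05
    t_max_h: float = 250.0
    dt_h: float = 8.0
    cap: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_h <= 0:
            raise ValueError("tau must be positive")
        if any(a <= 0 or a > self.cap for a in self.a_s0):
            raise ValueError("initial confluences must lie in (0, cap]")


def gen_confluence_curves(spec: ConfluenceSpec) -> tuple[pd.DataFrame, dict]:
    """Confluence curves A_s(t) = min(cap, A_s0 2^(t/tau) eps)."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.t_max_h + 0.5 * spec.dt_h, spec.dt_h)
    rows = []
    for sid, a0 in enumerate(spec.a_s0):
        eps = rng.lognormal(0.0, spec.noise_sigma, size=times.shape) \
            if spec.noise_sigma > 0 else np.ones_like(times)
        a_s = np.minimum(spec.cap, a0 * 2.0 ** (times / spec.tau_h) * eps)
        rows.append(pd.DataFrame({"sample_id": sid, "t_h": times, "a_s": a_s}))
    truth = {"tau_h": spec.tau_h, "a_s0": np.asarray(spec.a_s0),
             "cap": spec.cap}
    return pd.concat(rows, ignore_index=True), truth
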