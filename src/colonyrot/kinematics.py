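"""Trajectory kinematics of rotating cell clusters.

Tracked cell positions (track_id, cluster_id, t in hours, x and y in
micrometres; Cartesian, counterclockwise-positive angles) are
decomposed into radial and angular velocities about the per-frame
cluster centroid.  Clusters are partitioned into an inner and an
outer region by the cell radius at the first analysed frame, and
population statistics (mean +/- sample SD per region per interval)
and cluster-level summaries (time-averaged angular velocity versus
cluster area) are computed.

Conventions: the radial velocity V_rho is reported in um/min and the
angular velocity omega in rad/h, matching the time-lapse literature;
angular displacements per interval are wrapped to (-pi, pi], so the
detectable |omega| at a sampling interval dt_h is below pi/dt_h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_trajectories",
    "cluster_centroid",
    "polar_velocities",
    "partition_regions",
    "population_stats",
    "ClusterSummary",
    "summarize_cluster",
    "omega_vs_area",
]

REQUIRED_COLUMNS = ("track_id", "cluster_id", "t_h", "x_um", "y_um")

#: cells closer than this to the centroid have undefined angular velocity
R_EPS_UM = 2.0


def validate_trajectories(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trajectory table; returns a sorted copy.

    Requires the standard columns, unique (track_id, t_h) pairs and at
    least two sampled times per track.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    dup = df.duplicated(subset=["track_id", "t_h"])
    if dup.any():
        row = df.index[dup][0]
        raise ValueError(
            f"duplicate (track_id, t_h) at row {row}: "
            f"track {df.loc[row, 'track_id']} t={df.loc[row, 't_h']}"
        )
    for col in ("t_h", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
    counts = df.groupby("track_id")["t_h"].nunique()
    short = counts[counts < 2]
    if len(short):
        raise ValueError(
            f"tracks with fewer than 2 sampled times: {list(short.index[:5])}"
        )
    return df.sort_values(["cluster_id", "track_id", "t_h"]).reset_index(drop=True)


def cluster_centroid(frame: pd.DataFrame) -> tuple[float, float]:
    """Arithmetic mean of tracked cell positions in one frame."""
    if len(frame) < 3:
        raise ValueError(f"need at least 3 cells per frame, got {len(frame)}")
    return float(frame["x_um"].mean()), float(frame["y_um"].mean())


def _polar_frame(cluster: pd.DataFrame) -> pd.DataFrame:
    """Per-frame centroid-relative polar coordinates for one cluster."""
    out = []
    for t, frame in cluster.groupby("t_h"):
        cx, cy = cluster_centroid(frame)
        dx = frame["x_um"].to_numpy() - cx
        dy = frame["y_um"].to_numpy() - cy
        out.append(pd.DataFrame({
            "track_id": frame["track_id"].to_numpy(),
            "t_h": t,
            "r_um": np.hypot(dx, dy),
            "theta": np.arctan2(dy, dx),
        }))
    return pd.concat(out, ignore_index=True)


def polar_velocities(df: pd.DataFrame, interval_h: float = 2.0,
                     r_eps_um: float = R_EPS_UM) -> pd.DataFrame:
    """Radial and angular velocities about the per-frame centroid.

    For each cell and each interval [t, t + interval]:
    V_rho = (r(t+dt) - r(t)) / dt, converted to um/min, and
    omega = wrap(theta(t+dt) - theta(t)) / dt in rad/h with the
    angular difference wrapped to (-pi, pi].  The interval must be a
    multiple of the sampling step.  Cells within ``r_eps_um`` of the
    centroid at either end get NaN omega (kept for V_rho).  Intervals
    with a missing end frame are skipped.

    Returns columns (cluster_id, track_id, t_h, v_rho_um_min,
    omega_rad_h, r_um).
    """
    df = validate_trajectories(df)
    rows = []
    for cid, cluster in df.groupby("cluster_id"):
        times = np.array(sorted(cluster["t_h"].unique()))
        if len(times) >= 2:
            step = float(np.min(np.diff(times)))
            ratio = interval_h / step
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"interval {interval_h} h is not a multiple of the "
                    f"sampling step {step} h (cluster {cid})"
                )
        polar = _polar_frame(cluster)
        pivot_r = polar.pivot(index="track_id", columns="t_h", values="r_um")
        pivot_th = polar.pivot(index="track_id", columns="t_h", values="theta")
        for t0 in times:
            t1 = t0 + interval_h
            # tolerate float jitter in time stamps
            match = times[np.isclose(times, t1)]
            if len(match) == 0:
                continue
            t1 = match[0]
            r0, r1 = pivot_r[t0], pivot_r[t1]
            th0, th1 = pivot_th[t0], pivot_th[t1]
            ok = r0.notna() & r1.notna()
            dth = np.mod(th1 - th0 + np.pi, 2.0 * np.pi) - np.pi
            # wrap to (-pi, pi]: mod gives [-pi, pi) with -pi for exact pi
            dth = np.where(dth == -np.pi, np.pi, dth)
            omega = dth / interval_h
            omega = np.where((r0 < r_eps_um) | (r1 < r_eps_um), np.nan, omega)
            v_rho = (r1 - r0) / interval_h / 60.0   # um/h -> um/min
            sub = pd.DataFrame({
                "cluster_id": cid,
                "track_id": pivot_r.index,
                "t_h": t0,
                "v_rho_um_min": v_rho,
                "omega_rad_h": omega,
                "r_um": r0,
            })[ok.to_numpy()]
            rows.append(sub)
    if not rows:
        raise ValueError("no complete intervals found")
    return pd.concat(rows, ignore_index=True)


def partition_regions(df: pd.DataFrame, r_split_um: float) -> pd.DataFrame:
    """Inner/outer labels from the radius at the first analysed frame.

    A cell is 'inner' when its distance from the cluster centroid at
    the cluster's first frame is within ``r_split_um``; labels are
    fixed thereafter.  Returns columns (cluster_id, track_id, region).
    """
    if r_split_um <= 0:
        raise ValueError("r_split_um must be positive")
    df = validate_trajectories(df)
    rows = []
    for cid, cluster in df.groupby("cluster_id"):
        t0 = cluster["t_h"].min()
        frame = cluster[cluster["t_h"] == t0]
        cx, cy = cluster_centroid(frame)
        r = np.hypot(frame["x_um"] - cx, frame["y_um"] - cy)
        rows.append(pd.DataFrame({
            "cluster_id": cid,
            "track_id": frame["track_id"].to_numpy(),
            "region": np.where(r <= r_split_um, "inner", "outer"),
        }))
    out = pd.concat(rows, ignore_index=True)
    for cid, sub in out.groupby("cluster_id"):
        for region in ("inner", "outer"):
            if not (sub["region"] == region).any():
                import warnings

                warnings.warn(f"cluster {cid}: empty {region} region",
                              stacklevel=2)
    return out


def population_stats(kin: pd.DataFrame, regions: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Population mean +/- sample SD per region per interval.

    If ``regions`` is None all cells form a single region 'all'.
    Returns rows (cluster_id, region, t_h, n, v_rho_mean, v_rho_sd,
    omega_mean, omega_sd); the SD is NaN for single-cell regions.
    """
    kin = kin.copy()
    if regions is not None:
        kin = kin.merge(regions, on=["cluster_id", "track_id"], how="left")
        kin["region"] = kin["region"].fillna("all")
    else:
        kin["region"] = "all"
    grouped = kin.groupby(["cluster_id", "region", "t_h"])
    out = grouped.agg(
        n=("track_id", "size"),
        v_rho_mean=("v_rho_um_min", "mean"),
        v_rho_sd=("v_rho_um_min", lambda s: s.std(ddof=1)),
        omega_mean=("omega_rad_h", "mean"),
        omega_sd=("omega_rad_h", lambda s: s.std(ddof=1)),
    ).reset_index()
    return out


@dataclass
class ClusterSummary:
    """Geometry and time-averaged kinematics of one cluster."""

    cluster_id: object
    n_cells: int
    mean_radius_um: float
    aspect_ratio: float
    area_um2: float
    n_inner: int
    n_outer: int
    omega_mean_rad_h: float     # time-averaged population-mean omega
    v_rho_mean_um_min: float


def _cluster_geometry(frame: pd.DataFrame) -> tuple[float, float, float]:
    """Mean radius, aspect ratio (minor/major from the position
    covariance) and ellipse-equivalent area of one frame."""
    cx, cy = cluster_centroid(frame)
    dx = frame["x_um"].to_numpy() - cx
    dy = frame["y_um"].to_numpy() - cy
    mean_r = float(np.mean(np.hypot(dx, dy)))
    cov = np.cov(np.vstack([dx, dy]))
    evals = np.sort(np.linalg.eigvalsh(cov))
    aspect = float(np.sqrt(max(evals[0], 0.0) / evals[1])) if evals[1] > 0 else 1.0
    # uniform ellipse: cell positions sample it with axis = 2*sigma
    a = 2.0 * np.sqrt(evals[1])
    b = 2.0 * np.sqrt(max(evals[0], 0.0))
    area = float(np.pi * a * b)
    return mean_r, aspect, area


def summarize_cluster(df: pd.DataFrame, interval_h: float = 2.0,
                      r_split_um: float | None = None,
                      area_um2: float | None = None) -> ClusterSummary:
    """Summary of a single-cluster trajectory table.

    ``area_um2`` overrides the position-based area estimate when a
    traced contour area is available.  ``r_split_um`` defaults to half
    the initial mean radius.
    """
    df = validate_trajectories(df)
    cids = df["cluster_id"].unique()
    if len(cids) != 1:
        raise ValueError("summarize_cluster expects a single cluster")
    t0 = df["t_h"].min()
    frame0 = df[df["t_h"] == t0]
    mean_r, aspect, area_est = _cluster_geometry(frame0)
    if r_split_um is None:
        r_split_um = mean_r / 2.0
    regions = partition_regions(df, r_split_um)
    kin = polar_velocities(df, interval_h)
    stats_all = population_stats(kin)
    return ClusterSummary(
        cluster_id=cids[0],
        n_cells=frame0["track_id"].nunique(),
        mean_radius_um=mean_r,
        aspect_ratio=aspect,
        area_um2=area_um2 if area_um2 is not None else area_est,
        n_inner=int((regions["region"] == "inner").sum()),
        n_outer=int((regions["region"] == "outer").sum()),
        omega_mean_rad_h=float(stats_all["omega_mean"].mean()),
        v_rho_mean_um_min=float(stats_all["v_rho_mean"].mean()),
    )


def omega_vs_area(summaries: list[ClusterSummary]) -> dict:
    """Angular velocity versus cluster area across clusters.

    Returns the (area, omega) table, the OLS line omega = a + b*area,
    and the Spearman correlation of |omega| with area (the magnitude
    trend).  Requires at least 2 clusters with distinct areas.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 clusters")
    area = np.array([s.area_um2 for s in summaries], dtype=float)
    omega = np.array([s.omega_mean_rad_h for s in summaries], dtype=float)
    if np.ptp(area) == 0:
        raise ValueError("degenerate areas: all clusters identical")
    fit = stats.linregress(area, omega)
    if np.allclose(omega, 0.0):
        rho_abs, p_abs = 0.0, 1.0
    else:
        rho_abs, p_abs = stats.spearmanr(area, np.abs(omega))
    return {
        "table": pd.DataFrame({"area_um2": area, "omega_rad_h": omega}),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_stderr": float(fit.stderr),
        "intercept_stderr": float(fit.intercept_stderr),
        "pvalue": float(fit.pvalue),
        "spearman_abs_rho": float(rho_abs),
        "spearman_abs_p": float(p_abs),
        "mean_omega": float(np.mean(omega)),
        "sem_omega": float(np.std(omega, ddof=1) / np.sqrt(len(omega))),
    }
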