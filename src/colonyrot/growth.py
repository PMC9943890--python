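"""Colony-growth analysis: exponential fits and derived quantities.

Cell counts in freely expanding clusters follow N(t) = N0 2^(t/t_d)
with duplication time t_d; the confluence fraction A_s(t) of a whole
field of view follows the same law with doubling time tau once curves
from different seeding densities are shifted in time onto a master
curve.  The critical cluster area separating free expansion from the
density-increase regime follows from the boundary radial speed v_rho
via v_rho = sqrt(A_c / (4 pi tau^2)).

All exponential fits are performed on log2-transformed data
(variance-stabilising for multiplicative noise) with the amplitude
pinned to the first observation, so the characteristic time is the
only adjustable parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DoublingFit",
    "fit_doubling_time",
    "density_curve",
    "critical_area",
    "um_per_min_to_um_per_h",
    "equivalent_diameter",
    "MasterCurve",
    "build_master_curve",
]

#: cluster area above which the area per cell is constant (um^2)
FREE_EXPANSION_AREA_UM2 = 2.0e4


@dataclass
class DoublingFit:
    """Pooled exponential-growth fit result."""

    t_d_h: float            # doubling time (hours); inf if no growth
    stderr_h: float         # standard error of t_d
    r_squared: float
    n_points: int
    proliferating: bool     # False when the pooled slope is <= 0


def fit_doubling_time(records: pd.DataFrame, count_col: str = "n_cells",
                      ) -> DoublingFit:
    """Duplication time from pooled count series N(t) = N0 2^(t/t_d).

    ``records`` has columns (cluster_id, t_h, n_cells).  Per cluster,
    N0 is fixed to the first observation; y = log2(N/N0) is regressed
    on the elapsed time through the origin, pooling all clusters, so
    t_d is the only adjustable parameter.
    """
    required = {"cluster_id", "t_h", count_col}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if (records[count_col] <= 0).any():
        raise ValueError("non-positive cell counts")
    t_all, y_all = [], []
    for _, grp in records.groupby("cluster_id"):
        grp = grp.sort_values("t_h")
        n0 = float(grp[count_col].iloc[0])
        t0 = float(grp["t_h"].iloc[0])
        t_all.append(grp["t_h"].to_numpy(dtype=float) - t0)
        y_all.append(np.log2(grp[count_col].to_numpy(dtype=float) / n0))
    t = np.concatenate(t_all)
    y = np.concatenate(y_all)
    keep = t > 0
    if keep.sum() < 2:
        raise ValueError("need at least 3 observations per fit")
    t, y = t[keep], y[keep]
    slope = float(np.sum(t * y) / np.sum(t * t))
    resid = y - slope * t
    dof = max(len(t) - 1, 1)
    var_slope = float(np.sum(resid**2) / dof / np.sum(t * t))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if slope <= 0:
        return DoublingFit(t_d_h=np.inf, stderr_h=np.nan, r_squared=r2,
                           n_points=len(t), proliferating=False)
    t_d = 1.0 / slope
    stderr = np.sqrt(var_slope) / slope**2    # delta method for 1/slope
    return DoublingFit(t_d_h=t_d, stderr_h=float(stderr), r_squared=r2,
                       n_points=len(t), proliferating=True)


def density_curve(records: pd.DataFrame,
                  threshold_um2: float = FREE_EXPANSION_AREA_UM2) -> dict:
    """Area per cell A_cell = A_cluster / N_cells versus cluster area.

    Returns the pointwise table plus a change-point summary: the mean
    A_cell below and above the free-expansion threshold (NaN when a
    side is empty, e.g. a single cluster observation).
    """
    required = {"t_h", "n_cells", "area_um2"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if (records["n_cells"] <= 0).any():
        raise ValueError("non-positive cell counts")
    table = records.copy()
    table["a_cell_um2"] = table["area_um2"] / table["n_cells"]
    below = table.loc[table["area_um2"] < threshold_um2, "a_cell_um2"]
    above = table.loc[table["area_um2"] >= threshold_um2, "a_cell_um2"]
    return {
        "table": table,
        "threshold_um2": threshold_um2,
        "a_cell_below": float(below.mean()) if len(below) else np.nan,
        "a_cell_above": float(above.mean()) if len(above) else np.nan,
    }


def um_per_min_to_um_per_h(v: float) -> float:
    """Exact unit conversion um/min -> um/h."""
    return v * 60.0


def critical_area(tau_h: float, v_rho: float, v_rho_units: str = "um/h") -> float:
    """Critical cluster area of the free-expansion regime (um^2).

    Inverts v_rho = sqrt(A_c / (4 pi tau^2)):  A_c = 4 pi tau^2 v_rho^2,
    with tau in hours and v_rho in um/h (or um/min, converted exactly).
    """
    if v_rho_units == "um/min":
        v_rho = um_per_min_to_um_per_h(v_rho)
    elif v_rho_units != "um/h":
        raise ValueError(f"unknown v_rho_units {v_rho_units!r}")
    if tau_h <= 0 or v_rho <= 0:
        raise ValueError("tau and v_rho must be positive")
    return 4.0 * np.pi * tau_h**2 * v_rho**2


def equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the given area: d = 2 sqrt(A/pi)."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = 2.0 * np.sqrt(area / np.pi)
    return float(out) if out.ndim == 0 else out


@dataclass
class MasterCurve:
    """Master-curve alignment and pooled doubling-time fit."""

    tau_h: float
    a_s0: float                     # reference initial confluence
    shifts_h: dict                  # sample_id -> applied time shift
    reference_id: object
    shifted: pd.DataFrame           # columns sample_id, t_h, a_s
    n_points: int


def _log2_interp(t: np.ndarray, t_ref: np.ndarray, y_ref: np.ndarray
                 ) -> np.ndarray:
    return np.interp(t, t_ref, y_ref, left=np.nan, right=np.nan)


def build_master_curve(series: pd.DataFrame, cap: float = 1.0,
                       max_shift_h: float | None = None) -> MasterCurve:
    """Shift confluence curves onto a master curve and fit the
    occupancy doubling time.

    ``series`` has columns (sample_id, t_h, a_s) with 0 < a_s <= 1.
    Points at the saturation cap are excluded.  The reference is the
    sample whose initial confluence is closest to the median initial
    confluence; every other sample is shifted in time by the offset
    minimising the summed squared difference of log2(a_s) over the
    overlap (golden-section search over a bounded window).  The pooled
    fit of A_s = A_s0 2^(t/tau) on the shifted data keeps tau as the
    only free parameter, with A_s0 fixed to the reference's first
    (uncapped) observation.
    """
    required = {"sample_id", "t_h", "a_s"}
    if not required.issubset(series.columns):
        raise ValueError(f"series must have columns {sorted(required)}")
    if ((series["a_s"] <= 0) | (series["a_s"] > cap)).any():
        raise ValueError(f"a_s must lie in (0, {cap}]")
    work = series[series["a_s"] < cap].copy()   # capped frames excluded
    work["log2_as"] = np.log2(work["a_s"])
    ids = sorted(work["sample_id"].unique())
    if len(ids) < 2:
        raise ValueError("need at least 2 confluence series")

    initial = {sid: grp.sort_values("t_h")["a_s"].iloc[0]
               for sid, grp in work.groupby("sample_id")}
    med = np.median(list(initial.values()))
    ref_id = min(ids, key=lambda s: abs(initial[s] - med))
    ref = work[work["sample_id"] == ref_id].sort_values("t_h")
    t_ref = ref["t_h"].to_numpy(dtype=float)
    y_ref = ref["log2_as"].to_numpy(dtype=float)
    if max_shift_h is None:
        span = float(series["t_h"].max() - series["t_h"].min())
        max_shift_h = 3.0 * span + 1.0

    shifts: dict = {ref_id: 0.0}
    for sid in ids:
        if sid == ref_id:
            continue
        grp = work[work["sample_id"] == sid].sort_values("t_h")
        t_s = grp["t_h"].to_numpy(dtype=float)
        y_s = grp["log2_as"].to_numpy(dtype=float)
        if y_s.min() > y_ref.max() or y_s.max() < y_ref.min():
            raise ValueError(
                f"sample {sid!r}: confluence range disjoint from reference "
                f"{ref_id!r}; no overlap to align"
            )

        def cost(shift: float) -> float:
            y_at = _log2_interp(t_s + shift, t_ref, y_ref)
            ok = ~np.isnan(y_at)
            if ok.sum() < 2:
                return np.inf
            return float(np.mean((y_s[ok] - y_at[ok]) ** 2))

        # coarse scan (robust to the no-overlap plateau), then a
        # bounded golden-section refinement around the best cell
        grid = np.linspace(-max_shift_h, max_shift_h, 801)
        coarse = np.array([cost(s) for s in grid])
        if not np.any(np.isfinite(coarse)):
            raise ValueError(
                f"sample {sid!r}: no confluence overlap with reference "
                f"{ref_id!r}; cannot align"
            )
        ibest = int(np.nanargmin(np.where(np.isfinite(coarse), coarse, np.nan)))
        step = grid[1] - grid[0]
        lo = grid[max(ibest - 1, 0)]
        hi = grid[min(ibest + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda s: cost(s) if np.isfinite(cost(s)) else coarse[ibest] + s**2,
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-8},
        )
        shifts[sid] = float(res.x) if cost(res.x) <= coarse[ibest] else float(grid[ibest])

    shifted = work.copy()
    shifted["t_h"] = shifted.apply(
        lambda r: r["t_h"] + shifts[r["sample_id"]], axis=1)
    a_s0 = float(ref["a_s"].iloc[0])
    t0 = float(t_ref[0])
    t = shifted["t_h"].to_numpy(dtype=float) - t0
    y = shifted["log2_as"].to_numpy(dtype=float) - np.log2(a_s0)
    use = np.abs(t) > 1e-12
    slope = float(np.sum(t[use] * y[use]) / np.sum(t[use] ** 2))
    if slope <= 0:
        raise ValueError("non-growing confluence data: cannot fit tau")
    return MasterCurve(
        tau_h=1.0 / slope, a_s0=a_s0, shifts_h=shifts, reference_id=ref_id,
        shifted=shifted[["sample_id", "t_h", "a_s"]], n_points=int(use.sum()),
    )
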