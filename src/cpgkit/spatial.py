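"""Normalized interneuron soma positions, density maps and Hotelling's T² test.

Soma positions are measured in a transverse spinal-cord section as a polar
pair from the ventral limit of the central canal: distance ``d_um`` and angle
``alpha_deg`` from the medio-lateral axis, together with the section's
height ``H_um`` (central canal to dorsal edge) and hemicord width ``W_um``
(central canal to lateral edge).  They are normalized to fractional
coordinates

    DV = d * sin(alpha) / H        (ventral -> dorsal)
    ML = d * cos(alpha) / W        (medial -> lateral)

reported as percentages of spinal-cord height and hemicord width.  Both
hemicords are folded onto one side (left-side cells mirrored), so analysis
operates on one hemicord with ML, DV in [0, 1].

Group comparison uses the two-sample Hotelling's T² test — the
two-dimensional generalization of Student's t — on the (ML, DV) point
clouds.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi
from scipy import stats as _stats

from .rhythm import TestResult

__all__ = [
    "normalize_position",
    "normalize_positions",
    "density_maps",
    "hotelling_t2",
]

POSITION_COLUMNS = ("embryo_id", "genotype", "level", "d_um", "alpha_deg", "H_um", "W_um")


def normalize_position(d_um: float, alpha_deg: float, H_um: float, W_um: float) -> tuple[float, float]:
    """Fractional (DV, ML) position of one soma.

    Returns fractions in [0, 1] under exact measurements; multiply by 100
    for the conventional percentage read-out.
    """
    if H_um <= 0 or W_um <= 0:
        raise ValueError("section height H and hemicord width W must be > 0")
    if d_um < 0:
        raise ValueError("soma distance d must be >= 0")
    if not (0.0 <= alpha_deg <= 180.0):
        raise ValueError("alpha must lie in [0, 180] degrees")
    a = np.deg2rad(alpha_deg)
    return float(d_um * np.sin(a) / H_um), float(d_um * np.cos(a) / W_um)


def normalize_positions(df: pd.DataFrame, clamp: bool = True) -> pd.DataFrame:
    """Add ``dv_frac/ml_frac`` and ``dv_pct/ml_pct`` columns to a position table.

    Accepts either raw polar columns (``d_um, alpha_deg, H_um, W_um``) or
    precomputed ``dv_pct/ml_pct``.  Values slightly outside [0, 1]
    (measurement noise at the section border) are clamped with a warning
    rather than dropped.
    """
    out = df.copy()
    if {"dv_pct", "ml_pct"}.issubset(out.columns):
        dv = out["dv_pct"].to_numpy(dtype=float) / 100.0
        ml = out["ml_pct"].to_numpy(dtype=float) / 100.0
    else:
        missing = {"d_um", "alpha_deg", "H_um", "W_um"} - set(out.columns)
        if missing:
            raise ValueError(f"position table lacks columns: {sorted(missing)}")
        d = out["d_um"].to_numpy(dtype=float)
        a = np.deg2rad(out["alpha_deg"].to_numpy(dtype=float))
        H = out["H_um"].to_numpy(dtype=float)
        W = out["W_um"].to_numpy(dtype=float)
        if np.any(H <= 0) or np.any(W <= 0):
            raise ValueError("H and W must be > 0 for every record")
        dv = d * np.sin(a) / H
        ml = d * np.cos(a) / W
    if clamp:
        outside = (dv < 0) | (dv > 1) | (ml < 0) | (ml > 1)
        if np.any(outside):
            warnings.warn(
                f"{int(outside.sum())} cells outside the unit square were clamped",
                stacklevel=2,
            )
            dv = np.clip(dv, 0.0, 1.0)
            ml = np.clip(ml, 0.0, 1.0)
    out["dv_frac"] = dv
    out["ml_frac"] = ml
    out["dv_pct"] = dv * 100.0
    out["ml_pct"] = ml * 100.0
    return out


def _axis_density(x: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    """Per-point Gaussian kernel columns with reflection boundary correction.

    Kernel mass falling outside the section is folded back by mirroring each
    point at 0 and at 1, so a uniform field stays flat up to the tissue
    border instead of drooping by the truncated mass.
    """
    g = grid[:, None]
    out = np.zeros((grid.size, x.size))
    for mirrored in (x, -x, 2.0 - x):
        z = (g - mirrored[None, :]) / bw
        out += np.exp(-0.5 * z * z)
    return out


def density_maps(
    points: np.ndarray | pd.DataFrame,
    grid_size: int = 50,
    bandwidth: float = 0.05,
) -> dict:
    """2-D soma-density map over the unit (ML, DV) square with 1-D marginals.

    A fixed-bandwidth Gaussian product kernel is evaluated on a
    ``grid_size`` x ``grid_size`` grid of cell centres and renormalized so
    the map integrates to 1 over the unit square (the kernel mass lost
    beyond the tissue border is folded back by the renormalization).
    Marginals are 1-D kernel densities along each axis, each integrating
    to 1.
    """
    if isinstance(points, pd.DataFrame):
        pts = points[["ml_frac", "dv_frac"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValueError("density estimation requires at least one point")
    if bandwidth <= 0 or grid_size < 2:
        raise ValueError("bandwidth must be > 0 and grid_size >= 2")
    step = 1.0 / grid_size
    centers = (np.arange(grid_size) + 0.5) * step
    gx = _axis_density(pts[:, 0], centers, bandwidth)  # (grid, n) in ML
    gy = _axis_density(pts[:, 1], centers, bandwidth)  # (grid, n) in DV
    # separable product kernel summed over points: map[iy, ix]
    map2d = gy @ gx.T
    map2d = map2d / (map2d.sum() * step * step)
    marg_ml = gx.sum(axis=1)
    marg_ml = marg_ml / (marg_ml.sum() * step)
    marg_dv = gy.sum(axis=1)
    marg_dv = marg_dv / (marg_dv.sum() * step)
    return {
        "grid": centers,
        "map2d": map2d,  # rows: DV, columns: ML
        "marginal_ml": marg_ml,
        "marginal_dv": marg_dv,
        "bandwidth": float(bandwidth),
        "n": int(pts.shape[0]),
    }


def density_modes(map2d: np.ndarray, min_frac: float = 0.2) -> list[tuple[int, int]]:
    """(row, col) local maxima of a density map above ``min_frac`` of its peak."""
    footprint = np.ones((3, 3), dtype=bool)
    local_max = map2d == _ndi.maximum_filter(map2d, footprint=footprint, mode="nearest")
    local_max &= map2d >= min_frac * map2d.max()
    # collapse plateaus to one representative per connected component
    labels, nlab = _ndi.label(local_max)
    out = []
    for lab in range(1, nlab + 1):
        rows, cols = np.nonzero(labels == lab)
        out.append((int(round(rows.mean())), int(round(cols.mean()))))
    return out


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-sample Hotelling's T² on 2-D point clouds.

    T² = (n1 n2 / (n1 + n2)) (x̄1 − x̄2)ᵀ S⁻¹ (x̄1 − x̄2) with S the pooled
    covariance; F = T² (n1 + n2 − 3) / (2 (n1 + n2 − 2)) is referred to an
    F(2, n1 + n2 − 3) distribution.  The statistic is invariant under any
    common affine transformation of both groups.
    """
    A = np.asarray(group_a, dtype=float).reshape(-1, 2)
    B = np.asarray(group_b, dtype=float).reshape(-1, 2)
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 3 or n2 < 3:
        raise ValueError("each group needs at least 3 points")
    diff = A.mean(axis=0) - B.mean(axis=0)
    S = ((n1 - 1) * np.cov(A, rowvar=False) + (n2 - 1) * np.cov(B, rowvar=False)) / (
        n1 + n2 - 2
    )
    det = np.linalg.det(S)
    if not np.isfinite(det) or abs(det) < 1e-300:
        raise ValueError(
            "pooled covariance is singular; jitter the points or use an exact test"
        )
    t2 = float(n1 * n2 / (n1 + n2) * diff @ np.linalg.solve(S, diff))
    df2 = n1 + n2 - 3
    f_stat = t2 * df2 / (2.0 * (n1 + n2 - 2))
    p = float(_stats.f.sf(f_stat, 2, df2))
    return TestResult(
        name="hotelling_t2",
        statistic=t2,
        pvalue=min(max(p, 0.0), 1.0),
        n={"n1": n1, "n2": n2, "df": (2, df2), "F": float(f_stat)},
    )
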