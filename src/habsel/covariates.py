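"""Analysis-ready covariate layers and predictor screening.

Distance and kernel-density surfaces are derived from point/line features
on the projected grid; predictors are z-scored before modeling, screened
pairwise for collinearity (|Pearson r| threshold), and pruned by variance
inflation factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString

from .grid import CovariateStack, GridSpec

#: spacing (m) at which rivers/polylines are discretized into point features
LINE_DISCRETIZATION_M = 100.0

#: default quartic-kernel search radius (m) for density surfaces
DENSITY_RADIUS_M = 10_000.0

#: mean household size used to weight settlement points by population
MEAN_HOUSEHOLD_SIZE = 3.7


def discretize_line(line: LineString, spacing: float = LINE_DISCRETIZATION_M) -> np.ndarray:
    """Points along a polyline at fixed spacing (both endpoints included)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = max(int(np.ceil(line.length / spacing)), 1)
    dists = np.linspace(0.0, line.length, n + 1)
    pts = [line.interpolate(d) for d in dists]
    return np.array([[p.x, p.y] for p in pts])


def _collect_points(features, spacing: float) -> np.ndarray:
    pts: list[np.ndarray] = []
    for feat in features:
        if isinstance(feat, LineString):
            pts.append(discretize_line(feat, spacing))
        else:
            arr = np.atleast_2d(np.asarray(feat, dtype=float))
            if arr.shape[1] != 2:
                raise ValueError("point features must be (x, y) pairs")
            pts.append(arr)
    if not pts:
        raise ValueError("empty feature set")
    return np.vstack(pts)


def distance_to_features(
    grid: GridSpec, features, spacing: float = LINE_DISCRETIZATION_M
) -> np.ndarray:
    """Euclidean distance (m) from each cell center to the nearest feature.

    ``features`` is an iterable of (x, y) points and/or shapely LineStrings;
    polylines are discretized to points at ``spacing`` meters first, which
    bounds the discretization error by ``spacing / 2``.
    """
    pts = _collect_points(features, spacing)
    X, Y = grid.cell_centers()
    tree = cKDTree(pts)
    dist, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
    return dist.reshape(grid.shape)


def quartic_kernel(d: np.ndarray, h: float) -> np.ndarray:
    """Quartic (biweight) kernel density value at distance d, bandwidth h.

    Integrates to one over the plane: (3 / pi h^2) (1 - (d/h)^2)^2 for d < h.
    """
    u = np.asarray(d, dtype=float) / h
    out = np.zeros_like(u)
    inside = u < 1.0
    out[inside] = (3.0 / (np.pi * h * h)) * (1.0 - u[inside] ** 2) ** 2
    return out


def kernel_density(
    grid: GridSpec,
    points: np.ndarray,
    weights: np.ndarray | None = None,
    radius: float = DENSITY_RADIUS_M,
) -> np.ndarray:
    """Quartic-kernel density surface (per m^2) from weighted points.

    Each unit-weight point contributes unit mass; the surface is a true
    density, so the numeric integral over the grid approaches the total
    weight as the cell size shrinks relative to the radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if weights is None:
        weights = np.ones(len(points))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative weights")
    if len(weights) != len(points):
        raise ValueError("weights and points length mismatch")

    out = np.zeros(grid.shape)
    xc = grid.x_centers()
    yc = grid.y_centers()
    halo = int(np.ceil(radius / grid.cellsize)) + 1
    for (px, py), w in zip(points, weights):
        # stamp only the kernel footprint around each point
        ci = int((px - grid.x0) / grid.cellsize)
        ri = grid.nrows - 1 - int((py - grid.y0) / grid.cellsize)
        c0, c1 = max(ci - halo, 0), min(ci + halo + 1, grid.ncols)
        r0, r1 = max(ri - halo, 0), min(ri + halo + 1, grid.nrows)
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xc[c0:c1] - px
        dy = yc[r0:r1] - py
        d = np.hypot(dx[None, :], dy[:, None])
        out[r0:r1, c0:c1] += w * quartic_kernel(d, radius)
    return out


def settlement_weights(households: np.ndarray | None, n_points: int) -> np.ndarray:
    """Per-settlement weights: household counts scaled by mean household size."""
    if households is None:
        return np.ones(n_points)
    return np.asarray(households, dtype=float) * MEAN_HOUSEHOLD_SIZE


def standardize(stack: CovariateStack, names: list[str] | None = None) -> CovariateStack:
    """Z-score the named layers (all by default), recording (mean, sd).

    Already-standardized layers are re-centered against their current values,
    so the operation is idempotent. Raises on zero-variance layers.
    """
    out = stack.copy()
    for name in names if names is not None else stack.names():
        arr = out[name]
        valid = np.isfinite(arr)
        mean = float(arr[valid].mean())
        sd = float(arr[valid].std(ddof=0))
        if sd <= 0:
            raise ValueError(f"layer {name!r} has zero variance")
        out.layers[name] = (arr - mean) / sd
        prev = out.standardization.get(name)
        if prev is None:
            out.standardization[name] = (mean, sd)
        else:
            # compose with the earlier transform so the record still maps
            # raw units to the final z-scale
            out.standardization[name] = (prev[0] + mean * prev[1], sd * prev[1])
    return out


def standardize_with_record(
    stack: CovariateStack, record: dict[str, tuple[float, float]]
) -> CovariateStack:
    """Apply a previously computed standardization record to raw layers."""
    out = stack.copy()
    for name, (mean, sd) in record.items():
        if name in out:
            out.layers[name] = (out[name] - mean) / sd
            out.standardization[name] = (mean, sd)
    return out


def correlation_screen(
    columns: pd.DataFrame, aicc: dict[str, float], threshold: float = 0.70
) -> list[str]:
    """Drop the worse-supported member of every highly correlated pair.

    Pairs with |Pearson r| above ``threshold`` are resolved in decreasing
    order of |r|; within a pair the column with the higher AICc (weaker
    univariate support) is dropped. Ties on AICc drop the lexicographically
    later name, which keeps the outcome deterministic.
    """
    names = list(columns.columns)
    missing = [n for n in names if n not in aicc]
    if missing:
        raise ValueError(f"AICc missing for columns: {missing}")
    retained = set(names)
    corr = columns.corr().abs()
    while True:
        worst: tuple[float, str, str] | None = None
        for i, a in enumerate(names):
            if a not in retained:
                continue
            for b in names[i + 1 :]:
                if b not in retained:
                    continue
                r = corr.loc[a, b]
                if r > threshold and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        _, a, b = worst
        if aicc[a] > aicc[b] or (aicc[a] == aicc[b] and a > b):
            retained.discard(a)
        else:
            retained.discard(b)
    return [n for n in names if n in retained]


def vif_table(columns: pd.DataFrame) -> pd.Series:
    """Variance inflation factor for each column given the others.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression (with intercept) of
    column j on the remaining columns; singular fits yield +inf.
    """
    X = columns.to_numpy(dtype=float)
    n, p = X.shape
    out = {}
    for j, name in enumerate(columns.columns):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        if ss_tot <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(
    columns: pd.DataFrame, threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the largest-VIF column until all VIFs fall below
    ``threshold``; returns retained names plus the per-step VIF trace."""
    if columns.shape[1] < 2:
        return list(columns.columns), pd.DataFrame()
    if columns.shape[0] <= columns.shape[1]:
        raise ValueError("need more rows than columns for VIF")
    work = columns.copy()
    trace = []
    while work.shape[1] >= 2:
        vifs = vif_table(work)
        trace.append(vifs.rename(f"step{len(trace)}"))
        if vifs.max() < threshold:
            break
        work = work.drop(columns=[vifs.idxmax()])
    return list(work.columns), pd.concat(trace, axis=1) if trace else pd.DataFrame()
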