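"""Telemetry preprocessing, demographic classing, and kernel home ranges.

Home ranges are dry-season (Apr-Oct) utilization distributions from
Gaussian-kernel density estimates with diagonal direct-plug-in
bandwidths; the 95% isopleth (smallest set of cells holding 95% of the
UD mass) defines the availability domain for resource selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .grid import GridSpec

#: default impossible-movement threshold (m/h)
MAX_SPEED_M_PER_H = 10_000.0

#: residency screen: net-displacement window (days) and multiple of median
RESIDENCY_WINDOW_DAYS = 14
RESIDENCY_MULTIPLE = 3.0

#: minimum data rule: at least two months of daily positions
MIN_DAYS = 60

SUBADULT_MAX_AGE_YEARS = 4.0


def assign_class(birth_date, sex: str, season_start) -> str:
    """Demographic class from age at the start of the season.

    Subadult if age <= 4 years (boundary inclusive); class is sex by age
    group.
    """
    if not sex or str(sex).lower() not in ("male", "female", "m", "f"):
        raise ValueError(f"missing or unknown sex {sex!r}")
    birth = pd.Timestamp(birth_date)
    start = pd.Timestamp(season_start)
    if birth > start:
        raise ValueError("birth date after season start")
    age_years = (start - birth).days / 365.25
    group = "subadult" if age_years <= SUBADULT_MAX_AGE_YEARS else "adult"
    sex_word = "female" if str(sex).lower().startswith("f") else "male"
    return f"{group} {sex_word}"


def _speed_filter(df: pd.DataFrame, max_speed: float) -> pd.DataFrame:
    """Greedy forward pass dropping fixes that imply impossible speeds."""
    keep = []
    last = None
    for row in df.itertuples():
        if last is None:
            keep.append(row.Index)
            last = row
            continue
        dt_h = (row.timestamp - last.timestamp).total_seconds() / 3600.0
        dist = float(np.hypot(row.x - last.x, row.y - last.y))
        if dt_h <= 0 or dist / dt_h <= max_speed:
            keep.append(row.Index)
            last = row
    return df.loc[keep]


def _residency_filter(df: pd.DataFrame, window_days: int, multiple: float) -> pd.DataFrame:
    """Remove dispersal segments: windows whose net displacement exceeds a
    multiple of the median windowed net displacement."""
    if len(df) < 3:
        return df
    days = df["timestamp"].dt.normalize()
    uniq = days.drop_duplicates().sort_values().to_numpy()
    if len(uniq) <= window_days:
        return df
    nds, spans = [], []
    for start_idx in range(0, len(uniq) - window_days + 1):
        w0, w1 = uniq[start_idx], uniq[start_idx] + pd.Timedelta(days=window_days)
        sel = df[(days >= w0) & (days < w1)]
        if len(sel) < 2:
            continue
        nd = float(np.hypot(sel["x"].iloc[-1] - sel["x"].iloc[0],
                            sel["y"].iloc[-1] - sel["y"].iloc[0]))
        nds.append(nd)
        spans.append((w0, w1))
    if not nds:
        return df
    med = float(np.median(nds))
    bad = np.zeros(len(df), dtype=bool)
    for nd, (w0, w1) in zip(nds, spans):
        if med > 0 and nd > multiple * med:
            bad |= ((days >= w0) & (days < w1)).to_numpy()
    return df.loc[~bad]


def preprocess_telemetry(
    fixes: pd.DataFrame,
    max_speed: float = MAX_SPEED_M_PER_H,
    window_days: int = RESIDENCY_WINDOW_DAYS,
    residency_multiple: float = RESIDENCY_MULTIPLE,
    season: tuple[tuple[int, int], tuple[int, int]] = ((4, 1), (10, 31)),
) -> pd.DataFrame:
    """Clean daily-location table.

    Steps per individual: drop fixes implying step speed above
    ``max_speed`` (greedy forward pass), remove dispersal windows by the
    net-displacement residency rule, restrict to the Apr-Oct season, and
    keep one fix per day (the one closest to local noon).
    """
    df = fixes.copy()
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamps: {exc}") from exc
    out = []
    for _, grp in df.groupby("individual", sort=True):
        grp = grp.sort_values("timestamp")
        grp = _speed_filter(grp, max_speed)
        grp = _residency_filter(grp, window_days, residency_multiple)
        month_day = list(zip(grp["timestamp"].dt.month, grp["timestamp"].dt.day))
        in_season = np.array([season[0] <= md <= season[1] for md in month_day])
        grp = grp.loc[in_season]
        if grp.empty:
            continue
        noon = grp["timestamp"].dt.normalize() + pd.Timedelta(hours=12)
        grp = grp.assign(_off=(grp["timestamp"] - noon).abs())
        grp = grp.sort_values(["timestamp", "_off"]).groupby(
            grp["timestamp"].dt.normalize(), sort=True
        ).apply(lambda g: g.nsmallest(1, "_off"), include_groups=False)
        out.append(grp.reset_index(drop=True).drop(columns="_off"))
    if not out:
        return df.iloc[0:0]
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Direct plug-in bandwidths (diagonal, per axis)


def _phi_deriv(x: np.ndarray, r: int) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
    if r == 4:
        return (x**4 - 6 * x**2 + 3) * phi
    if r == 6:
        return (x**6 - 15 * x**4 + 45 * x**2 - 15) * phi
    raise ValueError(r)


def _psi_hat(x: np.ndarray, g: float, r: int, n_bins: int = 401) -> float:
    """Kernel estimate of the density functional psi_r = int f^(r) f.

    Uses linear binning onto an equispaced grid, so the double sum is
    over bin pairs rather than observation pairs.
    """
    n = len(x)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("degenerate sample")
    grid_pts = np.linspace(lo, hi, n_bins)
    delta = grid_pts[1] - grid_pts[0]
    pos = (x - lo) / delta
    left = np.clip(pos.astype(int), 0, n_bins - 2)
    frac = pos - left
    counts = np.bincount(left, weights=1 - frac, minlength=n_bins) + \
        np.bincount(left + 1, weights=frac, minlength=n_bins)
    diff = (grid_pts[:, None] - grid_pts[None, :]) / g
    kern = _phi_deriv(diff, r)
    return float(counts @ kern @ counts / (n * n * g ** (r + 1)))


def dpi_bandwidth_1d(x: np.ndarray) -> float:
    """Two-stage univariate direct-plug-in bandwidth (Gaussian kernel)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate sample: zero variance")
    sqrt2pi = np.sqrt(2 * np.pi)
    psi8_ns = 105.0 / (32.0 * np.sqrt(np.pi) * sd**9)
    g1 = ((30.0 / sqrt2pi) / (psi8_ns * n)) ** (1.0 / 9.0)
    psi6 = _psi_hat(x, g1, 6)
    if psi6 >= 0:  # numerically degenerate; fall back to normal scale
        psi6 = -15.0 / (16.0 * np.sqrt(np.pi) * sd**7)
    g2 = ((-6.0 / sqrt2pi) / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = _psi_hat(x, g2, 4)
    if psi4 <= 0:
        psi4 = 3.0 / (8.0 * np.sqrt(np.pi) * sd**5)
    return (1.0 / (2.0 * np.sqrt(np.pi) * psi4 * n)) ** 0.2


def plugin_bandwidth(points: np.ndarray, method: str = "dpi") -> np.ndarray:
    """Diagonal 2x2 bandwidth matrix H (m^2) with separate per-axis
    bandwidths.

    ``method='dpi'`` applies the univariate direct-plug-in pipeline to
    each axis; ``method='normal_reference'`` uses H_ii = sigma_i^2 *
    n^(-1/3).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    n = len(pts)
    if n < 30:
        raise ValueError("need at least 30 points for a bandwidth estimate")
    sds = pts.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise ValueError("degenerate (collinear) point set")
    if method == "normal_reference":
        h2 = sds**2 * n ** (-1.0 / 3.0)
    elif method == "dpi":
        h2 = np.array([dpi_bandwidth_1d(pts[:, 0]) ** 2,
                       dpi_bandwidth_1d(pts[:, 1]) ** 2])
    else:
        raise ValueError(f"unknown bandwidth method {method!r}")
    return np.diag(h2)


# ---------------------------------------------------------------------------
# Utilization distributions and isopleths


@dataclass
class UtilizationDistribution:
    individual: str
    season: str
    demographic_class: str
    ud: np.ndarray           # probability mass per cell, sums to 1
    grid: GridSpec
    bandwidth: np.ndarray    # 2x2, m^2
    n_fixes: int
    isopleths: list | None = None
    n_isopleth_parts: int = 0


def kde_ud(points: np.ndarray, H: np.ndarray, grid: GridSpec,
           max_mass_loss: float = 0.01) -> np.ndarray:
    """Gaussian-kernel UD on the grid, normalized to unit total mass.

    H must be positive definite; with a diagonal H the kernel separates
    and the surface is a product of axis contributions. Raises when more
    than ``max_mass_loss`` of the density mass falls outside the grid.
    """
    pts = np.asarray(points, dtype=float)
    H = np.asarray(H, dtype=float)
    if H.shape != (2, 2) or np.any(np.linalg.eigvalsh(H) <= 0):
        raise ValueError("bandwidth matrix must be 2x2 positive definite")
    if abs(H[0, 1]) > 1e-12 * np.sqrt(H[0, 0] * H[1, 1]):
        raise ValueError("only diagonal bandwidth matrices are supported")
    hx, hy = np.sqrt(H[0, 0]), np.sqrt(H[1, 1])
    xc, yc = grid.x_centers(), grid.y_centers()
    gx = np.exp(-0.5 * ((xc[None, :] - pts[:, 0][:, None]) / hx) ** 2) / (
        hx * np.sqrt(2 * np.pi)
    )
    gy = np.exp(-0.5 * ((yc[None, :] - pts[:, 1][:, None]) / hy) ** 2) / (
        hy * np.sqrt(2 * np.pi)
    )
    dens = (gy.T @ gx) / len(pts)         # (nrows, ncols) density per m^2
    mass = dens.sum() * grid.cellsize**2
    if mass < 1.0 - max_mass_loss:
        raise ValueError(
            f"grid captures only {mass:.3f} of the UD mass; enlarge the extent"
        )
    ud = dens / dens.sum()
    return ud


def isopleth_cells(ud: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Boolean mask of the smallest cell set holding >= level of the mass.

    Cells are ranked by density and cut at the cumulative level; this
    density-ranked cut is the minimal-cardinality set among all cell sets
    reaching the level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    flat = ud.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    ncut = int(np.searchsorted(csum, level)) + 1
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:ncut]] = True
    return mask.reshape(ud.shape)


def isopleth(ud: np.ndarray, grid: GridSpec, level: float = 0.95):
    """95% (by default) home-range polygons from a UD raster.

    Returns (list of polygons, number of disjoint parts). Multiple
    disjoint parts are all retained; the count flags non-contiguity.
    """
    mask = isopleth_cells(ud, level)
    rows, cols = np.where(mask)
    xc, yc = grid.x_centers(), grid.y_centers()
    half = grid.cellsize / 2.0
    boxes = [
        box(xc[c] - half, yc[r] - half, xc[c] + half, yc[r] + half)
        for r, c in zip(rows, cols)
    ]
    merged = unary_union(boxes)
    polys = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    return polys, len(polys)


def build_ud(
    fixes: pd.DataFrame,
    grid: GridSpec,
    individual: str,
    season: str,
    demographic_class: str,
    level: float = 0.95,
    bandwidth_method: str = "dpi",
    min_days: int = MIN_DAYS,
) -> UtilizationDistribution:
    """UD + isopleths for one individual-season from clean daily fixes."""
    pts = fixes[["x", "y"]].to_numpy(dtype=float)
    n_days = fixes["timestamp"].dt.normalize().nunique() if "timestamp" in fixes else len(pts)
    if n_days < min_days:
        raise ValueError(
            f"{individual}/{season}: {n_days} days of data; need >= {min_days}"
        )
    H = plugin_bandwidth(pts, method=bandwidth_method)
    ud = kde_ud(pts, H, grid)
    polys, nparts = isopleth(ud, grid, level)
    return UtilizationDistribution(
        individual=individual, season=season, demographic_class=demographic_class,
        ud=ud, grid=grid, bandwidth=H, n_fixes=len(pts),
        isopleths=polys, n_isopleth_parts=nparts,
    )
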