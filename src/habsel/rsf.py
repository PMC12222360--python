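"""Used-available resource selection functions with demographic classes.

Observed fixes are "used" points; "available" points are drawn uniformly
within each home range's 95% UD isopleth at a 1:4 used:available ratio
per range-season.  A logistic mixed model with a demographic-class main
effect and covariate-by-class interactions estimates relative selection;
single-term likelihood-ratio deletions (interactions first) give the
final model, reported as beta, SE, Wald Z, odds ratios with 95% CIs,
LRT chi-squares and Nakagawa R-squares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.ops import unary_union

from .glmm import CLASS_LEVELS, GLMMFit, RandomSpec, build_fixed_matrix, fit_glmm
from .grid import CovariateStack

USED_AVAILABLE_RATIO = 4


def sample_in_polygons(polygons, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points within a polygon set (area-weighted across parts)."""
    merged = unary_union(polygons)
    xmin, ymin, xmax, ymax = merged.bounds
    out = np.empty((0, 2))
    guard = 0
    while len(out) < n:
        m = max((n - len(out)) * 3, 64)
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(m, 2))
        keep = shapely.contains_xy(merged, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
        guard += 1
        if guard > 10_000:
            raise RuntimeError("degenerate polygon set: rejection sampling failed")
    return out[:n]


def build_design(
    used: dict[str, pd.DataFrame],
    range_info: dict[str, dict],
    stack: CovariateStack,
    covariate_names: list[str],
    ratio: int = USED_AVAILABLE_RATIO,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Used-available table with standardized covariates.

    ``used`` maps range-season id -> fix table with x, y columns;
    ``range_info`` maps the same ids to dicts with keys ``polygons``
    (95% isopleth polygons), ``individual`` and ``class``. Covariates are
    extracted from the raw stack at used and available points and then
    z-scored with one shared record across the whole design.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for rid in sorted(used):
        fixes = used[rid]
        info = range_info[rid]
        pts_u = fixes[["x", "y"]].to_numpy(dtype=float)
        if not np.all(stack.grid.contains(pts_u[:, 0], pts_u[:, 1])):
            raise ValueError(f"used points outside raster extent for range {rid}")
        pts_a = sample_in_polygons(info["polygons"], ratio * len(pts_u), rng)
        for pts, resp in ((pts_u, 1), (pts_a, 0)):
            vals = stack.extract(covariate_names, pts[:, 0], pts[:, 1])
            df = pd.DataFrame(vals, columns=covariate_names)
            df.insert(0, "used", resp)
            df["x"] = pts[:, 0]
            df["y"] = pts[:, 1]
            df["class"] = info["class"]
            df["individual"] = info["individual"]
            df["range_id"] = rid
            frames.append(df)
    design = pd.concat(frames, ignore_index=True)
    record: dict[str, tuple[float, float]] = {}
    for name in covariate_names:
        mean = float(design[name].mean())
        sd = float(design[name].std(ddof=0))
        if sd <= 0:
            raise ValueError(f"covariate {name!r} constant over the design")
        design[name] = (design[name] - mean) / sd
        record[name] = (mean, sd)
    return design, record


def lrt_term_deletion(
    design: pd.DataFrame,
    fixed_terms: list,
    random: RandomSpec | None,
    alpha: float = 0.05,
    response: str = "used",
) -> tuple[pd.DataFrame, list, GLMMFit]:
    """Single-term deletions from the full model using likelihood-ratio
    tests: covariate-by-class interactions first (df = 3), then main
    effects of covariates not involved in a retained interaction (df = 1).

    Returns (deletion table, final term list, final fit).  Main effects
    that take part in a retained interaction are kept without testing.
    """
    full = fit_glmm(design, fixed_terms, random, response)
    rows = []
    interactions = [t for t in fixed_terms if isinstance(t, tuple)]
    retained = list(fixed_terms)

    def test_drop(terms, term, df):
        reduced_terms = [t for t in terms if t != term]
        reduced = fit_glmm(design, reduced_terms, random, response)
        if not reduced.converged:
            return None, reduced
        chi2 = max(2.0 * (fit_for(terms).loglik - reduced.loglik), 0.0)
        return (chi2, stats.chi2.sf(chi2, df)), reduced

    _cache: dict[str, GLMMFit] = {}

    def fit_for(terms) -> GLMMFit:
        key = repr(terms)
        if key not in _cache:
            _cache[key] = fit_glmm(design, terms, random, response)
        return _cache[key]

    _cache[repr(list(fixed_terms))] = full

    drop_now = []
    for term in interactions:
        res, _ = test_drop(retained, term, df=3)
        if res is None:
            rows.append({"term": f"{term[0]}:class", "df": 3, "chi2": np.nan,
                         "p": np.nan, "kept": True, "note": "untestable"})
            continue
        chi2, p = res
        keep = p < alpha
        rows.append({"term": f"{term[0]}:class", "df": 3, "chi2": chi2,
                     "p": p, "kept": keep, "note": ""})
        if not keep:
            drop_now.append(term)
    retained = [t for t in retained if t not in drop_now]

    kept_interaction_covs = {t[0] for t in retained if isinstance(t, tuple)}
    mains = [t for t in retained
             if not isinstance(t, tuple) and t != "class"
             and t not in kept_interaction_covs]
    drop_now = []
    for term in mains:
        res, _ = test_drop(retained, term, df=1)
        if res is None:
            rows.append({"term": term, "df": 1, "chi2": np.nan, "p": np.nan,
                         "kept": True, "note": "untestable"})
            continue
        chi2, p = res
        keep = p < alpha
        rows.append({"term": term, "df": 1, "chi2": chi2, "p": p,
                     "kept": keep, "note": ""})
        if not keep:
            drop_now.append(term)
    retained = [t for t in retained if t not in drop_now]
    final = fit_for(retained)
    return pd.DataFrame(rows), retained, final


def odds_ratios(beta, se, z_crit: float = 1.96) -> pd.DataFrame:
    """Odds ratios with 95% confidence intervals: OR = exp(beta),
    CI = exp(beta -/+ 1.96 SE); values reported to 2 decimals."""
    beta = pd.Series(beta, dtype=float)
    se = pd.Series(np.asarray(se, dtype=float), index=beta.index)
    out = pd.DataFrame({
        "beta": beta,
        "se": se,
        "or": np.exp(beta),
        "ci_low": np.exp(beta - z_crit * se),
        "ci_high": np.exp(beta + z_crit * se),
    })
    for col in ("or", "ci_low", "ci_high"):
        out[col + "_2dp"] = out[col].round(2)
    return out


def r2_nakagawa(fit: GLMMFit, design: pd.DataFrame,
                class_col: str = "class") -> tuple[float, float]:
    """Marginal and conditional R-squared for the logistic mixed model.

    Marginal uses the fixed-effect linear-predictor variance over the
    design; conditional adds the summed random-effect variances; the
    logistic link contributes pi^2 / 3 residual variance.
    """
    X, _ = build_fixed_matrix(design, fit.fixed_terms, class_col)
    eta = X @ fit.beta.to_numpy()
    var_f = float(np.var(eta))
    var_r = float(sum(fit.re_variances.values()))
    denom = var_f + var_r + np.pi**2 / 3.0
    return var_f / denom, (var_f + var_r) / denom


def predict_rsf_map(
    fit: GLMMFit,
    stack: CovariateStack,
    demographic_class: str,
    rescale: bool = True,
) -> np.ndarray:
    """Relative-selection surface for one demographic class.

    w(x) = exp(beta_main' x + beta_class + beta_interaction' x for the
    class); the stack must be standardized with the fitting-time record.
    With ``rescale`` the map is linearly scaled to [0, 1] for display.
    """
    if demographic_class not in CLASS_LEVELS:
        raise ValueError(f"unknown class {demographic_class!r}")
    eta = np.zeros(stack.grid.shape)
    for name, b in fit.beta.items():
        if name == "(Intercept)":
            continue
        if ":" in name:
            cov, lev = name.split(":", 1)
            if lev == demographic_class:
                eta += b * stack[cov]
        elif name in CLASS_LEVELS:
            if name == demographic_class:
                eta += b
        else:
            eta += b * stack[name]
    w = np.exp(eta)
    if rescale:
        lo, hi = w.min(), w.max()
        return (w - lo) / (hi - lo) if hi > lo else np.zeros_like(w)
    return w


def fixed_effects_table(fit: GLMMFit, deletion: pd.DataFrame | None = None,
                        r2: tuple[float, float] | None = None) -> pd.DataFrame:
    """Report table mirroring the standard mixed-model output layout:
    beta, SE, Wald Z, P, OR (95% CI), and LRT columns where available."""
    ors = odds_ratios(fit.beta, fit.se)
    tab = pd.DataFrame({
        "beta": fit.beta.round(2),
        "se": fit.se.round(2),
        "z": fit.wald_z().round(2),
        "p_z": fit.wald_p().round(3),
        "or_95ci": [
            f"{o:.2f} ({lo:.2f}-{hi:.2f})"
            for o, lo, hi in zip(ors["or"], ors["ci_low"], ors["ci_high"])
        ],
    })
    tab.attrs["aic"] = fit.aic
    if deletion is not None:
        tab.attrs["lrt"] = deletion
    if r2 is not None:
        tab.attrs["r2_marginal"], tab.attrs["r2_conditional"] = r2
    return tab
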