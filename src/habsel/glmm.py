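"""Logistic mixed models by Laplace-approximated maximum likelihood.

The marginal likelihood integrates a logistic regression over Gaussian
random effects with one grouping factor (here: home-range/season within
individual).  For each group the integral over the random-effect vector
u is replaced by its Laplace approximation around the conditional mode,

    log L_g = l_g(u_hat) - u_hat' S^-1 u_hat / 2
              - log|S|/2 - log|Z_g' W Z_g + S^-1|/2,

with S the random-effect covariance, found by penalized Newton steps.
Fixed effects and covariance parameters (log-SDs, optionally Cholesky
off-diagonals) are optimized jointly by quasi-Newton; fixed-effect
standard errors come from the numerical Hessian at the optimum with the
covariance parameters held at their estimates (the lme4 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess2

CLASS_REFERENCE = "adult female"
CLASS_LEVELS = ("adult female", "subadult female", "adult male", "subadult male")


@dataclass(frozen=True)
class RandomSpec:
    """Random-effect structure for one grouping factor.

    ``slopes`` lists covariate columns with random slopes; ``correlated``
    requests a full covariance between the terms (otherwise diagonal).
    """

    group: str = "range_id"
    intercept: bool = True
    slopes: tuple[str, ...] = ()
    correlated: bool = False

    @property
    def terms(self) -> list[str]:
        out = ["(intercept)"] if self.intercept else []
        return out + list(self.slopes)

    @property
    def q(self) -> int:
        return len(self.terms)


def build_fixed_matrix(
    df: pd.DataFrame,
    terms: list,
    class_col: str = "class",
    reference: str = CLASS_REFERENCE,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix with treatment coding.

    ``terms`` entries are covariate column names, the string
    ``class_col`` for the demographic-class main effect, or tuples
    ``(covariate, class_col)`` for covariate-by-class interactions.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(Intercept)"]
    nonref = [lev for lev in CLASS_LEVELS if lev != reference]

    def dummies() -> dict[str, np.ndarray]:
        cls = df[class_col].astype(str)
        return {lev: (cls == lev).to_numpy(dtype=float) for lev in nonref}

    for term in terms:
        if isinstance(term, tuple):
            cov, _ = term
            x = df[cov].to_numpy(dtype=float)
            for lev, d in dummies().items():
                cols.append(x * d)
                names.append(f"{cov}:{lev}")
        elif term == class_col:
            for lev, d in dummies().items():
                cols.append(d)
                names.append(lev)
        else:
            cols.append(df[term].to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names


def _random_matrix(df: pd.DataFrame, spec: RandomSpec) -> np.ndarray:
    cols = []
    if spec.intercept:
        cols.append(np.ones(len(df)))
    for s in spec.slopes:
        cols.append(df[s].to_numpy(dtype=float))
    return np.column_stack(cols)


def _chol_from_theta(theta: np.ndarray, q: int, correlated: bool) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(theta[:q])
    if correlated and q > 1:
        L[np.tril_indices(q, -1)] = theta[q:]
    return L


def n_theta(q: int, correlated: bool) -> int:
    return q + (q * (q - 1) // 2 if correlated else 0)


class _LaplaceObjective:
    """Negative Laplace log-likelihood with warm-started inner modes."""

    def __init__(self, y, X, Z, group_rows, q, correlated):
        self.y = y
        self.X = X
        self.Z = Z
        self.group_rows = group_rows      # list of row-index arrays
        self.q = q
        self.correlated = correlated
        self.p = X.shape[1]
        self._modes = [np.zeros(q) for _ in group_rows]

    def split(self, params):
        return params[: self.p], params[self.p :]

    def __call__(self, params: np.ndarray) -> float:
        beta, theta = self.split(params)
        eta0 = self.X @ beta
        if self.q == 0:
            mu = _expit_clip(eta0)
            return -float(self.y @ np.log(mu) + (1 - self.y) @ np.log1p(-mu))
        L = _chol_from_theta(theta, self.q, self.correlated)
        # S^-1 via Cholesky; guard against exact singularity
        try:
            Linv = np.linalg.inv(L + 1e-12 * np.eye(self.q))
        except np.linalg.LinAlgError:
            return 1e12
        Sinv = Linv.T @ Linv
        logdetS = 2.0 * np.sum(np.log(np.abs(np.diag(L)) + 1e-12))
        total = 0.0
        for g, rows in enumerate(self.group_rows):
            total += self._group_ll(g, rows, eta0[rows], Sinv, logdetS)
        return -total

    def _group_ll(self, g, rows, eta0, Sinv, logdetS) -> float:
        y = self.y[rows]
        Z = self.Z[rows]
        u = self._modes[g].copy()
        h_old = self._penll(y, eta0, Z, u, Sinv)
        for _ in range(60):
            mu = _expit_clip(eta0 + Z @ u)
            w = mu * (1 - mu)
            grad = Z.T @ (y - mu) - Sinv @ u
            H = Z.T @ (Z * w[:, None]) + Sinv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            t = 1.0
            for _half in range(30):
                u_new = u + t * step
                h_new = self._penll(y, eta0, Z, u_new, Sinv)
                if h_new >= h_old - 1e-12:
                    break
                t *= 0.5
            u = u_new
            if h_new - h_old < 1e-10 and np.abs(grad).max() < 1e-6:
                h_old = h_new
                break
            h_old = h_new
        self._modes[g] = u
        mu = _expit_clip(eta0 + Z @ u)
        w = mu * (1 - mu)
        H = Z.T @ (Z * w[:, None]) + Sinv
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return -1e10
        return h_old - 0.5 * logdetS - 0.5 * logdetH

    @staticmethod
    def _penll(y, eta0, Z, u, Sinv) -> float:
        eta = eta0 + Z @ u
        mu = _expit_clip(eta)
        return float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu)
                     - 0.5 * u @ Sinv @ u)


def _expit_clip(x):
    mu = 0.5 * (1.0 + np.tanh(0.5 * x))
    return np.clip(mu, 1e-10, 1 - 1e-10)


def irls_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Plain logistic regression by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(100):
        mu = _expit_clip(X @ beta)
        w = mu * (1 - mu)
        z = X @ beta + (y - mu) / w
        WX = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ z, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


@dataclass
class GLMMFit:
    beta: pd.Series
    se: pd.Series
    vcov: np.ndarray
    re_variances: dict[str, float]
    re_correlation: np.ndarray | None
    loglik: float
    aic: float
    converged: bool
    singular: bool
    fixed_terms: list = field(default_factory=list)
    random: RandomSpec | None = None
    theta: np.ndarray | None = None
    n_obs: int = 0
    n_groups: int = 0

    def wald_z(self) -> pd.Series:
        return self.beta / self.se

    def wald_p(self) -> pd.Series:
        from scipy import stats
        return pd.Series(2 * stats.norm.sf(np.abs(self.wald_z())), index=self.beta.index)


def fit_glmm(
    design: pd.DataFrame,
    fixed_terms: list,
    random: RandomSpec | None = None,
    response: str = "used",
    class_col: str = "class",
    start_beta: np.ndarray | None = None,
) -> GLMMFit:
    """Fit the used-available logistic model with Gaussian random effects.

    With ``random=None`` (or an empty spec) the model collapses to an
    ordinary logistic regression; the Laplace machinery then returns the
    exact likelihood.
    """
    y = design[response].to_numpy(dtype=float)
    X, names = build_fixed_matrix(design, fixed_terms, class_col)
    dead = [n for n, col in zip(names, X.T) if not np.any(col != 0)]
    if dead:
        raise ValueError(f"empty design columns (missing class levels?): {dead}")
    if random is not None and random.q > 0:
        groups = design[random.group].astype(str).to_numpy()
        levels = pd.unique(groups)
        if len(levels) < 2:
            raise ValueError("need at least 2 grouping levels")
        group_rows = [np.where(groups == lev)[0] for lev in levels]
        Z = _random_matrix(design, random)
        q = random.q
        correlated = random.correlated
    else:
        group_rows, Z, q, correlated = [], np.zeros((len(y), 0)), 0, False
        random = None

    obj = _LaplaceObjective(y, X, Z, group_rows, q, correlated)
    beta0 = start_beta if start_beta is not None else irls_logistic(y, X)
    nth = n_theta(q, correlated)
    theta0 = np.concatenate([np.full(q, np.log(0.5)), np.zeros(nth - q)]) if q else np.array([])
    x0 = np.concatenate([beta0, theta0])
    bounds = [(None, None)] * X.shape[1] + [(-6.0, 4.0)] * q + [(-5.0, 5.0)] * (nth - q)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 400, "ftol": 1e-11})
    beta_hat, theta_hat = obj.split(res.x)

    # fixed-effect covariance: Hessian in beta at theta_hat
    def nll_beta(b):
        return obj(np.concatenate([b, theta_hat]))

    try:
        if q == 0:
            mu = _expit_clip(X @ beta_hat)
            Hb = X.T @ (X * (mu * (1 - mu))[:, None])  # exact information
        else:
            Hb = approx_hess2(beta_hat, nll_beta)
        vcov = np.linalg.pinv(Hb)
        se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    except Exception:
        vcov = np.full((len(beta_hat),) * 2, np.nan)
        se = np.full(len(beta_hat), np.nan)

    re_var: dict[str, float] = {}
    re_corr = None
    singular = False
    if q:
        L = _chol_from_theta(theta_hat, q, correlated)
        S = L @ L.T
        for i, term in enumerate(random.terms):
            re_var[term] = float(S[i, i])
        singular = bool(min(re_var.values()) < 1e-4)
        if correlated and q > 1:
            d = np.sqrt(np.diag(S))
            re_corr = S / np.outer(d, d)
    ll = -res.fun
    k = X.shape[1] + nth
    return GLMMFit(
        beta=pd.Series(beta_hat, index=names),
        se=pd.Series(se, index=names),
        vcov=vcov, re_variances=re_var, re_correlation=re_corr,
        loglik=float(ll), aic=float(-2 * ll + 2 * k),
        converged=bool(res.success or np.isfinite(res.fun)),
        singular=singular, fixed_terms=list(fixed_terms), random=random,
        theta=theta_hat, n_obs=len(y), n_groups=len(group_rows),
    )


def reduce_re_structure(
    design: pd.DataFrame,
    fixed_terms: list,
    random: RandomSpec,
    response: str = "used",
    var_floor: float = 1e-4,
    lrt_cut: float = 3.841,
) -> tuple[RandomSpec, GLMMFit]:
    """Parsimonious random-effect structure.

    Correlations are dropped first (if their removal is supported by a
    likelihood-ratio comparison), then slope terms whose variance falls
    below ``var_floor`` or whose removal changes the log-likelihood by
    less than half the chi-square(1) critical value.  The random
    intercept is the floor and is never removed.
    """
    fit = fit_glmm(design, fixed_terms, random, response)
    spec = random
    if spec.correlated and spec.q > 1:
        diag_spec = replace(spec, correlated=False)
        diag_fit = fit_glmm(design, fixed_terms, diag_spec, response)
        if 2.0 * (fit.loglik - diag_fit.loglik) < lrt_cut:
            spec, fit = diag_spec, diag_fit
    improved = True
    while improved and spec.slopes:
        improved = False
        order = sorted(spec.slopes, key=lambda s: fit.re_variances.get(s, np.inf))
        for slope in order:
            cand = replace(spec, slopes=tuple(s for s in spec.slopes if s != slope))
            if fit.re_variances.get(slope, np.inf) < var_floor:
                spec = cand
                fit = fit_glmm(design, fixed_terms, spec, response)
                improved = True
                break
            cand_fit = fit_glmm(design, fixed_terms, cand, response)
            if 2.0 * (fit.loglik - cand_fit.loglik) < lrt_cut:
                spec, fit = cand, cand_fit
                improved = True
                break
    return spec, fit
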