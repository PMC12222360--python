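"""Occupancy models for replicated presence/absence track surveys.

Three single-season likelihoods are provided:

* ``mackenzie`` — constant occupancy/detection with independent spatial
  replicates: ``L_i = psi * prod_j p^y (1-p)^(1-y) + (1-psi) 1[all 0]``;
* ``markov`` — as above but local presence along consecutive replicates
  follows a two-state Markov chain (theta0 = colonization of the next
  segment, theta1 = persistence), detection Bernoulli(p) where present;
* ``royle_nichols`` — abundance-induced heterogeneous detection: latent
  site abundance ``N ~ Poisson(lambda_i)`` with a log-linear model for
  ``lambda`` and per-individual detection probability r, giving replicate
  detection probability ``1 - (1 - r)^N``.

Model selection follows a univariate screen (Wald p on the abundance
coefficient), a pairwise collinearity screen, an all-subsets AICc
ranking, and conditional model averaging over the dAICc <= 2 set.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .covariates import correlation_screen
from .grid import CovariateStack

_LOG_GUARD = 1e-300


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _logit(p):
    return np.log(p) - np.log1p(-p)


@dataclass
class DetectionData:
    """Ragged per-site detection histories with site covariates."""

    site_ids: np.ndarray
    histories: list[np.ndarray]
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.histories) == 0:
            raise ValueError("empty history set")
        self.histories = [np.asarray(h, dtype=int) for h in self.histories]
        for h in self.histories:
            if h.ndim != 1 or len(h) < 1 or not np.isin(h, (0, 1)).all():
                raise ValueError("histories must be non-empty binary vectors")

    @property
    def n_sites(self) -> int:
        return len(self.histories)

    @property
    def n_replicates(self) -> np.ndarray:
        return np.array([len(h) for h in self.histories])

    def padded(self) -> tuple[np.ndarray, np.ndarray]:
        """(Y, mask) padded to the maximum replicate count."""
        J = self.n_replicates
        Y = np.zeros((self.n_sites, J.max()), dtype=int)
        mask = np.zeros_like(Y, dtype=bool)
        for i, h in enumerate(self.histories):
            Y[i, : len(h)] = h
            mask[i, : len(h)] = True
        return Y, mask

    def detections(self) -> np.ndarray:
        return np.array([h.sum() for h in self.histories])

    def design_matrix(self, names: list[str]) -> np.ndarray:
        cols = [np.ones(self.n_sites)]
        for name in names:
            if name not in self.covariates.columns:
                raise KeyError(f"unknown site covariate {name!r}")
            cols.append(self.covariates[name].to_numpy(dtype=float))
        return np.column_stack(cols)

    @classmethod
    def from_records(
        cls, records: pd.DataFrame, site_covariates: pd.DataFrame | None = None
    ) -> "DetectionData":
        """Build from a long table (site_id, replicate_index, detection)."""
        histories, ids = [], []
        for sid, grp in records.sort_values(["site_id", "replicate_index"]).groupby(
            "site_id", sort=True
        ):
            ids.append(sid)
            histories.append(grp["detection"].to_numpy(dtype=int))
        if site_covariates is not None:
            cov = site_covariates.set_index("site_id").loc[ids].reset_index(drop=True)
        else:
            cov = pd.DataFrame(index=range(len(ids)))
        return cls(np.asarray(ids), histories, cov)


def build_detection_histories(
    records: pd.DataFrame,
    base_length: float = 2_000.0,
    replicate_length: float | None = None,
    site_covariates: pd.DataFrame | None = None,
) -> DetectionData:
    """Detection histories from survey records, optionally merged to longer
    replicates.

    Records hold base segments of ``base_length`` meters in along-road
    order per site.  Aggregating to ``replicate_length`` (a multiple of
    the base length) OR-merges each run of consecutive base segments; a
    trailing remainder shorter than the target length is discarded.
    """
    data = DetectionData.from_records(records, site_covariates)
    if replicate_length is None or replicate_length == base_length:
        return data
    ratio = replicate_length / base_length
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError("replicate length must be a positive multiple of the base length")
    merged, ids, keep_rows = [], [], []
    for i, h in enumerate(data.histories):
        m = len(h) // k
        if m < 1:
            continue
        blocks = h[: m * k].reshape(m, k)
        merged.append((blocks.max(axis=1)).astype(int))
        ids.append(data.site_ids[i])
        keep_rows.append(i)
    if not merged:
        raise ValueError("no site retains a full replicate at this length")
    cov = data.covariates.iloc[keep_rows].reset_index(drop=True)
    return DetectionData(np.asarray(ids), merged, cov)


# ---------------------------------------------------------------------------
# Negative log-likelihoods (parameters on the link scale)


def nll_mackenzie(params: np.ndarray, data: DetectionData) -> float:
    """Constant single-season model; params = (logit psi, logit p)."""
    psi = _expit(params[0])
    p = _expit(params[1])
    Y, mask = data.padded()
    logp = np.where(Y == 1, np.log(np.maximum(p, _LOG_GUARD)),
                    np.log(np.maximum(1 - p, _LOG_GUARD)))
    cond = np.exp((logp * mask).sum(axis=1))
    all_zero = (Y * mask).sum(axis=1) == 0
    L = psi * cond + (1 - psi) * all_zero
    return float(-np.sum(np.log(np.maximum(L, _LOG_GUARD))))


def nll_markov(params: np.ndarray, data: DetectionData) -> float:
    """Markovian-dependence model; params = (logit psi, logit theta0,
    logit theta1, logit p, logit pi0).

    Local presence z_j along replicates of an occupied site follows a
    2-state chain; the forward algorithm marginalizes over z paths.
    """
    psi, t0, t1, p, pi0 = _expit(params[:5])
    Y, mask = data.padded()
    n, Jmax = Y.shape
    # emission probabilities for z=0 and z=1 at each (site, replicate)
    e0 = np.where(Y == 1, 0.0, 1.0)
    e1 = np.where(Y == 1, p, 1.0 - p)
    alpha0 = (1 - pi0) * e0[:, 0]
    alpha1 = pi0 * e1[:, 0]
    for j in range(1, Jmax):
        new0 = (alpha0 * (1 - t0) + alpha1 * (1 - t1)) * e0[:, j]
        new1 = (alpha0 * t0 + alpha1 * t1) * e1[:, j]
        live = mask[:, j]
        alpha0 = np.where(live, new0, alpha0)
        alpha1 = np.where(live, new1, alpha1)
    cond = alpha0 + alpha1
    all_zero = (Y * mask).sum(axis=1) == 0
    L = psi * cond + (1 - psi) * all_zero
    return float(-np.sum(np.log(np.maximum(L, _LOG_GUARD))))


def _rn_truncation(lam_max: float, K: int | None) -> int:
    """Smallest truncation with Poisson tail mass < 1e-8 (floor 50)."""
    lam_max = max(lam_max, 1e-12)
    if K is not None:
        if stats.poisson.sf(K, lam_max) > 1e-8:
            needed = int(stats.poisson.ppf(1.0 - 1e-8, lam_max)) + 1
            raise ValueError(
                f"truncation K={K} leaves Poisson tail mass > 1e-8 at lambda="
                f"{lam_max:.3g}; use K >= {max(needed, 50)}"
            )
        return K
    # mean + 10 SD + 10 comfortably clears the 1e-8 tail without a ppf call;
    # the cap keeps pathological optimizer excursions (huge lambda) cheap --
    # there the truncated sum undershoots the likelihood, which only steers
    # the search away from an already implausible region
    return max(50, min(int(lam_max + 10.0 * math.sqrt(lam_max) + 10.0), 1000))


def nll_royle_nichols(
    params: np.ndarray,
    data: DetectionData,
    covariate_names: list[str] | None = None,
    K: int | None = None,
) -> float:
    """Abundance-induced heterogeneity model.

    params = (a0, a_1..a_m, logit r) with lambda_i = exp(x_i' a);
    site likelihood is the Poisson-truncated sum over latent abundance
    N with replicate detection probability 1 - (1 - r)^N.
    """
    names = covariate_names or []
    X = data.design_matrix(names)
    a = np.asarray(params[: X.shape[1]], dtype=float)
    r = _expit(params[X.shape[1]])
    lam = np.exp(np.clip(X @ a, -30, 30))
    d = data.detections()
    J = data.n_replicates
    weights = np.ones(len(lam))
    if not names:
        # intercept-only: sites collapse to unique (detections, replicates)
        _, idx, counts = np.unique(np.column_stack([d, J]), axis=0,
                                   return_index=True, return_counts=True)
        lam, d, J, weights = lam[idx], d[idx], J[idx], counts.astype(float)
    Kuse = _rn_truncation(float(lam.max()), K)
    N = np.arange(Kuse + 1)
    log_pois = N[None, :] * np.log(lam)[:, None] - lam[:, None] - \
        np.cumsum(np.concatenate([[0.0], np.log(np.arange(1, Kuse + 1))]))[None, :]
    qbar = (1.0 - r) ** N  # P(miss | N) per replicate
    q = 1.0 - qbar
    with np.errstate(divide="ignore"):
        log_q = np.log(np.maximum(q, _LOG_GUARD))
        log_qbar = np.log(np.maximum(qbar, _LOG_GUARD))
    log_terms = log_pois + d[:, None] * log_q[None, :] + \
        (J - d)[:, None] * log_qbar[None, :]
    m = log_terms.max(axis=1)
    L = np.exp(m) * np.exp(log_terms - m[:, None]).sum(axis=1)
    return float(-np.sum(weights * np.log(np.maximum(L, _LOG_GUARD))))


# ---------------------------------------------------------------------------
# Fitting

_PARAM_NAMES = {
    "mackenzie": ["logit_psi", "logit_p"],
    "markov": ["logit_psi", "logit_theta0", "logit_theta1", "logit_p", "logit_pi0"],
}


@dataclass
class OccupancyFit:
    kind: str
    params: np.ndarray
    param_names: list[str]
    covariance: np.ndarray
    loglik: float
    aicc: float
    n_sites: int
    converged: bool
    covariate_names: list[str] = field(default_factory=list)
    K: int | None = None
    identifiable: bool = True

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def se(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.covariance), 0.0))

    def wald_p(self) -> np.ndarray:
        se = self.se()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / se
        return 2.0 * stats.norm.sf(np.abs(z))

    def lambda_coefficients(self) -> dict[str, float]:
        if self.kind != "royle_nichols":
            raise ValueError("lambda coefficients only exist for royle_nichols fits")
        out = {"intercept": float(self.params[0])}
        for i, name in enumerate(self.covariate_names):
            out[name] = float(self.params[1 + i])
        return out

    @property
    def r(self) -> float:
        if self.kind != "royle_nichols":
            raise ValueError("r only exists for royle_nichols fits")
        return float(_expit(self.params[-1]))


def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_occupancy(
    kind: str,
    data: DetectionData,
    covariate_names: list[str] | None = None,
    K: int | None = None,
    n_starts: int = 3,
    seed: int = 0,
    start: np.ndarray | None = None,
    need_covariance: bool = True,
) -> OccupancyFit:
    """Maximum-likelihood fit by quasi-Newton optimization with jittered
    multistart; covariance from the inverse numerical Hessian.

    ``start`` overrides the default (zero on the link scale) first start;
    ``need_covariance=False`` skips the Hessian, for bootstrap refits.
    """
    names = list(covariate_names or [])
    if kind == "royle_nichols":
        m = 1 + len(names)
        x0 = np.zeros(m + 1)
        obj = lambda p: nll_royle_nichols(p, data, names, K)
        pnames = ["a0", *[f"a_{n}" for n in names], "logit_r"]
    elif kind in _PARAM_NAMES:
        if names:
            raise ValueError(f"{kind} comparator is constant-parameter only")
        pnames = _PARAM_NAMES[kind]
        x0 = np.zeros(len(pnames))
        obj = {"mackenzie": nll_mackenzie, "markov": nll_markov}[kind]
        obj = (lambda f: lambda p: f(p, data))(obj)
    else:
        raise ValueError(f"unknown model kind {kind!r}")

    if start is not None:
        x0 = np.asarray(start, dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(n_starts, 1)):
        x_start = x0 if s == 0 else x0 + rng.normal(0, 0.7, size=len(x0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(obj, x_start, method="BFGS",
                                    options={"maxiter": 500, "gtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(np.isfinite(best.fun))
    if need_covariance:
        try:
            H = approx_hess1(best.x, obj)
            cov = np.linalg.pinv(H)
        except Exception:
            cov = np.full((len(best.x), len(best.x)), np.nan)
            converged = False
    else:
        cov = np.full((len(best.x), len(best.x)), np.nan)
    n = data.n_sites
    k = len(best.x)
    ll = -best.fun if converged else -math.inf
    identifiable = True
    if kind == "mackenzie" and int(data.n_replicates.max()) == 1:
        identifiable = False  # psi and p only jointly identified with J = 1
    Kused = None
    if kind == "royle_nichols":
        X = data.design_matrix(names)
        lam = np.exp(np.clip(X @ best.x[: X.shape[1]], -30, 30))
        Kused = _rn_truncation(float(lam.max()), K)
    return OccupancyFit(
        kind=kind, params=best.x, param_names=pnames, covariance=cov,
        loglik=ll, aicc=aicc(ll, k, n) if converged else math.inf,
        n_sites=n, converged=converged, covariate_names=names, K=Kused,
        identifiable=identifiable,
    )


def derived_occupancy(lam: np.ndarray) -> np.ndarray:
    """Occupancy probability implied by the abundance model: 1 - exp(-lambda)."""
    return 1.0 - np.exp(-np.asarray(lam, dtype=float))


# ---------------------------------------------------------------------------
# Replicate-length selection


def select_replicate_length(
    records: pd.DataFrame,
    base_length: float = 2_000.0,
    step: float = 2_000.0,
    max_length: float = 20_000.0,
    delta: float = 2.0,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Smallest replicate length at which the independent-replicates model
    beats the Markov-dependence comparator by at least ``delta`` AICc.

    Returns (chosen length, trace of both AICc values per length); if the
    rule is never satisfied the maximum length is returned with a warning.
    """
    if not (records["detection"] == 1).any():
        raise ValueError("degenerate survey: no detections")
    lengths = np.arange(base_length, max_length + 0.5 * step, step)
    rows = []
    chosen = None
    for L in lengths:
        try:
            data = build_detection_histories(records, base_length, L)
        except ValueError:
            break
        fit_m = fit_occupancy("mackenzie", data, seed=seed)
        fit_h = fit_occupancy("markov", data, seed=seed)
        rows.append((L, fit_m.aicc, fit_h.aicc, data.n_sites))
        if chosen is None and fit_m.aicc <= fit_h.aicc - delta:
            chosen = float(L)
            break
    trace = pd.DataFrame(rows, columns=["length", "aicc_mackenzie", "aicc_markov", "n_sites"])
    if chosen is None:
        warnings.warn("independence rule never satisfied; returning max length")
        chosen = float(trace["length"].iloc[-1]) if len(trace) else float(max_length)
    return chosen, trace


# ---------------------------------------------------------------------------
# Goodness of fit


def _expected_count_probs(fit: OccupancyFit, data: DetectionData) -> list[np.ndarray]:
    """P(number of detections = k | J_i) per site under the fitted model.

    Closed forms under exchangeable replicates (mackenzie and
    royle-nichols); detection count is sufficient for the history there.
    """
    J = data.n_replicates
    out = []
    if fit.kind == "mackenzie":
        psi, p = _expit(fit.params[0]), _expit(fit.params[1])
        for Ji in J:
            k = np.arange(Ji + 1)
            probs = psi * stats.binom.pmf(k, Ji, p)
            probs[0] += 1 - psi
            out.append(probs)
    elif fit.kind == "royle_nichols":
        X = data.design_matrix(fit.covariate_names)
        a = fit.params[: X.shape[1]]
        r = _expit(fit.params[X.shape[1]])
        lam = np.exp(np.clip(X @ a, -30, 30))
        Kuse = _rn_truncation(float(lam.max()), fit.K)
        N = np.arange(Kuse + 1)
        q = 1.0 - (1.0 - r) ** N
        cache: dict[tuple[float, int], np.ndarray] = {}
        for lam_i, Ji in zip(lam, J):
            key = (float(lam_i), int(Ji))
            if key not in cache:
                pois = stats.poisson.pmf(N, lam_i)
                k = np.arange(Ji + 1)
                binom = stats.binom.pmf(k[:, None], Ji, q[None, :])
                cache[key] = binom @ pois
            out.append(cache[key])
    else:
        raise ValueError(f"goodness of fit not implemented for kind {fit.kind!r}")
    return out


def _pearson_chi2(fit: OccupancyFit, data: DetectionData) -> float:
    """Pearson chi-square over detection-count frequencies, pooled within
    replicate-count cohorts (cells with expected count < 2 merged)."""
    probs = _expected_count_probs(fit, data)
    d = data.detections()
    J = data.n_replicates
    chi2 = 0.0
    for Ji in np.unique(J):
        idx = np.where(J == Ji)[0]
        expected = np.sum([probs[i] for i in idx], axis=0)
        observed = np.bincount(d[idx], minlength=Ji + 1).astype(float)
        order = np.argsort(expected)  # pool smallest-expected cells first
        obs_p, exp_p, o_acc, e_acc = [], [], 0.0, 0.0
        for cell in order:
            o_acc += observed[cell]
            e_acc += expected[cell]
            if e_acc >= 2.0:
                obs_p.append(o_acc)
                exp_p.append(e_acc)
                o_acc = e_acc = 0.0
        if e_acc > 0 and exp_p:
            obs_p[-1] += o_acc
            exp_p[-1] += e_acc
        elif e_acc > 0:
            obs_p.append(o_acc)
            exp_p.append(e_acc)
        for o, e in zip(obs_p, exp_p):
            chi2 += (o - e) ** 2 / e
    return float(chi2)


def simulate_from_fit(
    fit: OccupancyFit, data: DetectionData, rng: np.random.Generator
) -> DetectionData:
    """Parametric-bootstrap dataset with the observed site structure."""
    J = data.n_replicates
    histories = []
    if fit.kind == "mackenzie":
        psi, p = _expit(fit.params[0]), _expit(fit.params[1])
        for Ji in J:
            occ = rng.uniform() < psi
            histories.append((rng.uniform(size=Ji) < p * occ).astype(int))
    elif fit.kind == "royle_nichols":
        X = data.design_matrix(fit.covariate_names)
        a = fit.params[: X.shape[1]]
        r = _expit(fit.params[X.shape[1]])
        lam = np.exp(np.clip(X @ a, -30, 30))
        for lam_i, Ji in zip(lam, J):
            N = rng.poisson(lam_i)
            pdet = 1.0 - (1.0 - r) ** N
            histories.append((rng.uniform(size=Ji) < pdet).astype(int))
    else:
        raise ValueError(f"cannot simulate from kind {fit.kind!r}")
    return DetectionData(data.site_ids.copy(), histories, data.covariates.copy())


def gof_bootstrap(
    fit: OccupancyFit,
    data: DetectionData,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Parametric-bootstrap goodness of fit.

    Returns (observed Pearson chi-square, bootstrap p-value, c-hat =
    observed / mean bootstrap chi-square).
    """
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    chi_obs = _pearson_chi2(fit, data)
    rng = np.random.default_rng(seed)
    boot = []
    failures = 0
    for _ in range(n_boot):
        sim = simulate_from_fit(fit, data, rng)
        # adaptive truncation: refit parameters may explore larger lambda
        refit = fit_occupancy(fit.kind, sim, fit.covariate_names, K=None,
                              n_starts=1, seed=seed, start=fit.params,
                              need_covariance=False)
        if not refit.converged:
            failures += 1
            continue
        boot.append(_pearson_chi2(refit, sim))
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    boot = np.asarray(boot)
    p = float(np.mean(boot >= chi_obs))
    c_hat = float(chi_obs / boot.mean())
    return chi_obs, p, c_hat


# ---------------------------------------------------------------------------
# Multi-model selection and averaging


def model_selection(
    data: DetectionData,
    candidates: list[str],
    alpha: float = 0.05,
    r_threshold: float = 0.70,
    delta: float = 2.0,
    K: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, float], pd.DataFrame, dict]:
    """Univariate screen, collinearity screen, all-subsets AICc ranking,
    and conditional model averaging over the dAICc <= ``delta`` set.

    Returns (averaged coefficients incl. intercept and logit_r, ranking
    table, info dict recording screening decisions).
    """
    if len(candidates) > 10:
        raise ValueError("all-subsets search limited to 10 candidates")
    info: dict = {"univariate": {}, "screened_out": [], "kept": []}
    uni_aicc = {}
    survivors = []
    for name in candidates:
        f = fit_occupancy("royle_nichols", data, [name], K=K, seed=seed)
        p = f.wald_p()[1]
        uni_aicc[name] = f.aicc
        info["univariate"][name] = {"coef": float(f.params[1]), "p": float(p),
                                    "aicc": float(f.aicc)}
        if f.converged and p < alpha:
            survivors.append(name)
    if survivors:
        cols = data.covariates[survivors]
        survivors = correlation_screen(cols, {k: uni_aicc[k] for k in survivors},
                                       r_threshold)
    info["kept"] = survivors
    info["screened_out"] = [c for c in candidates if c not in survivors]

    subsets = [list(s) for r in range(len(survivors) + 1)
               for s in itertools.combinations(survivors, r)]
    rows = []
    fits = []
    for sub in subsets:
        f = fit_occupancy("royle_nichols", data, sub, K=K, seed=seed)
        fits.append(f)
        rows.append({"covariates": "+".join(sub) if sub else "(intercept)",
                     "k": f.n_params, "loglik": f.loglik, "aicc": f.aicc})
    ranking = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    order = np.argsort([f.aicc for f in fits])
    fits = [fits[i] for i in order]
    best = fits[0].aicc
    delta_all = np.array([f.aicc - best for f in fits])
    w_all = np.exp(-0.5 * delta_all)
    w_all /= w_all.sum()
    ranking["delta_aicc"] = delta_all
    ranking["akaike_weight"] = w_all

    support = [f for f, d in zip(fits, delta_all) if d <= delta]
    w_sup = np.exp(-0.5 * np.array([f.aicc - best for f in support]))
    averaged: dict[str, float] = {}
    terms = ["intercept"] + survivors
    for term in terms:
        num = den = 0.0
        for f, w in zip(support, w_sup):
            coefs = f.lambda_coefficients()
            if term in coefs:
                num += w * coefs[term]
                den += w
        if den > 0:
            averaged[term] = num / den
    # average logit_r over the whole support set (present in every model)
    averaged["logit_r"] = float(
        np.sum(w_sup * np.array([f.params[-1] for f in support])) / w_sup.sum()
    )
    if not survivors:
        warnings.warn("no covariate survived screening; intercept-only result")
    info["n_support"] = len(support)
    return averaged, ranking, info


def predict_abundance(averaged: dict[str, float], stack: CovariateStack) -> np.ndarray:
    """Relative-abundance surface lambda(x) = exp(a0 + a_bar' x)."""
    eta = np.full(stack.grid.shape, averaged.get("intercept", 0.0))
    for name, coef in averaged.items():
        if name in ("intercept", "logit_r"):
            continue
        eta += coef * stack[name]
    return np.exp(eta)
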