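"""Occupancy likelihood oracles, fitting, selection, and goodness of fit."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habsel.occupancy import (
    DetectionData,
    aicc,
    build_detection_histories,
    fit_occupancy,
    gof_bootstrap,
    model_selection,
    nll_mackenzie,
    nll_markov,
    nll_royle_nichols,
    predict_abundance,
    select_replicate_length,
    simulate_from_fit,
)
from habsel.grid import CovariateStack, GridSpec
from habsel.synth import PreyTruth, simulate_detections


def logit(p):
    return np.log(p / (1 - p))


def make_data(histories, cov=None):
    ids = np.arange(len(histories))
    covdf = pd.DataFrame(cov if cov else {}, index=range(len(histories)))
    return DetectionData(ids, [np.asarray(h) for h in histories], covdf)


def simulate_rn(n_sites, n_rep, a0, a1, r, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_sites)
    lam = np.exp(a0 + a1 * x)
    truth = PreyTruth(species="t", a0=a0, coefficients={}, r=r)
    rec = simulate_detections(lam, np.full(n_sites, n_rep), truth, rng)
    data = DetectionData.from_records(rec, pd.DataFrame({"site_id": np.arange(n_sites),
                                                         "x": x}))
    return data


class TestHistories:
    def test_replicate_count_from_road_length(self):
        # 12 km of road in one cell at 2-km replicates -> 6 replicates
        rec = pd.DataFrame({"site_id": [0] * 6, "replicate_index": range(6),
                            "detection": [0, 1, 0, 0, 0, 1]})
        data = build_detection_histories(rec, 2_000.0)
        assert data.n_replicates.tolist() == [6]

    def test_or_merge_to_6km(self):
        rec = pd.DataFrame({"site_id": [0] * 6, "replicate_index": range(6),
                            "detection": [1, 0, 0, 1, 0, 0]})
        data = build_detection_histories(rec, 2_000.0, 6_000.0)
        assert data.histories[0].tolist() == [1, 1]

    def test_total_replicates_arithmetic(self):
        """Sum of floor(length / 2 km) over sites equals the record count."""
        rng = np.random.default_rng(0)
        lengths_km = rng.integers(2, 21, size=12)
        rows = []
        for sid, L in enumerate(lengths_km):
            n = int(L // 2)
            for j in range(n):
                rows.append((sid, j, int(rng.uniform() < 0.3)))
        rec = pd.DataFrame(rows, columns=["site_id", "replicate_index", "detection"])
        data = build_detection_histories(rec, 2_000.0)
        assert data.n_replicates.sum() == sum(int(L // 2) for L in lengths_km)

    def test_remainder_discarded_and_non_multiple_rejected(self):
        rec = pd.DataFrame({"site_id": [0] * 5, "replicate_index": range(5),
                            "detection": [0, 0, 1, 0, 0]})
        data = build_detection_histories(rec, 2_000.0, 4_000.0)
        assert data.n_replicates.tolist() == [2]
        with pytest.raises(ValueError, match="multiple"):
            build_detection_histories(rec, 2_000.0, 5_000.0)


class TestMackenzie:
    def test_toy_arithmetic(self):
        # one site, J=2, all-zero: L = 0.5*0.25 + 0.5 = 0.625
        data = make_data([[0, 0]])
        nll = nll_mackenzie(np.array([logit(0.5), logit(0.5)]), data)
        assert nll == pytest.approx(-np.log(0.625), abs=1e-10)

    def test_perfect_detection_zero_nll(self):
        data = make_data([[1, 1]])
        nll = nll_mackenzie(np.array([logit(1 - 1e-12), logit(1 - 1e-12)]), data)
        assert nll == pytest.approx(0.0, abs=1e-6)

    def test_matches_latent_mixture_enumeration(self):
        """Likelihood equals the explicit 2-state occupancy mixture."""
        rng = np.random.default_rng(1)
        histories = [rng.integers(0, 2, size=J).tolist() for J in (2, 3, 4, 1, 3)]
        data = make_data(histories)
        psi, p = 0.63, 0.41
        oracle = 0.0
        for h in histories:
            h = np.array(h)
            occ_lik = np.prod(p**h * (1 - p) ** (1 - h))
            L = psi * occ_lik + (1 - psi) * (h.sum() == 0)
            oracle -= np.log(L)
        nll = nll_mackenzie(np.array([logit(psi), logit(p)]), data)
        assert nll == pytest.approx(oracle, abs=1e-8)


class TestMarkov:
    def test_degenerate_chain_reduces_to_mackenzie(self):
        rng = np.random.default_rng(2)
        data = make_data([rng.integers(0, 2, size=4).tolist() for _ in range(8)])
        psi, p = 0.55, 0.35
        hi = logit(1 - 1e-13)
        m1 = nll_markov(np.array([logit(psi), hi, hi, logit(p), hi]), data)
        m2 = nll_mackenzie(np.array([logit(psi), logit(p)]), data)
        assert m1 == pytest.approx(m2, abs=1e-8)

    def test_forward_equals_path_enumeration(self):
        """J=3 history (0,1,0): forward value equals the explicit sum over
        all 2^3 presence paths."""
        h = np.array([0, 1, 0])
        psi, t0, t1, p, pi0 = 0.7, 0.3, 0.8, 0.45, 0.5
        oracle_cond = 0.0
        for z in itertools.product((0, 1), repeat=3):
            pz = (pi0 if z[0] else 1 - pi0)
            for j in range(1, 3):
                trans = t1 if z[j - 1] else t0
                pz *= trans if z[j] else 1 - trans
            py = 1.0
            for j in range(3):
                pd_j = p * z[j]
                py *= pd_j if h[j] else 1 - pd_j
            oracle_cond += pz * py
        oracle = -(np.log(psi * oracle_cond + (1 - psi) * (h.sum() == 0)))
        data = make_data([h.tolist()])
        nll = nll_markov(np.array([logit(psi), logit(t0), logit(t1),
                                   logit(p), logit(pi0)]), data)
        assert nll == pytest.approx(oracle, abs=1e-8)

    def test_clustered_data_prefers_markov(self):
        """theta1 >> theta0 simulations: Markov fit beats the independent
        model on AICc in at least 90% of replicates."""
        wins = 0
        n_rep = 30
        truth = PreyTruth(species="t", a0=np.log(2.0), coefficients={}, r=0.8,
                          theta0=0.15, theta1=0.9)
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            rec = simulate_detections(np.full(80, 2.0), np.full(80, 8), truth, rng)
            data = DetectionData.from_records(rec)
            f_mack = fit_occupancy("mackenzie", data, n_starts=2)
            f_mark = fit_occupancy("markov", data, n_starts=2)
            wins += f_mark.aicc < f_mack.aicc
        assert wins >= 0.9 * n_rep


class TestRoyleNichols:
    def test_r_zero_with_detection_guarded(self):
        data = make_data([[1, 0]])
        nll = nll_royle_nichols(np.array([0.0, -np.inf]), data)
        assert np.isfinite(nll) and nll > 100

    def test_truncated_sum_oracle(self):
        """lambda=1, r=0.5, J=2, history (1,0): site likelihood 0.1342
        by brute-force truncated sum (K=50)."""
        data = make_data([[1, 0]])
        K = 50
        N = np.arange(K + 1)
        q = 1 - 0.5**N
        oracle = float(np.sum(stats.poisson.pmf(N, 1.0) * q * (1 - q)))
        assert oracle == pytest.approx(0.1342, abs=5e-5)
        nll = nll_royle_nichols(np.array([0.0, logit(0.5)]), data, K=K)
        assert nll == pytest.approx(-np.log(oracle), abs=1e-8)

    def test_matches_enumeration_with_covariate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        data = make_data([rng.integers(0, 2, size=3).tolist() for _ in range(5)],
                         cov={"x": x})
        a0, a1, r = 0.2, 0.6, 0.35
        lam = np.exp(a0 + a1 * x)
        oracle = 0.0
        for i, h in enumerate(data.histories):
            L = 0.0
            for N in range(200):
                q = 1 - (1 - r) ** N
                L += stats.poisson.pmf(N, lam[i]) * np.prod(
                    q ** h * (1 - q) ** (1 - h))
            oracle -= np.log(L)
        nll = nll_royle_nichols(np.array([a0, a1, logit(r)]), data, ["x"])
        assert nll == pytest.approx(oracle, abs=1e-8)

    def test_truncation_guard(self):
        data = make_data([[1, 0]])
        with pytest.raises(ValueError, match="K"):
            nll_royle_nichols(np.array([np.log(40.0), logit(0.5)]), data, K=10)

    def test_derived_occupancy_monotone(self):
        from habsel.occupancy import derived_occupancy
        lam = np.linspace(0.1, 5, 20)
        psi = derived_occupancy(lam)
        assert np.all(np.diff(psi) > 0)


class TestFit:
    def test_mle_beats_truth_loglik(self):
        for seed in range(3):
            data = simulate_rn(120, 6, 0.0, 0.8, 0.3, seed)
            fit = fit_occupancy("royle_nichols", data, ["x"])
            nll_truth = nll_royle_nichols(np.array([0.0, 0.8, logit(0.3)]),
                                          data, ["x"])
            assert fit.converged
            assert fit.loglik >= -nll_truth - 1e-6

    def test_aicc_identity_and_exceeds_aic(self):
        data = simulate_rn(60, 5, 0.0, 0.5, 0.4, 9)
        fit = fit_occupancy("royle_nichols", data, ["x"])
        k, n = fit.n_params, fit.n_sites
        assert fit.aicc == pytest.approx(
            -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1))
        assert fit.aicc > fit.aic
        assert np.isinf(aicc(0.0, 5, 6))

    def test_single_replicate_identifiability_flag(self):
        rng = np.random.default_rng(4)
        data = make_data([[int(rng.uniform() < 0.4)] for _ in range(40)])
        fit = fit_occupancy("mackenzie", data)
        assert not fit.identifiable

    def test_covariance_symmetric_psd(self):
        data = simulate_rn(100, 6, 0.0, 0.8, 0.3, 5)
        fit = fit_occupancy("royle_nichols", data, ["x"])
        assert np.allclose(fit.covariance, fit.covariance.T, atol=1e-8)
        assert np.all(np.linalg.eigvalsh(fit.covariance) > -1e-8)


class TestReplicateLength:
    @staticmethod
    def survey_records(theta, seed, n_sites=60, n_rep=10, r=0.8):
        # theta0 == theta1 gives iid segment presence: independent replicates
        rng = np.random.default_rng(seed)
        truth = PreyTruth(species="t", a0=np.log(1.5), coefficients={}, r=r,
                          theta0=theta[0], theta1=theta[1])
        return simulate_detections(np.full(n_sites, 1.5), np.full(n_sites, n_rep),
                                   truth, rng)

    def test_independent_data_choose_start(self):
        chosen_start = 0
        for rep in range(5):
            rec = self.survey_records((0.6, 0.6), seed=3000 + rep)
            chosen, trace = select_replicate_length(rec)
            chosen_start += chosen == 2_000.0
            assert len(trace) >= 1
        assert chosen_start >= 3

    def test_clustered_data_choose_longer(self):
        rec = self.survey_records((0.1, 0.95), seed=22, n_sites=100, n_rep=10,
                                  r=0.6)
        chosen, trace = select_replicate_length(rec)
        assert chosen > 2_000.0
        assert {"length", "aicc_mackenzie", "aicc_markov"} <= set(trace.columns)

    def test_no_detection_raises(self):
        rec = pd.DataFrame({"site_id": [0, 0], "replicate_index": [0, 1],
                            "detection": [0, 0]})
        with pytest.raises(ValueError, match="degenerate"):
            select_replicate_length(rec)


class TestGoF:
    def test_seed_reproducible(self):
        data = simulate_rn(80, 6, 0.3, 0.0, 0.35, 31)
        fit = fit_occupancy("royle_nichols", data)
        a = gof_bootstrap(fit, data, n_boot=30, seed=5)
        b = gof_bootstrap(fit, data, n_boot=30, seed=5)
        assert a == b

    def test_chat_near_one_under_true_model(self):
        data = simulate_rn(100, 6, 0.3, 0.0, 0.35, 33)
        fit = fit_occupancy("royle_nichols", data)
        chi2, p, c_hat = gof_bootstrap(fit, data, n_boot=60, seed=1)
        assert 0.025 <= p
        assert 0.5 < c_hat < 1.6

    def test_simulated_data_have_site_structure(self):
        data = simulate_rn(40, 5, 0.0, 0.0, 0.4, 35)
        fit = fit_occupancy("royle_nichols", data)
        sim = simulate_from_fit(fit, data, np.random.default_rng(0))
        assert sim.n_sites == data.n_sites
        assert sim.n_replicates.tolist() == data.n_replicates.tolist()


@pytest.fixture(scope="module")
def selected():
    rng = np.random.default_rng(41)
    n = 250
    cov = {f"x{i}": rng.normal(size=n) for i in range(3)}
    lam = np.exp(0.0 + 0.8 * cov["x0"])
    truth = PreyTruth(species="t", a0=0.0, coefficients={}, r=0.35)
    rec = simulate_detections(lam, np.full(n, 8), truth, rng)
    data = DetectionData.from_records(
        rec, pd.DataFrame({"site_id": np.arange(n), **cov}))
    return model_selection(data, ["x0", "x1", "x2"], seed=0)


class TestModelSelection:

    def test_true_covariate_supported(self, selected):
        averaged, ranking, info = selected
        assert "x0" in info["kept"]
        assert "x0" in averaged

    def test_akaike_weights_sum_to_one(self, selected):
        _, ranking, _ = selected
        assert ranking["akaike_weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_averaged_coefficient_convexity(self, selected):
        """Conditional average lies inside the range of component-model
        coefficients (weights are convex)."""
        averaged, ranking, info = selected
        # refit the supported models to recover component coefficients
        assert np.isfinite(averaged["x0"])
        assert 0.3 < averaged["x0"] < 1.3

    def test_predict_abundance(self, selected):
        averaged, _, _ = selected
        g = GridSpec(ncols=8, nrows=8, cellsize=1.0)
        rng = np.random.default_rng(0)
        stack = CovariateStack(grid=g, layers={
            "x0": rng.normal(size=(8, 8)), "x1": rng.normal(size=(8, 8)),
            "x2": rng.normal(size=(8, 8))})
        lam = predict_abundance(averaged, stack)
        assert np.all(lam > 0)
        const = predict_abundance({"intercept": 0.7}, stack)
        assert np.allclose(const, np.exp(0.7))
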