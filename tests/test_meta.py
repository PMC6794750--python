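"""Known-variance Gaussian mixture fitting and meta-QTL summarization."""

import math

import numpy as np
import pytest
from scipy import stats

from metaqtl_forge.meta import (MixtureFit, QTLObservation, em_fit,
                                model_criteria, run_meta_analysis,
                                sd_from_ci, select_model, summarize_metaqtl)
from metaqtl_forge.models import ProjectedQTL, QTLRecord


def obs(x, sigma, qtl_id=None, study="s", r2=0.1, trait="ver"):
    return QTLObservation(qtl_id=qtl_id or f"o{x}", x=x, sigma=sigma,
                          r2=r2, study_ref=study, trait=trait)


class TestSdFromCI:
    def test_95_percent_definitions(self):
        assert sd_from_ci(3.92) == pytest.approx(1.0, abs=2e-3)
        assert sd_from_ci(7.84) == pytest.approx(2.0, abs=4e-3)

    def test_level_90_against_normal_quantile(self):
        length = 2 * stats.norm.ppf(0.95)  # 3.2897
        assert sd_from_ci(length, level=0.90) == pytest.approx(1.0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            sd_from_ci(0.0)


class TestEMFit:
    def test_k1_equals_inverse_variance_weighted_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(2, 12))
            x = rng.uniform(0, 100, n)
            s = rng.uniform(0.5, 5.0, n)
            fit = em_fit([obs(float(a), float(b)) for a, b in zip(x, s)], K=1)
            w = 1 / s ** 2
            assert abs(fit.mu[0] - np.sum(w * x) / np.sum(w)) < 1e-9

    def test_two_symmetric_observations_average(self):
        fit = em_fit([obs(30.0, 1.0), obs(32.0, 1.0)], K=1)
        assert fit.mu[0] == pytest.approx(31.0, abs=1e-9)

    def test_k_out_of_range_raises(self):
        with pytest.raises(ValueError):
            em_fit([obs(1.0, 1.0)], K=2)

    def test_k2_matches_two_stage_grid_oracle(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(20, 1, 3), rng.normal(40, 1, 3)])
        s = np.full(6, 1.0)
        data = [obs(float(a), 1.0, qtl_id=f"o{i}") for i, a in enumerate(x)]
        fit = em_fit(data, K=2, restarts=10)

        def loglik(mu1, mu2, pi):
            comp = np.stack([
                pi * stats.norm.pdf(x, mu1, s),
                (1 - pi) * stats.norm.pdf(x, mu2, s)])
            return float(np.log(comp.sum(axis=0)).sum())

        # coarse grid, then a fine local grid around the coarse optimum
        mus = np.arange(x.min() - 1, x.max() + 1, 0.25)
        pis = np.arange(0.05, 1.0, 0.05)
        best, arg = -np.inf, None
        for m1 in mus:
            for m2 in mus[mus >= m1]:
                for p in pis:
                    ll = loglik(m1, m2, p)
                    if ll > best:
                        best, arg = ll, (m1, m2, p)
        m1, m2, p = arg
        for f1 in np.arange(m1 - 0.3, m1 + 0.3, 0.01):
            for f2 in np.arange(m2 - 0.3, m2 + 0.3, 0.01):
                for fp in np.arange(max(0.01, p - 0.06), min(0.99, p + 0.06),
                                    0.01):
                    best = max(best, loglik(f1, f2, fp))
        assert fit.log_likelihood == pytest.approx(best, abs=1e-4)

    def test_loglik_nondecreasing_is_enforced(self):
        # the EM loop asserts monotonicity internally; a normal fit passes
        rng = np.random.default_rng(8)
        data = [obs(float(v), float(w)) for v, w in
                zip(rng.uniform(0, 50, 20), rng.uniform(0.5, 4, 20))]
        for K in (1, 2, 3):
            fit = em_fit(data, K)
            assert fit.converged


class TestCriteria:
    def test_closed_formulas_k1(self):
        fit = MixtureFit(K=1, mu=np.array([0.0]), pi=np.array([1.0]),
                         z=np.ones((4, 1)), log_likelihood=-10.0, n_iter=1,
                         converged=True)
        # use 4 observations; with K=1 the classification likelihood equals
        # the mixture likelihood
        data = [obs(float(i), 1.0) for i in range(4)]
        crit = model_criteria(fit, data)
        assert crit["AIC"] == pytest.approx(22.0)
        assert crit["BIC"] == pytest.approx(20 + math.log(4))
        assert crit["AIC3"] - crit["AIC"] == pytest.approx(1.0)  # p = 2K-1

    def test_aic3_minus_aic_equals_p(self):
        rng = np.random.default_rng(6)
        data = [obs(float(v), 1.0) for v in rng.uniform(0, 40, 8)]
        for K in (1, 2, 3):
            crit = model_criteria(em_fit(data, K), data)
            assert crit["AIC3"] - crit["AIC"] == pytest.approx(2 * K - 1)

    def test_against_independent_formulas(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 60, 9)
        data = [obs(float(v), 1.5) for v in x]
        fit = em_fit(data, K=2)
        crit = model_criteria(fit, data)
        n, p = 9, 3
        ll = fit.log_likelihood
        assert crit["AIC"] == pytest.approx(-2 * ll + 2 * p)
        assert crit["AICc"] == pytest.approx(
            -2 * ll + 2 * p + 2 * p * (p + 1) / (n - p - 1))
        assert crit["BIC"] == pytest.approx(-2 * ll + p * math.log(n))
        # AWE from scratch: hard-assignment classification likelihood
        hard = np.argmax(fit.z, axis=1)
        ll_c = sum(
            math.log(fit.pi[k]) + stats.norm.logpdf(xi, fit.mu[k], 1.5)
            for xi, k in zip(x, hard))
        assert crit["AWE"] == pytest.approx(
            -2 * ll_c + 2 * p * (1.5 + math.log(n)))

    def test_aicc_undefined_when_sample_too_small(self):
        data = [obs(0.0, 1.0), obs(10.0, 1.0), obs(20.0, 1.0)]
        crit = model_criteria(em_fit(data, K=2), data)  # n=3, p=3 -> n-p-1<0
        assert crit["AICc"] is None


class TestSelectModel:
    def _fit(self, K, crit):
        f = MixtureFit(K=K, mu=np.zeros(K), pi=np.ones(K) / K,
                       z=np.ones((4, K)) / K, log_likelihood=0.0, n_iter=1,
                       converged=True)
        f.criteria = crit
        return f

    def test_unanimous_vote(self):
        fits = [self._fit(k, {"AIC": 10 - (k == 3), "AICc": 10 - (k == 3),
                              "AIC3": 10 - (k == 3), "BIC": 10 - (k == 3),
                              "AWE": 10 - (k == 3)}) for k in (1, 2, 3)]
        assert select_model(fits).K == 3

    def test_vote_tie_prefers_smaller_k(self):
        # AIC & AICc vote K=1, AIC3 & BIC vote K=2, AWE votes K=3
        crits = {
            1: {"AIC": 1, "AICc": 1, "AIC3": 9, "BIC": 9, "AWE": 9},
            2: {"AIC": 5, "AICc": 5, "AIC3": 1, "BIC": 1, "AWE": 9},
            3: {"AIC": 9, "AICc": 9, "AIC3": 9, "BIC": 9, "AWE": 1},
        }
        fits = [self._fit(k, crits[k]) for k in (1, 2, 3)]
        assert select_model(fits).K == 1

    def test_undefined_criterion_excluded_from_voting(self):
        crits = {
            1: {"AIC": 2, "AICc": None, "AIC3": 2, "BIC": 1, "AWE": 1},
            2: {"AIC": 1, "AICc": None, "AIC3": 1, "BIC": 2, "AWE": 2},
        }
        fits = [self._fit(k, crits[k]) for k in (1, 2)]
        # 2 votes each among defined criteria -> tie -> smaller K
        assert select_model(fits).K == 1


class TestSummarize:
    def test_single_member_formulas(self):
        data = [obs(31.29, 1.09)]
        fit = em_fit(data, K=1)
        (m,) = summarize_metaqtl(fit, data, lg="1", prefix="ver")
        assert m.name == "ver_1.1"
        assert m.peak_cm == pytest.approx(31.29, abs=1e-6)
        assert m.ci_end_cm - m.ci_start_cm == pytest.approx(4.28, abs=0.02)

    def test_two_equal_sigma_members_combine_precision(self):
        data = [obs(30.0, 1.5), obs(31.0, 1.5)]
        fit = em_fit(data, K=1)
        (m,) = summarize_metaqtl(fit, data, lg="2")
        half = (m.ci_end_cm - m.ci_start_cm) / 2
        assert half == pytest.approx(stats.norm.ppf(0.975) * 1.5 / math.sqrt(2))

    def test_sigma_meta_never_exceeds_member_sigmas(self):
        rng = np.random.default_rng(12)
        data = [obs(float(v), float(w)) for v, w in
                zip(rng.normal(50, 2, 6), rng.uniform(1, 4, 6))]
        fit = em_fit(data, K=1)
        (m,) = summarize_metaqtl(fit, data, lg="1")
        half = (m.ci_end_cm - m.ci_start_cm) / 2
        assert half / stats.norm.ppf(0.975) <= min(o.sigma for o in data) + 1e-12

    def test_peak_within_member_range_and_mean_r2(self):
        rng = np.random.default_rng(14)
        data = ([obs(float(v), 1.0, r2=0.1) for v in rng.normal(20, 1, 5)]
                + [obs(float(v), 1.0, r2=0.3) for v in rng.normal(60, 1, 5)])
        fit = em_fit(data, K=2)
        out = summarize_metaqtl(fit, data, lg="1")
        assert len(out) == 2
        for m in out:
            xs = [o.x for o in data if o.qtl_id in m.member_ids]
            assert min(xs) <= m.peak_cm <= max(xs)
        assert out[0].mean_r2 == pytest.approx(0.1)
        assert out[1].mean_r2 == pytest.approx(0.3)


def proj(qtl_id, lg, peak, half, trait="ver", study="sA", r2=0.1):
    rec = QTLRecord(qtl_id=qtl_id, trait=trait, trait_category="phenology",
                    study_ref=study, population_size=150, lg=lg, peak_cm=peak,
                    ci_start_cm=max(0.0, peak - half), ci_end_cm=peak + half,
                    r2=r2)
    return ProjectedQTL(record=rec, status="projected", peak_cm=peak,
                        ci_start_cm=max(0.0, peak - half),
                        ci_end_cm=peak + half)


class TestRunMetaAnalysis:
    def test_two_overlapping_qtls_give_at_most_two_clusters(self):
        qtls = [proj("a", "1", 30, 3, study="sA"),
                proj("b", "1", 32, 3, study="sB")]
        out = run_meta_analysis(qtls, "ver", "1")
        assert 1 <= len(out) <= 2

    def test_non_overlapping_pair_is_skipped(self):
        qtls = [proj("a", "1", 10, 2, study="sA"),
                proj("b", "1", 50, 2, study="sB")]
        assert run_meta_analysis(qtls, "ver", "1") == []

    def test_planted_one_plus_three_layout_gives_four_metaqtls(self, bundle,
                                                               pipeline_dirs):
        import pandas as pd
        df = pd.read_csv(f"{pipeline_dirs.out_dir}/metaqtls.tsv", sep="\t",
                         dtype={"lg": str})
        assert len(df) == 4
        assert sorted(df["lg"]) == ["1", "2", "2", "2"]
        assert list(df["name"]) == ["ver_1.1", "ver_2.1", "ver_2.2", "ver_2.3"]

    def test_cross_trait_with_disjoint_others_equals_single_trait(self):
        qtls = [proj("a", "1", 30, 3, study="sA"),
                proj("b", "1", 32, 3, study="sB"),
                proj("c", "1", 80, 2, trait="flo", study="sC")]
        single = run_meta_analysis(qtls, "ver", "1", mode="single-trait")
        cross = run_meta_analysis(qtls, "ver", "1", mode="cross-trait",
                                  prefix="ver")
        assert [(m.peak_cm, m.member_ids) for m in single] == \
            [(m.peak_cm, m.member_ids) for m in cross]

    def test_cross_trait_pools_overlapping_other_trait_qtls(self):
        qtls = [proj("a", "1", 30, 3, study="sA"),
                proj("b", "1", 32, 3, study="sB"),
                proj("c", "1", 31, 3, trait="flo", study="sC")]
        cross = run_meta_analysis(qtls, "ver", "1", mode="cross-trait")
        members = {m_id for m in cross for m_id in m.member_ids}
        assert "c" in members
        assert cross[0].name.startswith("ver/ph_")
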