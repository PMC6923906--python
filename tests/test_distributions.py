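"""Unit and property tests for the model zoo."""

import numpy as np
import pytest
from scipy import stats

from m3s.distributions import (
    COMPLEXITY_RANK,
    ModelFit,
    ModelName,
    ModelParams,
    default_zcut,
    fit_model,
    model_cdf,
    model_loglik,
    model_sample,
    peak_count,
)
from m3s.distributions._mixture import fit_censored_mixture, split_widest
from m3s.errors import InvalidParameterError, UnsupportedDataError
from m3s.simulate import draw_params

ALL_MODELS = list(ModelName)


class TestModelName:
    def test_eleven_members(self):
        assert len(ALL_MODELS) == 11

    def test_complexity_ordering(self):
        r = {m.value: COMPLEXITY_RANK[m] for m in ModelName}
        assert r["P"] < r["NB"] == r["G"] < r["ZIP"] < r["ZINB"] == r["ZIG"] == r["LTG"]
        assert r["LTG"] < r["BP"] < r["MG"] < r["ZIMG"] == r["LTMG"]


class TestFitModel:
    def test_poisson_mle_is_mean(self):
        x = [2, 2, 2, 2, 2]
        fit = fit_model(x, ModelName.P)
        assert fit.params.lambda_ == pytest.approx(2.0)
        assert fit.loglik == pytest.approx(5 * stats.poisson.logpmf(2, 2.0))

    def test_gaussian_recovers_sample_moments(self):
        rng = np.random.default_rng(7)
        x = rng.normal(5, 1, 500)
        fit = fit_model(x, ModelName.G)
        assert fit.params.mu == pytest.approx(x.mean())
        assert fit.params.sigma == pytest.approx(x.std())
        assert abs(fit.params.mu - 5) < 3 / np.sqrt(500)

    def test_mg_recovers_planted_mixture_vs_kmeans(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1, 250)])
        fit = fit_model(x, ModelName.MG, max_components=5, seed=3)
        assert fit.n_components == 2
        mus = np.sort(fit.params.mus)
        assert np.allclose(mus, [0, 6], atol=0.3)
        # independent oracle: k-means centroids on the same data
        centers = np.sort(
            KMeans(n_clusters=2, n_init=10, random_state=0)
            .fit(x.reshape(-1, 1))
            .cluster_centers_.ravel()
        )
        assert np.allclose(mus, centers, atol=0.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(UnsupportedDataError, match="nonnegative"):
            fit_model([-1, 2, 3, 4, 5], ModelName.P)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(UnsupportedDataError, match="integer"):
            fit_model([1.5, 2.0, 3.0, 4.0], ModelName.NB)

    def test_constant_vector_only_p_or_g(self):
        fit_model([3.0] * 20, ModelName.P)
        g = fit_model([3.0] * 20, ModelName.G)
        assert g.params.sigma >= 1e-4
        with pytest.raises(UnsupportedDataError, match="constant"):
            fit_model([3.0] * 20, ModelName.MG)

    def test_mixture_refuses_k_above_distinct(self):
        with pytest.raises(UnsupportedDataError):
            fit_censored_mixture(np.array([1.0, 2.0] * 10), 3)

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_fit_deterministic_given_seed(self, model):
        rng = np.random.default_rng(3)
        params = draw_params(model, rng)
        x = model_sample(model, params, 300, seed=5)
        f1 = fit_model(x, model, seed=9)
        f2 = fit_model(x, model, seed=9)
        assert f1.loglik == f2.loglik
        assert f1.params.as_dict(model) == f2.params.as_dict(model)

    def test_ltg_censored_mle_close_to_truth(self):
        p = ModelParams(mu=3.0, sigma=1.5, zcut=2.5)
        x = model_sample(ModelName.LTG, p, 2000, seed=21)
        fit = fit_model(x, ModelName.LTG, zcut=2.5, seed=1)
        assert fit.params.mu == pytest.approx(3.0, abs=0.2)
        assert fit.params.sigma == pytest.approx(1.5, abs=0.2)


class TestNestedDominance:
    def test_zip_dominates_poisson(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            x = np.random.default_rng(seed).poisson(4, 200).astype(float)
            x[:20] = 0
            ll_p = fit_model(x, ModelName.P).loglik
            ll_zip = fit_model(x, ModelName.ZIP).loglik
            assert ll_zip >= ll_p - 1e-6

    def test_mg_loglik_nondecreasing_in_k(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(5, 1, 150)])
        prev = None
        prev_ll = -np.inf
        for k in range(1, 5):
            w, m, s, ll, _ = fit_censored_mixture(x, k, seed=0)
            if prev is not None:
                w2, m2, s2, ll2, _ = fit_censored_mixture(
                    x, k, seed=0, init=split_widest(*prev)
                )
                if ll2 > ll:
                    w, m, s, ll = w2, m2, s2, ll2
            assert ll >= prev_ll - 1e-6
            prev, prev_ll = (w, m, s), ll


class TestCdf:
    def test_gaussian_symmetry(self):
        p = ModelParams(mu=0.0, sigma=1.0)
        assert model_cdf(ModelName.G, p, 0.0)[0] == pytest.approx(0.5)

    def test_ltg_normalizes_to_one(self):
        p = ModelParams(mu=0.0, sigma=1.0, zcut=0.0)
        assert model_cdf(ModelName.LTG, p, 1e9)[0] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_cdf_monotone_and_reaches_one(self, model):
        params = draw_params(model, np.random.default_rng(8))
        q = np.linspace(-5, 300, 400)
        f = model_cdf(model, params, q)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all((f >= 0) & (f <= 1))
        assert model_cdf(model, params, 1e9)[0] == pytest.approx(1.0, abs=1e-6)

    def test_bp_cdf_matches_monte_carlo(self):
        p = ModelParams(bp_alpha=2.0, bp_beta=4.0, bp_scale=20.0)
        n = 10**6
        draws = model_sample(ModelName.BP, p, n, seed=42)
        for q in (2.0, 5.0, 8.0, 12.0, 15.0):
            mc = np.mean(draws <= q)
            se = np.sqrt(max(mc * (1 - mc), 1e-12) / n)
            quad = model_cdf(ModelName.BP, p, q)[0]
            assert abs(quad - mc) < 3 * se + 1e-9

    def test_invalid_params_raise(self):
        with pytest.raises(InvalidParameterError):
            model_cdf(ModelName.G, ModelParams(mu=0.0, sigma=-1.0), 0.0)
        with pytest.raises(InvalidParameterError):
            model_cdf(ModelName.ZIP, ModelParams(pi0=1.5, lambda_=2.0), 0.0)


class TestSample:
    def test_poisson_clt_bound(self):
        x = model_sample(ModelName.P, ModelParams(lambda_=3.0), 10**5, seed=1)
        assert abs(x.mean() - 3.0) < 3 * np.sqrt(3.0 / 10**5)

    def test_zip_degenerate_inflation(self):
        p = ModelParams(pi0=1.0, lambda_=5.0)
        x = model_sample(ModelName.ZIP, p, 100, seed=2)
        assert np.all(x == 0)

    def test_one_component_mg_is_gaussian(self):
        p = ModelParams(weights=[1.0], mus=[2.0], sigmas=[1.0])
        x = model_sample(ModelName.MG, p, 1000, seed=3)
        assert stats.kstest(x, "norm", args=(2.0, 1.0)).pvalue > 0.01

    def test_reproducible(self):
        p = ModelParams(lambda_=4.0)
        assert np.array_equal(
            model_sample(ModelName.P, p, 50, seed=9),
            model_sample(ModelName.P, p, 50, seed=9),
        )

    def test_lt_censor_and_truncate_modes(self):
        p = ModelParams(mu=1.0, sigma=1.0, zcut=1.0)
        cens = model_sample(ModelName.LTG, p, 500, seed=4, lt_mode="censor")
        trunc = model_sample(ModelName.LTG, p, 500, seed=4, lt_mode="truncate")
        assert np.mean(cens == 1.0) > 0.3  # censored mass piles at zcut
        assert np.all(trunc >= 1.0) and np.mean(trunc == 1.0) == 0.0


class TestPeakCount:
    def test_unimodal_is_one(self):
        fit = fit_model(np.random.default_rng(0).normal(0, 1, 100), ModelName.G)
        assert peak_count(fit) == 1

    def test_zimg_counts_nonzero_components(self):
        p = ModelParams(pi0=0.4, weights=[0.3, 0.3, 0.4], mus=[1, 4, 8], sigmas=[1, 1, 1])
        fit = ModelFit(model=ModelName.ZIMG, params=p, loglik=0.0, n_components=3)
        assert peak_count(fit) == 3

    def test_ltmg_two_components(self):
        p = ModelParams(weights=[0.5, 0.5], mus=[1, 5], sigmas=[1, 1], zcut=0.0)
        fit = ModelFit(model=ModelName.LTMG, params=p, loglik=0.0, n_components=2)
        assert peak_count(fit) == 2


class TestRoundTrip:
    """Loose sanity round trips; tight 3-SE coverage lives in acceptance."""

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_selfsample_loglik_beats_truth_nearby(self, model):
        rng = np.random.default_rng(31)
        params = draw_params(model, rng)
        x = model_sample(model, params, 1000, seed=13)
        fit = fit_model(
            x, model, seed=5,
            zcut=params.zcut if model in (ModelName.LTG, ModelName.LTMG) else None,
        )
        # MLE log-likelihood must not fall below the generating parameters'
        assert fit.loglik >= model_loglik(model, params, x) - 1e-6 * abs(fit.loglik) - 2.0


def test_default_zcut_prefers_smallest_positive():
    assert default_zcut(np.array([0.0, 0.0, 1.5, 3.0])) == 1.5
    assert default_zcut(np.array([2.0, 3.0])) == 2.0
    assert default_zcut(np.array([-1.0, 0.0, 2.0])) == -1.0


def test_serialization_row():
    fit = fit_model([1, 2, 3, 2, 1, 0, 2, 3], ModelName.P)
    row = fit.to_tsv_row().split("\t")
    assert row[0] == "P"
    assert float(row[2].split("=")[1]) == pytest.approx(1.75)
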