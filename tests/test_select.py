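"""Tests for KS goodness-of-fit, BH-FDR, and the selection pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from m3s.distributions import ModelFit, ModelName, ModelParams, model_sample
from m3s.errors import InvalidParameterError, NotConvergedError
from m3s.io import ExpressionMatrix
from m3s.normalize import DataCharacteristics
from m3s.select import (
    candidate_models,
    fdr_adjust,
    ks_gof,
    m3s,
    peak_parsimony_test,
    select_best,
)


def _gfit(mu=0.0, sigma=1.0):
    return ModelFit(
        model=ModelName.G, params=ModelParams(mu=mu, sigma=sigma), loglik=0.0
    )


class TestKsGof:
    def test_plugin_quantiles_minimize_d(self):
        n = 100
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d, _ = ks_gof(x, _gfit())
        assert d <= 0.5 / n + 1e-9

    def test_two_point_matches_grid_oracle(self):
        x = np.array([0.0, 1.0])
        d, _ = ks_gof(x, _gfit())
        grid = np.sort(np.concatenate([np.linspace(-8, 8, 400001), x, x - 1e-9]))
        ecdf = np.searchsorted(np.sort(x), grid, side="right") / x.size
        d_grid = np.max(np.abs(ecdf - stats.norm.cdf(grid)))
        assert d == pytest.approx(d_grid, abs=1e-9)

    def test_nonconverged_fit_raises(self):
        fit = _gfit()
        fit.converged = False
        with pytest.raises(NotConvergedError):
            ks_gof([0.0, 1.0], fit)

    def test_pvalues_near_uniform_under_null(self):
        # known-parameter calibration (plug-in bias excluded by design)
        pvals = []
        for seed in range(200):
            x = np.random.default_rng(seed).normal(0, 1, 500)
            _, p = ks_gof(x, _gfit())
            pvals.append(p)
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.15

    def test_discrete_model_left_limit_handling(self):
        # Poisson data under its own fitted law should fit comfortably
        x = np.random.default_rng(0).poisson(5, 500).astype(float)
        fit = ModelFit(
            model=ModelName.P, params=ModelParams(lambda_=x.mean()), loglik=0.0
        )
        d, p = ks_gof(x, fit)
        assert p > 0.5  # conservative for discrete + plug-in

    def test_bootstrap_pvalue_in_range(self):
        x = np.random.default_rng(1).normal(0, 1, 80)
        fit = ModelFit(
            model=ModelName.G,
            params=ModelParams(mu=x.mean(), sigma=x.std()),
            loglik=0.0,
        )
        d, p = ks_gof(x, fit, n_boot=30, seed=4)
        assert 0.0 < p <= 1.0


class TestFdrAdjust:
    def test_hand_computed_example(self):
        # p(i)*n/i then cumulative min from the largest rank
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_value_identity(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_raises(self):
        with pytest.raises(InvalidParameterError):
            fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = fdr_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ranks(self, pvals):
        p = np.asarray(pvals)
        adj = fdr_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)


class TestCandidateModels:
    def test_raw_counts_admit_all_eleven(self):
        chars = DataCharacteristics(True, True, True, False, 0.3)
        assert len(candidate_models(chars)) == 11

    def test_log_scale_reals_with_zeros(self):
        chars = DataCharacteristics(True, True, False, False, 0.3)
        models = set(candidate_models(chars))
        assert models == {
            ModelName.G, ModelName.ZIG, ModelName.LTG,
            ModelName.MG, ModelName.ZIMG, ModelName.LTMG,
        }

    def test_positive_reals_no_zeros(self):
        chars = DataCharacteristics(True, False, False, False, 0.0)
        models = set(candidate_models(chars))
        assert models == {ModelName.G, ModelName.LTG, ModelName.MG, ModelName.LTMG}

    def test_sorted_by_complexity(self):
        chars = DataCharacteristics(True, True, True, False, 0.3)
        ranks = [m.complexity_rank for m in candidate_models(chars)]
        assert ranks == sorted(ranks)


def _fit_with(model, fdr, p=0.5, n_components=1):
    params = {
        ModelName.P: ModelParams(lambda_=1.0),
        ModelName.G: ModelParams(mu=0.0, sigma=1.0),
        ModelName.MG: ModelParams(weights=[0.5, 0.5], mus=[0, 3], sigmas=[1, 1]),
        ModelName.LTMG: ModelParams(
            weights=[0.5, 0.5], mus=[0, 3], sigmas=[1, 1], zcut=-1.0
        ),
    }[model]
    f = ModelFit(model=model, params=params, loglik=0.0, n_components=n_components)
    f.ks_pvalue, f.ks_fdr = p, fdr
    return f


class TestSelectBest:
    def test_simplest_passing_wins_regardless_of_fit(self):
        fits = [
            _fit_with(ModelName.P, fdr=0.5, p=0.2),
            _fit_with(ModelName.MG, fdr=0.99, p=0.99, n_components=2),
        ]
        assert select_best(fits) == (ModelName.P, True)

    def test_only_complex_model_passes(self):
        fits = [
            _fit_with(ModelName.P, fdr=0.01),
            _fit_with(ModelName.LTMG, fdr=0.4, n_components=2),
        ]
        assert select_best(fits) == (ModelName.LTMG, True)

    def test_none_pass_returns_provisional(self):
        fits = [
            _fit_with(ModelName.P, fdr=0.01, p=0.001),
            _fit_with(ModelName.G, fdr=0.05, p=0.04),
        ]
        model, adequate = select_best(fits)
        assert model is ModelName.G and adequate is False

    def test_empty_table_raises(self):
        with pytest.raises(InvalidParameterError):
            select_best([])


class TestPeakParsimony:
    def test_identical_vectors_half(self):
        assert peak_parsimony_test([2, 2, 2, 1], [2, 2, 2, 1]) == pytest.approx(0.5)

    def test_clear_separation_significant(self):
        p = peak_parsimony_test([1] * 5, [3] * 5)
        assert p < 0.01

    def test_single_tied_pair(self):
        assert peak_parsimony_test([2], [2]) >= 0.5


class TestM3S:
    def test_poisson_panel_selects_p(self):
        rng = np.random.default_rng(6)
        values = rng.poisson(5.0, size=(50, 300)).astype(float)
        matrix = ExpressionMatrix(
            values, [f"g{i}" for i in range(50)], [f"s{j}" for j in range(300)]
        )
        results = m3s(matrix, seed=1, normalization="none", max_components=3)
        frac_p = np.mean([r.best_model is ModelName.P for r in results])
        assert frac_p >= 0.8

    def test_planted_bimodal_gene(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(1, 0.5, 250), rng.normal(6, 0.5, 250)])
        matrix = ExpressionMatrix(
            x[None, :], ["g0"], [f"s{j}" for j in range(500)]
        )
        (res,) = m3s(matrix, seed=2, normalization="none")
        assert res.best_model in (ModelName.MG, ModelName.LTMG)
        assert res.n_peaks == 2

    def test_empty_matrix_raises(self):
        with pytest.raises(Exception):
            m3s(ExpressionMatrix(np.empty((0, 0)), [], []))

    def test_too_few_samples_raises(self):
        matrix = ExpressionMatrix(np.ones((2, 5)), ["a", "b"], list("12345"))
        with pytest.raises(InvalidParameterError):
            m3s(matrix)

    def test_determinism_bit_identical(self, count_matrix):
        r1 = m3s(count_matrix, seed=11, max_components=3)
        r2 = m3s(count_matrix, seed=11, max_components=3)
        for a, b in zip(r1, r2):
            assert a.best_model is b.best_model
            assert a.n_peaks == b.n_peaks
            for m in a.fits:
                assert a.fits[m].loglik == b.fits[m].loglik
                np.testing.assert_array_equal(a.fits[m].ks_pvalue, b.fits[m].ks_pvalue)
                assert a.fits[m].params.as_dict(m) == b.fits[m].params.as_dict(m)

    def test_result_order_matches_input(self, count_matrix):
        results = m3s(count_matrix, seed=1, max_components=2)
        assert [r.gene for r in results] == count_matrix.gene_ids
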