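"""Size factors, normalization, NB-GLM fits, dispersion and the LRT designs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from pip3scope.core_io import Dataset, SampleMeta
from pip3scope.de_engine import (
    ComparisonSpec,
    SizeFactorError,
    _nb_loglik,
    bh_adjust,
    estimate_dispersion,
    estimate_size_factors,
    fit_nb_glm,
    normalize,
    run_comparison,
)
from pip3scope.synthetic_data import GeneratorConfig, generate_dataset


def median_of_ratios_oracle(mat):
    """Independent literal implementation of the median-of-ratios method."""
    mat = np.asarray(mat, dtype=float)
    keep = (mat > 0).all(axis=1)
    ref = np.exp(np.mean(np.log(mat[keep]), axis=1))
    return np.array([np.median(mat[keep, j] / ref) for j in range(mat.shape[1])])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        mat = np.tile([[3], [8], [20]], (1, 2))
        assert np.allclose(estimate_size_factors(mat), [1.0, 1.0])

    def test_doubled_column_splits_sqrt2(self):
        col = np.array([4, 10, 24, 7])
        mat = np.column_stack([col, 2 * col])
        sf = estimate_size_factors(mat)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            mat = rng.integers(1, 500, size=(6, 4))
            assert np.allclose(
                estimate_size_factors(mat), median_of_ratios_oracle(mat), atol=1e-12
            )

    def test_no_all_positive_gene_raises_with_fallback_hint(self):
        mat = np.array([[0, 5], [3, 0]])
        with pytest.raises(SizeFactorError, match="pseudo_reference"):
            estimate_size_factors(mat)
        sf = estimate_size_factors(mat, pseudo_reference=True)
        assert (sf > 0).all()


class TestNormalize:
    def test_rpkm_direct_arithmetic(self):
        samples = [SampleMeta("s1", "WT", 0, 1)]
        counts = pd.DataFrame({"s1": [10, 999_990]}, index=pd.Index(["g1", "g2"], name="gene_id"))
        genes = pd.DataFrame(
            {"length_bp": [2000, 1000], "terms": [[], []]}, index=counts.index
        )
        ds = Dataset(counts, samples, genes)
        rpkm = normalize(ds, "rpkm")
        assert rpkm.loc["g1", "s1"] == pytest.approx(5.0)

    def test_sizefactor_formula_matches_oracle(self, small_dataset):
        ds, _ = small_dataset
        norm = normalize(ds, "sizefactor")
        sf = estimate_size_factors(ds.counts)
        assert np.allclose(norm.to_numpy(), ds.counts.to_numpy() / sf.to_numpy(), atol=1e-12)


class TestNBGLM:
    def test_intercept_only_fits_sample_mean(self):
        fit = fit_nb_glm([3, 5, 7], np.ones((3, 1)), None, 0.4)
        assert np.exp(fit.coefficients[0]) == pytest.approx(5.0, abs=1e-6)

    def test_two_group_saturated_fit(self):
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = fit_nb_glm([2, 4, 20, 40], X, None, 0.2)
        assert np.exp(fit.coefficients[0]) == pytest.approx(3.0, abs=1e-6)
        assert fit.coefficients[1] / np.log(2) == pytest.approx(np.log2(10), abs=1e-6)

    def test_loglik_matches_brute_force_optimizer(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(6, 12))
            X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
            y = rng.poisson(rng.uniform(3, 40), size=n).astype(float)
            a = float(rng.uniform(0.05, 0.5))
            fit = fit_nb_glm(y, X, None, a)
            res = minimize(
                lambda b: -_nb_loglik(y, np.exp(X @ b), a),
                np.zeros(2),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_poisson_limit_agrees_with_poisson_glm(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 12
            X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
            y = rng.poisson(20, size=n).astype(float)
            fit = fit_nb_glm(y, X, None, 1e-8)
            oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            assert np.abs(fit.coefficients - oracle.params).max() < 1e-4

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm([1, 2, 3, 4], X, None, 0.1)


class TestDispersion:
    def test_poisson_data_hits_low_estimates(self):
        rng = np.random.default_rng(3)
        low = sum(
            estimate_dispersion(rng.poisson(50, 50), np.ones((50, 1))) <= 0.01
            for _ in range(50)
        )
        assert low >= 45

    def test_nb_data_recovers_alpha(self):
        rng = np.random.default_rng(4)
        a, mu = 0.2, 100.0
        ests = [
            estimate_dispersion(
                rng.negative_binomial(1 / a, 1 / (1 + a * mu), 50), np.ones((50, 1))
            )
            for _ in range(50)
        ]
        assert 0.1 <= np.median(ests) <= 0.4

    def test_constant_counts_hit_lower_bound(self):
        assert estimate_dispersion([5, 5, 5, 5], np.ones((4, 1))) == pytest.approx(
            1e-8, abs=1e-9
        )


class TestBHAdjust:
    def test_all_equal_p_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_matches_reference_and_propagates_nan(self):
        rng = np.random.default_rng(6)
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=15)
            assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRunComparison:
    def test_deviance_stat_nonnegative_and_deterministic(self, small_dataset):
        ds, _ = small_dataset
        spec = ComparisonSpec("c", "pairwise", "PTEN_KO", "WT", time_a=0, time_b=0)
        r1 = run_comparison(ds, spec)
        assert (r1.table["stat"].dropna() >= 0).all()
        r2 = run_comparison(ds, spec)
        assert r1.table.equals(r2.table)

    def test_padj_at_least_pvalue(self, small_dataset):
        ds, _ = small_dataset
        res = run_comparison(
            ds, ComparisonSpec("c", "timecourse", "WT")
        )
        ok = res.table.dropna()
        assert (ok["padj"] >= ok["pvalue"] - 1e-12).all()

    def test_lrt_invariant_under_sample_reordering(self, small_dataset):
        ds, _ = small_dataset
        spec = ComparisonSpec("c", "pairwise", "PTEN_KO", "WT", time_a=0, time_b=0)
        base = run_comparison(ds, spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds.samples))
        shuffled = Dataset(
            counts=ds.counts.iloc[:, perm],
            samples=[ds.samples[i] for i in perm],
            genes=ds.genes,
        )
        again = run_comparison(shuffled, spec)
        assert np.allclose(
            base.table["stat"].dropna(), again.table["stat"].dropna(), rtol=1e-6
        )

    def test_unknown_condition_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            run_comparison(
                ds, ComparisonSpec("c", "pairwise", "NOPE", "WT", time_a=0, time_b=0)
            )

    def test_interaction_direction_sign_follows_condition_a(self, small_dataset):
        ds, truth = small_dataset
        res = run_comparison(ds, ComparisonSpec("c", "interaction", "PTEN_KO", "WT"))
        up = sorted(truth.genes_in("coherent_up") & res.significant)
        if up:
            assert (res.table.loc[up, "log2fc"] > 0).all()


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_bh_monotone_in_ranks(p):
    """BH preserves the p-value ordering and never exceeds 1."""
    adj = bh_adjust(np.array(p))
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    assert (adj <= 1 + 1e-12).all()
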