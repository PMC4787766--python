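"""KS/Mann–Whitney oracles, Fisher enrichment, correlation and PCA QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from pip3scope.stats_compare import (
    compare_sm_distributions,
    fisher_enrichment,
    ks_two_sample,
    mann_whitney_u,
    pca_samples,
    sample_correlation_matrix,
)


def ks_d_brute(x, y):
    pooled = np.unique(np.concatenate([x, y]))
    ecdf = lambda s, t: np.mean(s <= t)
    return max(abs(ecdf(np.asarray(x), t) - ecdf(np.asarray(y), t)) for t in pooled)


def mw_u_brute(x, y):
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


class TestKS:
    def test_identical_samples_d_zero(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0

    def test_separated_supports_d_one(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6])[0] == 1.0

    def test_matches_brute_force_and_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 10, size=rng.integers(3, 12)).astype(float)
            y = rng.integers(0, 10, size=rng.integers(3, 12)).astype(float)
            d, p = ks_two_sample(x, y)
            assert d == pytest.approx(ks_d_brute(x, y), abs=1e-12)
            ref = stats.ks_2samp(x, y, method="asymp")
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestMW:
    def test_complete_dominance(self):
        assert mann_whitney_u([3, 4], [1, 2])[0] == 4.0
        assert mann_whitney_u([1, 2], [3, 4])[0] == 0.0

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 6, size=rng.integers(3, 10)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(3, 10)).astype(float)
            u, _ = mann_whitney_u(x, y)
            assert u == pytest.approx(mw_u_brute(x, y), abs=1e-12)
            u_rev, _ = mann_whitney_u(y, x)
            assert u + u_rev == pytest.approx(len(x) * len(y), abs=1e-12)


@given(
    st.lists(st.integers(0, 20), min_size=3, max_size=10),
    st.lists(st.integers(0, 20), min_size=3, max_size=10),
)
@settings(max_examples=40, deadline=None)
def test_ks_mw_invariant_under_monotone_transform(x, y):
    """Rank statistics are unchanged by strictly monotone transforms."""
    x, y = np.array(x, dtype=float), np.array(y, dtype=float)
    f = lambda v: np.exp(v / 4.0) + v
    d0, _ = ks_two_sample(x, y)
    d1, _ = ks_two_sample(f(x), f(y))
    u0, _ = mann_whitney_u(x, y)
    u1, _ = mann_whitney_u(f(x), f(y))
    assert d0 == pytest.approx(d1, abs=1e-12)
    assert u0 == pytest.approx(u1, abs=1e-12)


class TestFisher:
    def test_worked_hypergeometric_example(self):
        universe = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(5)}
        gene_set = {f"g{i}" for i in range(10)}
        ann = pd.Series({g: (["T"] if g in term_genes else []) for g in universe})
        table = fisher_enrichment(gene_set, universe, ann)
        expected = comb(15, 5, exact=True) / comb(20, 10, exact=True)
        assert table.loc[table["term"] == "T", "pvalue"].iloc[0] == pytest.approx(
            expected, abs=1e-10
        )

    def test_matches_hypergeom_oracle_on_random_annotation(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(20):
            ann = pd.Series(
                {g: (["T"] if rng.random() < 0.3 else []) for g in universe}
            )
            gene_set = set(rng.choice(universe, size=15, replace=False))
            table = fisher_enrichment(gene_set, set(universe), ann)
            row = table[table["term"] == "T"]
            if not len(row):
                continue
            n_term = int(row["term_size"].iloc[0])
            k = int(row["overlap"].iloc[0])
            oracle = stats.hypergeom.sf(k - 1, 60, n_term, 15)
            assert row["pvalue"].iloc[0] == pytest.approx(oracle, abs=1e-10)

    def test_hypergeometric_completeness(self):
        # upper tail at o plus lower tail at o-1 sums to 1
        M, n, N, o = 50, 12, 20, 6
        assert stats.hypergeom.sf(o - 1, M, n, N) + stats.hypergeom.cdf(
            o - 1, M, n, N
        ) == pytest.approx(1.0, abs=1e-12)

    def test_overlap_at_expectation_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(10, 60)}  # overlap 10 = expectation
        ann = pd.Series({g: (["T"] if g in term else []) for g in universe})
        table = fisher_enrichment(gene_set, universe, ann)
        assert table.loc[table["term"] == "T", "pvalue"].iloc[0] >= 0.5


class TestQC:
    def test_correlation_trivial_cases(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=30)
        mat = pd.DataFrame({"a": col, "b": col, "c": -col})
        corr = sample_correlation_matrix(mat)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_correlation_matches_oracle_and_is_psd(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(40, 6)))
        corr = sample_correlation_matrix(mat)
        oracle = np.corrcoef(mat.to_numpy(), rowvar=False)
        assert np.allclose(corr.to_numpy(), oracle, atol=1e-12)
        assert np.linalg.eigvalsh(corr.to_numpy()).min() >= -1e-10

    def test_zero_variance_column_warns_nan(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.warns(UserWarning):
            corr = sample_correlation_matrix(mat)
        assert np.isnan(corr.loc["a", "b"])

    def test_pca_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        _, frac = pca_samples(pd.DataFrame(rng.normal(size=(50, 8))))
        assert frac.sum() == pytest.approx(1.0, abs=1e-10)

    def test_rank_one_matrix_has_single_component(self):
        u = np.arange(1, 21, dtype=float)[:, None]
        v = np.array([[1.0, 2.0, 3.0, 4.0]])
        _, frac = pca_samples(pd.DataFrame(u @ v))
        assert frac[0] == pytest.approx(1.0, abs=1e-10)

    def test_replicates_cluster_in_pc_space(self, small_dataset):
        from pip3scope.de_engine import normalize

        ds, _ = small_dataset
        coords, _ = pca_samples(np.log1p(normalize(ds, "sizefactor")))
        pc = coords.iloc[:, :2].to_numpy()
        groups = {}
        for i, s in enumerate(ds.samples):
            groups.setdefault(s.group, []).append(i)
        within = np.mean(
            [
                np.linalg.norm(pc[i] - pc[j])
                for idx in groups.values()
                for i in idx
                for j in idx
                if i < j
            ]
        )
        centers = {g: pc[idx].mean(axis=0) for g, idx in groups.items()}
        cc = list(centers.values())
        between = np.mean(
            [np.linalg.norm(a - b) for i, a in enumerate(cc) for b in cc[i + 1 :]]
        )
        assert between / within > 5


class TestCompareDistributions:
    def test_identical_sets_give_zero_d(self, small_dataset):
        from pip3scope import motif_activity as ma

        ds, truth = small_dataset
        E = ma.promoter_expression(ds, truth.promoter_map)
        model = ma.fit_motif_activities(E, truth.motif_sites, ridge_lambda=10.0)
        scores = ma.dedup_to_genes(
            ma.target_scores(model, truth.motif_sites), truth.promoter_map
        )
        genes = set(truth.categories.index)
        with pytest.warns(UserWarning):
            res = compare_sm_distributions(scores, genes, genes, model)
        if len(res.table):
            assert (res.table["ks_d"] == 0).all()
            assert (res.table["mw_p"] > 0.99).all()
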