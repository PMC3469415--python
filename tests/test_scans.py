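"""Single-locus and pairwise regression scans against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleionet.io import GenotypeMatrix
from pleionet.scans import (CovariateSet, pairwise_fit, select_covariates,
                            single_locus_scan)
from tests.conftest import random_dataset


def _geno(arr, loci=None):
    arr = np.asarray(arr, dtype=float)
    loci = loci or [f"L{j + 1}" for j in range(arr.shape[1])]
    return GenotypeMatrix(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=loci))


class TestSingleLocusScan:
    def test_exact_fit_has_unit_slope_zero_intercept(self):
        G = _geno(np.array([[0], [0], [1], [1]]))
        Y = np.array([[0.0], [0.0], [1.0], [1.0]])
        row = single_locus_scan(G, Y).iloc[0]
        assert row["beta"] == pytest.approx(1.0, abs=1e-12)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert row["se"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_design_gives_zero_effect(self):
        G = _geno(np.array([[0], [1], [0], [1]]))
        Y = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        row = single_locus_scan(G, Y).iloc[0]
        assert row["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        G, P = random_dataset(rng, n=200, loci=5, phenotypes=2)
        Y = P.values
        tab = single_locus_scan(G, Y)
        for locus in G.locus_ids:
            x = G.data[locus].to_numpy()
            A = np.column_stack([np.ones(len(x)), x])
            theta = np.linalg.solve(A.T @ A, A.T @ Y)
            resid = Y - A @ theta
            sigma2 = (resid**2).sum(axis=0) / (len(x) - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(A.T @ A)[1, 1])
            sub = tab[tab["locus"] == locus].sort_values("eigentrait")
            np.testing.assert_allclose(sub["beta"], theta[1], atol=1e-10)
            np.testing.assert_allclose(sub["intercept"], theta[0], atol=1e-10)
            np.testing.assert_allclose(sub["se"], se, atol=1e-10)

    def test_constant_locus_skipped_with_warning(self, rng):
        G = _geno(np.column_stack([np.zeros(10), (rng.random(10) < 0.5)]))
        Y = rng.normal(size=(10, 1))
        with pytest.warns(UserWarning, match="constant"):
            tab = single_locus_scan(G, Y)
        assert set(tab["locus"]) == {"L2"}

    def test_null_statistics_follow_t_distribution(self):
        # pure-null scans: |beta|/SE should be |t| with n-2 dof
        rng = np.random.default_rng(77)
        n = 30
        stats_ = []
        for _ in range(1000):
            x = (rng.random(n) < 0.5).astype(float)
            if x.std() == 0:
                continue
            y = rng.normal(size=(n, 1))
            stats_.append(single_locus_scan(_geno(x[:, None]), y)["stat"].iloc[0])
        # fold the t distribution: compare |t| via its CDF transform
        u = 2 * stats.t.cdf(stats_, df=n - 2) - 1
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestSelectCovariates:
    def test_threshold_is_inclusive(self):
        tab = pd.DataFrame({
            "locus": ["a", "b", "c"], "eigentrait": [0, 0, 0],
            "intercept": 0.0, "beta": 1.0, "se": 1.0,
            "stat": [4.0, 1.0, 3.6], "n_used": 10,
        })
        cov = select_covariates(tab, 3.55)
        assert cov.per_trait[0] == ["a", "c"]

    def test_all_below_threshold_empty(self):
        tab = pd.DataFrame({
            "locus": ["a", "b"], "eigentrait": [0, 0], "intercept": 0.0,
            "beta": 1.0, "se": 1.0, "stat": [1.0, 2.0], "n_used": 10,
        })
        assert select_covariates(tab, 3.55).per_trait[0] == []

    def test_exclusion_of_pair_members(self):
        cov = CovariateSet({0: ["a", "b", "c"]})
        assert cov.for_trait(0, exclude=("b",)) == ["a", "c"]


class TestPairwiseFit:
    def test_pure_interaction_balanced_design(self):
        # y = x1 * x2 exactly on a balanced 2x2 design
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 3, dtype=float)
        y = (X[:, 0] * X[:, 1])[:, None]
        fit = pairwise_fit(_geno(X), y, ("L1", "L2"))
        assert fit.beta12[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.beta1[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.beta2[0] == pytest.approx(0.0, abs=1e-10)

    def test_additive_data_has_no_interaction(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 3, dtype=float)
        y = (2 * X[:, 0] - X[:, 1])[:, None]
        fit = pairwise_fit(_geno(X), y, ("L1", "L2"))
        assert fit.beta12[0] == pytest.approx(0.0, abs=1e-10)

    def test_toy_fit_matches_lstsq_oracle_with_covariate(self, rng):
        X = np.array([
            [0, 0, 0], [0, 1, 1], [1, 0, 0], [1, 1, 1],
            [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 0],
        ], dtype=float)
        y = rng.normal(size=(8, 1))
        cov = CovariateSet({0: ["L3"]})
        fit = pairwise_fit(_geno(X), y, ("L1", "L2"), cov)
        A = np.column_stack([np.ones(8), X[:, 2], X[:, 0], X[:, 1],
                             X[:, 0] * X[:, 1]])
        theta = np.linalg.lstsq(A, y[:, 0], rcond=None)[0]
        np.testing.assert_allclose(fit.theta[0], theta, atol=1e-10)
        resid = y[:, 0] - A @ theta
        sigma2 = resid @ resid / (8 - 5)
        np.testing.assert_allclose(fit.cov_full[0],
                                   sigma2 * np.linalg.inv(A.T @ A), atol=1e-10)

    def test_interaction_invariant_to_covariate_order(self, rng):
        G, P = random_dataset(rng, n=120, loci=5)
        Y = P.values
        f1 = pairwise_fit(G, Y, ("L1", "L2"), CovariateSet({0: ["L3", "L4"],
                                                            1: ["L3", "L4"]}))
        f2 = pairwise_fit(G, Y, ("L1", "L2"), CovariateSet({0: ["L4", "L3"],
                                                            1: ["L4", "L3"]}))
        np.testing.assert_allclose(f1.beta12, f2.beta12, atol=1e-12)

    def test_no_double_variant_samples_flagged_inestimable(self):
        # x1 * x2 is identically zero -> interaction column degenerate
        X = np.array([[0, 0], [0, 1], [1, 0], [0, 1], [1, 0], [0, 0]],
                     dtype=float)
        fit = pairwise_fit(_geno(X), np.random.default_rng(0).normal(size=(6, 1)),
                           ("L1", "L2"))
        assert not fit.estimable
        assert "inestimable" in fit.note

    def test_identical_columns_skipped_with_note(self, rng):
        x = (rng.random(30) < 0.5).astype(float)
        X = np.column_stack([x, x])
        fit = pairwise_fit(_geno(X), rng.normal(size=(30, 1)), ("L1", "L2"))
        assert not fit.estimable
        assert "identical" in fit.note

    def test_missing_genotypes_excluded_listwise(self, rng):
        G, P = random_dataset(rng, n=100, loci=3)
        gdf = G.data.copy()
        gdf.iloc[:10, 0] = np.nan
        Gm = GenotypeMatrix(gdf)
        fit = pairwise_fit(Gm, P.values, ("L1", "L2"))
        assert fit.n_used == 90
        # equals the fit on the complete-case subset
        fit_sub = pairwise_fit(GenotypeMatrix(gdf.iloc[10:]),
                               P.values[10:], ("L1", "L2"))
        np.testing.assert_allclose(fit.beta12, fit_sub.beta12, atol=1e-12)
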