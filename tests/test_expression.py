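"""Expression-mode SVD, gene sets, enrichment and modes-as-phenotypes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pleionet.expression import (augment_with_phenotypes, decompose_expression,
                                 enrichment, mode_gene_sets, modes_as_phenotypes)
from pleionet.io import AnnotationSets, ExpressionMatrix, PhenotypeTable


@pytest.fixture
def expr(rng):
    genes = [f"g{i}" for i in range(50)]
    samples = [f"s{i}" for i in range(12)]
    return ExpressionMatrix(pd.DataFrame(rng.normal(size=(50, 12)),
                                         index=genes, columns=samples))


@pytest.fixture
def pheno12(rng):
    return PhenotypeTable(pd.DataFrame(
        rng.normal(size=(12, 2)), index=[f"s{i}" for i in range(12)],
        columns=["me", "pr"]))


class TestAugment:
    def test_appended_rows_have_target_sd(self, expr, pheno12):
        aug = augment_with_phenotypes(expr, pheno12, target_sd=2.0)
        np.testing.assert_allclose(aug.loc["me"].std(ddof=1), 2.0, atol=1e-12)
        np.testing.assert_allclose(aug.loc["pr"].std(ddof=1), 2.0, atol=1e-12)

    def test_gene_rows_unchanged_and_row_count(self, expr, pheno12):
        aug = augment_with_phenotypes(expr, pheno12)
        assert aug.shape[0] == 52
        np.testing.assert_array_equal(aug.iloc[:50].to_numpy(), expr.values)

    def test_sample_mismatch_rejected(self, expr, rng):
        bad = PhenotypeTable(pd.DataFrame(
            rng.normal(size=(3, 2)), index=["a", "b", "c"], columns=["me", "pr"]))
        with pytest.raises(ValueError, match="missing"):
            augment_with_phenotypes(expr, bad)

    def test_reference_sample_centering(self, expr, pheno12):
        aug = augment_with_phenotypes(expr, pheno12, reference_sample="s0")
        # the reference strain's own entry sits at the origin up to scaling
        scaled = aug.loc["me"]
        raw = pheno12.data["me"] - pheno12.data["me"].loc["s0"]
        np.testing.assert_allclose(np.sign(scaled), np.sign(raw), atol=0)


class TestDecomposeExpression:
    def test_rank_one_matrix_single_mode(self, rng):
        u = rng.normal(size=30)
        v = rng.normal(size=8)
        df = pd.DataFrame(np.outer(u, v), index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(8)])
        modes = decompose_expression(df)
        assert modes.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self, expr):
        modes = decompose_expression(expr.data)
        assert modes.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)

    def test_phenotype_rows_reported_separately(self, expr, pheno12):
        aug = augment_with_phenotypes(expr, pheno12)
        modes = decompose_expression(aug, phenotype_rows=["me", "pr"])
        assert list(modes.phenotype_weights.index) == ["me", "pr"]
        assert modes.gene_weights.shape[0] == 50

    def test_appended_phenotypes_barely_move_modes(self, rng):
        # two extra rows among thousands leave sample patterns essentially
        # unchanged; use data with dominant modes (as in real expression),
        # since sample patterns are only stable when singular values are
        # well separated
        genes, n = 5000, 20
        programs = rng.normal(size=(3, n)) * np.array([[8.0], [5.0], [3.0]])
        loadings = rng.normal(size=(genes, 3))
        df = pd.DataFrame(loadings @ programs + rng.normal(size=(genes, n)),
                          index=[f"g{i}" for i in range(genes)],
                          columns=[f"s{i}" for i in range(n)])
        pheno = PhenotypeTable(pd.DataFrame(
            rng.normal(size=(20, 2)), index=df.columns, columns=["me", "pr"]))
        base = decompose_expression(df)
        aug = decompose_expression(
            augment_with_phenotypes(ExpressionMatrix(df), pheno),
            phenotype_rows=["me", "pr"])
        for j in range(3):
            delta = np.min([
                np.max(np.abs(aug.sample_patterns[j] - base.sample_patterns[j])),
                np.max(np.abs(aug.sample_patterns[j] + base.sample_patterns[j])),
            ])
            assert delta < 1e-3


class TestModeGeneSets:
    def test_two_sided_normal_tail_fraction(self, rng):
        genes = [f"g{i}" for i in range(10000)]
        df = pd.DataFrame(rng.normal(size=(10000, 6)), index=genes,
                          columns=[f"s{i}" for i in range(6)])
        modes = decompose_expression(df)
        sets = mode_gene_sets(modes, k_sd=2.0)
        flagged = len(sets[0].genes) + len(sets[1].genes)
        assert flagged / 10000 == pytest.approx(0.0455, abs=0.005)

    def test_no_extreme_weights_empty_sets(self):
        df = pd.DataFrame(
            np.outer(np.linspace(-1, 1, 20), [1.0, 0.5]),
            index=[f"g{i}" for i in range(20)], columns=["s1", "s2"])
        modes = decompose_expression(df)
        sets = mode_gene_sets(modes, k_sd=3.0)
        assert sets[0].genes == [] and sets[1].genes == []

    def test_sign_partition(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 5)),
                          index=[f"g{i}" for i in range(500)],
                          columns=[f"s{i}" for i in range(5)])
        modes = decompose_expression(df)
        sets = mode_gene_sets(modes, k_sd=1.5)
        w = dict(zip(modes.gene_ids, modes.gene_weights[:, 0]))
        mu = modes.gene_weights[:, 0].mean()
        assert all(w[g] > mu for g in sets[0].genes)
        assert all(w[g] < mu for g in sets[1].genes)


class TestEnrichment:
    def test_fisher_matches_hypergeometric_enumeration(self):
        # brute force: P(overlap >= k) by enumerating draws of the set
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:5])
        gene_set = universe[:5]          # set identical to the term
        ann = AnnotationSets({"T": term}, {"T": {"description": "",
                                                 "category": "GO"}})
        results, _ = enrichment(gene_set, universe, ann, n_perm=10)
        from math import comb
        n, K, s = 20, 5, 5
        p_brute = sum(
            comb(K, k) * comb(n - K, s - k) / comb(n, s)
            for k in range(5, s + 1)
        )
        assert results[0].p == pytest.approx(p_brute, rel=1e-10)

    def test_disjoint_term_skipped_with_warning(self):
        ann = AnnotationSets({"T": {"zz1", "zz2"}},
                             {"T": {"description": "", "category": "GO"}})
        with pytest.warns(UserWarning, match="disjoint"):
            results, _ = enrichment(["g1"], ["g1", "g2"], ann, n_perm=5)
        assert results == []

    def test_empty_set_empty_results(self):
        ann = AnnotationSets({"T": {"g1"}}, {})
        results, fdr = enrichment([], ["g1", "g2"], ann)
        assert results == [] and fdr is None

    def test_tf_bonferroni_factor(self):
        universe = [f"g{i}" for i in range(30)]
        ann = AnnotationSets(
            {f"TF{i}": set(universe[i:i + 5]) for i in range(6)},
            {f"TF{i}": {"description": "", "category": "TF"} for i in range(6)})
        results, _ = enrichment(universe[:5], universe, ann, category="TF")
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 6))

    def test_permutation_fdr_near_nominal(self, rng):
        # random sets vs random annotations: estimated FDR should sit near
        # the null expectation within a factor of ~2
        universe = [f"g{i}" for i in range(400)]
        ann = AnnotationSets(
            {f"T{i}": set(rng.choice(universe, size=30, replace=False))
             for i in range(40)},
            {})
        gene_set = list(rng.choice(universe, size=30, replace=False))
        cutoff = 0.05
        results, fdr = enrichment(gene_set, universe, ann, p_cutoff=cutoff,
                                  n_perm=300, seed=3)
        n_hits = sum(r.p <= cutoff for r in results)
        # fdr = mean null hits / observed hits; with random data observed
        # and null hit rates coincide in expectation
        expected = 40 * np.mean([r.p <= cutoff for r in results]) / max(n_hits, 1)
        if n_hits:
            assert fdr == pytest.approx(expected, rel=1.0)


class TestModesAsPhenotypes:
    def test_orthogonal_columns(self, expr):
        modes = decompose_expression(expr.data)
        df = modes_as_phenotypes(modes, 2)
        assert abs(df.iloc[:, 0] @ df.iloc[:, 1]) < 1e-10
        assert df.attrs["already_orthogonal"]

    def test_k_beyond_rank_rejected(self, expr):
        modes = decompose_expression(expr.data)
        with pytest.raises(ValueError, match="rank"):
            modes_as_phenotypes(modes, 13)

    def test_influences_from_modes_match_phenotype_run_in_sign(self, rng):
        # forward-simulate two phenotypes with one planted suppression,
        # derive expression driven by those phenotypes, and check that the
        # influence inferred from 3 expression modes agrees in sign
        from pleionet.model import InfluenceModel
        from pleionet.simulate import suppression_fixture, simulate_expression
        G, pheno, truth = suppression_fixture(n=120, seed=21)
        E = simulate_expression(pheno, n_genes=800, genes_per_program=150,
                                noise_sd=0.3, seed=21)
        aug = augment_with_phenotypes(ExpressionMatrix(E), pheno)
        modes = decompose_expression(aug, phenotype_rows=pheno.phenotype_ids)
        Ymodes = modes_as_phenotypes(modes, 3)
        res_modes = InfluenceModel(G, Ymodes, decompose=False).fit(
            n_perm_pair=200, seed=21)
        res_pheno = InfluenceModel(G, pheno).fit(n_perm_pair=200, seed=21)
        tm = res_modes.influences_table().set_index(["source", "target"])
        tp = res_pheno.influences_table().set_index(["source", "target"])
        g_modes = tm.loc[("B", "A"), "gamma"]
        g_pheno = tp.loc[("B", "A"), "gamma"]
        assert np.sign(g_modes) == np.sign(g_pheno) == -1
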