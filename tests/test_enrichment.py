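"""Weighted-KS enrichment score and phenotype-permutation significance."""

import numpy as np
import pandas as pd
import pytest

from mycoarch.enrichment import (
    RankedList,
    enrichment_score,
    permutation_significance,
    rank_genes_by_phenotype,
)
from mycoarch.io_formats import GeneExpressionTable, GeneSetCollection


def brute_force_es(metric, hits, weight):
    """Straight-line transcription of the running-sum definition."""
    n = len(metric)
    n_hits = sum(hits)
    denom = sum(abs(m) ** weight for m, h in zip(metric, hits) if h)
    running, best = 0.0, 0.0
    for m, h in zip(metric, hits):
        if h:
            running += (abs(m) ** weight / denom) if denom else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def make_expr(matrix, genes=None, samples=None):
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(matrix.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(matrix.shape[1])]
    return GeneExpressionTable(pd.DataFrame(matrix, index=genes,
                                            columns=samples))


class TestRanking:
    def test_self_and_anti_correlated_genes(self):
        phenotype = [1.0, 2.0, 3.0, 4.0]
        expr = make_expr([phenotype, [-v for v in phenotype],
                          [0.3, -1.0, 0.8, 0.1]],
                         genes=["SAME", "ANTI", "NOISE"])
        ranked = rank_genes_by_phenotype(expr, phenotype)
        assert ranked.genes[0] == "SAME"
        assert ranked.genes[-1] == "ANTI"
        assert ranked.metric[0] == pytest.approx(1.0)
        assert ranked.metric[-1] == pytest.approx(-1.0)

    def test_toy_ordering_matches_hand_pearson(self):
        phenotype = np.array([0.0, 1.0, 2.0, 3.0])
        rows = {"A": [1.0, 2.0, 2.5, 4.0], "B": [5.0, 1.0, 4.0, 2.0],
                "C": [0.0, 0.0, 1.0, 1.0]}
        expr = make_expr(list(rows.values()), genes=list(rows))
        ranked = rank_genes_by_phenotype(expr, phenotype)
        hand = {g: np.corrcoef(v, phenotype)[0, 1] for g, v in rows.items()}
        expected = sorted(hand, key=lambda g: (-hand[g], g))
        assert ranked.genes == expected
        np.testing.assert_allclose(ranked.metric,
                                   [hand[g] for g in expected], atol=1e-12)

    def test_zero_variance_gene_gets_metric_zero(self):
        expr = make_expr([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                         genes=["FLAT", "UP"])
        ranked = rank_genes_by_phenotype(expr, [0.0, 1.0, 2.0])
        assert ranked.metric[ranked.genes.index("FLAT")] == 0.0

    def test_zero_variance_phenotype_is_error(self):
        expr = make_expr([[0.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="variance"):
            rank_genes_by_phenotype(expr, [1.0, 1.0, 1.0])

    def test_ties_break_by_gene_symbol(self):
        phenotype = [0.0, 1.0, 2.0]
        expr = make_expr([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]],
                         genes=["ZZZ", "AAA"])
        ranked = rank_genes_by_phenotype(expr, phenotype)
        assert ranked.genes == ["AAA", "ZZZ"]


class TestEnrichmentScore:
    def test_single_top_gene_unweighted(self):
        ranked = RankedList(genes=["A", "B", "C", "D"],
                            metric=np.array([0.9, 0.5, 0.1, -0.4]))
        es, running = enrichment_score(ranked, ["A"], weight=0.0)
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_five_gene_hand_enumeration(self):
        # hits at ranks 2 and 4 (weight 0): running sums
        # -1/3, +1/6, -1/6, +1/3, 0 -> first max-magnitude value is -1/3
        ranked = RankedList(genes=list("ABCDE"),
                            metric=np.array([0.5, 0.4, 0.3, 0.2, 0.1]))
        es, running = enrichment_score(ranked, ["B", "D"], weight=0.0)
        np.testing.assert_allclose(
            running, [-1 / 3, 1 / 6, -1 / 6, 1 / 3, 0.0], atol=1e-12)
        assert es == pytest.approx(
            brute_force_es(ranked.metric, [False, True, False, True, False],
                           0.0))

    def test_reversal_negates_es_unweighted(self):
        metric = np.array([0.8, 0.6, 0.2, -0.1, -0.5])
        ranked = RankedList(genes=list("ABCDE"), metric=metric)
        flipped = RankedList(genes=list("EDCBA"), metric=-metric[::-1])
        es_fwd, _ = enrichment_score(ranked, ["A", "B"], weight=0.0)
        es_rev, _ = enrichment_score(flipped, ["A", "B"], weight=0.0)
        assert es_rev == pytest.approx(-es_fwd)

    def test_degenerate_sets_rejected(self):
        ranked = RankedList(genes=list("ABC"),
                            metric=np.array([0.5, 0.1, -0.2]))
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(ranked, ["ZZZ"])
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, ["A", "B", "C"])

    def test_brute_force_agreement_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 50))
            metric = np.sort(rng.normal(size=n))[::-1]
            genes = [f"G{i:03d}" for i in range(n)]
            n_hits = int(rng.integers(1, n))
            hit_idx = set(rng.choice(n, size=n_hits, replace=False).tolist())
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            ranked = RankedList(genes=genes, metric=metric)
            es, _ = enrichment_score(
                ranked, [genes[i] for i in sorted(hit_idx)], weight=weight)
            expected = brute_force_es(metric, [i in hit_idx for i in range(n)],
                                      weight)
            assert es == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= es <= 1.0


def planted_expression(rng, n_genes=150, n_samples=60, set_size=15, rho=0.8):
    phenotype = rng.normal(size=n_samples)
    z = (phenotype - phenotype.mean()) / phenotype.std()
    matrix = rng.normal(size=(n_genes, n_samples))
    matrix[:set_size] = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(
        size=(set_size, n_samples))
    genes = [f"G{i:03d}" for i in range(n_genes)]
    expr = make_expr(matrix, genes=genes)
    sets = GeneSetCollection({
        "PLANTED": genes[:set_size],
        "NULL_A": genes[set_size:set_size + 15],
        "NULL_B": genes[set_size + 15:set_size + 30],
    })
    return expr, phenotype, sets


class TestPermutationSignificance:
    def test_planted_set_passes_filter(self, rng):
        expr, phenotype, sets = planted_expression(rng)
        result = permutation_significance(expr, phenotype, sets,
                                          n_perm=200, seed=5)
        row = result.set_index("gene_set").loc["PLANTED"]
        assert row["pass_filter"]
        assert row["p_perm"] < 0.05 and row["fdr_q"] < 0.25
        assert row["ES"] > 0

    def test_p_values_positive_and_bounded(self, rng):
        expr, phenotype, sets = planted_expression(rng)
        result = permutation_significance(expr, phenotype, sets,
                                          n_perm=100, seed=5)
        assert ((result["p_perm"] > 0) & (result["p_perm"] <= 1)).all()
        assert (result["ES"].abs() <= 1).all()

    def test_seed_determinism_bit_identical(self, rng):
        expr, phenotype, sets = planted_expression(rng)
        a = permutation_significance(expr, phenotype, sets, n_perm=100, seed=9)
        b = permutation_significance(expr, phenotype, sets, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_too_few_permutations_rejected(self, rng):
        expr, phenotype, sets = planted_expression(rng)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(expr, phenotype, sets, n_perm=10, seed=1)
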