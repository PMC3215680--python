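import itertools

import numpy as np
import pytest

from prodige import (
    AssociationTable,
    DiseaseIndex,
    FeatureTable,
    GeneIndex,
    LOOCVResult,
    RunConfig,
    auc_from_rank,
    hypergeom_enrichment,
    linear_kernel,
    loocv,
    overlap_stats,
    rank_of,
    recall_curve,
    wilcoxon_paired,
)


class TestRankOf:
    def test_no_ties_both_rules(self):
        scores = {"a": 0.9, "t": 0.5, "b": 0.3}
        assert rank_of(scores, "t", "mid") == 2
        assert rank_of(scores, "t", "worst") == 2

    def test_tie_arithmetic(self):
        scores = {"a": 0.9, "t": 0.5, "b": 0.5, "c": 0.1}
        assert rank_of(scores, "t", "mid") == 2.5
        assert rank_of(scores, "t", "worst") == 3

    def test_full_tie(self):
        scores = {f"g{i}": 1.0 for i in range(10)}
        assert rank_of(scores, "g3", "mid") == 5.5

    def test_missing_target_errors(self):
        with pytest.raises(KeyError):
            rank_of({"a": 1.0}, "t")


class TestAucFromRank:
    def test_printed_identity(self):
        assert auc_from_rank(1, 10) == pytest.approx(0.9)
        assert auc_from_rank(10, 10) == 0.0

    def test_inverse_identity_exact(self):
        for n in (5, 17, 100):
            for rank in range(1, n + 1):
                auc = auc_from_rank(rank, n)
                assert n * (1 - auc) == pytest.approx(rank, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_from_rank(0, 10)
        with pytest.raises(ValueError):
            auc_from_rank(11, 10)

    def test_midrank_equals_half_credit_auc_under_ties(self, rng):
        # brute-force AUC giving 1/2 credit to tied comparisons
        for _ in range(20):
            scores = rng.integers(0, 5, size=12).astype(float)  # many ties
            names = [f"g{i}" for i in range(12)]
            target = names[int(rng.integers(12))]
            mapping = dict(zip(names, scores))
            r = rank_of(mapping, target, "mid")
            others = [mapping[n] for n in names if n != target]
            t = mapping[target]
            credit = sum(1.0 if t > o else 0.5 if t == o else 0.0 for o in others)
            auc_brute = credit / len(others) if others else 1.0
            # rank = (#others + 1) * (1 - AUC_half) + 1/2 ... equivalently:
            auc = 1 - (r - 0.5) / len(names)
            assert auc == pytest.approx(
                (credit + 0.5) / len(names), abs=1e-12
            )
            assert r == pytest.approx(len(others) * (1 - auc_brute) + 1, abs=1e-12)


class TestRecallCurve:
    def make_result(self, ranks, n_cands):
        k = len(ranks)
        return LOOCVResult(
            disease_ids=tuple(f"d{i}" for i in range(k)),
            gene_ids=tuple(f"g{i}" for i in range(k)),
            ranks=np.asarray(ranks, dtype=float),
            n_candidates=np.asarray(n_cands),
        )

    def test_basic_fractions(self):
        res = self.make_result([1, 2, 3], [10, 10, 10])
        curve = recall_curve(res, [2])
        assert curve.values[0] == pytest.approx(2 / 3)

    def test_saturates_at_one(self):
        res = self.make_result([1, 5, 9], [10, 10, 10])
        assert recall_curve(res, [10]).values[0] == 1.0

    def test_percent_thresholds_resolved_per_row(self):
        # rank 2 of 100 candidates is within the top 5%; rank 2 of 20 is not
        res = self.make_result([2, 2], [100, 20])
        curve = recall_curve(res, ["5%"])
        assert curve.values[0] == pytest.approx(0.5)

    def test_standard_grid_layout(self):
        res = self.make_result([1, 4, 40, 200], [400] * 4)
        curve = recall_curve(res, [1, 10, "1%", "5%", "10%"])
        assert curve.grid == ("1", "10", "1%", "5%", "10%")
        assert np.all(np.diff(curve.values) >= 0)  # nondecreasing grid here

    def test_monotone_and_reaches_one(self, rng):
        ranks = rng.integers(1, 50, size=30)
        res = self.make_result(ranks, [50] * 30)
        curve = recall_curve(res, list(range(1, 51)))
        assert np.all(np.diff(curve.values) >= 0)
        assert curve.values[-1] == 1.0

    def test_empty_inputs_rejected(self):
        res = self.make_result([1], [10])
        with pytest.raises(ValueError):
            recall_curve(res, [])


class TestWilcoxonPaired:
    def test_identical_vectors_give_p_one(self):
        a = np.arange(1, 11, dtype=float)
        stat, p, direction = wilcoxon_paired(a, a)
        assert p == 1.0 and direction == "none"

    def test_exact_p_for_uniformly_better_method(self):
        # 10 pairs, method a strictly better in all, untied magnitudes:
        # two-sided exact p = 2 / 2^10
        b = np.arange(1, 11, dtype=float) * 10
        a = b - np.arange(1, 11)
        stat, p, direction = wilcoxon_paired(a, b)
        assert p == pytest.approx(2 / 2**10)
        assert direction == "a"

    def test_exact_vs_enumeration_oracle(self, rng):
        # enumerate all sign assignments for small n
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        _, p, _ = wilcoxon_paired(a, b)
        d = a - b
        d = d[d != 0]
        mags = np.abs(d)
        signed_ranks = np.argsort(np.argsort(mags)) + 1.0
        w_obs = signed_ranks[d > 0].sum()
        n = d.size
        total = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for r, s in zip(signed_ranks, signs) if s)
            mu = signed_ranks.sum() / 2
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                total += 1
        assert p == pytest.approx(total / 2**n, abs=1e-12)

    def test_exact_and_approx_branches_agree_at_boundary(self, rng):
        a = rng.normal(size=25)
        b = a + rng.normal(size=25) * 0.8
        _, p_exact, _ = wilcoxon_paired(a, b)
        import scipy.stats

        _, p_approx = scipy.stats.wilcoxon(a, b, zero_method="wilcox",
                                           correction=True, method="approx")
        assert p_exact == pytest.approx(p_approx, abs=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired(np.ones(3), np.ones(4))


class TestHypergeomEnrichment:
    def test_single_term_tail_closed_form(self):
        # universe 10, reference 5, top 5, overlap 5: p = 1 / C(10,5)
        top = [f"g{i}" for i in range(5)]
        p = hypergeom_enrichment(top, top, universe_size=10)
        assert p == pytest.approx(1 / 252)

    def test_zero_overlap_gives_p_one(self):
        p = hypergeom_enrichment(["a", "b"], ["c", "d"], universe_size=10)
        assert p == pytest.approx(1.0)

    def test_matches_pmf_summation_oracle(self, rng):
        from math import comb

        for _ in range(10):
            universe = 30
            ids = [f"g{i}" for i in range(universe)]
            ref = list(rng.choice(ids, size=8, replace=False))
            top = list(rng.choice(ids, size=6, replace=False))
            overlap = len(set(ref) & set(top))
            brute = sum(
                comb(8, k) * comb(universe - 8, 6 - k) / comb(universe, 6)
                for k in range(overlap, min(6, 8) + 1)
            )
            p = hypergeom_enrichment(top, ref, universe)
            assert p == pytest.approx(brute, rel=1e-10)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["a", "b"], ["c"], universe_size=2)

    def test_precision_recall(self):
        prec, rec = overlap_stats(["a", "b", "c", "d"], ["c", "d", "e"])
        assert prec == pytest.approx(2 / 4)
        assert rec == pytest.approx(2 / 3)


@pytest.fixture(scope="module")
def small_bench():
    from prodige import SyntheticConfig, generate

    bench = generate(SyntheticConfig(n_genes=40, n_diseases=3,
                                     genes_per_disease=3, seed=5))
    kernels = [linear_kernel(t) for t in bench.feature_tables]
    return bench, kernels


class TestLOOCV:
    def test_shapes_and_bounds(self, small_bench):
        bench, kernels = small_bench
        res = loocv(1, bench.genes, kernels, bench.associations, None,
                    RunConfig(variant=1, B=6, seed=1))
        assert len(res) == bench.associations.T
        n = len(bench.genes)
        for r, n_c, d in zip(res.ranks, res.n_candidates, res.disease_ids):
            # the held-out gene rejoins the candidate set
            assert n_c == n - len(bench.associations.positive_set(d)) + 1
            assert 1 <= r <= n_c

    def test_variant1_rejects_single_gene_disease(self):
        genes = GeneIndex([f"g{i}" for i in range(6)])
        diseases = DiseaseIndex(["d1", "d2"])
        assoc = AssociationTable(
            (("d1", "g0"), ("d1", "g1"), ("d2", "g2")), genes, diseases
        )
        K = linear_kernel(FeatureTable(genes, np.eye(6)))
        with pytest.raises(ValueError, match="d2"):
            loocv(1, genes, [K], assoc, None, RunConfig(variant=1, B=2))

    def test_duplicate_kernel_column_ranks_first(self):
        # a held-out gene whose kernel row equals a remaining positive's
        # receives that positive's decision value, hence rank 1
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 8))
        X[5] = X[1]  # g5 duplicates positive g1
        genes = GeneIndex([f"g{i}" for i in range(12)])
        diseases = DiseaseIndex(["d1"])
        K = linear_kernel(FeatureTable(genes, X))
        assoc = AssociationTable((("d1", "g1"), ("d1", "g5")), genes, diseases)
        res = loocv(1, genes, [K], assoc, None, RunConfig(variant=1, B=8, seed=2))
        row = dict(zip(res.gene_ids, res.ranks))
        assert row["g5"] <= 1.5  # rank 1, allowing a mid-rank tie with g1's twin

    def test_association_storage_order_irrelevant(self, small_bench):
        bench, kernels = small_bench
        cfg = RunConfig(variant=2, B=4, seed=8)
        res1 = loocv(2, bench.genes, kernels, bench.associations, None, cfg)
        shuffled = AssociationTable(
            tuple(reversed(bench.associations.pairs)),
            bench.genes, bench.diseases,
        )
        res2 = loocv(2, bench.genes, kernels, shuffled, None, cfg)
        assert res1.disease_ids == res2.disease_ids
        np.testing.assert_allclose(res1.ranks, res2.ranks, atol=1e-9)


class TestRandomBaseline:
    def test_uniform_mean_and_quantiles(self):
        from prodige import random_baseline

        res = LOOCVResult(("d",), ("g",), np.array([2.0]), np.array([3]))
        draws = random_baseline(res, n_draws=100_000, seed=4)
        # single row, n=3: mean (n+1)/2 = 2, each value in {1,2,3} w.p. 1/3
        se = np.sqrt(2 / 3 / 100_000)
        assert abs(draws.mean() - 2.0) < 3 * se
        for v in (1.0, 2.0, 3.0):
            assert abs(np.mean(draws == v) - 1 / 3) < 0.01
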