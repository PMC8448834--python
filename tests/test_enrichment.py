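import numpy as np
import pandas as pd
import pytest

from plsassay import (
    EnrichmentParams,
    ExpressionMatrix,
    GeneSet,
    RankedList,
    enrichment_score,
    gsea,
    nes_and_fdr,
    null_distribution,
    rank_by_correlation,
    rank_by_phenotype,
    read_rnk,
    write_rnk,
)
from plsassay.enrichment import EnrichmentResult, results_frame

from _oracles import es_brute_force, pooled_fdr_oracle
from conftest import make_ranked


def matrix_from(values, genes, samples, scale="log2"):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples),
        scale=scale,
    )


class TestRankedList:
    def test_ties_broken_by_gene_id(self):
        rl = RankedList.from_unsorted(["b", "a", "c"], [1.0, 1.0, 2.0])
        assert rl.genes == ("c", "a", "b")

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedList.from_unsorted(["a", "a"], [1.0, 2.0])

    def test_rnk_round_trip(self, tmp_path):
        rl = make_ranked(15, seed=3)
        p = tmp_path / "x.rnk"
        write_rnk(rl, p)
        back = read_rnk(p)
        assert back.genes == rl.genes
        np.testing.assert_allclose(back.metric, rl.metric)


class TestRankByPhenotype:
    def test_upshifted_gene_ranks_above_flat_gene(self):
        vals = [[10, 11, 2, 1], [5, 5, 5, 5]]
        m = matrix_from(vals, ["up", "flat"], ["c1", "c2", "r1", "r2"])
        rl = rank_by_phenotype(m, ["c1", "c2"], ["r1", "r2"])
        assert rl.genes[0] == "up" and rl.metric[0] > 0

    def test_identical_groups_give_zero_metric(self):
        m = matrix_from([[4, 6, 4, 6], [1, 2, 3, 4]], ["a", "b"], ["c1", "c2", "r1", "r2"])
        rl = rank_by_phenotype(m, ["c1", "c2"], ["r1", "r2"])
        assert rl.metric[list(rl.genes).index("a")] == 0.0

    def test_signal2noise_matches_hand_arithmetic_with_floor(self):
        # case (8, 10): mu=9, sd=sqrt(2); floored sd = max(sqrt(2), 1.8, 0.2) = 1.8
        # ref (1, 3): mu=2, sd=sqrt(2); floored sd = max(sqrt(2), 0.4, 0.2) = sqrt(2)
        # s2n = 7 / (1.8 + sqrt(2))
        m = matrix_from([[8, 10, 1, 3], [0, 0, 0, 0]], ["a", "z"], ["c1", "c2", "r1", "r2"])
        rl = rank_by_phenotype(m, ["c1", "c2"], ["r1", "r2"])
        expected = 7.0 / (1.8 + np.sqrt(2.0))
        assert rl.metric[list(rl.genes).index("a")] == pytest.approx(expected, abs=1e-12)

    def test_log2fc_is_mean_difference(self):
        m = matrix_from([[5, 7, 1, 3], [1, 1, 1, 1]], ["a", "b"], ["c1", "c2", "r1", "r2"])
        rl = rank_by_phenotype(m, ["c1", "c2"], ["r1", "r2"], metric="log2fc")
        assert rl.metric[list(rl.genes).index("a")] == pytest.approx(4.0)

    def test_overlapping_groups_rejected(self):
        m = matrix_from([[1, 2, 3], [4, 5, 6]], ["a", "b"], ["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="overlap"):
            rank_by_phenotype(m, ["s1", "s2"], ["s2", "s3"])

    def test_single_replicate_rejected_for_signal2noise(self):
        m = matrix_from([[1, 2], [3, 4]], ["a", "b"], ["s1", "s2"])
        with pytest.raises(ValueError, match="replicates"):
            rank_by_phenotype(m, ["s1"], ["s2"])


class TestRankByCorrelation:
    def test_gene_equal_to_covariate_ranks_first(self):
        cov = [1.0, 2.0, 3.0, 4.0]
        m = matrix_from([cov, [-c for c in cov], [5, 1, 4, 2]], ["pos", "neg", "x"],
                        [f"s{i}" for i in range(4)])
        rl = rank_by_correlation(m, cov)
        assert rl.genes[0] == "pos" and rl.metric[0] == pytest.approx(1.0)
        assert rl.genes[-1] == "neg" and rl.metric[-1] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        cov = [0.5, 1.5, 2.0, 4.0]
        gene = [2.0, 1.0, 4.0, 3.0]
        m = matrix_from([gene, [1, 2, 3, 4]], ["g", "h"], [f"s{i}" for i in range(4)])
        rl = rank_by_correlation(m, cov)
        x, y = np.asarray(gene), np.asarray(cov)
        r = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert rl.metric[list(rl.genes).index("g")] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_genes_excluded(self):
        m = matrix_from([[1, 2, 3], [3, 1, 2], [7, 7, 7]], ["g", "h", "flat"],
                        ["s1", "s2", "s3"])
        rl = rank_by_correlation(m, [1.0, 2.0, 3.0])
        assert "flat" not in rl.genes and len(rl) == 2

    def test_constant_covariate_rejected(self):
        m = matrix_from([[1, 2, 3], [4, 5, 6]], ["a", "b"], ["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="constant"):
            rank_by_correlation(m, [2.0, 2.0, 2.0])


class TestEnrichmentScore:
    def test_top_set_unweighted_es_is_one(self):
        rl = make_ranked(30, seed=1)
        s = GeneSet("top", rl.genes[:5])
        es, running, leading = enrichment_score(rl, s, weight_p=0)
        assert es == 1.0
        assert leading == rl.genes[:5]
        assert len(running) == 30

    def test_bottom_set_unweighted_es_is_minus_one(self):
        rl = make_ranked(30, seed=1)
        es, _, leading = enrichment_score(rl, GeneSet("bot", rl.genes[-5:]), weight_p=0)
        assert es == -1.0
        assert set(leading) == set(rl.genes[-5:])

    def test_hits_at_ranks_1_and_4_match_brute_force(self):
        genes = tuple("abcdefghij")
        metric = np.array([5.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.2, 0.1])
        rl = RankedList(genes, metric)
        s = GeneSet("s", ("a", "c"))  # hits at ranks 1 and 3
        member = np.isin(np.asarray(genes, dtype=object), list(s.genes))
        es, _, _ = enrichment_score(rl, s, weight_p=1)
        assert es == pytest.approx(es_brute_force(member, metric, 1), abs=1e-12)

    def test_empty_intersection_rejected(self):
        rl = make_ranked(10)
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(rl, GeneSet("none", ("zz",)), 1)

    def test_whole_list_set_rejected(self):
        rl = make_ranked(10)
        with pytest.raises(ValueError, match="whole"):
            enrichment_score(rl, GeneSet("all", rl.genes), 1)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(5, 120))
            k = int(rng.integers(1, min(15, n - 1) + 1))
            metric = np.sort(rng.normal(0, 2, n))[::-1]
            genes = tuple(f"g{i:04d}" for i in range(n))
            rl = RankedList(genes, metric)
            hits = rng.choice(n, size=k, replace=False)
            s = GeneSet("s", tuple(genes[i] for i in sorted(hits)))
            p = float(rng.choice([0, 1, 2]))
            member = np.isin(np.asarray(genes, dtype=object), list(s.genes))
            es, _, _ = enrichment_score(rl, s, p)
            assert abs(es - es_brute_force(member, metric, p)) < 1e-12

    def test_constant_shift_invariance_only_when_unweighted(self):
        rl = make_ranked(40, seed=7)
        shifted = RankedList(rl.genes, rl.metric + 5.0)
        # scattered set so the extremum never swallows every hit (which
        # would make the weighted ES trivially shift-invariant too)
        s = GeneSet("s", rl.genes[:3] + rl.genes[-3:])
        es0a, _, _ = enrichment_score(rl, s, 0)
        es0b, _, _ = enrichment_score(shifted, s, 0)
        assert es0a == pytest.approx(es0b, abs=1e-12)
        es1a, _, _ = enrichment_score(rl, s, 1)
        es1b, _, _ = enrichment_score(shifted, s, 1)
        assert es1a != pytest.approx(es1b, abs=1e-9)

    def test_reversed_list_negates_unweighted_es(self):
        rl = make_ranked(35, seed=9)
        rev = RankedList(rl.genes[::-1], -rl.metric[::-1])
        s = GeneSet("s", rl.genes[2:8])
        es_f, _, _ = enrichment_score(rl, s, 0)
        es_r, _, _ = enrichment_score(rev, s, 0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)


class TestNullAndFdr:
    def test_same_seed_reproduces_null(self):
        rl = make_ranked(60, seed=2)
        params = EnrichmentParams(n_perm=200, seed=5)
        a = null_distribution(rl, 8, params)
        b = null_distribution(rl, 8, params)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 200

    def test_null_mean_near_zero_on_symmetric_metric(self):
        n = 100
        metric = np.linspace(1, -1, n)
        rl = RankedList(tuple(f"g{i:03d}" for i in range(n)), metric)
        null = null_distribution(rl, 10, EnrichmentParams(n_perm=1000, seed=0))
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean()) < 3 * se

    def test_all_nulls_equal_observed_gives_nes_one_p_one(self):
        r = EnrichmentResult("s", es=0.5, nes=np.nan, p_nominal=1, fdr_q=1,
                             leading_edge=(), n_hits=3)
        out = nes_and_fdr([r], {"s": np.full(100, 0.5)})
        assert out[0].nes == pytest.approx(1.0)
        assert out[0].p_nominal == pytest.approx(1.0)

    def test_observed_exceeding_all_nulls_hits_clamp(self):
        rng = np.random.default_rng(0)
        null = np.abs(rng.normal(0, 0.1, 100)) + 0.01  # all positive, all < 0.9
        r = EnrichmentResult("s", es=0.9, nes=np.nan, p_nominal=1, fdr_q=1,
                             leading_edge=(), n_hits=3)
        out = nes_and_fdr([r], {"s": null})
        assert out[0].p_nominal == pytest.approx(1 / (1 + 100))

    def test_no_same_sign_nulls_flagged_degenerate(self):
        r = EnrichmentResult("s", es=-0.4, nes=np.nan, p_nominal=1, fdr_q=1,
                             leading_edge=(), n_hits=3)
        out = nes_and_fdr([r], {"s": np.full(100, 0.5)})  # all positive nulls
        assert out[0].degenerate and out[0].p_nominal == 1.0

    def test_fdr_matches_independent_pooled_oracle(self):
        rng = np.random.default_rng(42)
        rl = make_ranked(80, seed=4)
        sets = [GeneSet("a", rl.genes[:6]), GeneSet("b", rl.genes[40:52])]
        params = EnrichmentParams(n_perm=200, seed=9)
        results = gsea(rl, sets, params)
        nulls = {
            s.name: null_distribution(rl, len(s), params) for s in sets
        }
        obs = {}
        for s in sets:
            es, _, _ = enrichment_score(rl, s, params.weight_p)
            obs[s.name] = es
        oracle = pooled_fdr_oracle(obs, nulls)
        for r in results:
            assert r.fdr_q == pytest.approx(oracle[r.set_name], abs=1e-12)


class TestGsea:
    def test_planted_up_and_down_sets_get_opposite_nes_signs(self):
        rng = np.random.default_rng(8)
        genes = [f"u{i}" for i in range(10)] + [f"d{i}" for i in range(10)] + [
            f"n{i}" for i in range(80)
        ]
        case = np.concatenate([rng.normal(3, 1, 10), rng.normal(-3, 1, 10),
                               rng.normal(0, 1, 80)])
        vals = np.column_stack([
            case + rng.normal(0, 0.3, 100),
            case + rng.normal(0, 0.3, 100),
            rng.normal(0, 0.3, 100),
            rng.normal(0, 0.3, 100),
        ])
        m = matrix_from(vals, genes, ["c1", "c2", "r1", "r2"])
        sets = [GeneSet("up", tuple(genes[:10])), GeneSet("down", tuple(genes[10:20]))]
        res = gsea((m, ["c1", "c2"], ["r1", "r2"]), sets, EnrichmentParams(n_perm=200, seed=1))
        by = {r.set_name: r for r in res}
        assert by["up"].nes > 0 and by["down"].nes < 0

    def test_sets_absent_from_matrix_error(self):
        rl = make_ranked(20)
        with pytest.raises(ValueError, match="no genes"):
            gsea(rl, [GeneSet("none", ("zzz",))], EnrichmentParams(n_perm=100, seed=0))

    def test_same_seed_gives_identical_result_table(self):
        rl = make_ranked(50, seed=6)
        sets = [GeneSet("a", rl.genes[:5]), GeneSet("b", rl.genes[20:28])]
        params = EnrichmentParams(n_perm=150, seed=3)
        t1 = results_frame(gsea(rl, sets, params)).to_csv()
        t2 = results_frame(gsea(rl, sets, params)).to_csv()
        assert t1 == t2

    def test_phenotype_permutation_mode_runs(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(30)]
        vals = rng.normal(5, 1, (30, 6))
        m = matrix_from(vals, genes, [f"s{i}" for i in range(6)])
        res = gsea(
            (m, ["s0", "s1", "s2"], ["s3", "s4", "s5"]),
            [GeneSet("a", tuple(genes[:6]))],
            EnrichmentParams(n_perm=100, seed=2, perm_mode="phenotype"),
        )
        assert len(res) == 1 and np.isfinite(res[0].fdr_q)
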