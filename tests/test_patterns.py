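import collections

import numpy as np
import pytest

from engep.data_model import ExpressionMatrix
from engep.patterns import (Pattern, assign_to_known, build_spatial_weights,
                            classify_by_likelihood, cluster_genes,
                            detect_multimodality, discover_novel_patterns,
                            filter_singleton_patterns, filter_spatial_genes,
                            find_known_patterns, gene_network,
                            likelihood_scores, morans_i, representative_genes,
                            run_pattern_discovery, sci, sci_matrix)
from engep.patterns import _prune_low_degree
from engep.simulate import SimSpec, generate_spatial_truth

from conftest import make_matrix
from _oracles import morans_i_naive


def lattice(n_side=10, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side))
    c = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    return c + rng.uniform(-jitter, jitter, c.shape)


class TestSpatialWeights:
    def test_invariants_on_jittered_grid(self):
        W = build_spatial_weights(lattice(12, jitter=0.3), k_spatial=6)
        assert np.allclose(np.diag(W.W), 0.5)
        assert np.array_equal(W.W, W.W.T)
        np.testing.assert_allclose(W.W.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(W.W >= 0)

    def test_three_cell_chain_fallback_weights(self):
        """A path graph admits no doubly stochastic scaling; the max-degree
        fallback gives the middle cell two neighbors at 0.25 each."""
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        with pytest.warns(UserWarning, match="infeasible"):
            W = build_spatial_weights(coords, k_spatial=1)
        assert W.W[1, 0] == pytest.approx(0.25)
        assert W.W[1, 2] == pytest.approx(0.25)
        assert W.W[0, 2] == 0.0
        assert np.array_equal(W.W, W.W.T)

    def test_delaunay_option(self):
        W = build_spatial_weights(lattice(8, jitter=0.2), method="delaunay")
        assert np.array_equal(W.W, W.W.T)
        assert np.allclose(np.diag(W.W), 0.5)

    def test_k_spatial_too_large_errors(self):
        with pytest.raises(ValueError):
            build_spatial_weights(lattice(2), k_spatial=4)


class TestMoransI:
    def test_affine_invariance(self, rng):
        W = build_spatial_weights(lattice(8), k_spatial=4)
        x = rng.random(64)
        i1, _ = morans_i(x, W)
        i2, _ = morans_i(2.0 * x + 1.0, W)
        assert i1 == pytest.approx(i2)

    def test_two_block_pattern_is_strongly_autocorrelated(self):
        coords = lattice(10)
        W = build_spatial_weights(coords, k_spatial=4)
        x = (coords[:, 1] >= 5).astype(float)
        I, p = morans_i(x, W)
        assert I > 0.5 and p < 1e-3

    def test_matches_double_loop_oracle(self, rng):
        W = build_spatial_weights(lattice(7, jitter=0.2, seed=2), k_spatial=3)
        x = rng.random(49)
        I, _ = morans_i(x, W)
        assert I == pytest.approx(morans_i_naive(x, W.off_diagonal))

    def test_permutation_p_close_to_normal_p(self, rng):
        coords = lattice(9, jitter=0.1, seed=3)
        W = build_spatial_weights(coords, k_spatial=4)
        x = coords[:, 1] + rng.normal(0, 2.0, 81)
        _, p_norm = morans_i(x, W)
        _, p_perm = morans_i(x, W, p_method="permutation", n_perm=499, seed=0)
        assert abs(p_norm - p_perm) < 0.1

    def test_constant_input_errors(self):
        W = build_spatial_weights(lattice(5), k_spatial=3)
        with pytest.raises(ValueError):
            morans_i(np.ones(25), W)


class TestFilterSpatialGenes:
    def test_sparse_and_noise_genes_excluded_layered_retained(self, rng):
        coords = lattice(15, jitter=0.2, seed=1)
        n = coords.shape[0]
        W = build_spatial_weights(coords, k_spatial=6)
        layered = np.exp(-((coords[:, 1] - 7) ** 2) / 8.0)
        noise = rng.permutation(layered)
        rare = np.zeros(n)
        hot = np.argsort(coords[:, 0])[:int(0.04 * n)]
        rare[hot] = 5.0  # spatially coherent but expressed in 4% of cells
        m = make_matrix(np.column_stack([layered, noise, rare]),
                        normalized=True)
        kept = filter_spatial_genes(m, W, alpha=0.05, min_frac=0.05)
        assert "g0" in kept
        assert "g1" not in kept
        assert "g2" not in kept  # excluded by expression fraction alone


class TestSci:
    @pytest.fixture()
    def W(self):
        return build_spatial_weights(lattice(10, jitter=0.2, seed=4),
                                     k_spatial=5)

    def test_symmetry(self, W, rng):
        x, y = rng.random(100), rng.random(100)
        assert sci(x, y, W) == pytest.approx(sci(y, x, W))

    def test_translation_invariance(self, W, rng):
        x, y = rng.random(100), rng.random(100)
        assert sci(x, y + 7.0, W) == pytest.approx(sci(x, y, W))

    def test_self_loop_rewards_same_cell_agreement(self, W, rng):
        x = np.exp(-((lattice(10, jitter=0.2, seed=4)[:, 1] - 5) ** 2) / 4)
        x = x + rng.normal(0, 0.05, 100)
        assert sci(x, x, W) > sci(x, rng.permutation(x), W)

    def test_matrix_agrees_with_pairwise_calls(self, W, rng):
        X = rng.random((100, 4))
        S = sci_matrix(X, W)
        for i in range(4):
            for j in range(4):
                assert S[i, j] == pytest.approx(sci(X[:, i], X[:, j], W))

    def test_constant_input_errors(self, W):
        with pytest.raises(ValueError):
            sci(np.ones(100), np.arange(100.0), W)


class TestGeneNetwork:
    def test_retains_top_decile_of_offdiagonal(self, rng):
        S = rng.random((20, 20))
        S = (S + S.T) / 2
        G = gene_network(S, percentile=10)
        assert np.count_nonzero(np.triu(G, 1)) == pytest.approx(19, abs=1)
        assert np.allclose(G, G.T)
        assert np.all(np.diag(G) == 0)

    def test_degenerate_all_equal_keeps_every_edge(self):
        S = np.full((5, 5), 0.7)
        G = gene_network(S, percentile=10)
        assert np.count_nonzero(np.triu(G, 1)) == 10

    def test_nonpositive_values_never_become_edges(self):
        S = np.full((4, 4), -0.5)
        np.fill_diagonal(S, 1.0)
        assert gene_network(S, percentile=100).sum() == 0

    def test_asymmetric_input_rejected(self, rng):
        with pytest.raises(ValueError):
            gene_network(rng.random((4, 4)))


class TestClusterGenes:
    def test_two_disconnected_cliques(self, rng):
        G = np.zeros((8, 8))
        G[:4, :4] = 0.9
        G[4:, 4:] = 0.9
        np.fill_diagonal(G, 0.0)
        expr = make_matrix(rng.random((10, 8)), normalized=True)
        pats = cluster_genes(G, expr, [f"g{j}" for j in range(8)], seed=0)
        assert len(pats) == 2
        assert sorted(len(p.member_genes) for p in pats) == [4, 4]

    def test_profile_is_member_mean(self, rng):
        G = np.ones((3, 3)) - np.eye(3)
        expr = make_matrix(rng.random((6, 3)), normalized=True)
        pats = cluster_genes(G, expr, ["g0", "g1", "g2"], seed=0)
        assert len(pats) == 1
        np.testing.assert_allclose(pats[0].profile, expr.values.mean(axis=1))

    def test_same_seed_same_clustering(self, rng):
        G = np.abs(rng.random((30, 30)))
        G = (G + G.T) / 2
        np.fill_diagonal(G, 0)
        expr = make_matrix(rng.random((5, 30)), normalized=True)
        ids = [f"g{j}" for j in range(30)]
        a = cluster_genes(G, expr, ids, resolution=1.0, seed=5)
        b = cluster_genes(G, expr, ids, resolution=1.0, seed=5)
        assert [p.member_genes for p in a] == [p.member_genes for p in b]


class TestSingletonFilter:
    def _pats(self, sizes, rng):
        return [Pattern(i, [f"g{i}_{j}" for j in range(s)], rng.random(4))
                for i, s in enumerate(sizes)]

    def test_drops_singletons(self, rng):
        out = filter_singleton_patterns(self._pats([5, 3, 1], rng))
        assert [len(p.member_genes) for p in out] == [5, 3]

    def test_all_singletons_warns_to_empty(self, rng):
        with pytest.warns(UserWarning):
            assert filter_singleton_patterns(self._pats([1, 1], rng)) == []

    def test_flag_off_keeps_everything(self, rng):
        pats = self._pats([5, 1], rng)
        assert filter_singleton_patterns(pats, enabled=False) is pats


class TestLikelihoodPipeline:
    @pytest.fixture()
    def setup(self, rng):
        coords = lattice(12, jitter=0.2, seed=6)
        W = build_spatial_weights(coords, k_spatial=6)
        p1 = np.exp(-((coords[:, 1] - 3) ** 2) / 4)
        p2 = np.exp(-((coords[:, 0] - 8) ** 2) / 4)
        known = [Pattern(0, ["a"], p1), Pattern(1, ["b"], p2)]
        return coords, W, known, rng

    def test_gene_equal_to_profile_scores_its_pattern(self, setup):
        coords, W, known, rng = setup
        expr = make_matrix(np.column_stack([known[1].profile]),
                           normalized=True)
        scores = likelihood_scores(expr, known, W)
        assert scores[0] == pytest.approx(sci(known[1].profile,
                                              known[1].profile, W))

    def test_constant_shift_leaves_score_unchanged(self, setup):
        coords, W, known, rng = setup
        g = known[0].profile + rng.normal(0, 0.1, len(known[0].profile))
        a = likelihood_scores(make_matrix(g[:, None], normalized=True),
                              known, W)
        b = likelihood_scores(make_matrix(g[:, None] + 5.0, normalized=True),
                              known, W)
        assert a[0] == pytest.approx(b[0])

    def test_shuffled_gene_scores_low(self, setup):
        coords, W, known, rng = setup
        g = known[0].profile + rng.normal(0, 0.05, 144)
        shuf = rng.permutation(g)
        expr = make_matrix(np.column_stack([g, shuf]), normalized=True)
        scores = likelihood_scores(expr, known, W)
        assert scores[1] < scores[0] / 2

    def test_assignment_and_tie_break(self, setup):
        coords, W, known, rng = setup
        expr = make_matrix(np.column_stack([known[1].profile,
                                            known[0].profile]),
                           normalized=True)
        out = assign_to_known(["g0", "g1"], expr, known, W)
        assert out == {"g0": 1, "g1": 0}
        # identical patterns -> lowest id wins
        twins = [Pattern(0, ["a"], known[0].profile),
                 Pattern(1, ["b"], known[0].profile)]
        out = assign_to_known(["g1"], expr, twins, W)
        assert out == {"g1": 0}
        assert assign_to_known([], expr, known, W) == {}


class TestClassification:
    def test_valley_between_constructed_modes(self, rng):
        scores = np.concatenate([rng.normal(0.2, 0.04, 150),
                                 rng.normal(0.8, 0.04, 150)])
        cls = classify_by_likelihood(scores, [f"g{i}" for i in range(300)])
        assert 0.4 < cls.s_split < 0.6
        counts = collections.Counter(cls.groups.tolist())
        assert counts["known-associated"] == pytest.approx(150, abs=5)
        assert counts["novel-candidate"] == pytest.approx(150, abs=5)

    def test_band_rule(self):
        scores = np.concatenate([np.full(50, 0.2), np.full(50, 0.8),
                                 [0.51, 0.83]])
        cls = classify_by_likelihood(scores, [f"g{i}" for i in range(102)])
        s = cls.s_split
        assert cls.groups[-1] == "known-associated"  # 0.83 > s + 0.05
        if abs(0.51 - s) < 0.05:
            assert cls.groups[-2] == "weak"

    def test_unimodal_scores_error_for_fallback(self, rng):
        with pytest.raises(ValueError, match="peaks"):
            classify_by_likelihood(rng.normal(0.5, 0.01, 200),
                                   [f"g{i}" for i in range(200)])

    def test_multimodality_detector_contract(self, rng):
        with pytest.raises(ValueError):
            detect_multimodality(np.arange(5))
        d, p = detect_multimodality(
            np.concatenate([rng.normal(0.2, 0.04, 100),
                            rng.normal(0.8, 0.04, 100)]), seed=0)
        assert p < 0.05


class TestNovelDiscovery:
    def test_pruning_is_a_fixed_point(self, rng):
        net = (rng.random((40, 40)) > 0.5).astype(float)
        net = np.triu(net, 1) + np.triu(net, 1).T
        members = np.arange(40)
        once = _prune_low_degree(net, members, 10)
        twice = _prune_low_degree(net, once, 10)
        np.testing.assert_array_equal(once, twice)

    def test_too_few_candidates_warns_empty(self, rng):
        coords = lattice(8)
        W = build_spatial_weights(coords, k_spatial=4)
        expr = make_matrix(rng.random((64, 10)), normalized=True)
        with pytest.warns(UserWarning, match="fewer than 20"):
            assert discover_novel_patterns(expr, W) == []

    def test_all_background_candidates_yield_nothing(self, rng):
        coords = lattice(12, jitter=0.2, seed=8)
        W = build_spatial_weights(coords, k_spatial=6)
        vals = rng.random((144, 60))
        expr = make_matrix(vals, normalized=True)
        assert discover_novel_patterns(expr, W, seed=0) == []


class TestRepresentativeGenes:
    def test_singleton_pattern_returns_its_gene(self, rng):
        coords = lattice(8)
        W = build_spatial_weights(coords, k_spatial=4)
        expr = make_matrix(rng.random((64, 1)), normalized=True)
        p = Pattern(0, ["g0"], expr.values[:, 0])
        assert representative_genes(p, expr, W) == ["g0"]

    def test_profile_identical_gene_ranked_first_and_matches_oracle(self, rng):
        coords = lattice(8, jitter=0.1, seed=9)
        W = build_spatial_weights(coords, k_spatial=4)
        profile = np.exp(-((coords[:, 1] - 4) ** 2) / 3)
        vals = np.column_stack([
            profile + rng.normal(0, 0.3, 64),
            profile,
            rng.random(64),
        ])
        expr = make_matrix(vals, normalized=True)
        p = Pattern(0, ["g0", "g1", "g2"], profile)
        top = representative_genes(p, expr, W, top_n=3)
        assert top[0] == "g1"
        oracle = sorted(p.member_genes,
                        key=lambda g: -sci(expr.values[:, int(g[1:])],
                                           profile, W))
        assert top == oracle


class TestPlantedPipeline:
    def test_known_pattern_recovery_ari(self):
        spec = SimSpec(n_cells=400, n_genes_measured=48, n_genes_unmeasured=4,
                       n_patterns_known=4, n_patterns_novel=0,
                       genes_per_novel=0, known_unmeasured_frac=1.0,
                       noise_sd=0.25, seed=11)
        query, truth = generate_spatial_truth(spec)
        W = build_spatial_weights(query.coords, k_spatial=6)
        known = find_known_patterns(query.expr, W, seed=0)
        from sklearn.metrics import adjusted_rand_score
        found, planted = [], []
        for p in known:
            for g in p.member_genes:
                found.append(p.id)
                planted.append(str(truth.pattern_of_gene[g]))
        assert adjusted_rand_score(planted, found) >= 0.9

    def test_full_pipeline_recovers_planted_novel_program(self, rng):
        spec = SimSpec(n_cells=600, n_genes_measured=60,
                       n_genes_unmeasured=360, n_patterns_known=4,
                       n_patterns_novel=1, genes_per_novel=30,
                       known_unmeasured_frac=0.25, noise_sd=0.25, seed=2)
        query, truth = generate_spatial_truth(spec)
        noise = rng.normal(0, 0.25, (spec.n_cells,
                                     len(truth.unmeasured_genes)))
        pred = ExpressionMatrix(
            np.maximum(truth.true_expr.subset_genes(
                truth.unmeasured_genes).values + noise, 0),
            query.expr.cell_ids,
            np.array(truth.unmeasured_genes, dtype=object), normalized=True)
        res = run_pattern_discovery(query.expr, pred, query.coords, seed=0)
        assert res["dip"][1] < 0.05
        planted = {g for g, v in truth.pattern_of_gene.items()
                   if v == "novel0"}
        assert len(res["novel"]) >= 1
        best = max(len(set(p.member_genes) & planted)
                   / len(set(p.member_genes) | planted)
                   for p in res["novel"])
        assert best >= 0.8
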