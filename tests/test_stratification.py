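import numpy as np
import pandas as pd
import pytest
from scipy.stats import ranksums

from breakgene import stratification as strat
from breakgene.profiles_io import BinaryEventMatrix


def path_network():
    """3-node path a - b - c with unit weights."""
    edges = pd.DataFrame({"gene_a": ["a", "b"], "gene_b": ["b", "c"],
                          "weight": [1.0, 1.0]})
    return strat.GeneNetwork.from_edges(edges)


class TestMergeEvents:
    def test_gene_in_both_matrices_is_or_merged(self):
        bp = BinaryEventMatrix(pd.DataFrame([[1, 0]], index=["SMAD4"],
                                            columns=["A", "B"]))
        mut = BinaryEventMatrix(pd.DataFrame([[0, 1]], index=["SMAD4"],
                                             columns=["A", "B"]))
        merged, zero = strat.merge_events(bp, mut)
        assert merged.data.loc["SMAD4"].tolist() == [1, 1]
        assert zero == []

    def test_disjoint_gene_sets_concatenate(self):
        bp = BinaryEventMatrix(pd.DataFrame([[1, 0]], index=["g1"], columns=["A", "B"]))
        mut = BinaryEventMatrix(pd.DataFrame([[0, 1]], index=["g2"], columns=["A", "B"]))
        merged, _ = strat.merge_events(bp, mut)
        assert sorted(merged.rows) == ["g1", "g2"]

    def test_idempotent(self):
        m = BinaryEventMatrix(pd.DataFrame([[1, 0], [0, 0]], index=["g1", "g2"],
                                           columns=["A", "B"]))
        merged, zero = strat.merge_events(m, m)
        pd.testing.assert_frame_equal(merged.data, m.data.astype(np.int8),
                                      check_names=False)
        assert zero == ["B"]  # no event in any gene

    def test_disjoint_samples_rejected(self):
        a = BinaryEventMatrix(pd.DataFrame([[1]], index=["g"], columns=["A"]))
        b = BinaryEventMatrix(pd.DataFrame([[1]], index=["g"], columns=["B"]))
        with pytest.raises(ValueError, match="no samples"):
            strat.merge_events(a, b)


class TestPropagate:
    def test_small_alpha_recovers_input(self):
        net = path_network()
        events = BinaryEventMatrix(pd.DataFrame([[1, 0, 0]], index=["S1"],
                                                columns=["a", "b", "c"]).T)
        out = strat.propagate(events, net, alpha=1e-9, quantile_norm=False)
        assert np.allclose(out.to_numpy(), [[1, 0, 0]], atol=1e-6)

    def test_matches_closed_form_on_path(self):
        net = path_network()
        alpha = 0.6
        events = BinaryEventMatrix(pd.DataFrame([[1], [0], [0]],
                                                index=["a", "b", "c"], columns=["S1"]))
        out = strat.propagate(events, net, alpha=alpha, tol=1e-12,
                              quantile_norm=False)
        A = net.normalized_adjacency()
        closed = (1 - alpha) * np.linalg.solve(
            (np.eye(3) - alpha * A).T, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(out.to_numpy()[0], closed, atol=1e-9)

    def test_no_network_overlap_rejected(self):
        net = path_network()
        events = BinaryEventMatrix(pd.DataFrame([[1]], index=["zzz"], columns=["S1"]))
        with pytest.raises(ValueError, match="no event gene"):
            strat.propagate(events, net)

    def test_quantile_normalization_equalizes_samples(self):
        net = path_network()
        events = BinaryEventMatrix(pd.DataFrame(
            [[1, 1], [0, 1], [0, 1]], index=["a", "b", "c"], columns=["S1", "S2"]))
        out = strat.propagate(events, net, alpha=0.5)
        # after rank-mapping to the mean distribution every sample has the
        # same multiset of values
        assert np.allclose(np.sort(out.to_numpy()[0]), np.sort(out.to_numpy()[1]))


class TestNetNMF:
    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(0, 1, size=(20, 15))
        D = np.diag(np.full(15, 2.0))
        A = np.zeros((15, 15))
        for i in range(14):
            A[i, i + 1] = A[i + 1, i] = 1.0
        W, H, trace = strat.netnmf(V, D, A, k=3, lam=0.5, rng=rng)
        assert np.all(np.diff(trace) <= 1e-8)
        assert np.all(W >= 0) and np.all(H >= 0)

    def test_recovers_exact_rank_one_factorization(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.5, 1.5, size=(12, 1))
        h = rng.uniform(0.5, 1.5, size=(1, 9))
        V = w @ h
        W, H, trace = strat.netnmf(V, np.zeros((9, 9)), np.zeros((9, 9)),
                                   k=1, lam=0.0, max_iter=2000, tol=0.0, rng=rng)
        assert np.linalg.norm(V - W @ H) <= 1e-6

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            strat.netnmf(np.ones((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)), k=5)


def _block_smoothed(rng, n_per_block=15, k=3, n_genes=30):
    """Noisy block-structured sample x gene matrix."""
    V = rng.uniform(0, 0.05, size=(n_per_block * k, n_genes))
    per = n_genes // k
    for j in range(k):
        V[j * n_per_block:(j + 1) * n_per_block, j * per:(j + 1) * per] += 1.0
    samples = [f"s{i}" for i in range(V.shape[0])]
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(V, index=samples, columns=genes)


def _empty_network(genes):
    return strat.GeneNetwork(list(genes), np.zeros((len(genes), len(genes))))


class TestConsensus:
    def test_recovers_block_structure_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        sm = _block_smoothed(rng)
        net = _empty_network(sm.columns)
        cfg = strat.NBSConfig(k=3, n_iter=30, seed=11, max_iter=100)
        run, assign = strat.consensus_cluster(sm, net, cfg)
        truth = np.repeat([0, 1, 2], 15)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, assign.labels.to_numpy()) == 1.0
        # determinism under the same seed
        _, assign2 = strat.consensus_cluster(sm, net, cfg)
        assert assign.labels.equals(assign2.labels)

    def test_similarity_matrix_properties(self):
        rng = np.random.default_rng(6)
        sm = _block_smoothed(rng)
        cfg = strat.NBSConfig(k=3, n_iter=20, seed=3, max_iter=50)
        run, assign = strat.consensus_cluster(sm, _empty_network(sm.columns), cfg)
        S = assign.similarity.to_numpy()
        assert np.allclose(S, S.T)
        assert np.all((S >= 0) & (S <= 1))
        assert np.all(np.diag(S) == 1.0)  # every sample selected at least once

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            strat.NBSConfig(alpha=1.5)
        with pytest.raises(ValueError):
            strat.NBSConfig(k=1)
        with pytest.raises(ValueError):
            strat.NBSConfig(sample_frac=0.0)


class TestGeneScores:
    def _run_from_factors(self, samples, genes, factors):
        n, p = len(samples), len(genes)
        accum = np.zeros((n, p))
        counts = np.zeros(n)
        for s_idx, g_idx, W, H in factors:
            accum[np.ix_(s_idx, g_idx)] += W @ H
            counts[s_idx] += 1
        return strat.NBSRun(samples, genes, accum, counts,
                            np.eye(n), strat.NBSConfig(), list(factors))

    def test_single_iteration_score_is_reconstruction_row(self):
        W = np.array([[1.0, 0.0], [0.5, 0.5]])
        H = np.array([[1.0, 2.0], [3.0, 4.0]])
        run = self._run_from_factors(["s1", "s2"], ["g1", "g2"],
                                     [(np.array([0, 1]), np.array([0, 1]), W, H)])
        scores = strat.extract_gene_scores(run)
        assert np.allclose(scores.scores.loc["s1"].to_numpy(), (W @ H)[0])

    def test_never_selected_sample_zero_and_flagged(self):
        W = np.array([[1.0], [2.0]])
        H = np.array([[1.0, 1.0]])
        run = self._run_from_factors(["s1", "s2", "s3"], ["g1", "g2"],
                                     [(np.array([0, 1]), np.array([0, 1]), W, H)])
        scores = strat.extract_gene_scores(run)
        assert scores.never_selected == ["s3"]
        assert (scores.scores.loc["s3"] == 0).all()

    def test_three_mock_iterations_average_and_paths_agree(self):
        rng = np.random.default_rng(2)
        factors = []
        for _ in range(3):
            s_idx = np.sort(rng.choice(3, size=2, replace=False))
            W = rng.uniform(size=(2, 2))
            H = rng.uniform(size=(2, 2))
            factors.append((s_idx, np.array([0, 1]), W, H))
        run = self._run_from_factors(["s1", "s2", "s3"], ["g1", "g2"], factors)
        # hand computation for sample 0
        expect = np.zeros(2)
        c = 0
        for s_idx, g_idx, W, H in factors:
            if 0 in s_idx:
                expect += (W @ H)[list(s_idx).index(0)]
                c += 1
        scores_stored = strat.extract_gene_scores(run)
        assert np.allclose(scores_stored.scores.loc["s1"], expect / c)
        # accumulator path (factors discarded) gives identical R_s
        run.factors = []
        scores_accum = strat.extract_gene_scores(run)
        pd.testing.assert_frame_equal(scores_stored.scores, scores_accum.scores)


class TestAssociation:
    def _scores(self, values, samples, genes):
        return strat.GeneScoreMatrix(
            scores=pd.DataFrame(values, index=samples, columns=genes),
            selection_counts=pd.Series(1, index=samples), never_selected=[])

    def test_identical_distributions_give_large_p(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(40)]
        scores = self._scores(rng.normal(size=(40, 3)), samples, ["g1", "g2", "g3"])
        labels = pd.Series([1] * 20 + [2] * 20, index=samples)
        assign = strat.SubtypeAssignment(labels, pd.DataFrame(np.eye(40),
                                                              index=samples,
                                                              columns=samples))
        out = strat.subtype_gene_association(scores, assign)
        assert out.shape == (3, 2)
        assert (out > 0.05).all().all()

    def test_shifted_subtype_detected_and_matches_ranksum(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(60)]
        vals = rng.normal(size=(60, 2))
        vals[:20, 0] += 5.0  # gene g1 elevated in subtype 1 (n=20 vs 40)
        scores = self._scores(vals, samples, ["g1", "g2"])
        labels = pd.Series([1] * 20 + [2] * 40, index=samples)
        assign = strat.SubtypeAssignment(labels, pd.DataFrame(np.eye(60),
                                                              index=samples,
                                                              columns=samples))
        out = strat.subtype_gene_association(scores, assign)
        assert out.loc["g1", 1] < 1e-6
        # independent rank-sum check (normal approximation)
        ref = ranksums(vals[:20, 0], vals[20:, 0]).pvalue
        assert np.isclose(np.log(out.loc["g1", 1]), np.log(ref), atol=1.0)

    def test_tiny_subtype_yields_nan(self):
        samples = [f"s{i}" for i in range(5)]
        scores = self._scores(np.ones((5, 1)), samples, ["g1"])
        labels = pd.Series([1, 2, 2, 2, 2], index=samples)
        assign = strat.SubtypeAssignment(labels, pd.DataFrame(np.eye(5),
                                                              index=samples,
                                                              columns=samples))
        out = strat.subtype_gene_association(scores, assign)
        assert np.isnan(out.loc["g1", 1])
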