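import numpy as np
import pytest
import scipy.stats

from cemb.connectome_io import Connectome
from cemb.embedding import (
    EmbedConfig,
    EmbeddingEnsemble,
    WalkConfig,
    cosine_similarity,
    embed_ensemble,
    generate_walks,
    spectral_embed,
    train_cbow,
    transition_model,
)


def brute_force_second_order(w, p, q):
    """Independent oracle: alpha-weighted normalization over all (t, v, x)."""
    n = w.shape[0]
    table = {}
    for t in range(n):
        for v in range(n):
            if w[t, v] <= 0:
                continue
            un = {}
            for x in range(n):
                if w[v, x] <= 0:
                    continue
                if x == t:
                    alpha = 1.0 / p
                elif w[t, x] > 0:
                    alpha = 1.0
                else:
                    alpha = 1.0 / q
                un[x] = w[v, x] * alpha
            z = sum(un.values())
            table[(t, v)] = {x: val / z for x, val in un.items()}
    return table


class TestTransitionModel:
    def test_p_q_one_is_first_order(self, fix5):
        """With p = q = 1 every step is plain weight-proportional."""
        tm = transition_model(fix5, 1.0, 1.0)
        w = fix5.weights
        for (t, v), probs in tm.second_order.items():
            nbr = tm.neighbors[v]
            expected = w[v, nbr] / w[v, nbr].sum()
            assert np.allclose(probs, expected)

    def test_path_graph_return_probability(self):
        # path a-b-c: from b (arrived from a), prob(c) = p / (p + q)
        w = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
        c = Connectome(["a", "b", "c"], ["left", "midline", "right"],
                       np.array([-1, -1, -1]), w)
        for p, q in [(2.0, 2.0), (0.1, 1.6), (5.0, 0.3)]:
            tm = transition_model(c, p, q)
            nbr, probs = tm.step_probs(0, 1)
            prob_c = probs[list(nbr).index(2)]
            assert prob_c == pytest.approx(p / (p + q))

    def test_matches_brute_force_oracle(self, fix5):
        p, q = 0.1, 1.6
        tm = transition_model(fix5, p, q)
        oracle = brute_force_second_order(fix5.weights, p, q)
        assert set(tm.second_order) == set(oracle)
        for (t, v), probs in tm.second_order.items():
            for x, pr in zip(tm.neighbors[v], probs):
                assert pr == pytest.approx(oracle[(t, v)][x])


class TestGenerateWalks:
    def test_forced_alternation_on_single_edge(self):
        w = np.array([[0, 1.0], [1.0, 0]])
        c = Connectome(["a", "b"], ["left", "right"], np.array([1, 0]), w)
        corpus = generate_walks(c, WalkConfig(p=0.5, q=2.0, walk_length=4,
                                              num_walks=6, seed=0))
        for seq in corpus.sequences:
            assert list(seq[::2]) == [seq[0]] * 2
            assert list(seq[1::2]) == [1 - seq[0]] * 2

    def test_round_robin_start_cycling(self, fix5):
        corpus = generate_walks(fix5, WalkConfig(num_walks=5 * 10, seed=1))
        starts = np.array([s[0] for s in corpus.sequences])
        assert np.array_equal(np.bincount(starts, minlength=5), [10] * 5)

    def test_walks_traverse_positive_edges_only(self, fix5):
        corpus = generate_walks(fix5, WalkConfig(num_walks=200, seed=2))
        for seq in corpus.sequences:
            for a, b in zip(seq[:-1], seq[1:]):
                assert fix5.weights[a, b] > 0

    def test_reproducible_from_seed(self, fix5):
        wc = WalkConfig(num_walks=50, seed=7)
        c1 = generate_walks(fix5, wc)
        c2 = generate_walks(fix5, wc)
        assert all(np.array_equal(a, b) for a, b in zip(c1.sequences, c2.sequences))

    def test_no_edges_rejected(self):
        c = Connectome(["a", "b"], ["left", "right"], np.array([-1, -1]),
                       np.zeros((2, 2)))
        with pytest.raises(ValueError, match="no edges"):
            generate_walks(c, WalkConfig())

    def test_empirical_transitions_match_exact_table(self, fix5):
        """Sampling check: second-order step frequencies converge to the
        alpha-normalized distributions (>= 1e5 transitions, GOF alpha=0.01)."""
        p, q = 0.1, 1.6
        tm = transition_model(fix5, p, q)
        corpus = generate_walks(
            fix5, WalkConfig(p=p, q=q, walk_length=20, num_walks=6000, seed=3)
        )
        counts: dict[tuple[int, int], np.ndarray] = {
            key: np.zeros(len(tm.neighbors[key[1]])) for key in tm.second_order
        }
        n_trans = 0
        for seq in corpus.sequences:
            for s in range(2, len(seq)):
                t, v, x = int(seq[s - 2]), int(seq[s - 1]), int(seq[s])
                pos = list(tm.neighbors[v]).index(x)
                counts[(t, v)][pos] += 1
                n_trans += 1
        assert n_trans >= 1e5
        stat, dof = 0.0, 0
        for key, obs in counts.items():
            exp = tm.second_order[key] * obs.sum()
            sel = exp > 0
            stat += float(((obs[sel] - exp[sel]) ** 2 / exp[sel]).sum())
            dof += int(sel.sum()) - 1
        assert scipy.stats.chi2.sf(stat, dof) > 0.01


class TestTrainCbow:
    def test_nodes_with_identical_contexts_align(self):
        # star leaves a and b only ever see the hub as context, so their
        # vectors converge to near-identical directions
        w = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        star = Connectome(["a", "b", "hub"], ["left", "right", "midline"],
                          np.array([1, 0, -1]), w)
        corpus = generate_walks(star, WalkConfig(p=1, q=1, walk_length=10,
                                                 num_walks=300, seed=0))
        run = train_cbow(corpus, EmbedConfig(dimensions=8, window=1,
                                             epochs=10), seed=1)
        assert cosine_similarity(run.vectors[0], run.vectors[1]) > 0.9

    def test_cliques_separate(self):
        # two disconnected cliques: within-clique cosine > between-clique
        w = np.zeros((8, 8))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        c = Connectome([f"n{i}" for i in range(8)],
                       ["left"] * 4 + ["right"] * 4,
                       np.full(8, -1), w)
        corpus = generate_walks(c, WalkConfig(p=1, q=1, walk_length=10,
                                              num_walks=400, seed=5))
        run = train_cbow(corpus, EmbedConfig(dimensions=8, window=3), seed=2)
        within, between = [], []
        for i in range(8):
            for j in range(i + 1, 8):
                sim = cosine_similarity(run.vectors[i], run.vectors[j])
                (within if (i < 4) == (j < 4) else between).append(sim)
        assert np.mean(within) > np.mean(between)

    def test_deterministic_given_seed(self, fix5):
        corpus = generate_walks(fix5, WalkConfig(num_walks=50, seed=3))
        r1 = train_cbow(corpus, EmbedConfig(dimensions=6), seed=9)
        r2 = train_cbow(corpus, EmbedConfig(dimensions=6), seed=9)
        assert np.array_equal(r1.vectors, r2.vectors)

    def test_empty_corpus_rejected(self):
        from cemb.embedding import WalkCorpus

        with pytest.raises(ValueError):
            train_cbow(WalkCorpus([], 5), EmbedConfig())


class TestEnsemble:
    def test_same_master_seed_identical(self, fix5):
        e1 = embed_ensemble(fix5, WalkConfig(num_walks=40), EmbedConfig(dimensions=6),
                            n_runs=2, master_seed=4)
        e2 = embed_ensemble(fix5, WalkConfig(num_walks=40), EmbedConfig(dimensions=6),
                            n_runs=2, master_seed=4)
        for a, b in zip(e1.runs, e2.runs):
            assert np.array_equal(a.vectors, b.vectors)

    def test_single_run_ensemble(self, fix5):
        ens = embed_ensemble(fix5, WalkConfig(num_walks=40),
                             EmbedConfig(dimensions=6), n_runs=1, master_seed=0)
        assert len(ens) == 1

    def test_runs_differ_but_cosine_structure_stable(self, synth_ens):
        """Distinct seeds give distinct vectors, yet the pairwise cosine
        matrices of different runs stay strongly rank-correlated."""
        r0, r1 = synth_ens[0], synth_ens[1]
        assert not np.allclose(r0.vectors, r1.vectors)

        def cosmat(run):
            v = run.vectors / np.linalg.norm(run.vectors, axis=1, keepdims=True)
            m = v @ v.T
            return m[np.triu_indices_from(m, k=1)]

        rho, _ = scipy.stats.spearmanr(cosmat(r0), cosmat(r1))
        assert rho > 0.5


class TestSpectralEmbed:
    def test_four_cycle_closed_form(self):
        """C4 normalized Laplacian has eigenvalues {0, 1, 1, 2}; the
        embedding columns must be eigenvectors of the hand-built L."""
        w = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], float
        )
        c = Connectome(["a", "b", "c", "d"], ["left"] * 2 + ["right"] * 2,
                       np.full(4, -1), w)
        lap = np.eye(4) - w / 2.0  # degree 2 everywhere
        vals = np.sort(np.linalg.eigvalsh(lap))
        assert np.allclose(vals, [0, 1, 1, 2])
        run = spectral_embed(c, dimensions=2)
        for k, lam in enumerate([1.0, 1.0]):
            col = run.vectors[:, k]
            assert np.allclose(lap @ col, lam * col, atol=1e-10)

    def test_columns_orthonormal(self, synth_c):
        run = spectral_embed(synth_c, dimensions=30)
        active = np.linalg.norm(run.vectors, axis=1) > 0
        g = run.vectors[active].T @ run.vectors[active]
        assert np.allclose(g, np.eye(30), atol=1e-8)

    def test_relabeling_invariance_up_to_sign(self, fix5):
        run = spectral_embed(fix5, dimensions=3)
        perm = np.array([2, 0, 4, 1, 3])
        c2 = Connectome(
            [fix5.labels[i] for i in perm],
            [fix5.hemisphere[i] for i in perm],
            np.full(5, -1),
            fix5.weights[np.ix_(perm, perm)],
        )
        run2 = spectral_embed(c2, dimensions=3)
        back = run2.vectors[np.argsort(perm)]
        for k in range(3):
            assert np.allclose(back[:, k], run.vectors[:, k], atol=1e-8) or \
                np.allclose(back[:, k], -run.vectors[:, k], atol=1e-8)

    def test_isolated_node_zero_vector(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        c = Connectome(list("abcde"), ["left"] * 5, np.full(5, -1), w)
        run = spectral_embed(c, dimensions=2)
        assert np.all(run.vectors[4] == 0)

    def test_too_many_dimensions_rejected(self, fix5):
        with pytest.raises(ValueError):
            spectral_embed(fix5, dimensions=5)


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1.0, 2.0, 2.0), (1.0, 2.0, 2.0), 1.0),
            ((1.0, 0.0), (0.0, 1.0), 0.0),
            ((1.0, 2.0, 2.0), (2.0, 1.0, 2.0), 8.0 / 9.0),
            ((1.0, 1.0), (-1.0, -1.0), -1.0),
        ],
    )
    def test_known_values(self, u, v, expected):
        assert cosine_similarity(np.array(u), np.array(v)) == pytest.approx(expected)

    def test_zero_vector_is_nan(self):
        assert np.isnan(cosine_similarity(np.zeros(3), np.ones(3)))
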