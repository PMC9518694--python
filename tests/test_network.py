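"""Lexical network construction: co-occurrence, GTOM, modules, layers, thresholds."""

import math

import networkx as nx
import numpy as np
import pytest

import fluencylab as fl
from fluencylab.network import LexicalNetwork, WeightedLayer


def binom_tail_oracle(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestCooccurrence:
    def test_consistently_adjacent_pair_is_linked(self):
        rng = np.random.default_rng(0)
        fillers = [f"w{i}" for i in range(8)]
        corpus = []
        for _ in range(50):
            rest = list(rng.permutation(fillers))
            corpus.append(["a", "b"] + rest)
        net = fl.cooccurrence_edges(corpus, window=2, alpha=0.001)
        assert net.graph.has_edge("a", "b")
        # cross-check the tail probability with a direct-summation oracle
        n_slots = sum(max(0, len(l) - d) for l in corpus for d in (1, 2))
        total = sum(len(l) for l in corpus)
        p = 2 * (50 / total) * (50 / total)
        assert binom_tail_oracle(50, n_slots, p) < 0.001

    def test_single_occurrences_cannot_reach_significance(self):
        corpus = [["a", "b", "c", "d", "e"]]
        net = fl.cooccurrence_edges(corpus, window=2, alpha=0.001)
        assert net.n_edges == 0
        # best attainable tail probability with one co-occurrence is >> alpha
        assert binom_tail_oracle(1, 7, 2 * (1 / 5) * (1 / 5)) > 0.001

    def test_degenerate_alpha_links_every_cooccurring_pair(self):
        corpus = [["a", "b", "c"]]
        net = fl.cooccurrence_edges(corpus, window=2, alpha=1.0)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset({"a", "b"}), frozenset({"b", "c"}), frozenset({"a", "c"})
        }

    def test_permutation_null_agrees_on_strong_signal(self):
        rng = np.random.default_rng(1)
        corpus = [["a", "b"] + list(rng.permutation([f"w{i}" for i in range(6)]))
                  for _ in range(40)]
        net = fl.cooccurrence_edges(corpus, window=2, alpha=0.01,
                                    null="permutation", n_permutations=300, seed=5)
        assert net.graph.has_edge("a", "b")


def gtom_oracle(graph, order):
    """Brute-force set arithmetic on the radius-``order`` neighbourhoods."""
    words = sorted(graph.nodes)
    lengths = dict(nx.all_pairs_shortest_path_length(graph, cutoff=order))
    nbhd = {w: {v for v, d in lengths.get(w, {}).items() if 0 < d <= order} for w in words}
    n = len(words)
    out = np.zeros((n, n))
    for i, a in enumerate(words):
        for j, b in enumerate(words):
            if i == j:
                continue
            aij = 1.0 if b in nbhd[a] else 0.0
            num = len(nbhd[a] & nbhd[b]) + aij
            den = min(len(nbhd[a]), len(nbhd[b])) + 1 - aij
            out[i, j] = 1.0 - num / den
    return words, out


class TestGTOM:
    def test_shared_neighbourhood_gives_zero_dissimilarity(self):
        g = nx.Graph([("a", "b"), ("a", "c"), ("b", "c")])
        words, d = fl.gtom_dissimilarity(LexicalNetwork(g), gtom_order=1)
        assert d[words.index("a"), words.index("b")] == pytest.approx(0.0)

    def test_disjoint_components_get_dissimilarity_one(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        words, d = fl.gtom_dissimilarity(LexicalNetwork(g), gtom_order=1)
        assert d[words.index("a"), words.index("c")] == pytest.approx(1.0)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, order):
        rng = np.random.default_rng(13)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"w{i}" for i in g.nodes})
            words, d = fl.gtom_dissimilarity(LexicalNetwork(g), gtom_order=order)
            owords, od = gtom_oracle(g, order)
            assert words == owords
            np.testing.assert_allclose(d, od, atol=1e-12)
            assert np.all((d >= 0) & (d <= 1))
            np.testing.assert_allclose(d, d.T, atol=0)
            assert np.all(np.diag(d) == 0)


class TestModules:
    def test_two_zero_dissimilarity_blocks_recovered(self):
        words = ["a", "b", "c", "x", "y", "z"]
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        labels = fl.module_detection(words, d, n_modules=2)
        assert len({labels[w] for w in "abc"}) == 1
        assert labels["a"] != labels["x"]

    def test_automatic_cut_finds_planted_blocks(self):
        words = [f"w{i}" for i in range(9)]
        rng = np.random.default_rng(2)
        truth = np.repeat([0, 1, 2], 3)
        d = np.where(truth[:, None] == truth[None, :], 0.05, 0.9)
        d = d + rng.normal(0, 0.01, d.shape)
        d = np.clip((d + d.T) / 2, 0, 1)
        np.fill_diagonal(d, 0.0)
        labels = fl.module_detection(words, d)
        assert len(set(labels.values())) == 3

    def test_planted_noisy_blocks_mostly_recovered(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(100):
            truth = np.repeat([0, 1, 2], 5)
            d = np.where(truth[:, None] == truth[None, :], 0.1, 0.8)
            d = d + rng.normal(0, 0.05, d.shape)
            d = np.clip((d + d.T) / 2, 0, 1)
            np.fill_diagonal(d, 0.0)
            words = [f"w{i}" for i in range(15)]
            labels = fl.module_detection(words, d, n_modules=3)
            got = np.array([labels[w] for w in words])
            # exact recovery up to relabeling
            mapping = {}
            ok = True
            for t, g in zip(truth, got):
                if mapping.setdefault(t, g) != g:
                    ok = False
            hits += ok and len(set(mapping.values())) == 3
        assert hits >= 95

    def test_completion_makes_modules_cliques_without_removing_edges(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        g.add_nodes_from(["c", "z"])
        net = LexicalNetwork(g)
        labels = {"a": 1, "b": 1, "c": 1, "x": 2, "y": 2, "z": 2}
        done = fl.complete_modules(net, labels)
        for module in (["a", "b", "c"], ["x", "y", "z"]):
            sub = done.graph.subgraph(module)
            assert sub.number_of_edges() == 3
        assert done.graph.has_edge("a", "b")

    def test_too_many_modules_rejected(self):
        with pytest.raises(ValueError):
            fl.module_detection(["a", "b"], np.zeros((2, 2)), n_modules=3)


class TestAttachment:
    def _modular_net(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        return LexicalNetwork(g, modules={"a": 1, "b": 1, "x": 2, "y": 2})

    def test_identical_embedding_joins_that_module(self):
        net = self._modular_net()
        emb = {w: v for w, v in zip("abxy", np.eye(4))}
        emb["new"] = emb["x"].copy()
        out = fl.attach_remaining_words(net, ["new"], emb)
        assert out.modules["new"] == 2
        assert out.graph.has_edge("new", "x") and out.graph.has_edge("new", "y")
        assert out.graph.has_edge("a", "b")  # untouched

    def test_orthogonal_embedding_breaks_ties_lexicographically(self):
        net = self._modular_net()
        emb = {"a": np.array([1.0, 0]), "b": np.array([1.0, 0]),
               "x": np.array([0, 1.0]), "y": np.array([0, 1.0]),
               "new": np.array([1.0, 1.0])}
        out = fl.attach_remaining_words(net, ["new"], emb)
        assert out.modules["new"] == 1  # tie: "a" is lexicographically first

    def test_planted_centroids_fully_recovered(self, synthetic_fixtures):
        cfg, _, _, emb, planted = synthetic_fixtures
        words = sorted(planted.modules)
        keep = [w for i, w in enumerate(words) if i % 3 != 0]
        held_out = [w for w in words if w not in keep]
        sub = LexicalNetwork(planted.graph.subgraph(keep).copy(),
                             {w: planted.modules[w] for w in keep})
        out = fl.attach_remaining_words(sub, held_out, emb)
        assert all(out.modules[w] == planted.modules[w] for w in held_out)


@pytest.fixture(scope="module")
def layers(cmu_prons):
    rng = np.random.default_rng(0)
    vocab = ["fit", "fat", "fate", "freight", "fox", "fun"]
    emb = {w: rng.standard_normal(8) for w in vocab}
    emb["fit"] = emb["fat"] + 0.01 * rng.standard_normal(8)
    return fl.build_letterf_layers(vocab, emb, cmu_prons)


class TestLetterFLayers:
    def test_self_similarity_is_maximal(self, cmu_prons):
        i = 0
        layer = fl.build_letterf_layers(["fit", "fox"], {"fit": np.ones(3), "fox": np.ones(3) * 2},
                                        cmu_prons)
        assert layer["orthographic"].weights[i, i] == 0.0  # zero edit distance
        sem = layer["semantic"].weights
        assert sem[0, 1] == pytest.approx(1.0)  # parallel vectors

    def test_orthographic_similarity_is_negative_edit_distance(self, layers):
        orth = layers["orthographic"]
        i, j = orth.words.index("fat"), orth.words.index("fit")
        assert orth.weights[i, j] == -1.0

    def test_phonological_scores_respect_feature_similarity(self):
        ctx = ("F", "AA")
        g_k = fl.needleman_wunsch_score(ctx + ("G",), ctx + ("K",))
        g_sh = fl.needleman_wunsch_score(ctx + ("G",), ctx + ("SH",))
        assert g_k > g_sh

    def test_zweights_standardized_over_unique_pairs(self, layers):
        for layer in layers.values():
            n = len(layer.words)
            iu = np.triu_indices(n, k=1)
            z = layer.zweights[iu]
            assert abs(z.mean()) < 1e-6
            assert abs(z.std() - 1.0) < 1e-6

    def test_missing_resource_word_gets_floor_zweight(self, cmu_prons):
        emb = {"fit": np.array([1.0, 0.0]), "fat": np.array([0.9, 0.1]),
               "fox": np.array([0.0, 1.0])}
        layers = fl.build_letterf_layers(["fit", "fat", "fox", "fzz"], emb, cmu_prons)
        sem = layers["semantic"]
        i, j = sem.words.index("fzz"), sem.words.index("fit")
        iu = np.triu_indices(len(sem.words), k=1)
        assert sem.zweights[i, j] == np.min(sem.zweights[iu])


class TestGridSearchAndUnion:
    def _layers_from_z(self, words, zs):
        """Layers whose pairwise z-weights are forced to the given matrices."""
        out = {}
        for name, z in zs.items():
            layer = WeightedLayer.__new__(WeightedLayer)
            layer.name, layer.words = name, words
            layer.weights = z
            layer.zweights = z
            layer.defined = np.isfinite(z)
            out[name] = layer
        return out

    def _random_layers(self, rng, words):
        n = len(words)
        zs = {}
        for name in ("semantic", "phonological", "orthographic"):
            m = rng.standard_normal((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, -10.0)
            zs[name] = m
        return self._layers_from_z(words, zs)

    def test_perfectly_recoverable_threshold(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        words = [f"f{i}" for i in range(12)]
        layers = self._random_layers(rng, words)
        # labels exactly equal "semantic z > 1.0"; other layers forced below range
        layers["phonological"].zweights[:] = -10.0
        layers["orthographic"].zweights[:] = -10.0
        pairs = [(words[i], words[j]) for i in range(12) for j in range(i + 1, 12)]
        sem = layers["semantic"]
        rows = [{"word1": a, "word2": b, "rater": "r1",
                 "related": int(sem.zweights[words.index(a), words.index(b)] > 1.0)}
                for a, b in pairs]
        triple = fl.threshold_grid_search(layers, pd.DataFrame(rows), step=0.05, zrange=(-1, 4))
        assert triple.achieved_kappa == pytest.approx(1.0)
        net = fl.finalize_letterf_network(layers, triple)
        predicted = {frozenset(e) for e in net.graph.edges}
        truth = {frozenset((a, b)) for a, b in pairs
                 if sem.zweights[words.index(a), words.index(b)] > 1.0}
        assert predicted == truth

    def test_identical_raters_mean_equals_individual(self):
        import pandas as pd
        rng = np.random.default_rng(9)
        words = [f"f{i}" for i in range(8)]
        layers = self._random_layers(rng, words)
        pairs = [(words[i], words[j]) for i in range(8) for j in range(i + 1, 8)]
        labels = rng.integers(0, 2, size=len(pairs))
        rows = [{"word1": a, "word2": b, "rater": r, "related": int(l)}
                for r in ("r1", "r2") for (a, b), l in zip(pairs, labels)]
        triple = fl.threshold_grid_search(layers, pd.DataFrame(rows), step=0.25, zrange=(-1, 2))
        assert triple.per_rater_kappa[0] == pytest.approx(triple.per_rater_kappa[1])
        assert triple.achieved_kappa == pytest.approx(triple.per_rater_kappa[0])

    def test_random_labels_achieve_near_zero_kappa(self):
        import pandas as pd
        rng = np.random.default_rng(10)
        words = [f"f{i}" for i in range(21)]
        pairs = [(words[i], words[j]) for i in range(21) for j in range(i + 1, 21)][:200]
        kappas = []
        for rep in range(30):
            layers = self._random_layers(rng, words)
            rows = [{"word1": a, "word2": b, "rater": "r1",
                     "related": int(rng.random() < 0.5)} for a, b in pairs]
            triple = fl.threshold_grid_search(layers, pd.DataFrame(rows),
                                              step=0.5, zrange=(-1, 2))
            kappas.append(triple.achieved_kappa)
        # optimized over a coarse grid, so a small positive bias is expected
        assert np.median(kappas) < 0.25

    def test_extreme_thresholds(self):
        rng = np.random.default_rng(3)
        words = [f"f{i}" for i in range(6)]
        layers = self._random_layers(rng, words)
        empty = fl.finalize_letterf_network(
            layers, fl.ThresholdTriple(99, 99, 99, achieved_kappa=0.0))
        assert empty.n_edges == 0
        full = fl.finalize_letterf_network(
            layers, fl.ThresholdTriple(-99, -99, -99, achieved_kappa=0.0))
        assert full.n_edges == 15

    def test_union_edge_count_matches_set_oracle(self):
        rng = np.random.default_rng(4)
        words = [f"f{i}" for i in range(6)]
        layers = self._random_layers(rng, words)
        thr = fl.ThresholdTriple(0.3, 0.1, 0.5, achieved_kappa=0.0)
        net = fl.finalize_letterf_network(layers, thr)
        expected = set()
        for name, t in [("semantic", 0.3), ("phonological", 0.1), ("orthographic", 0.5)]:
            z = layers[name].zweights
            for i in range(6):
                for j in range(i + 1, 6):
                    if z[i, j] > t:
                        expected.add(frozenset((words[i], words[j])))
        assert {frozenset(e) for e in net.graph.edges} == expected


class TestNetworkStats:
    def test_triangle_graph(self):
        net = LexicalNetwork(nx.complete_graph(["a", "b", "c"]))
        s = fl.network_stats(net)
        assert s["mean_degree"] == pytest.approx(2.0)
        assert s["density_percent"] == pytest.approx(100.0)
        assert s["mean_clustering"] == pytest.approx(1.0)
        assert s["mean_path_length"] == pytest.approx(1.0)

    def test_path_graph(self):
        net = LexicalNetwork(nx.path_graph(["a", "b", "c"]))
        s = fl.network_stats(net)
        assert s["mean_clustering"] == pytest.approx(0.0)
        assert s["mean_path_length"] == pytest.approx(4.0 / 3.0)

    def test_self_consistency_mean_degree(self, synthetic_fixtures):
        *_, planted = synthetic_fixtures
        s = fl.network_stats(planted)
        assert s["mean_degree"] * s["vertices"] == pytest.approx(2 * s["edges"])


def test_animal_network_pipeline_recovers_planted_modules(synthetic_fixtures):
    """End-to-end: co-occurring module-mates reassemble into their modules."""
    cfg, _, _, emb, planted = synthetic_fixtures
    rng = np.random.default_rng(17)
    by_module = {}
    for w, m in planted.modules.items():
        by_module.setdefault(m, []).append(w)
    corpus = []
    for _ in range(120):
        mods = rng.permutation(sorted(by_module))
        lst = []
        for m in mods[:3]:
            members = list(rng.permutation(by_module[m]))
            lst.extend(members[:4])
        corpus.append(lst)
    net = fl.build_animal_network(corpus, emb, alpha=0.001,
                                  n_modules=len(by_module))
    assert net.modules is not None
    # words from one planted module should overwhelmingly share a derived module
    agree = 0
    total = 0
    for members in by_module.values():
        labels = [net.modules[w] for w in members if w in net.modules]
        agree += max(labels.count(l) for l in set(labels))
        total += len(labels)
    assert agree / total > 0.8
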