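import itertools

import networkx as nx
import numpy as np
import pytest

from herbminer.corpus import Prescription, PrescriptionCorpus
from herbminer.errors import (EmptyInputError, GraphStructureError,
                              InsufficientDataError)
from herbminer.gcn import (ClusterAssignment, EmbeddingMatrix, GcnHyperparams,
                           build_cooccurrence_graph, cluster_embeddings,
                           gcn_embed, score_clusters, weighted_degrees)

from conftest import make_corpus


class TestCooccurrenceGraph:
    def test_hand_enumerated_weights_and_degrees(self, tiny_corpus):
        g = build_cooccurrence_graph(tiny_corpus)
        assert {frozenset(e): d["weight"] for *e, d in g.edges(data=True)} == {
            frozenset("AB"): 2, frozenset("AC"): 1, frozenset("BC"): 2}
        assert weighted_degrees(g) == {"A": 3, "B": 4, "C": 3}

    def test_single_herb_prescriptions_give_edgeless_graph(self):
        corpus = make_corpus({"P1": {"A"}, "P2": {"B"}})
        g = build_cooccurrence_graph(corpus)
        assert set(g.nodes) == {"A", "B"} and g.number_of_edges() == 0

    def test_isolated_herbs_retained_as_nodes(self):
        corpus = make_corpus({"P1": {"A", "B"}, "P2": {"Z"}})
        g = build_cooccurrence_graph(corpus)
        assert "Z" in g.nodes and g.degree("Z") == 0

    def test_weights_match_direct_prescription_scan(self, reference_synthetic):
        corpus, _ = reference_synthetic
        anti = corpus.subset("anti_recurrence")
        g = build_cooccurrence_graph(anti)
        rng = np.random.default_rng(0)
        herbs = rng.choice(anti.vocabulary, size=12, replace=False)
        for a, b in itertools.combinations(sorted(herbs), 2):
            expected = sum(1 for p in anti if a in p.herbs and b in p.herbs)
            got = g[a][b]["weight"] if g.has_edge(a, b) else 0
            assert got == expected

    def test_empty_corpus_rejected(self):
        with pytest.raises(EmptyInputError):
            build_cooccurrence_graph(PrescriptionCorpus([]))


def two_cliques_graph(size=10):
    g = nx.Graph()
    for offset, prefix in ((0, "a"), (size, "b")):
        members = [f"{prefix}{i}" for i in range(size)]
        for u, v in itertools.combinations(members, 2):
            g.add_edge(u, v, weight=3)
    # single weak bridge keeps the graph connected
    g.add_edge("a0", "b0", weight=1)
    return g


class TestGcnEmbed:
    def test_shape_and_trace_contract(self, tiny_corpus):
        g = build_cooccurrence_graph(tiny_corpus)
        hyper = GcnHyperparams(hidden_dim=8, out_dim=4, epochs=30, seed=0)
        emb = gcn_embed(g, hyper)
        assert emb.vectors.shape == (3, 4)
        assert len(emb.training_loss_trace) == 30
        assert np.all(np.isfinite(emb.vectors))
        assert all(np.isfinite(v) for v in emb.training_loss_trace)

    def test_determinism_same_seed(self):
        g = two_cliques_graph()
        a = gcn_embed(g, GcnHyperparams(epochs=50, seed=7))
        b = gcn_embed(g, GcnHyperparams(epochs=50, seed=7))
        assert np.array_equal(a.vectors, b.vectors)
        assert a.training_loss_trace == b.training_loss_trace

    def test_two_cliques_separate_in_embedding_space(self):
        g = two_cliques_graph()
        emb = gcn_embed(g, GcnHyperparams(seed=3))
        idx = {n: i for i, n in enumerate(emb.nodes)}
        a = emb.vectors[[idx[n] for n in emb.nodes if n.startswith("a")]]
        b = emb.vectors[[idx[n] for n in emb.nodes if n.startswith("b")]]

        def mean_dist(x, y):
            return np.mean(np.linalg.norm(x[:, None, :] - y[None, :, :], axis=-1))

        intra = (mean_dist(a, a) + mean_dist(b, b)) / 2
        inter = mean_dist(a, b)
        assert intra < inter

    @pytest.mark.parametrize("seed", range(5))
    def test_training_reduces_loss_on_connected_graph(self, seed):
        g = nx.connected_watts_strogatz_graph(20, 4, 0.3, seed=42)
        nx.set_edge_attributes(g, 2, "weight")
        g = nx.relabel_nodes(g, {i: f"h{i}" for i in g.nodes})
        emb = gcn_embed(g, GcnHyperparams(epochs=100, seed=seed))
        assert emb.training_loss_trace[-1] < emb.training_loss_trace[0]

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        with pytest.raises(GraphStructureError):
            gcn_embed(g, GcnHyperparams(epochs=5))


def blob_embedding(n_per=20, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, 16))
    b = rng.normal(sep, 1.0, size=(n_per, 16))
    nodes = [f"n{i}" for i in range(2 * n_per)]
    return EmbeddingMatrix(nodes, np.vstack([a, b]), []), n_per


class TestClustering:
    def test_k_one_is_rejected(self):
        emb, _ = blob_embedding()
        with pytest.raises(ValueError):
            cluster_embeddings(emb, k=1)

    def test_auto_recovers_two_separated_blobs_perfectly(self):
        emb, n_per = blob_embedding(sep=10.0, seed=1)
        out = cluster_embeddings(emb, "auto", (2, 8), seed=0)
        assert out.k == 2
        first = {out.labels[f"n{i}"] for i in range(n_per)}
        second = {out.labels[f"n{i}"] for i in range(n_per, 2 * n_per)}
        assert len(first) == 1 and len(second) == 1 and first != second
        assert out.silhouette > 0.8

    def test_fixed_k_respected(self):
        emb, _ = blob_embedding()
        out = cluster_embeddings(emb, k=3, seed=0)
        assert out.k == 3 and len(set(out.labels.values())) == 3

    def test_auto_needs_at_least_three_nodes(self):
        emb = EmbeddingMatrix(["a", "b"], np.eye(2), [])
        with pytest.raises(InsufficientDataError):
            cluster_embeddings(emb, "auto")

    def test_determinism(self):
        emb, _ = blob_embedding(seed=2)
        a = cluster_embeddings(emb, "auto", (2, 6), seed=5)
        b = cluster_embeddings(emb, "auto", (2, 6), seed=5)
        assert a.k == b.k and a.labels == b.labels and a.silhouette == b.silhouette


class TestScoreClusters:
    def test_hand_computed_components(self, tiny_corpus):
        g = build_cooccurrence_graph(tiny_corpus)
        assignment = ClusterAssignment(2, {"A": 0, "B": 0, "C": 1}, 0.5)
        scores = {s.cluster_id: s for s in score_clusters(g, tiny_corpus, assignment)}
        ab, c = scores[0], scores[1]
        assert ab.avg_degree == pytest.approx(3.5)
        assert ab.subgraph_density == pytest.approx(2.0)   # weight 2 over 1 pair
        assert ab.coverage == 1.0                          # every rx has A or B
        assert c.avg_degree == pytest.approx(3.0)
        assert c.subgraph_density == 0.0                   # singleton
        assert c.coverage == pytest.approx(2 / 3)

    def test_single_cluster_coverage_is_one_and_constant_components_half(self, tiny_corpus):
        g = build_cooccurrence_graph(tiny_corpus)
        assignment = ClusterAssignment(1, {"A": 0, "B": 0, "C": 0}, 0.0)
        (s,) = score_clusters(g, tiny_corpus, assignment)
        assert s.coverage == 1.0
        assert s.composite == pytest.approx(0.5)  # every component constant

    def test_invariant_to_cluster_relabeling_and_node_order(self, tiny_corpus):
        g = build_cooccurrence_graph(tiny_corpus)
        a = ClusterAssignment(2, {"A": 0, "B": 0, "C": 1}, 0.5)
        b = ClusterAssignment(2, {"C": 0, "B": 1, "A": 1}, 0.5)  # swapped ids, reordered
        sa = {s.members: (s.avg_degree, s.subgraph_density, s.coverage, s.composite)
              for s in score_clusters(g, tiny_corpus, a)}
        sb = {s.members: (s.avg_degree, s.subgraph_density, s.coverage, s.composite)
              for s in score_clusters(g, tiny_corpus, b)}
        assert sa == sb

    def test_stricter_coverage_flag(self, tiny_corpus):
        g = build_cooccurrence_graph(tiny_corpus)
        assignment = ClusterAssignment(2, {"A": 0, "B": 0, "C": 1}, 0.5)
        scores = {s.cluster_id: s for s in
                  score_clusters(g, tiny_corpus, assignment, min_members_covered=2)}
        assert scores[0].coverage == pytest.approx(2 / 3)  # only P1, P2 have both A and B
        assert scores[1].coverage == 0.0

    def test_planted_module_cluster_ranks_first(self, reference_synthetic):
        corpus, truth = reference_synthetic
        anti = corpus.subset("anti_recurrence")
        g = build_cooccurrence_graph(anti)
        emb = gcn_embed(g, GcnHyperparams(seed=1))
        assignment = cluster_embeddings(emb, "auto", (2, 10), seed=1)
        scores = score_clusters(g, anti, assignment)
        planted = truth.planted_modules[0]
        assert len(scores[0].members & planted) >= 6
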