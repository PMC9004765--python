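"""Chinese Whispers, NMI, and the two clustering phases."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clicktypes import synth
from clicktypes.clustering import (
    ClusterParams,
    Partition,
    build_similarity_graph,
    cap_nodes,
    chinese_whispers,
    cluster_bin,
    cluster_types,
    correlation_distance,
    eligible_detections,
    match_templates,
    nmi,
    prune_least_connected,
)
from clicktypes.templates import template


class TestCorrelationDistance:
    def test_identical_is_zero(self, rng):
        u = rng.standard_normal(50)
        assert correlation_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_is_two(self, rng):
        u = rng.standard_normal(50)
        assert correlation_distance(u, -u + 3.0) == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_pearson(self, rng):
        """Explicit covariance-formula oracle to 1e-12."""
        for _ in range(20):
            u, v = rng.standard_normal((2, 40))
            num = np.sum((u - u.mean()) * (v - v.mean()))
            den = np.sqrt(np.sum((u - u.mean()) ** 2) * np.sum((v - v.mean()) ** 2))
            assert correlation_distance(u, v) == pytest.approx(1 - num / den, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation_distance(np.ones(10), np.arange(10.0))


def two_cliques(n=30, w_in=1.0, w_bridge=0.01):
    g = nx.Graph()
    for block in (range(n), range(n, 2 * n)):
        for i in block:
            for j in block:
                if i < j:
                    g.add_edge(i, j, weight=w_in)
    g.add_edge(0, n, weight=w_bridge)
    return g


class TestChineseWhispers:
    def test_planted_two_cliques(self):
        """Two 30-node cliques joined by a weak edge → exactly their 2 clusters."""
        part = chinese_whispers(two_cliques(), seed=1)
        assert part.n_clusters == 2
        labels = part.labels
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_single_node(self):
        g = nx.Graph()
        g.add_node(0)
        assert chinese_whispers(g).n_clusters == 1

    def test_empty_graph(self):
        part = chinese_whispers(nx.Graph())
        assert part.n_clusters == 0 and len(part.labels) == 0

    def test_complete_graph_converges_to_one_cluster(self):
        g = nx.complete_graph(12)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = chinese_whispers(g, max_iterations=30, seed=3)
        assert part.n_clusters == 1

    def test_every_node_labelled(self, rng):
        g = nx.gnp_random_graph(60, 0.1, seed=7)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = chinese_whispers(g, seed=2)
        assert len(part.labels) == 60
        assert set(part.labels) == set(range(part.n_clusters))


def _entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log(p))


def _nmi_bruteforce(a, b):
    """Independent oracle: direct entropy/MI computation."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ha, hb = _entropy(a), _entropy(b)
    if ha == 0 and hb == 0:
        return 1.0
    if ha == 0 or hb == 0:
        return 0.0
    mi = 0.0
    for ua in np.unique(a):
        for ub in np.unique(b):
            pij = np.mean((a == ua) & (b == ub))
            if pij > 0:
                mi += pij * np.log(pij / (np.mean(a == ua) * np.mean(b == ub)))
    return mi / np.sqrt(ha * hb)


class TestNMI:
    def test_identical_partitions(self, rng):
        a = rng.integers(0, 4, 200)
        assert nmi(a, a) == pytest.approx(1.0)

    def test_relabelling_invariance(self, rng):
        a = rng.integers(0, 4, 200)
        assert nmi(a, (a + 2) % 4) == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self, rng):
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        assert nmi(a, b) < 0.05

    def test_single_cluster_edge_cases(self):
        assert nmi(np.zeros(10, int), np.ones(10, int)) == pytest.approx(1.0)
        assert nmi(np.zeros(10, int), np.arange(10) % 2) == pytest.approx(0.0)

    @given(st.lists(st.integers(0, 3), min_size=5, max_size=40))
    def test_matches_bruteforce_and_symmetry(self, labels_a):
        rng = np.random.default_rng(len(labels_a))
        a = np.array(labels_a)
        b = rng.integers(0, 3, len(a))
        v = nmi(a, b)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(nmi(b, a), abs=1e-12)
        assert v == pytest.approx(_nmi_bruteforce(a, b), abs=1e-9)


def _toy_detections(n, rl=130.0, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "time_s": np.sort(rng.uniform(0, 300, n)),
        "rl_dbpp": np.full(n, rl),
        "duration_us": np.full(n, 100.0),
    })
    spec = pd.DataFrame(rng.standard_normal((n, 181)),
                        columns=[f"spec_{f:.1f}" for f in np.arange(10, 100.25, 0.5)])
    env = pd.DataFrame(rng.random((n, 100)),
                       columns=[f"env_{i:03d}" for i in range(100)])
    return pd.concat([frame, spec, env], axis=1)


class TestClusterBin:
    def test_small_cluster_discarded(self, rng):
        """A bin with only 40 same-type clicks emits no cluster (minimum 50)."""
        dets = synth.synth_bin_detections(template("kogia"), 40, rng)
        assert cluster_bin(dets, ClusterParams(), rng) == []

    def test_rl_floor_applied(self, rng):
        """Detections below 120 dBpp never enter phase-1 clustering."""
        dets = _toy_detections(200, rl=119.9)
        assert len(eligible_detections(dets, ClusterParams(), rng)) == 0
        assert cluster_bin(dets, ClusterParams(), rng) == []

    def test_node_cap_at_10000(self, rng):
        dets = _toy_detections(10_050, rl=130.0)
        eligible = eligible_detections(dets, ClusterParams(), rng)
        assert len(eligible) == 10_000

    def test_phase2_cap_at_20000(self, rng):
        capped = cap_nodes(list(range(20_010)), 20_000, rng)
        assert len(capped) == 20_000
        assert capped == sorted(capped)  # order preserved

    def test_two_planted_types_recovered(self, rng):
        """100 Cuvier + 100 Kogia clicks split into two pure clusters."""
        dets = pd.concat(
            [synth.synth_bin_detections(template("cuvier_beaked_whale"), 100, rng),
             synth.synth_bin_detections(template("kogia"), 100, rng)],
            ignore_index=True)
        clusters = cluster_bin(dets, ClusterParams(), rng)
        assert len(clusters) == 2
        sizes = sorted(c.member_count for c in clusters)
        assert sizes[0] >= 95 and sizes[1] <= 105

    def test_empty_result_when_nothing_passes(self, rng):
        dets = _toy_detections(0)
        assert cluster_bin(dets, ClusterParams(), rng) == []


class TestClusterTypes:
    def test_small_type_cluster_discarded(self, rng):
        """A type cluster of 20 bins is below the 25-bin minimum."""
        bins = []
        for b in range(20):
            dd = synth.synth_bin_detections(template("kogia"), 60, rng,
                                            bin_start_s=b * 300.0)
            bins.extend(cluster_bin(dd, ClusterParams(), rng, bin_start=b * 300.0))
        assert len(bins) == 20
        assert cluster_types(bins, ClusterParams(), rng) == []

    def test_prune_count_is_one_percent(self):
        """Exactly 10 of 1000 single-cluster nodes are pruned at 1%."""
        g = nx.path_graph(1000)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = Partition(labels=np.zeros(1000, dtype=int), n_clusters=1)
        keep = prune_least_connected(g, part, 0.01)
        assert len(keep) == 990

    def test_empty_input(self, rng):
        assert cluster_types([], ClusterParams(), rng) == []


class TestMatchTemplates:
    def _kogia_cluster(self, rng):
        dets = synth.synth_bin_detections(template("kogia"), 80, rng)
        return cluster_bin(dets, ClusterParams(), rng)

    def test_kogia_cluster_assigned_kogia(self, rng):
        clusters = self._kogia_cluster(rng)
        names = match_templates([clusters], [template("kogia"),
                                             template("cuvier_beaked_whale")])
        assert names == ["kogia"]

    def test_empty_template_list(self, rng):
        clusters = self._kogia_cluster(rng)
        assert match_templates([clusters], []) == ["unassigned"]

    def test_zero_ceiling_unassigns_all(self, rng):
        clusters = self._kogia_cluster(rng)
        names = match_templates([clusters], [template("kogia")], distance_ceiling=0.0)
        assert names == ["unassigned"]


class TestSimilarityGraph:
    def test_edges_only_above_threshold(self, rng):
        base = rng.standard_normal(50)
        feats = np.stack([base + 0.05 * rng.standard_normal(50) for _ in range(5)]
                         + [rng.standard_normal(50) for _ in range(5)])
        g = build_similarity_graph(feats, threshold=0.85)
        clique = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        for i, j in clique:
            assert g.has_edge(i, j)
        for i in range(5):
            for j in range(5, 10):
                assert not g.has_edge(i, j)
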