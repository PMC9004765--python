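"""Two-phase unsupervised clustering of click detections and bin features.

Phase 1 clusters the detections inside each 5-minute bin on the correlation
distance between their normalized spectra; phase 2 clusters bin-level mean
spectra and envelopes across the dataset to find the dominant click types.
Both phases use Chinese Whispers — randomized label propagation on a
weighted similarity graph — run several times with different node orders;
the partition kept is the one with the highest average normalized mutual
information (NMI) against the other runs.

Standard filters: detections below 120 dB peak-to-peak are excluded from
phase 1; bins are subsampled to at most 10,000 nodes and the phase-2 network
to at most 20,000; clusters below 50 detections (phase 1) or 25 bins
(phase 2) are discarded; phase 2 additionally prunes the 1% least-connected
nodes inside each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from clicktypes.features import (
    BinCluster,
    ICI_BIN_WIDTH_S,
    ICI_MAX_S,
    fit_ici_gaussian,
    ici_distribution,
    normalize_spectrum,
)
from clicktypes.templates import ClickTypeTemplate

__all__ = [
    "Partition",
    "ClusterParams",
    "correlation_distance",
    "chinese_whispers",
    "nmi",
    "build_similarity_graph",
    "eligible_detections",
    "cap_nodes",
    "cluster_bin",
    "cluster_types",
    "prune_least_connected",
    "match_templates",
]


@dataclass
class Partition:
    """A labelling of graph nodes with contiguous cluster ids."""

    labels: np.ndarray  # labels[i] = cluster id of node i
    n_clusters: int
    mean_nmi: float = float("nan")

    @classmethod
    def from_raw(cls, raw: np.ndarray, mean_nmi: float = float("nan")) -> "Partition":
        _, contiguous = np.unique(raw, return_inverse=True)
        return cls(labels=contiguous, n_clusters=int(contiguous.max()) + 1 if len(contiguous) else 0,
                   mean_nmi=mean_nmi)


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for the two clustering phases (defaults are the standard ones)."""

    min_rl_dbpp: float = 120.0
    min_cluster_size_clicks: int = 50
    max_nodes_phase1: int = 10_000
    max_cw_iterations: int = 15
    min_cluster_size_bins: int = 25
    max_nodes_phase2: int = 20_000
    prune_fraction: float = 0.01
    n_trials_phase1: int = 5
    n_trials_phase2: int = 5
    edge_similarity_threshold: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prune_fraction <= 0.1):
            raise ValueError("prune_fraction must be within [0, 0.1]")
        if self.min_cluster_size_clicks <= 0 or self.min_cluster_size_bins <= 0:
            raise ValueError("cluster-size minima must be positive")


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 − Pearson correlation; 0 for identical shape, 2 for perfect anticorrelation."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    du, dv = u - u.mean(), v - v.mean()
    nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
    if nu == 0 or nv == 0:
        raise ValueError("correlation undefined for constant vectors")
    return float(1.0 - (du @ dv) / (nu * nv))


def chinese_whispers(graph: nx.Graph, max_iterations: int = 15,
                     seed: int | np.random.Generator = 0) -> Partition:
    """Chinese Whispers label propagation on a weighted undirected graph.

    Every node starts in its own cluster; nodes are visited in a fresh
    random order each iteration, and each adopts the label with the largest
    summed edge weight among its neighbours (ties broken at random).  Stops
    when a full pass changes no label or after ``max_iterations`` passes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = list(graph.nodes)
    if not nodes:
        return Partition(labels=np.empty(0, dtype=int), n_clusters=0)
    index = {n: i for i, n in enumerate(nodes)}
    labels = np.arange(len(nodes))
    for _ in range(max_iterations):
        changed = False
        for i in rng.permutation(len(nodes)):
            node = nodes[i]
            weight_by_label: dict[int, float] = {}
            for nb, data in graph.adj[node].items():
                lab = labels[index[nb]]
                weight_by_label[lab] = weight_by_label.get(lab, 0.0) + data.get("weight", 1.0)
            if not weight_by_label:
                continue
            best = max(weight_by_label.values())
            winners = [lab for lab, w in weight_by_label.items() if w == best]
            new = winners[rng.integers(len(winners))] if len(winners) > 1 else winners[0]
            if new != labels[i]:
                labels[i] = new
                changed = True
        if not changed:
            break
    return Partition.from_raw(labels)


def nmi(a: np.ndarray | Partition, b: np.ndarray | Partition) -> float:
    """Normalized mutual information between two partitions of one node set.

    Mutual information normalized by sqrt(H(a)·H(b)); 1 for partitions that
    are identical up to relabelling, symmetric in its arguments.  Two
    all-one-cluster partitions (zero entropy on both sides) count as
    identical → 1; a single-cluster partition against a split one scores 0.
    """
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("partitions must cover the same node set")
    if la.size == 0:
        return 1.0
    return float(normalized_mutual_info_score(la, lb, average_method="geometric"))


def build_similarity_graph(features: np.ndarray, threshold: float = 0.85,
                           block: int = 512) -> nx.Graph:
    """Similarity graph from pairwise correlation distances.

    Node pairs with similarity ``1 − distance/2`` above ``threshold`` are
    connected; the edge weight is the *excess* similarity above the
    threshold, which sharpens the contrast between strongly and marginally
    connected pairs so label propagation does not coalesce across adjacent
    types.  Distances are computed blockwise so large node sets never
    materialize a full n×n matrix.
    """
    x = np.asarray(features, dtype=float)
    n = len(x)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n < 2:
        return g
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = np.inf  # constant rows correlate with nothing
    unit = centered / norms[:, None]
    for s in range(0, n, block):
        e = min(s + block, n)
        corr = unit[s:e] @ unit.T  # similarity = 1 - (1 - corr)/2 = (1 + corr)/2
        sim = (1.0 + corr) / 2.0
        for i_local, i in enumerate(range(s, e)):
            js = np.flatnonzero(sim[i_local, i + 1:] > threshold) + i + 1
            for j in js:
                g.add_edge(i, int(j), weight=float(sim[i_local, j] - threshold))
    return g


def _best_of_runs(graph: nx.Graph, n_runs: int, max_iterations: int,
                  rng: np.random.Generator) -> Partition:
    """Run CW ``n_runs`` times; keep the run with highest mean NMI vs the others.

    Ties are broken toward fewer clusters, then toward the earlier run.
    """
    runs = [chinese_whispers(graph, max_iterations, rng) for _ in range(n_runs)]
    if n_runs == 1:
        runs[0].mean_nmi = 1.0
        return runs[0]
    scores = []
    for i, ri in enumerate(runs):
        others = [nmi(ri, rj) for j, rj in enumerate(runs) if j != i]
        scores.append(float(np.mean(others)))
        ri.mean_nmi = scores[-1]
    order = sorted(range(n_runs), key=lambda i: (-scores[i], runs[i].n_clusters, i))
    return runs[order[0]]


def eligible_detections(detections: pd.DataFrame, params: ClusterParams,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Phase-1 node set: received-level floor, then random cap at 10,000 nodes."""
    eligible = detections[detections["rl_dbpp"] >= params.min_rl_dbpp]
    if len(eligible) > params.max_nodes_phase1:
        keep = rng.choice(len(eligible), size=params.max_nodes_phase1, replace=False)
        eligible = eligible.iloc[np.sort(keep)]
    return eligible


def cap_nodes(items: Sequence, max_nodes: int, rng: np.random.Generator) -> list:
    """Random subsample preserving order when over the network-size cap."""
    items = list(items)
    if len(items) <= max_nodes:
        return items
    keep = rng.choice(len(items), size=max_nodes, replace=False)
    return [items[i] for i in np.sort(keep)]


def cluster_bin(detections: pd.DataFrame, params: ClusterParams = ClusterParams(),
                rng: Optional[np.random.Generator] = None,
                bin_start: float = 0.0) -> list[BinCluster]:
    """Phase 1: cluster the detections of one 5-minute bin by spectral shape.

    Detections below the 120 dB received-level floor are dropped; at most
    10,000 of the remainder (chosen at random) become graph nodes.  Chinese
    Whispers runs ``n_trials_phase1`` times and the highest-average-NMI
    partition is kept; clusters below 50 members are discarded.  Each
    surviving cluster is summarized as a :class:`BinCluster`.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    spec_cols = [c for c in detections.columns if c.startswith("spec_")]
    env_cols = [c for c in detections.columns if c.startswith("env_")]
    eligible = eligible_detections(detections, params, rng)
    if len(eligible) == 0:
        return []
    spectra = eligible[spec_cols].to_numpy(dtype=float)
    # min-max normalize each spectrum; constant spectra cannot be normalized
    rng_ok = spectra.max(axis=1) > spectra.min(axis=1)
    eligible = eligible.iloc[np.flatnonzero(rng_ok)]
    spectra = spectra[rng_ok]
    if len(eligible) == 0:
        return []
    norm = np.stack([normalize_spectrum(s) for s in spectra])
    graph = build_similarity_graph(norm, params.edge_similarity_threshold)
    part = _best_of_runs(graph, params.n_trials_phase1, params.max_cw_iterations, rng)

    out: list[BinCluster] = []
    cid_out = 0
    for cid in range(part.n_clusters):
        members = np.flatnonzero(part.labels == cid)
        if len(members) < params.min_cluster_size_clicks:
            continue
        sub = eligible.iloc[members]
        times = np.sort(sub["time_s"].to_numpy(dtype=float))
        hist = ici_distribution(times)
        try:
            modal, _ = fit_ici_gaussian(hist)
        except ValueError:
            modal = float("nan")
        env = sub[env_cols].to_numpy(dtype=float).mean(axis=0) if env_cols else np.zeros(0)
        if env.size and env.max() > 0:
            env = env / env.max()
        out.append(
            BinCluster(
                bin_start=bin_start,
                cluster_id=cid_out,
                member_count=len(members),
                mean_spectrum=norm[members].mean(axis=0),
                ici_hist=hist,
                mean_envelope=env,
                modal_ici_s=modal,
                rl_max_dbpp=float(sub["rl_dbpp"].max()),
            )
        )
        cid_out += 1
    return out


def prune_least_connected(graph: nx.Graph, partition: Partition,
                          fraction: float) -> np.ndarray:
    """Indices that survive pruning the least-connected nodes of each cluster.

    Within every cluster, ``floor(fraction * size)`` nodes with the lowest
    summed intra-cluster edge weight are removed (exactly 10 from a
    1000-node cluster at the default 1%).
    """
    labels = partition.labels
    keep = np.ones(len(labels), dtype=bool)
    for cid in range(partition.n_clusters):
        members = np.flatnonzero(labels == cid)
        n_prune = int(np.floor(fraction * len(members)))
        if n_prune == 0:
            continue
        member_set = set(members.tolist())
        strength = np.array([
            sum(d.get("weight", 1.0) for nb, d in graph.adj[m].items() if nb in member_set)
            for m in members
        ])
        drop = members[np.argsort(strength, kind="stable")[:n_prune]]
        keep[drop] = False
    return np.flatnonzero(keep)


def cluster_types(bin_clusters: Sequence[BinCluster],
                  params: ClusterParams = ClusterParams(),
                  rng: Optional[np.random.Generator] = None) -> list[list[BinCluster]]:
    """Phase 2: cluster bin-level mean spectra + envelopes into click types.

    The node distance is the unweighted mean of the spectral and envelope
    correlation distances.  The network is capped at 20,000 bins; the whole
    procedure (CW over the similarity graph) is repeated for
    ``n_trials_phase2`` trials with different random orders and the best
    trial is chosen by highest average NMI.  Within each cluster of the
    winning partition the 1% least-connected nodes are pruned, and clusters
    with fewer than 25 bins are discarded.
    """
    if not bin_clusters:
        return []
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    clusters = cap_nodes(bin_clusters, params.max_nodes_phase2, rng)
    spec = np.stack([c.mean_spectrum for c in clusters])
    env = np.stack([c.mean_envelope for c in clusters])

    # fused similarity: mean of spectral and envelope correlation similarities
    def corr_sim(x: np.ndarray) -> np.ndarray:
        centered = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        norms[norms == 0] = np.inf
        unit = centered / norms[:, None]
        return (1.0 + unit @ unit.T) / 2.0

    sim = 0.5 * (corr_sim(spec) + corr_sim(env))
    g = nx.Graph()
    g.add_nodes_from(range(len(clusters)))
    ii, jj = np.nonzero(np.triu(sim > params.edge_similarity_threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(int(i), int(j),
                   weight=float(sim[i, j] - params.edge_similarity_threshold))

    part = _best_of_runs(g, params.n_trials_phase2, params.max_cw_iterations, rng)
    survivors = set(prune_least_connected(g, part, params.prune_fraction).tolist())
    out: list[list[BinCluster]] = []
    for cid in range(part.n_clusters):
        members = [i for i in np.flatnonzero(part.labels == cid) if i in survivors]
        if len(members) < params.min_cluster_size_bins:
            continue
        out.append([clusters[i] for i in members])
    return out


def match_templates(type_clusters: Sequence[Sequence[BinCluster]],
                    templates: Sequence[ClickTypeTemplate],
                    distance_ceiling: float = 0.5) -> list[str]:
    """Assign each type cluster to the nearest template by mean-spectrum shape.

    The cluster's mean of member mean-spectra is compared to each template's
    idealized normalized spectrum by correlation distance; clusters farther
    than ``distance_ceiling`` from every template are labelled
    ``"unassigned"``.  Replaces the manual grouping step of operational
    workflows with a programmatic stand-in for synthetic data.
    """
    names = [t.name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError("templates must be distinct")
    refs = [normalize_spectrum(t.power_spectrum()) for t in templates]
    out = []
    for cluster in type_clusters:
        mean_spec = np.mean([c.mean_spectrum for c in cluster], axis=0)
        best_name, best_dist = "unassigned", np.inf
        for name, ref in zip(names, refs):
            d = correlation_distance(mean_spec, ref)
            if d < best_dist:
                best_name, best_dist = name, d
        out.append(best_name if best_dist <= distance_ceiling else "unassigned")
    return out
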