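"""Statistically significant community detection and spatial diagnostics.

Bioregions (and, later, species groups) are communities of a weighted
similarity network.  The primary detector follows the contract of
order-statistics local optimization (OSLOM-style): candidate clusters are
proposed by modularity optimization and accepted only when they are unlikely
under a configuration-model null that preserves every node's degree and
incident-weight profile.  The significance score combines per-node tail
probabilities through order statistics, with a correction for the size of
the candidate pool a member could have been picked from, so that random
networks do not yield spurious communities.

Two cross-check detectors are exposed: plain weighted modularity
optimization (Leiden) and Ward agglomerative clustering on 1 − similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .cellnet import SimilarityNetwork
from .errors import ParameterError
from .gridding import GridSpec

__all__ = [
    "Partition",
    "BioregionPartition",
    "detect_communities",
    "cluster_significance",
    "assign_homeless",
    "spatial_connectivity",
    "cluster_report",
]

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_TINY = 1e-300


@dataclass
class Partition:
    """Hard assignment of network nodes to clusters 1..K (0 = unassigned).

    ``significance`` maps cluster id to its configuration-model score;
    ``hierarchy`` optionally holds coarser label arrays (level 1 = coarsest
    grouping found above the base partition).  ``diagnostics`` records raw
    accepted clusters, homeless nodes and isolated singletons.
    """

    nodes: np.ndarray
    labels: np.ndarray
    method: str
    seed: int | None = None
    significance: dict[int, float] = field(default_factory=dict)
    hierarchy: list[np.ndarray] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.nodes) != len(self.labels):
            raise ValueError("nodes and labels length mismatch")

    @property
    def K(self) -> int:
        pos = self.labels[self.labels > 0]
        return int(len(np.unique(pos)))

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def to_frame(self, node_name: str = "cell_id", cluster_name: str = "bioregion") -> pd.DataFrame:
        return pd.DataFrame({node_name: self.nodes, cluster_name: self.labels})

    def label_of(self) -> dict:
        return dict(zip(self.nodes.tolist(), self.labels.tolist()))


#: Alias used by the bioregion-facing API; species groups reuse the same type.
BioregionPartition = Partition


# ---------------------------------------------------------------------------
# configuration-model significance machinery
# ---------------------------------------------------------------------------


def _node_arrays(network: SimilarityNetwork):
    A = network.adjacency()
    d = np.diff(A.indptr).astype(np.int64)  # degree (edge count)
    s = np.asarray(A.sum(axis=1)).ravel()  # strength
    A2 = A.copy()
    A2.data = A2.data**2
    ssq = np.asarray(A2.sum(axis=1)).ravel()  # sum of squared incident weights
    return A, d, s, ssq


def _r_values_analytic(A, d, s, ssq, comp_stubs: float, cluster_idx: np.ndarray) -> np.ndarray:
    """Normal-approximation tail probability of each member's internal strength.

    Null: the endpoints of a node's edges land on other nodes of its
    component with probability proportional to degree, keeping the node's own
    degree and incident weights fixed.
    """
    sub = A[cluster_idx][:, cluster_idx]
    w_in = np.asarray(sub.sum(axis=1)).ravel()
    d_c = d[cluster_idx]
    dC = float(d_c.sum())
    denom = np.maximum(comp_stubs - d_c, 1.0)
    p = np.clip((dC - d_c) / denom, 0.0, 1.0)
    mu = p * s[cluster_idx]
    var = p * (1.0 - p) * ssq[cluster_idx]
    # continuity correction of half a typical incident weight: keeps the
    # tail valid (P(W >= observed), ties included) where W is near-discrete
    half_w = 0.5 * s[cluster_idx] / np.maximum(d_c, 1)
    r = np.ones(len(cluster_idx))
    ok = var > 0
    r[ok] = norm.sf((w_in[ok] - half_w[ok] - mu[ok]) / np.sqrt(var[ok]))
    degenerate = ~ok
    r[degenerate] = np.where(w_in[degenerate] <= mu[degenerate] + 1e-12, 1.0, 0.0)
    return np.clip(r, _TINY, 1.0)


def _combine_r(r: np.ndarray, comp_size: int, m_correct: int | None = None) -> float:
    """Order-statistics cluster score from per-node tail probabilities.

    The members' r-values are corrected for selection out of the whole
    component: the k-th smallest observed r is compared with the law of the
    k-th order statistic of ``comp_size`` uniforms, Beta(k, comp_size−k+1),
    as if the cluster had been assembled from the component's most internally
    connected nodes.  Only ranks whose r does not exceed 1/2 count as
    evidence (a member no better than the null median cannot support a
    cluster), and the best rank is Šidák-corrected over the cluster size.
    A singleton or the full component carries no partition evidence.
    """
    m = len(r)
    if m <= 1 or m >= comp_size:
        return 1.0
    rs = np.clip(np.sort(r), _TINY, 1.0)
    k = np.arange(1, m + 1)
    usable = rs <= 0.5
    if not usable.any():
        return 1.0
    pk = beta_dist.cdf(rs[usable], k[usable], comp_size - k[usable] + 1)
    raw = float(pk.min())
    m_eff = m_correct if m_correct is not None else m
    return float(-np.expm1(m_eff * np.log1p(-min(raw, 1.0 - 1e-16))))


def cluster_significance(
    cluster,
    network: SimilarityNetwork,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo configuration-model score of a candidate cluster.

    For every member, its edge endpoints are re-drawn ``n_null`` times under
    the degree-proportional null (keeping the member's degree and incident
    weights), and the probability of attaining at least the observed internal
    connection strength is estimated with the usual +1 correction.  Per-node
    probabilities are combined exactly as in the analytic score used by the
    detector.  A cluster equal to the whole node set carries no partition
    evidence and scores 1; so does a singleton (no internal edges).
    """
    if n_null < 100:
        raise ParameterError("n_null must be >= 100")
    idx_map = network.node_index()
    try:
        cluster_idx = np.array(sorted({idx_map[v] for v in cluster}), dtype=np.int64)
    except KeyError as exc:
        raise ParameterError(f"cluster node {exc.args[0]!r} not in network") from exc
    if len(cluster_idx) == 0:
        raise ParameterError("cluster is empty")
    n = network.n_nodes
    if len(cluster_idx) >= n:
        return 1.0
    if len(cluster_idx) == 1:
        return 1.0

    A, d, s, ssq = _node_arrays(network)
    n_comp, comp = connected_components(A, directed=False)
    comp_sizes = np.bincount(comp, minlength=n_comp)
    comp_stubs = np.bincount(comp, weights=d, minlength=n_comp)

    sub = A[cluster_idx][:, cluster_idx]
    w_in_obs = np.asarray(sub.sum(axis=1)).ravel()
    in_cluster = np.zeros(n, dtype=bool)
    in_cluster[cluster_idx] = True
    dC_by_comp = np.bincount(comp[cluster_idx], weights=d[cluster_idx], minlength=n_comp)

    rng = np.random.default_rng(seed)
    A_csr = A.tocsr()
    r = np.ones(len(cluster_idx))
    for pos, u in enumerate(cluster_idx):
        du = int(d[u])
        if du == 0:
            continue
        cu = comp[u]
        pool = comp_stubs[cu] - d[u]
        if pool <= 0:
            continue
        p_u = min(max((dC_by_comp[cu] - d[u]) / pool, 0.0), 1.0)
        w_u = A_csr.data[A_csr.indptr[u] : A_csr.indptr[u + 1]]
        hits = rng.random((n_null, du)) < p_u
        w_null = hits @ w_u
        exceed = int(np.sum(w_null >= w_in_obs[pos] - 1e-12))
        r[pos] = (1 + exceed) / (n_null + 1)

    comp_size = int(comp_sizes[comp[cluster_idx]].max())  # containing component
    if len(np.unique(comp[cluster_idx])) > 1:
        comp_size = int(comp_sizes[np.unique(comp[cluster_idx])].sum())
    return _combine_r(r, comp_size)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _build_igraph(edges: np.ndarray, n: int):
    import igraph

    return igraph.Graph(n=n, edges=edges.tolist())


def _leiden_membership(g, weights, seed: int) -> np.ndarray:
    import leidenalg

    part = leidenalg.find_partition(
        g,
        leidenalg.ModularityVertexPartition,
        weights=np.asarray(weights, dtype=float),
        seed=int(seed),
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=np.int64)


def _local_stats(edges: np.ndarray, weights: np.ndarray, n: int):
    """Adjacency plus per-node degree/strength/sum-of-squares arrays."""
    i, j = edges[:, 0], edges[:, 1]
    A = sparse.csr_matrix(
        (
            np.concatenate([weights, weights]),
            (np.concatenate([i, j]), np.concatenate([j, i])),
        ),
        shape=(n, n),
    )
    d = np.diff(A.indptr).astype(np.int64)
    s = np.asarray(A.sum(axis=1)).ravel()
    A2 = A.copy()
    A2.data = A2.data**2
    ssq = np.asarray(A2.sum(axis=1)).ravel()
    return A, d, s, ssq


def _trim_cluster(stats, total_stubs, comp_size, cluster_idx):
    """Trim up to 10% of a candidate's weakest members to minimize its score.

    The Šidák step always uses the original size, so trimming cannot
    manufacture evidence.  Returns the best (member indices, raw score) seen;
    None when the candidate is a singleton or the whole component.
    """
    A, d, s, ssq = stats
    idx = np.asarray(cluster_idx, dtype=np.int64)
    m0 = len(idx)
    if m0 < 2 or m0 >= comp_size:
        return None
    budget = max(1, int(np.ceil(0.1 * m0)))
    # dense internal block computed once; trimming updates it in O(m)
    block = np.asarray(A[idx][:, idx].todense())
    d_c, s_c, ssq_c = d[idx].astype(float), s[idx], ssq[idx]
    best: tuple[np.ndarray, float] | None = None
    for removed in range(budget + 1):
        w_in = block.sum(axis=1)
        dC = d_c.sum()
        p = np.clip((dC - d_c) / np.maximum(total_stubs - d_c, 1.0), 0.0, 1.0)
        mu = p * s_c
        var = p * (1.0 - p) * ssq_c
        half_w = 0.5 * s_c / np.maximum(d_c, 1.0)
        r = np.ones(len(idx))
        ok = var > 0
        r[ok] = norm.sf((w_in[ok] - half_w[ok] - mu[ok]) / np.sqrt(var[ok]))
        r[~ok] = np.where(w_in[~ok] <= mu[~ok] + 1e-12, 1.0, 0.0)
        r = np.clip(r, _TINY, 1.0)
        score = _combine_r(r, comp_size, m_correct=m0)
        if best is None or score < best[1]:
            best = (idx, score)
        if len(idx) <= 2:
            break
        worst = int(np.argmax(r))
        keep = np.arange(len(idx)) != worst
        idx = idx[keep]
        block = block[keep][:, keep]
        d_c, s_c, ssq_c = d_c[keep], s_c[keep], ssq_c[keep]
    return best


def _candidate_runs(g, weights, n, stats, run_seeds):
    """Leiden proposals with trimmed clusters and raw scores, one per seed."""
    total_stubs = float(stats[1].sum())
    runs = []
    for rs in run_seeds:
        membership = _leiden_membership(g, weights, int(rs))
        clusters = []
        for k in np.unique(membership):
            res = _trim_cluster(stats, total_stubs, n, np.flatnonzero(membership == k))
            if res is not None:
                clusters.append(res)
        obj = float(sum(max(0.0, -np.log(max(sc, _TINY))) for _, sc in clusters))
        runs.append((obj, clusters))
    return runs


def _rewire_edges(edges: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Degree-preserving rewiring (double-edge swaps) via igraph."""
    import random

    import igraph

    igraph.set_random_number_generator(random.Random(int(seed)))
    g = igraph.Graph(n=n, edges=[(int(a), int(b)) for a, b in edges])
    with np.errstate(all="ignore"):
        g.rewire(n=10 * len(edges))
    out = np.array(g.get_edgelist(), dtype=np.int64)
    return out


def _null_min_scores(edges, weights, n, n_runs, n_null_networks, seed):
    """Minimum cluster score attained by the same detection on null networks.

    Each replicate preserves every node's degree: for sparse graphs the
    topology is rewired by double-edge swaps and the weights reshuffled over
    edges; for dense graphs (where swaps barely change anything) the weight
    shuffle alone carries the randomization.
    """
    density = 2.0 * len(edges) / max(n * (n - 1), 1)
    do_rewire = density < 0.5
    ss = np.random.SeedSequence(seed)
    mins = np.ones(n_null_networks)
    g_fixed = None if do_rewire else _build_igraph(edges, n)
    for b, child in enumerate(ss.spawn(n_null_networks)):
        rng = np.random.default_rng(child)
        if do_rewire:
            e_b = _rewire_edges(edges, n, int(rng.integers(2**31 - 1)))
            g_b = _build_igraph(e_b, n)
        else:
            e_b, g_b = edges, g_fixed
        w_b = rng.permutation(weights)[: len(e_b)]
        stats_b = _local_stats(e_b, w_b, n)
        run_seeds = rng.integers(2**31 - 1, size=n_runs)
        best = 1.0
        for _, clusters in _candidate_runs(g_b, w_b, n, stats_b, run_seeds):
            for _, sc in clusters:
                best = min(best, sc)
        mins[b] = best
    return mins


def _quotient_network(network: SimilarityNetwork, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster-level graph: mean pairwise similarity between cluster pairs."""
    ids = np.unique(labels[labels > 0])
    pos = {k: i for i, k in enumerate(ids.tolist())}
    sizes = np.array([(labels == k).sum() for k in ids], dtype=float)
    K = len(ids)
    tot = np.zeros((K, K))
    la = labels[np.asarray(network.edges[:, 0])]
    lb = labels[np.asarray(network.edges[:, 1])]
    for a, b, w in zip(la, lb, network.weights):
        if a > 0 and b > 0 and a != b:
            i, j = pos[int(a)], pos[int(b)]
            tot[i, j] += w
            tot[j, i] += w
    denom = sizes[:, None] * sizes[None, :]
    mean_w = np.where(denom > 0, tot / denom, 0.0)
    iu = np.triu_indices(K, 1)
    edges = np.column_stack([iu[0], iu[1]])
    weights = mean_w[iu]
    keep = weights > 0
    return ids, edges[keep], weights[keep]


def _subset_edges(edges, weights, subset):
    """Edges induced by a node subset, re-indexed to 0..len(subset)-1."""
    n_old = int(edges.max(initial=-1)) + 1 if len(edges) else 0
    local = -np.ones(max(n_old, int(subset.max()) + 1), dtype=np.int64)
    local[subset] = np.arange(len(subset))
    if len(edges) == 0:
        return edges, weights
    a, b = local[edges[:, 0]], local[edges[:, 1]]
    keep = (a >= 0) & (b >= 0)
    return np.column_stack([a[keep], b[keep]]), weights[keep]


def _significant_clusters(
    edges, weights, n, n_runs, n_null_networks, tolerance, seed, depth=0
):
    """Recursively accepted clusters of a (local) graph, with found-by-chance p.

    One level proposes candidates (best of ``n_runs`` Leiden restarts, each
    trimmed), calibrates their scores against null-network minima, and keeps
    those below tolerance.  Each accepted cluster is then re-analyzed on its
    induced subgraph — this refinement step undoes the resolution limit of
    the modularity proposals, so small but significant communities inside a
    larger accepted one are still separated.
    """
    stats = _local_stats(edges, weights, n)
    state = np.random.SeedSequence(seed).generate_state(n_runs + 1) % (2**31 - 1)
    g = _build_igraph(edges, n)
    runs = _candidate_runs(g, weights, n, stats, state[:n_runs].astype(int))
    _, candidates = max(runs, key=lambda t: t[0])
    if not candidates:
        return []
    null_mins = _null_min_scores(
        edges, weights, n, n_runs, n_null_networks, int(state[-1])
    )
    accepted = []
    for idx, sc in candidates:
        p_found = (1 + int(np.sum(null_mins <= sc))) / (n_null_networks + 1)
        if p_found < tolerance:
            accepted.append((idx, p_found))
    out = []
    for idx, p_found in accepted:
        if depth < 2 and 8 <= len(idx) < n:
            sub_e, sub_w = _subset_edges(edges, weights, idx)
            child_seed = int(
                np.random.SeedSequence([seed, depth + 1, int(idx.min())]).generate_state(1)[0]
                % (2**31 - 1)
            )
            finer = _significant_clusters(
                sub_e, sub_w, len(idx), n_runs, n_null_networks, tolerance,
                child_seed, depth + 1,
            )
            if len(finer) >= 2 and _split_detaches(edges, weights, n, idx, finer):
                out.extend((idx[sub_idx], sub_p) for sub_idx, sub_p in finer)
                continue
        out.append((idx, p_found))
    return out


def _split_detaches(edges, weights, n, parent, finer, factor: float = 2.0) -> bool:
    """Whether a refinement genuinely detaches the parent's sub-clusters.

    The sub-clusters are kept only when their mutual (per-pair mean)
    similarity is no more than ``factor`` times the parent's background
    similarity to the rest of the graph.  This guards against slicing a
    smooth similarity gradient into bands: bands of a continuum remain far
    more attached to each other than to the background, whereas distinct
    communities merged by the resolution limit are not.
    """
    sub_label = -np.ones(len(parent), dtype=np.int64)
    for g, (sub_idx, _) in enumerate(finer):
        sub_label[sub_idx] = g
    in_parent = np.zeros(n, dtype=bool)
    in_parent[parent] = True
    parent_pos = -np.ones(n, dtype=np.int64)
    parent_pos[parent] = np.arange(len(parent))

    a, b = edges[:, 0], edges[:, 1]
    pa, pb = in_parent[a], in_parent[b]
    # between different sub-clusters, inside the parent
    both = pa & pb
    la = np.where(both, sub_label[parent_pos[a * both]], -1)
    lb = np.where(both, sub_label[parent_pos[b * both]], -1)
    btw_mask = both & (la >= 0) & (lb >= 0) & (la != lb)
    sizes = np.array([len(sub_idx) for sub_idx, _ in finer])
    n_btw_pairs = (sizes.sum() ** 2 - (sizes**2).sum()) / 2.0
    w_btw = float(weights[btw_mask].sum()) / max(n_btw_pairs, 1.0)
    # parent to the rest of the graph
    bg_mask = pa ^ pb
    n_bg_pairs = len(parent) * (n - len(parent))
    if n_bg_pairs == 0:
        return False
    w_bg = float(weights[bg_mask].sum()) / n_bg_pairs
    return w_btw <= factor * w_bg + 1e-12


def detect_communities(
    network: SimilarityNetwork,
    method: str = "significance_local_opt",
    tolerance: float = 0.1,
    seed: int = 0,
    n_runs: int = 10,
    n_clusters: int | None = None,
    n_null_networks: int = 19,
) -> Partition:
    """Detect communities in a weighted similarity network.

    ``significance_local_opt`` proposes clusters by weighted modularity
    optimization within each connected component and trims each candidate to
    its most internally over-connected core.  A candidate is accepted only
    if the probability of finding an equally extreme cluster in a random
    null model — the same detection run on ``n_null_networks``
    degree/strength-preserving randomizations of the component — is below
    ``tolerance``.  Nodes of rejected clusters are re-attached by maximum
    similarity (:func:`assign_homeless`); a component with no significant
    sub-structure is returned as a single cluster (score 1).

    ``modularity`` keeps the Leiden partition as is (raw order-statistic
    scores are still reported); ``ward`` cuts a Ward dendrogram of
    1 − similarity at a user-chosen ``n_clusters``.

    The best of ``n_runs`` restarts is kept — by summed cluster evidence for
    the primary method, by modularity for the Leiden method — and the whole
    procedure is deterministic given (seed, n_runs, n_null_networks).
    """
    if not (0.0 < tolerance < 1.0):
        raise ParameterError("tolerance must lie strictly between 0 and 1")
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    if n_null_networks + 1 < int(np.ceil(1.0 / tolerance)):
        raise ParameterError(
            "n_null_networks too small to resolve the requested tolerance"
        )
    n = network.n_nodes
    if n == 0:
        raise ParameterError("network has no nodes")
    if method == "ward":
        return _detect_ward(network, n_clusters, seed)
    if method not in ("significance_local_opt", "modularity"):
        raise ParameterError(f"unknown detection method {method!r}")

    A, d, s, ssq = _node_arrays(network)
    n_comp, comp = connected_components(A, directed=False)
    seed_seq = np.random.SeedSequence(seed)
    run_seeds = (seed_seq.generate_state(n_runs) % (2**31 - 1)).astype(int)
    null_seeds = (seed_seq.generate_state(n_comp + n_runs) % (2**31 - 1))[n_runs:]

    labels = np.zeros(n, dtype=np.int64)
    cluster_scores: list[float] = []
    raw_accepted: list[np.ndarray] = []
    next_label = 1
    isolated: list = []

    for c in range(n_comp):
        comp_idx = np.flatnonzero(comp == c)
        comp_size = len(comp_idx)
        if comp_size == 1:
            labels[comp_idx] = next_label
            cluster_scores.append(1.0)
            if d[comp_idx[0]] == 0:
                isolated.append(network.nodes[comp_idx[0]])
            next_label += 1
            continue

        # edges restricted to this component, re-indexed locally
        local = -np.ones(n, dtype=np.int64)
        local[comp_idx] = np.arange(comp_size)
        emask = np.isin(network.edges[:, 0], comp_idx)
        le = local[network.edges[emask]]
        lw = network.weights[emask]

        if method == "modularity":
            stats = _local_stats(le, lw, comp_size)
            g_comp = _build_igraph(le, comp_size)
            best = None
            for rs in run_seeds:
                membership = _leiden_membership(g_comp, lw, int(rs))
                obj = _modularity(le, lw, comp_size, membership)
                if best is None or obj > best[0]:
                    best = (obj, membership)
            membership = best[1]
            total_stubs = float(stats[1].sum())
            clusters = [
                np.flatnonzero(membership == k) for k in np.unique(membership)
            ]
            scores = [
                _combine_r(
                    _r_values_analytic(*stats, total_stubs, cl), comp_size
                )
                for cl in clusters
            ]
        else:
            found = _significant_clusters(
                le, lw, comp_size, n_runs, n_null_networks, tolerance,
                int(null_seeds[c]),
            )
            clusters = [idx for idx, _ in found]
            scores = [p for _, p in found]

        if not clusters:  # no significant sub-structure: whole component
            labels[comp_idx] = next_label
            cluster_scores.append(1.0)
            next_label += 1
            continue
        order = sorted(
            range(len(clusters)),
            key=lambda i: (-len(clusters[i]), int(clusters[i].min())),
        )
        for i in order:
            global_members = comp_idx[clusters[i]]
            labels[global_members] = next_label
            cluster_scores.append(float(scores[i]))
            raw_accepted.append(network.nodes[global_members])
            next_label += 1

    part = Partition(
        nodes=network.nodes.copy(),
        labels=labels,
        method=method,
        seed=seed,
        significance={k + 1: sc for k, sc in enumerate(cluster_scores)},
        diagnostics={
            "raw_accepted_clusters": raw_accepted,
            "homeless": network.nodes[labels == 0].tolist(),
            "isolated_singletons": isolated,
        },
    )
    part = assign_homeless(part, network)
    _attach_hierarchy(part, network, A, d, s, ssq, comp, seed, tolerance)
    return part


def _modularity(edges, weights, n, membership) -> float:
    two_w = 2.0 * float(np.sum(weights))
    if two_w == 0:
        return 0.0
    strength = np.zeros(n)
    np.add.at(strength, edges[:, 0], weights)
    np.add.at(strength, edges[:, 1], weights)
    same = membership[edges[:, 0]] == membership[edges[:, 1]]
    w_in = float(np.sum(weights[same]))
    q = w_in / (two_w / 2.0)
    for k in np.unique(membership):
        sk = strength[membership == k].sum()
        q -= (sk / two_w) ** 2
    return q


def _detect_ward(network: SimilarityNetwork, n_clusters, seed) -> Partition:
    if n_clusters is None:
        raise ParameterError("ward clustering requires n_clusters")
    n = network.n_nodes
    D = np.ones((n, n))
    np.fill_diagonal(D, 0.0)
    for (a, b), w in zip(network.edges, network.weights):
        D[a, b] = D[b, a] = 1.0 - w
    Z = linkage(squareform(D, checks=False), method="ward")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber deterministically: by descending size, then smallest member
    ids = np.unique(raw)
    order = sorted(ids, key=lambda k: (-(raw == k).sum(), int(np.flatnonzero(raw == k).min())))
    remap = {k: i + 1 for i, k in enumerate(order)}
    labels = np.array([remap[k] for k in raw], dtype=np.int64)
    A, d, s, ssq = _node_arrays(network)
    n_comp, comp = connected_components(A, directed=False)
    comp_stubs = np.bincount(comp, weights=d, minlength=n_comp)
    comp_sizes = np.bincount(comp, minlength=n_comp)
    significance = {}
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        c = comp[idx[0]]
        significance[int(k)] = _combine_r(
            _r_values_analytic(A, d, s, ssq, float(comp_stubs[c]), idx),
            int(comp_sizes[c]),
        )
    return Partition(
        nodes=network.nodes.copy(),
        labels=labels,
        method="ward",
        seed=seed,
        significance=significance,
    )


def _attach_hierarchy(part, network, A, d, s, ssq, comp, seed, tolerance) -> None:
    """Look for a coarser grouping of the detected clusters (diagnostic).

    The cluster-level quotient graph (mean between-cluster similarity) is
    clustered once more; when a non-trivial coarser level exists it is stored
    as hierarchy level 1, with per-supercluster scores in diagnostics.
    """
    if part.method != "significance_local_opt" or part.K < 3:
        return
    ids, qedges, qweights = _quotient_network(network, part.labels)
    if len(qedges) == 0:
        return
    membership = _leiden_membership(_build_igraph(qedges, len(ids)), qweights, int(seed))
    K2 = len(np.unique(membership))
    if not (1 < K2 < len(ids)):
        return
    coarse = np.zeros(len(part.labels), dtype=np.int64)
    for i, k in enumerate(ids.tolist()):
        coarse[part.labels == k] = int(membership[i]) + 1
    scores = {}
    comp_stubs_all = float(d.sum())
    for k in np.unique(coarse[coarse > 0]):
        idx = np.flatnonzero(coarse == k)
        cstubs = float(d[np.flatnonzero(comp == comp[idx[0]])].sum())
        csize = int((comp == comp[idx[0]]).sum())
        scores[int(k)] = _combine_r(
            _r_values_analytic(A, d, s, ssq, cstubs, idx), csize
        )
    part.hierarchy = [coarse]
    part.diagnostics["hierarchy_significance"] = scores


# ---------------------------------------------------------------------------
# post-processing and diagnostics
# ---------------------------------------------------------------------------


def assign_homeless(partition: Partition, network: SimilarityNetwork) -> Partition:
    """Attach every unassigned node to the cluster it is most similar to.

    Each unassigned node joins the cluster maximizing its summed edge weight,
    ties going to the lowest cluster id; passes repeat until stable.  A node
    with no edge to any cluster becomes its own flagged singleton cluster.
    """
    labels = partition.labels.copy()
    A = network.adjacency().tocsr()
    changed = True
    while changed and (labels == 0).any():
        changed = False
        for u in np.flatnonzero(labels == 0):
            row = A[u]
            neigh, w = row.indices, row.data
            nl = labels[neigh]
            pos = nl > 0
            if not pos.any():
                continue
            totals: dict[int, float] = {}
            for lab, wt in zip(nl[pos], w[pos]):
                totals[int(lab)] = totals.get(int(lab), 0.0) + float(wt)
            best = max(totals.items(), key=lambda kv: (kv[1], -kv[0]))
            labels[u] = best[0]
            changed = True
    isolated = list(partition.diagnostics.get("isolated_singletons", []))
    next_label = int(labels.max()) + 1 if labels.max() > 0 else 1
    significance = dict(partition.significance)
    for u in np.flatnonzero(labels == 0):
        labels[u] = next_label
        significance[next_label] = 1.0
        isolated.append(network.nodes[u])
        next_label += 1
    diagnostics = dict(partition.diagnostics)
    diagnostics["isolated_singletons"] = isolated
    return Partition(
        nodes=partition.nodes,
        labels=labels,
        method=partition.method,
        seed=partition.seed,
        significance=significance,
        hierarchy=partition.hierarchy,
        diagnostics=diagnostics,
    )


def spatial_connectivity(cluster_cells, grid: GridSpec) -> float:
    """Largest-patch ratio of a set of grid cells.

    Patches are connected components under rook (4-neighbor) adjacency; the
    returned value is |largest patch| / |cluster|, in (0, 1].
    """
    cells = list(cluster_cells)
    if not cells:
        raise ParameterError("cluster is empty")
    mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for cid in cells:
        row, col = grid.rowcol_of(int(cid))
        if not grid.contains(row, col):
            raise ParameterError(f"cell {cid} outside grid")
        mask[row, col] = True
    lab, n_patches = ndimage.label(mask, structure=_ROOK)
    sizes = np.bincount(lab.ravel())[1:]
    return float(sizes.max() / mask.sum())


def cluster_report(
    partition: Partition,
    network: SimilarityNetwork,
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Per-cluster size, significance and (when a grid is given) connectivity."""
    rows = []
    for k, size in sorted(partition.sizes().items()):
        row = {
            "cluster": k,
            "size": size,
            "significance": partition.significance.get(k, float("nan")),
        }
        if grid is not None:
            row["connectivity"] = spatial_connectivity(
                partition.nodes[partition.members(k)], grid
            )
        rows.append(row)
    return pd.DataFrame(rows)
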