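"""Signed co-occurrence networks from compositional abundances.

Counts are centred-log-ratio (CLR) transformed to remove compositional
closure, then a sparse conditional-dependence graph is inferred by
neighbourhood selection: every taxon is L1-regressed on all others and an
edge is kept where either coefficient is nonzero (OR rule; AND by flag).
The penalty is chosen by StARS stability selection — the smallest penalty
whose average edge instability across random subsamples stays below a
threshold.  Edge sign is the sign of the symmetrised coefficient.

Node- and network-level topology statistics mirror the usual comparative
summaries: degree, density, path length and diameter on the largest
connected component, clustering, eigenvector centrality, greedy
modularity, and positive/negative edge partitions by the niche label of
the endpoints (generalist-involving, specialist-involving,
generalist–specialist, others).
"""

from __future__ import annotations

import itertools
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .core_io import CommunityTable, filter_taxa


def clr_transform(table: CommunityTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centred log-ratio transform; rows (samples) sum to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    X = table.matrix.T.astype(float) + pseudocount  # samples × taxa
    logX = np.log(X)
    clr = logX - logX.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.taxon_ids)


def subnetwork_by_category(table: CommunityTable, meta: pd.DataFrame,
                           category: str,
                           min_rel_abund: float = 1e-4) -> CommunityTable:
    """Restrict to one salinity category and re-filter rare taxa.

    Taxa below ``min_rel_abund`` of the subset's total reads (the 0.01%
    pre-filter by default) are removed within the subset.
    """
    samples = meta.index[meta["salinity_category"] == category]
    if len(samples) == 0:
        raise ValueError(f"no samples in salinity category {category!r}")
    sub = table.select_samples(samples)
    return filter_taxa(sub, min_total_rel_abund=min_rel_abund, min_prevalence=1)


def _neighbourhood_adjacency(X: np.ndarray, alphas: np.ndarray,
                             rule: str) -> np.ndarray:
    """Boolean adjacency (n_alpha, p, p) from per-node lasso paths."""
    n, p = X.shape
    coefs = np.zeros((p, p - 1, len(alphas)))
    for j in range(p):
        y = X[:, j]
        Xo = np.delete(X, j, axis=1)
        _, c, _ = lasso_path(Xo, y, alphas=alphas)
        coefs[j] = c
    adj = np.zeros((len(alphas), p, p), bool)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        nz = coefs[j] != 0  # (p-1, n_alpha)
        for pos, k in enumerate(others):
            adj[:, j, k] |= nz[pos]
    if rule == "or":
        adj = adj | adj.transpose(0, 2, 1)
    elif rule == "and":
        adj = adj & adj.transpose(0, 2, 1)
    else:
        raise ValueError(f"unknown edge rule {rule!r}")
    return adj


def infer_network(
    clr: pd.DataFrame,
    lambda_path: np.ndarray | None = None,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
    stars_subsample: float = 0.8,
    stars_reps: int = 20,
    stars_threshold: float = 0.05,
    rule: str = "or",
    seed: int = 0,
) -> nx.Graph:
    """Sparse signed conditional-dependence graph with StARS selection.

    Parameters mirror the usual stability-selection setup: ``stars_reps``
    random subsamples of fraction ``stars_subsample`` are fit along the
    penalty path; edge instability at a penalty is the mean of
    ``2·θ·(1−θ)`` over node pairs, where θ is the edge's selection
    frequency; the chosen penalty is the smallest whose (monotonised)
    instability is at most ``stars_threshold``.  The final graph is fit on
    the full data at that penalty.  Deterministic for a fixed seed.
    """
    if clr.shape[0] < 8:
        raise ValueError("need at least 8 samples for network inference")
    rng = np.random.default_rng(seed)
    X = clr.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant taxa before "
                      "network inference")
    names = [t for t, k in zip(clr.columns, keep) if k]
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    n, p = X.shape

    if lambda_path is None:
        lam_max = 0.0
        for j in range(p):
            Xo = np.delete(X, j, axis=1)
            lam_max = max(lam_max, np.abs(Xo.T @ X[:, j]).max() / n)
        lambda_path = np.logspace(np.log10(lam_max),
                                  np.log10(lam_max * lambda_min_ratio), n_lambda)
    lambda_path = np.sort(np.asarray(lambda_path, float))[::-1]

    b = max(int(np.floor(stars_subsample * n)), 4)
    freq = np.zeros((len(lambda_path), p, p))
    for _ in range(stars_reps):
        idx = rng.choice(n, size=b, replace=False)
        Xs = X[idx]
        Xs = (Xs - Xs.mean(axis=0)) / np.maximum(Xs.std(axis=0, ddof=0), 1e-12)
        freq += _neighbourhood_adjacency(Xs, lambda_path, rule)
    theta = freq / stars_reps
    iu = np.triu_indices(p, 1)
    instab = (2 * theta * (1 - theta))[:, iu[0], iu[1]].mean(axis=1)
    instab_mono = np.maximum.accumulate(instab)  # from sparsest (largest λ) down
    ok = np.flatnonzero(instab_mono <= stars_threshold)
    sel = ok[-1] if len(ok) else 0
    lam_star = lambda_path[sel]

    # final fit on the full data at the selected penalty
    coef = np.zeros((p, p))
    for j in range(p):
        Xo = np.delete(X, j, axis=1)
        _, c, _ = lasso_path(Xo, X[:, j], alphas=[lam_star])
        others = [k for k in range(p) if k != j]
        coef[j, others] = c[:, 0]

    G = nx.Graph(lambda_selected=float(lam_star),
                 stars_threshold=float(stars_threshold))
    G.add_nodes_from(names)
    for a, bb in itertools.combinations(range(p), 2):
        c1, c2 = coef[a, bb], coef[bb, a]
        present = (c1 != 0 or c2 != 0) if rule == "or" else (c1 != 0 and c2 != 0)
        if not present:
            continue
        nz = [c for c in (c1, c2) if c != 0]
        w = float(np.mean(nz))
        G.add_edge(names[a], names[bb], weight=w, abs_weight=abs(w),
                   sign="+" if w > 0 else "-")
    return G


def _eigenvector_centrality(G: nx.Graph) -> dict:
    """Eigenvector centrality on |weight|, computed per connected component
    (the dominant eigenvector is ill-defined across disconnected parts;
    each component is solved separately, isolated nodes get 0)."""
    cent = {n: 0.0 for n in G.nodes}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        if sub.number_of_nodes() == 1:
            continue
        cent.update(nx.eigenvector_centrality_numpy(sub, weight="abs_weight"))
    return cent


def _edge_partition_class(lab_a: str, lab_b: str) -> str:
    labs = {lab_a, lab_b}
    if labs == {"generalist", "specialist"}:
        return "generalist_specialist"
    if "generalist" in labs and "specialist" not in labs:
        return "generalist_involving"
    if "specialist" in labs and "generalist" not in labs:
        return "specialist_involving"
    return "others"


def topology_summary(G: nx.Graph, labels=None) -> dict:
    """Network-level topology and signed edge-partition percentages.

    Path length and diameter are computed on the largest connected
    component ignoring edge sign; clustering is the unweighted mean local
    clustering coefficient; eigenvector centrality uses |weight|;
    modularity is that of a deterministic greedy community partition on
    absolute weights.  Edge partition percentages are relative to all
    edges, so the four classes of each sign sum to that sign's total.
    """
    N = G.number_of_nodes()
    E = G.number_of_edges()
    if N == 0 or E == 0:
        warnings.warn("empty graph: all-zero topology summary")
        return {k: 0.0 for k in (
            "n_nodes", "n_edges", "average_degree", "average_path_length",
            "diameter", "average_clustering_coefficient",
            "average_eigenvector_centrality", "modularity", "graph_density",
            "percent_positive_edges", "percent_negative_edges")}
    labels = labels or {}
    lcc = max(nx.connected_components(G), key=len)
    sub = G.subgraph(lcc)
    if sub.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(sub)
        diam = nx.diameter(sub)
    else:
        apl, diam = 0.0, 0
    cent = _eigenvector_centrality(G)
    comms = nx.community.greedy_modularity_communities(G, weight="abs_weight")
    mod = nx.community.modularity(G, comms, weight="abs_weight")

    signs = np.array([d["sign"] for _, _, d in G.edges(data=True)])
    n_pos = int((signs == "+").sum())
    n_neg = E - n_pos
    summary = {
        "n_nodes": N,
        "n_edges": E,
        "average_degree": 2 * E / N,
        "average_path_length": apl,
        "diameter": diam,
        "average_clustering_coefficient": nx.average_clustering(G),
        "average_eigenvector_centrality": float(np.mean(list(cent.values()))),
        "modularity": mod,
        "graph_density": 2 * E / (N * (N - 1)) if N > 1 else 0.0,
        "percent_positive_edges": 100.0 * n_pos / E,
        "percent_negative_edges": 100.0 * n_neg / E,
        "n_communities": len(comms),
    }
    for sign_name, sign_sym in (("positive", "+"), ("negative", "-")):
        counts = {"generalist_involving": 0, "specialist_involving": 0,
                  "generalist_specialist": 0, "others": 0}
        for u, v, d in G.edges(data=True):
            if d["sign"] != sign_sym:
                continue
            counts[_edge_partition_class(labels.get(u, "others"),
                                         labels.get(v, "others"))] += 1
        for cls, c in counts.items():
            summary[f"{sign_name}_{cls}_pct"] = 100.0 * c / E
    return summary


def node_topology(G: nx.Graph, labels=None) -> pd.DataFrame:
    """Node-level degree, clustering, eigenvector and betweenness centrality."""
    labels = labels or {}
    if G.number_of_edges() == 0:
        return pd.DataFrame(columns=["degree", "clustering", "eigenvector",
                                     "betweenness", "label"])
    cent = _eigenvector_centrality(G)
    btw = nx.betweenness_centrality(G)
    clus = nx.clustering(G)
    return pd.DataFrame({
        "degree": dict(G.degree()),
        "clustering": clus,
        "eigenvector": cent,
        "betweenness": btw,
        "label": {n: labels.get(n, "others") for n in G.nodes},
    })


def write_edge_list(G: nx.Graph, path) -> None:
    rows = [{"node1": u, "node2": v, "sign": d["sign"], "weight": d["weight"]}
            for u, v, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["node1", "node2", "sign", "weight"]).to_csv(
        path, sep="\t", index=False)
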