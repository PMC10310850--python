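"""Preranked gene-set enrichment, similarity networks and over-representation.

Three complementary enrichment views, mirroring the study's pathway
stage: a weighted Kolmogorov-Smirnov enrichment score over a ranked gene
list with a gene-permutation null (preranked GSEA); an enrichment-map
style network joining significant sets by membership similarity, with
global graph metrics; and hypergeometric over-representation of hit
lists against an expression-defined background.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from ffed.stats import bh_adjust

__all__ = [
    "gsea_es",
    "gsea_significance",
    "build_similarity_network",
    "network_metrics",
    "summarize_clusters",
    "hypergeom_enrichment",
    "NetworkMetrics",
]

STOPWORDS = frozenset(
    "of the and in to a an for by with via regulation process positive negative".split()
)


def _as_ranked(ranked) -> tuple[list[str], np.ndarray]:
    if isinstance(ranked, pd.Series):
        ranked = list(ranked.items())
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    if not (np.diff(scores) <= 0).all():
        raise ValueError("ranked list must be sorted by descending score")
    return genes, scores


def gsea_es(ranked, gene_set, exponent: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running-sum profile.

    Hits advance the running sum by ``|score|**exponent`` (normalized to
    sum 1 over hits), misses retreat by ``1/(N - |set in list|)``. The ES
    is the extremum of the walk by absolute value.
    """
    genes, scores = _as_ranked(ranked)
    members = set(gene_set)
    hit = np.array([g in members for g in genes])
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    n = len(genes)
    weights = np.abs(scores) ** exponent
    hit_w = np.where(hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores are zero: fall back to equal weights
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def gsea_significance(
    ranked,
    collection: dict[str, set],
    n_perm: int = 1000,
    exponent: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-permutation significance for every set in a collection.

    The null for a set of size k is the ES of k genes drawn uniformly
    from the ranked list, ``n_perm`` times. Nominal p is the add-one
    tail proportion among same-sign null scores; NES divides ES by the
    mean same-sign null magnitude; FDR q is the GSEA-style ratio of
    null-vs-observed NES tail frequencies, clipped to [0, 1].
    """
    genes, scores = _as_ranked(ranked)
    rng = np.random.default_rng(seed)
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    observed, nes_null_all = {}, []
    null_by_set = {}
    sizes = {}
    for name, members in collection.items():
        inside = [g for g in members if g in gene_index]
        if not inside:
            continue
        es, _ = gsea_es(list(zip(genes, scores)), inside, exponent)
        observed[name] = es
        sizes[name] = len(inside)

    # share null draws per distinct set size
    null_cache: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes.values())):
        draws = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(n, size=k, replace=False)
            sel = [genes[i] for i in idx]
            draws[b], _ = gsea_es(list(zip(genes, scores)), sel, exponent)
        null_cache[k] = draws

    rows = []
    for name, es in observed.items():
        null = null_by_set[name] = null_cache[sizes[name]]
        if es >= 0:
            same = null[null >= 0]
            nes = es / same.mean() if same.size else np.nan
            p = (1 + int((null >= es).sum())) / (same.size + 1) if same.size else 1.0
        else:
            same = null[null < 0]
            nes = es / np.abs(same.mean()) if same.size else np.nan
            p = (1 + int((null <= es).sum())) / (same.size + 1) if same.size else 1.0
        rows.append({"set": name, "ES": es, "NES": nes, "pvalue": min(p, 1.0),
                     "size": sizes[name]})
    result = pd.DataFrame(rows).set_index("set")

    # GSEA-style FDR q on the NES scale
    null_nes = []
    for name in result.index:
        null = null_by_set[name]
        pos, neg = null[null >= 0], null[null < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg.mean()) if neg.size else np.nan
        scaled = np.where(null >= 0,
                          null / pos_mean if pos.size else np.nan,
                          null / neg_mean if neg.size else np.nan)
        null_nes.append(scaled[~np.isnan(scaled)])
    null_nes = np.concatenate(null_nes) if null_nes else np.array([])
    obs_nes = result["NES"].to_numpy()
    qs = []
    for nes in obs_nes:
        if np.isnan(nes):
            qs.append(np.nan)
            continue
        if nes >= 0:
            null_tail = (null_nes >= nes).mean() if null_nes.size else 1.0
            obs_tail = (obs_nes[~np.isnan(obs_nes)] >= nes).mean()
        else:
            null_tail = (null_nes <= nes).mean() if null_nes.size else 1.0
            obs_tail = (obs_nes[~np.isnan(obs_nes)] <= nes).mean()
        qs.append(min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0)
    result["q"] = qs
    result["direction"] = np.where(result["ES"] >= 0, "up", "down")
    return result


def _similarity(a: set, b: set) -> float:
    """EnrichmentMap combined coefficient: half Jaccard, half overlap."""
    inter = len(a & b)
    if inter == 0:
        return 0.0
    jaccard = inter / len(a | b)
    overlap = inter / min(len(a), len(b))
    return 0.5 * jaccard + 0.5 * overlap


def build_similarity_network(
    results: pd.DataFrame,
    collection: dict[str, set],
    q_threshold: float = 0.05,
    cutoff: float = 0.375,
    direction: str | None = None,
) -> nx.Graph:
    """Enrichment-map graph over sets passing the FDR threshold.

    Nodes carry (q, direction); edges join set pairs whose combined
    similarity coefficient reaches ``cutoff``. An empty significant list
    yields an empty graph (the explicit "no network" outcome — the study
    hit this for ASD downregulation).
    """
    sig = results[results["q"] < q_threshold]
    if direction is not None:
        sig = sig[sig["direction"] == direction]
    g = nx.Graph()
    for name, row in sig.iterrows():
        g.add_node(name, q=float(row["q"]), direction=row["direction"])
    names = list(g.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sim = _similarity(set(collection[a]), set(collection[b]))
            if sim >= cutoff:
                g.add_edge(a, b, similarity=sim)
    return g


@dataclass(frozen=True)
class NetworkMetrics:
    """Global properties of a pathway network (NetConfer-style)."""

    total_nodes: int
    total_edges: int
    diameter: float
    density: float
    clustering_coefficient: float
    average_degree: float


def network_metrics(net: nx.Graph) -> NetworkMetrics:
    """Six global graph metrics; diameter on the largest connected component.

    Clustering coefficient is the mean local coefficient over all nodes
    (the global transitivity is available via networkx if preferred).
    """
    n, e = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        return NetworkMetrics(0, 0, 0.0, 0.0, 0.0, 0.0)
    if n >= 2:
        largest = max(nx.connected_components(net), key=len)
        sub = net.subgraph(largest)
        diameter = float(nx.diameter(sub)) if sub.number_of_nodes() > 1 else 0.0
    else:
        diameter = 0.0
    density = nx.density(net)
    clustering = nx.average_clustering(net) if n > 0 else 0.0
    return NetworkMetrics(
        total_nodes=n,
        total_edges=e,
        diameter=diameter,
        density=density,
        clustering_coefficient=clustering,
        average_degree=2.0 * e / n,
    )


def summarize_clusters(
    net: nx.Graph, method: str = "components", top_tokens: int = 3
) -> list[dict]:
    """Deterministic cluster labels from member set names.

    Clusters are connected components (default) or greedy-modularity
    communities; the label is the most frequent non-stopword tokens of
    the member names, ties broken alphabetically.
    """
    if net.number_of_nodes() == 0:
        return []
    if method == "components":
        groups = list(nx.connected_components(net))
    elif method == "modularity":
        groups = [set(c) for c in nx.community.greedy_modularity_communities(net)]
    else:
        raise ValueError(f"unknown clustering method: {method!r}")
    clusters = []
    for members in sorted(groups, key=lambda m: (-len(m), sorted(m)[0])):
        tokens = Counter()
        for name in members:
            for tok in str(name).lower().replace("_", " ").split():
                if tok not in STOPWORDS:
                    tokens[tok] += 1
        label = " ".join(t for t, _ in sorted(tokens.items(), key=lambda kv: (-kv[1], kv[0]))[:top_tokens])
        clusters.append({"label": label, "members": sorted(members)})
    return clusters


def hypergeom_enrichment(
    hits: set, target_list: set, background: set
) -> dict[str, float]:
    """Upper-tail hypergeometric over-representation of hits in a target list.

    With N = |background|, K = |target within background|, n = |hits|,
    k = |hits in target|: p = P(X >= k) for X ~ Hypergeom(N, K, n).
    Hits must be drawn from the background (else the background is
    misspecified and an error is raised).
    """
    hits, target_list, background = set(hits), set(target_list), set(background)
    if not hits <= background:
        raise ValueError("hits are not a subset of the background gene list")
    N = len(background)
    K = len(target_list & background)
    n = len(hits)
    k = len(hits & target_list)
    p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
    return {"N": N, "K": K, "n": n, "k": k, "pvalue": min(p, 1.0)}


def hypergeom_enrichment_multi(
    hits: set, target_lists: dict[str, set], background: set
) -> pd.DataFrame:
    """Over-representation against several curated lists, BH-adjusted."""
    rows = []
    for name, target in target_lists.items():
        res = hypergeom_enrichment(hits, target, background)
        res["list"] = name
        rows.append(res)
    out = pd.DataFrame(rows).set_index("list")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
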