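"""Protein-protein interaction network screening.

Essential proteins are screened by three node-centrality measures —
subgraph centrality (closed-walk participation, the diagonal of the
adjacency-matrix exponential), shortest-path betweenness, and closeness —
followed by an intersection of the per-measure top deciles. Candidate
protein complexes (e.g. from a cluster-growth tool) are scored by density,
cohesiveness-style quality and a permutation p-value, and filtered at the
conventional thresholds (size >= 3, density >= 0.45, quality >= 0.5,
p < 0.05). Finally the screened subnetwork is intersected with
pharmacophore hit lists to produce ranked candidate targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

MEASURES = ("subgraph", "betweenness", "closeness")

MIN_SIZE = 3
MIN_DENSITY = 0.45
MIN_QUALITY = 0.5
MAX_P = 0.05


def as_graph(graph) -> nx.Graph:
    """Validate and normalize to a simple undirected graph (no self-loops)."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes())
    for u, v, data in graph.edges(data=True):
        if u == v:
            raise ValueError(f"self-loop at node {u!r}")
        g.add_edge(u, v, weight=data.get("weight", 1.0))
    return g


def read_edge_list(path) -> nx.Graph:
    """TSV edge list: two id columns and an optional weight column."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    g = nx.Graph()
    for row in frame.itertuples(index=False):
        u, v = str(row[0]), str(row[1])
        if u == v:
            continue
        w = float(row[2]) if len(row) > 2 and not pd.isna(row[2]) else 1.0
        g.add_edge(u, v, weight=w)
    return g


def subgraph_centrality(graph: nx.Graph) -> dict:
    """CS(u) = sum_v (v_vu)^2 e^{lambda_v}: the u-th diagonal entry of
    exp(A), computed from the eigendecomposition of the adjacency matrix.
    An isolated node scores e^0 = 1."""
    nodes = list(graph.nodes())
    if not nodes:
        return {}
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    lam, vec = scipy.linalg.eigh(A)
    cs = (vec**2) @ np.exp(lam)
    return dict(zip(nodes, cs))


def betweenness_centrality(graph: nx.Graph) -> dict:
    """CB(u) = sum over unordered pairs s != u != t of the fraction of
    shortest s-t paths passing through u; cross-component pairs contribute
    nothing. Unnormalized, unweighted shortest paths (Brandes)."""
    return nx.betweenness_centrality(graph, normalized=False, weight=None)


def closeness_centrality(graph: nx.Graph, variant: str = "standard") -> dict:
    """Closeness per connected component.

    standard: CC(u) = (n_comp - 1) / sum_v dist(u, v) over u's component.
    literal: numerator replaced by (deg(u) - 1), the neighbor-count form
    printed in some applied work; kept for comparability only.
    Singleton components score 0.
    """
    if variant not in ("standard", "literal"):
        raise ValueError(f"unknown closeness variant {variant!r}")
    cc = {}
    for comp in nx.connected_components(graph):
        comp = list(comp)
        sub = graph.subgraph(comp)
        for u in comp:
            if len(comp) == 1:
                cc[u] = 0.0
                continue
            total = sum(nx.single_source_shortest_path_length(sub, u).values())
            num = (len(comp) - 1) if variant == "standard" else (graph.degree[u] - 1)
            cc[u] = num / total
    return cc


def centrality_table(graph: nx.Graph, variant: str = "standard") -> pd.DataFrame:
    g = as_graph(graph)
    table = pd.DataFrame({
        "subgraph": pd.Series(subgraph_centrality(g)),
        "betweenness": pd.Series(betweenness_centrality(g)),
        "closeness": pd.Series(closeness_centrality(g, variant)),
    })
    for m in MEASURES:
        table[f"top_{m}"] = table.index.isin(top_decile(table[m]))
    return table


def top_decile(values: pd.Series, fraction: float = 0.10) -> set:
    """The top ceil(fraction*n) nodes by value; ties at the boundary value
    are all included."""
    n = len(values)
    if n == 0:
        return set()
    k = max(1, math.ceil(fraction * n))
    cutoff = values.sort_values(ascending=False).iloc[k - 1]
    return set(values.index[values >= cutoff])


def top_decile_overlap(table: pd.DataFrame, fraction: float = 0.10,
                       merge: str = "intersection") -> set:
    """Merge the three per-measure top deciles into the screened node set.

    merge="intersection": nodes in all three deciles (default).
    merge="pairwise": nodes in at least two deciles.
    """
    deciles = [top_decile(table[m], fraction) for m in MEASURES]
    if merge == "intersection":
        return set.intersection(*deciles)
    if merge == "pairwise":
        return {u for u in set.union(*deciles)
                if sum(u in d for d in deciles) >= 2}
    raise ValueError(f"unknown merge mode {merge!r}")


@dataclass
class ClusterMetrics:
    members: frozenset
    size: int
    density: float
    quality: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "members": sorted(map(str, self.members)),
            "size": self.size,
            "density": self.density,
            "quality": self.quality,
            "p_value": self.p_value,
        }


def _density(graph: nx.Graph, members: set) -> float:
    k = len(members)
    m_in = graph.subgraph(members).number_of_edges()
    return 2.0 * m_in / (k * (k - 1))


def cluster_metrics(graph: nx.Graph, members, n_perm: int = 999,
                    seed: int = 0) -> ClusterMetrics:
    """Density, cohesiveness quality and permutation p-value of a candidate
    cluster.

    density = 2 m_in / (k (k-1)); quality = w_in / (w_in + w_boundary) with
    boundary edges having exactly one endpoint inside; p-value is the
    +1-corrected tail probability that a uniformly random k-node set has
    density >= the observed one, over ``n_perm`` seeded draws.
    """
    g = as_graph(graph)
    members = set(members)
    if not members <= set(g.nodes()):
        raise ValueError("cluster members must be graph nodes")
    k = len(members)
    if k < 2:
        raise ValueError("cluster must have at least 2 members")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    density = _density(g, members)
    w_in = sum(d.get("weight", 1.0) for u, v, d in g.edges(members, data=True)
               if u in members and v in members)
    w_boundary = sum(d.get("weight", 1.0) for u, v, d in g.edges(members, data=True)
                     if (u in members) != (v in members))
    quality = w_in / (w_in + w_boundary) if (w_in + w_boundary) > 0 else 0.0

    rng = np.random.default_rng(seed)
    nodes = np.array(list(g.nodes()), dtype=object)
    hits = 0
    for _ in range(n_perm):
        sample = set(rng.choice(nodes, size=k, replace=False))
        if _density(g, sample) >= density - 1e-12:
            hits += 1
    p_value = (hits + 1) / (n_perm + 1)
    return ClusterMetrics(frozenset(members), k, density, quality, p_value)


def filter_clusters(metrics, min_size: int = MIN_SIZE, min_density: float = MIN_DENSITY,
                    min_quality: float = MIN_QUALITY, max_p: float = MAX_P) -> list:
    """Keep clusters with size >= 3, density >= 0.45, quality >= 0.5 and
    p < 0.05 (thresholds configurable)."""
    return [m for m in metrics
            if m.size >= min_size and m.density >= min_density
            and m.quality >= min_quality and m.p_value < max_p]


def intersect_targets(subnetwork, hit_lists: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Candidate targets: proteins present in every pharmacophore hit list
    and in the screened subnetwork, ranked by mean fit score (descending).

    Each hit list is a DataFrame with columns ``protein`` and ``score``.
    Proteins absent from the subnetwork are simply not candidates; they are
    reported in the frame attribute ``unmapped``.
    """
    subnetwork = set(subnetwork)
    common: set | None = None
    for frame in hit_lists.values():
        ids = set(frame["protein"].astype(str))
        common = ids if common is None else common & ids
    common = common or set()
    unmapped = sorted(common - subnetwork)
    candidates = common & subnetwork
    rows = []
    for prot in candidates:
        scores = [float(frame.loc[frame["protein"].astype(str) == prot, "score"].mean())
                  for frame in hit_lists.values()]
        rows.append((prot, float(np.mean(scores))))
    out = pd.DataFrame(rows, columns=["protein", "mean_score"])
    out = out.sort_values("mean_score", ascending=False, kind="stable").reset_index(drop=True)
    out.attrs["unmapped"] = unmapped
    return out
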