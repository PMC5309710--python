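"""Hierarchical clustering of the IBD network by modularity maximization.

The flat partition at each level comes from the seeded multi-level
(Louvain) heuristic; finer structure is obtained by inducing the subgraph
of each sufficiently large cluster and re-running the same algorithm, as
in the two-level (optionally three-level) analysis the network pipeline
performs. The multi-level algorithm's internal hierarchy is not used —
only its final flat partition at each recursion level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community

__all__ = [
    "modularity",
    "multilevel_cluster",
    "recursive_cluster",
    "cluster_density",
    "ClusterHierarchy",
]


def modularity(G: nx.Graph, partition: dict, weight: str = "weight") -> float:
    """Weighted Newman-Girvan modularity Q = sum_c (e_c/m - (a_c/2m)^2).

    ``e_c`` is the total weight of edges inside cluster c, ``m`` the total
    edge weight and ``a_c`` the summed weighted degree of c's vertices.
    """
    missing = set(G.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} vertices")
    m = G.size(weight=weight)
    if m == 0:
        return 0.0
    e = {}
    a = {}
    for u, v, d in G.edges(data=True):
        w = d.get(weight, 1.0)
        cu, cv = partition[u], partition[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + w
        a[cu] = a.get(cu, 0.0) + w
        a[cv] = a.get(cv, 0.0) + w
    return float(sum(e.get(c, 0.0) / m - (a.get(c, 0.0) / (2 * m)) ** 2 for c in set(partition.values())))


def _canonical_labels(communities) -> dict:
    """Stable integer labels: communities ordered by (-size, smallest member)."""
    comms = sorted((sorted(c) for c in communities), key=lambda c: (-len(c), c[0]))
    return {node: k for k, comm in enumerate(comms) for node in comm}


def multilevel_cluster(G: nx.Graph, seed: int = 0, resolution: float = 1.0) -> dict:
    """Flat partition from the seeded multi-level (Louvain) heuristic.

    Returns a vertex -> integer label mapping, deterministic given the
    seed; labels are assigned by decreasing cluster size.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    if G.number_of_edges() == 0:
        return {node: k for k, node in enumerate(sorted(G.nodes))}
    comms = nx_community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=int(seed)
    )
    return _canonical_labels(comms)


@dataclass
class ClusterHierarchy:
    """Nested partitions of the IBD network.

    ``assignments`` maps each vertex to a tuple of labels, one per level;
    a vertex whose cluster was not subdivided keeps a shorter tuple.
    ``metadata`` holds per-cluster size and network densities (W_in,
    W_out), keyed by the label tuple.
    """

    assignments: dict = field(default_factory=dict)
    levels: int = 1
    metadata: dict = field(default_factory=dict)

    def labels_at(self, level: int) -> dict:
        """Vertex -> label-tuple truncated to ``level`` levels (1-based)."""
        return {v: t[: min(level, len(t))] for v, t in self.assignments.items()}

    def flat_labels(self, level: int) -> dict:
        """Vertex -> integer label for the partition at ``level``."""
        tuples = self.labels_at(level)
        uniq = {t: k for k, t in enumerate(sorted(set(tuples.values())))}
        return {v: uniq[t] for v, t in tuples.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in sorted(self.assignments):
            t = self.assignments[v]
            row = {"sample": v}
            for lvl in range(self.levels):
                row[f"level{lvl + 1}"] = t[lvl] if lvl < len(t) else -1
            rows.append(row)
        return pd.DataFrame(rows)

    def metadata_json(self) -> str:
        payload = {
            ".".join(map(str, key)): val for key, val in sorted(self.metadata.items())
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def recursive_cluster(
    G: nx.Graph,
    levels: int = 2,
    min_cluster_size: int = 100,
    seed: int = 0,
    resolution: float = 1.0,
) -> ClusterHierarchy:
    """Recursively partition the network with the multi-level algorithm.

    Level 1 partitions the whole graph; each resulting cluster with at
    least ``min_cluster_size`` members is induced as a subgraph and
    partitioned again, down to the requested depth. Smaller clusters are
    leaves. Per-cluster metadata (size, W_in, W_out) is recorded at every
    level.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    hierarchy = ClusterHierarchy(levels=levels)

    def _recurse(sub: nx.Graph, prefix: tuple, depth: int, seed_: int):
        labels = multilevel_cluster(sub, seed=seed_, resolution=resolution)
        for v, lab in labels.items():
            hierarchy.assignments[v] = prefix + (lab,)
        dens = cluster_density(sub, labels)
        for lab, meta in dens.items():
            hierarchy.metadata[prefix + (lab,)] = meta
        if depth >= levels:
            return
        for lab in sorted(set(labels.values())):
            members = [v for v, l in labels.items() if l == lab]
            if len(members) < min_cluster_size or len(members) < 2:
                continue
            _recurse(sub.subgraph(members).copy(), prefix + (lab,), depth + 1, seed_ + 1 + lab)

    _recurse(G, (), 1, seed)
    return hierarchy


def cluster_density(G: nx.Graph, partition: dict) -> dict:
    """Per-cluster within (W_in) and cross (W_out) mean edge weight.

    W_in averages the weights of edges joining two members; W_out averages
    edges joining a member to a non-member. A cluster with no qualifying
    edges gets density 0 and a flag.
    """
    sums: dict = {}
    for lab in set(partition.values()):
        sums[lab] = {"size": 0, "w_in": 0.0, "n_in": 0, "w_out": 0.0, "n_out": 0}
    for v, lab in partition.items():
        sums[lab]["size"] += 1
    for u, v, d in G.edges(data=True):
        w = d.get("weight", 1.0)
        cu, cv = partition[u], partition[v]
        if cu == cv:
            sums[cu]["w_in"] += w
            sums[cu]["n_in"] += 1
        else:
            for c in (cu, cv):
                sums[c]["w_out"] += w
                sums[c]["n_out"] += 1
    out = {}
    for lab, s in sums.items():
        out[lab] = {
            "size": s["size"],
            "W_in": s["w_in"] / s["n_in"] if s["n_in"] else 0.0,
            "W_out": s["w_out"] / s["n_out"] if s["n_out"] else 0.0,
            "W_in_defined": s["n_in"] > 0,
            "W_out_defined": s["n_out"] > 0,
        }
    return out
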