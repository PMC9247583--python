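"""Succession-stage / OTU bipartite network and its modularity.

Each habitat (succession stage) and each OTU is a node; an edge links OTU o
to stage h when o occurs in h, weighted by default with o's summed
per-sample relative abundance over the stage's samples.  Modularity Q is
Newman's weighted modularity on this graph treated as an ordinary weighted
graph; higher Q means OTUs compartmentalise more strongly among stages,
i.e. stronger habitat specificity at the community level.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import OtuTable

WEIGHT_MODES = ("summed_relative_abundance", "raw_count", "presence")


@dataclass
class ModularityPartition:
    community_of_node: dict
    Q: float
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        if not (-0.5 - 1e-12 <= self.Q <= 1 + 1e-12):
            raise ValueError(f"modularity {self.Q} outside [-0.5, 1]")

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of_node.values()))


def build_network(table: OtuTable, stage_of_sample: dict,
                  weight_mode: str = "summed_relative_abundance") -> nx.Graph:
    """Bipartite stage-OTU graph; nodes carry ``bipartite`` 0 (stage) / 1 (OTU).

    An edge (h, o) exists iff OTU o has nonzero abundance among stage h's
    samples; zero-weight edges are never created, so every retained node has
    degree >= 1 apart from OTUs absent everywhere (which are dropped).
    """
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    stages = sorted(set(stage_of_sample.values()))
    stage_arr = np.array([stage_of_sample[s] for s in table.sample_ids])
    G = nx.Graph()
    clash = set(stages) & set(table.otu_ids)
    if clash:
        raise ValueError(f"stage labels collide with OTU ids: {sorted(clash)}")
    G.add_nodes_from(stages, bipartite=0)
    rel = table.relative_abundance()
    for h in stages:
        mask = stage_arr == h
        if not mask.any():
            raise ValueError(f"stage {h!r} has no samples")
        if weight_mode == "summed_relative_abundance":
            w = rel[mask].sum(axis=0)
        elif weight_mode == "raw_count":
            w = table.counts[mask].sum(axis=0).astype(float)
        else:
            w = (table.counts[mask].sum(axis=0) > 0).astype(float)
        for j in np.flatnonzero(w > 0):
            o = table.otu_ids[j]
            if o not in G:
                G.add_node(o, bipartite=1)
            G.add_edge(h, o, weight=float(w[j]))
    if G.number_of_edges() == 0:
        raise ValueError("network has no edges")
    return G


def modularity_score(G: nx.Graph, partition: dict) -> float:
    """Newman weighted modularity of a node->community map.

    Q = sum_c [ L_c / m - (D_c / 2m)^2 ] with m the total edge weight,
    L_c the intra-community edge weight and D_c the summed weighted degree
    of community c.  Equals the standard (1/2m) double sum over node pairs.
    """
    if G.number_of_edges() == 0:
        raise ValueError("empty edge set")
    missing = [n for n in G if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover node(s): {missing[:5]}")
    m = G.size(weight="weight")
    L: dict = {}
    D: dict = {}
    for u, v, w in G.edges(data="weight", default=1.0):
        cu, cv = partition[u], partition[v]
        if cu == cv:
            L[cu] = L.get(cu, 0.0) + w
        D[cu] = D.get(cu, 0.0) + w
        D[cv] = D.get(cv, 0.0) + w
    return float(sum(L.get(c, 0.0) / m - (d / (2 * m)) ** 2 for c, d in D.items()))


def detect_communities(G: nx.Graph, resolution: float = 1.0,
                       seed: int = 0) -> ModularityPartition:
    """Louvain greedy modularity maximisation (seeded, reproducible).

    The reported Q is always the resolution-1 Newman modularity of the
    found partition, whatever resolution steered the search.
    """
    comms = nx.community.louvain_communities(G, weight="weight",
                                             resolution=resolution, seed=seed)
    partition = {n: ci for ci, c in enumerate(sorted(map(sorted, comms))) for n in c}
    return ModularityPartition(partition, modularity_score(G, partition),
                               resolution, seed)


def edge_list(G: nx.Graph) -> pd.DataFrame:
    """Tidy (habitat, otu, weight) frame for TSV export."""
    rows = []
    for u, v, w in G.edges(data="weight", default=1.0):
        if G.nodes[u].get("bipartite", 1) == 0:
            h, o = u, v
        else:
            h, o = v, u
        rows.append({"habitat": h, "otu_id": o, "weight": w})
    return pd.DataFrame(rows).sort_values(["habitat", "otu_id"]).reset_index(drop=True)


def write_gexf(G: nx.Graph, partition: ModularityPartition | None, path) -> None:
    """GEXF export (viewable in standard graph tools), with community ids."""
    H = G.copy()
    if partition is not None:
        nx.set_node_attributes(H, {n: int(c) for n, c in
                                   partition.community_of_node.items()}, "community")
    nx.write_gexf(H, path)
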