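"""MI-thresholded long-range residue interaction network and centralities.

An undirected graph over residues connects pairs that are far in
sequence (|i - j| > 6), spatially distant (trajectory-averaged Calpha
distance at or above a cutoff, default the 6.0 A contact cutoff — the
network deliberately keeps only non-contacting pairs so it reports
long-range information transfer, not direct packing), and strongly
coupled (corrected MI at or above a threshold, default 0.25 bits).
Edge weights are MI normalized by the largest included MI. Degree
centrality is deg(i)/(N-1); betweenness is the unnormalized shortest-
path count ratio sum over unordered pairs (hop-count paths by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from mdinfonet.fluctuation import pool_frames
from mdinfonet.infotheory import MIMatrix
from mdinfonet.trajio import Selection, Trajectory


@dataclass
class NetworkConfig:
    mi_threshold: float = 0.25
    distance_cutoff: float = 6.0        # Angstrom; edge requires D >= cutoff
    min_separation: int = 6             # edge requires |i - j| > this
    weighted_paths: bool = False        # betweenness on 1/w lengths if True

    def __post_init__(self) -> None:
        if self.mi_threshold < 0 or self.distance_cutoff <= 0 \
                or self.min_separation < 0:
            raise ValueError("invalid network configuration")


@dataclass
class DistanceMatrix:
    residue_keys: list[tuple[str, int]]
    values: np.ndarray           # (n_res, n_res) reduced over frames
    reduction: str = "mean"


def distance_matrix(ensemble: list[Trajectory] | np.ndarray,
                    sel: Selection,
                    residue_keys: list[tuple[str, int]] | None = None,
                    reduction: str = "mean") -> DistanceMatrix:
    """Trajectory-reduced pairwise Calpha distance matrix.

    Per-frame Euclidean distances are reduced over pooled frames with
    'mean' (default) or 'min'; 'stack' returns the per-frame stack.
    """
    if isinstance(ensemble, np.ndarray):
        frames = ensemble
        if residue_keys is None:
            raise ValueError("raw frames need residue keys")
    else:
        frames = pool_frames(ensemble)
        residue_keys = [ensemble[0].atoms[i].residue_key for i in sel.indices]
    sub = frames[:, sel.indices, :]
    diff = sub[:, :, None, :] - sub[:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)        # (T, n, n)
    if reduction == "mean":
        vals = d.mean(axis=0)
    elif reduction == "min":
        vals = d.min(axis=0)
    elif reduction == "stack":
        vals = d
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return DistanceMatrix(residue_keys=residue_keys, values=vals,
                          reduction=reduction)


def build_graph(mi: MIMatrix, dist: DistanceMatrix,
                cfg: NetworkConfig | None = None) -> nx.Graph:
    """Construct the long-range MI network.

    Edge (i, j) exists iff |i - j| > min_separation AND
    D_ij >= distance_cutoff AND MI_ij >= mi_threshold. Weights are
    w = MI / max(MI over included edges), so the strongest edge has
    weight 1 whenever the edge set is non-empty. Every residue is a
    node; an empty edge set is a valid (edgeless) graph.
    """
    cfg = cfg or NetworkConfig()
    if mi.residue_keys != dist.residue_keys:
        raise ValueError("MI and distance matrices cover different residues")
    n = mi.n_residues
    g = nx.Graph()
    for k, key in enumerate(mi.residue_keys):
        g.add_node(key, res_name=mi.res_names[k], index=k)
    rid = np.array([k[1] for k in mi.residue_keys])
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            v = mi.matrix[i, j]
            if np.isnan(v):
                continue
            if (abs(int(rid[i]) - int(rid[j])) > cfg.min_separation
                    and dist.values[i, j] >= cfg.distance_cutoff
                    and v >= cfg.mi_threshold):
                edges.append((i, j, float(v)))
    if edges:
        mi_max = max(e[2] for e in edges)
        for i, j, v in edges:
            g.add_edge(mi.residue_keys[i], mi.residue_keys[j],
                       mi=v, weight=v / mi_max)
    return g


def degree_centrality(graph: nx.Graph) -> pd.DataFrame:
    """C_D(i) = deg(i)/(N - 1) with N = |V| (0 for N <= 1)."""
    n = graph.number_of_nodes()
    cd = {v: (graph.degree(v) / (n - 1) if n > 1 else 0.0)
          for v in graph.nodes}
    return _node_table(graph, cd, "degree_centrality")


def betweenness_centrality(graph: nx.Graph) -> pd.DataFrame:
    """C_B(i) = sum over unordered pairs s != i != t of
    sigma_st(i)/sigma_st, on hop-count shortest paths (unnormalized, as
    the formula is stated); disconnected graphs are handled per
    component. Set NetworkConfig.weighted_paths upstream and pass
    weighted=True here to use 1/w edge lengths instead.
    """
    cb = nx.betweenness_centrality(graph, normalized=False)
    return _node_table(graph, cb, "betweenness_centrality")


def betweenness_centrality_weighted(graph: nx.Graph) -> pd.DataFrame:
    """Weighted variant: shortest paths on 1/w edge lengths."""
    for u, v, d in graph.edges(data=True):
        d["_len"] = 1.0 / d["weight"]
    cb = nx.betweenness_centrality(graph, normalized=False, weight="_len")
    return _node_table(graph, cb, "betweenness_centrality")


def _node_table(graph: nx.Graph, values: dict, col: str) -> pd.DataFrame:
    nodes = list(graph.nodes)
    residue_keyed = all(isinstance(k, tuple) and len(k) == 2 for k in nodes)
    return pd.DataFrame({
        "chain": [k[0] if residue_keyed else "" for k in nodes],
        "res_id": [k[1] if residue_keyed else k for k in nodes],
        col: [values[k] for k in nodes],
    })


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [{
        "res_i": f"{u[0]}:{u[1]}", "res_j": f"{v[0]}:{v[1]}",
        "mi_bits": d["mi"], "weight": d["weight"],
    } for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["res_i", "res_j", "mi_bits", "weight"])
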