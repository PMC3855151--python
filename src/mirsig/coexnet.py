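"""Per-group Pearson coexpression networks and their comparison.

For each miRNA pair within one clinical group, the Pearson correlation
of log10 expression is computed on pairwise-complete samples; pairs
with r >= 0.79 and two-sided p < 0.02 (the published construction
thresholds) become edges of an undirected weighted graph whose node set
is the endpoints of surviving edges.  Subnetworks are seeded by the
PCR-validated miRNAs plus their first neighbors, and edge sets of the
two group networks are compared as unordered pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.79
DEFAULT_P_MAX = 0.02


def pairwise_pearson(
    log10_expr: pd.DataFrame, min_overlap: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and two-sided p for a (miRNA x sample) matrix.

    Uses pairwise-complete observations; pairs with fewer than
    ``min_overlap`` shared samples (or zero variance) are missing.
    p comes from t = r*sqrt((m-2)/(1-r^2)) on m-2 degrees of freedom.
    Diagonal is excluded (NaN).
    """
    if log10_expr.shape[1] < 3:
        raise ValueError("need at least 3 samples in the group")
    r = log10_expr.T.corr(method="pearson", min_periods=min_overlap)
    notna = log10_expr.notna().to_numpy(dtype=float)
    m = pd.DataFrame(notna @ notna.T, index=log10_expr.index, columns=log10_expr.index)
    rv = r.to_numpy(dtype=float)
    mv = m.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((mv - 2.0) / (1.0 - rv**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(mv - 2.0, 1.0))
    p = np.where(np.isclose(np.abs(rv), 1.0), 0.0, p)
    p = np.where(np.isnan(rv) | (mv < min_overlap), np.nan, p)
    np.fill_diagonal(rv, np.nan)
    np.fill_diagonal(p, np.nan)
    idx = log10_expr.index
    return (
        pd.DataFrame(rv, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        m,
    )


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
    use_abs: bool = False,
    group: str | None = None,
) -> nx.Graph:
    """Threshold the correlation matrices into an undirected weighted graph.

    Edge iff r >= r_min (or |r| >= r_min with ``use_abs``) and p < p_max;
    the published rule keeps positive correlations only.  Nodes are the
    endpoints of surviving edges (degree >= 1).
    """
    if not r.index.equals(p.index) or not r.columns.equals(p.columns):
        raise ValueError("r and p matrices are not aligned")
    g = nx.Graph(group=group)
    ids = list(r.index)
    rv, pv = r.to_numpy(), p.to_numpy()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            rij, pij = rv[i, j], pv[i, j]
            if np.isnan(rij) or np.isnan(pij):
                continue
            mag_ok = abs(rij) >= r_min if use_abs else rij >= r_min
            if mag_ok and pij < p_max:
                g.add_edge(ids[i], ids[j], r=float(rij), p=float(pij))
    return g


def group_network(
    log10_expr: pd.DataFrame,
    sample_ids: list[str],
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
    use_abs: bool = False,
    group: str | None = None,
    min_overlap: int = 3,
) -> nx.Graph:
    """Convenience: restrict to one group's samples and build its network."""
    r, p, _ = pairwise_pearson(log10_expr[sample_ids], min_overlap=min_overlap)
    return build_network(r, p, r_min=r_min, p_max=p_max, use_abs=use_abs, group=group)


def first_neighbor_subnetwork(net: nx.Graph, seeds) -> nx.Graph:
    """Induced subgraph on the present seeds plus their direct neighbors."""
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    present = seeds & set(net.nodes)
    absent = sorted(seeds - present)
    if absent:
        logger.info("seed miRNA(s) absent from network: %s", absent)
    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    return net.subgraph(nodes).copy()


@dataclass
class NetworkComparison:
    shared_edges: set[tuple[str, str]]
    unique_to_a: set[tuple[str, str]]
    unique_to_b: set[tuple[str, str]]
    shared_nodes: set[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_edges)

    def summary(self) -> dict:
        return {
            "shared_edges": len(self.shared_edges),
            "unique_to_a": len(self.unique_to_a),
            "unique_to_b": len(self.unique_to_b),
            "shared_nodes": len(self.shared_nodes),
        }


def _edge_set(g: nx.Graph) -> set[tuple[str, str]]:
    return {tuple(sorted(e)) for e in g.edges}


def compare_networks(a: nx.Graph, b: nx.Graph) -> NetworkComparison:
    """Set operations on unordered edge pairs; weights ignored for membership."""
    ea, eb = _edge_set(a), _edge_set(b)
    return NetworkComparison(
        shared_edges=ea & eb,
        unique_to_a=ea - eb,
        unique_to_b=eb - ea,
        shared_nodes=set(a.nodes) & set(b.nodes),
    )


def export_network(net: nx.Graph, fmt: str, path) -> None:
    """Write a Cytoscape-readable file: 'sif', 'graphml' or edge-list 'tsv'.

    Edges are emitted in lexicographic order for reproducible diffs.
    """
    edges = sorted(_edge_set(net))
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b in edges:
                fh.write(f"{a}\tcoexp\t{b}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(sorted(net.nodes))
        for a, b in edges:
            g.add_edge(a, b, **net.edges[a, b])
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tr\tp\n")
            for a, b in edges:
                attrs = net.edges[a, b]
                fh.write(f"{a}\t{b}\t{attrs.get('r', '')}\t{attrs.get('p', '')}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; use sif, graphml or tsv")
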