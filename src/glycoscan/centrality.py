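"""Node centralities of the pathway graph and their association with
selection signals.

Five centralities are computed per gene: node degree, eccentricity,
closeness, betweenness and centroid. Eccentricity and closeness follow the
CentiScaPe reciprocal convention by default (1 / max distance and
1 / total distance, so larger = more central); a convention flag exposes the
classical definitions. Betweenness sums sigma_st(v) / sigma_st over
unordered endpoint pairs excluding v, unnormalized. Centroid(v) is
min over w != v of gamma_v(w) - gamma_w(v), where gamma_v(w) counts vertices
strictly closer to v than to w (ties count for neither; the census ranges
over all vertices including v and w).

Association with a significant-gene set is a Mann-Whitney test per
centrality (group 1 = non-significant, group 2 = significant) with a
Bonferroni flag over the five centralities.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import GlycoscanError, PathwayGraph
from .pathway import MannWhitneyResult, mann_whitney

CENTRALITIES = ("degree", "eccentricity_c", "closeness_c", "betweenness", "centroid")


def shortest_path_distances(graph: PathwayGraph | nx.Graph) -> pd.DataFrame:
    """All-pairs BFS unit-weight distances; inf for disconnected pairs."""
    g = graph.graph if isinstance(graph, PathwayGraph) else graph
    nodes = list(g.nodes)
    dist = pd.DataFrame(np.inf, index=nodes, columns=nodes)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            dist.loc[src, dst] = float(d)
    return dist


def compute_centralities(
    graph: PathwayGraph | nx.Graph, convention: str = "centiscape"
) -> pd.DataFrame:
    """The five per-gene centrality values.

    On a disconnected graph, eccentricity/closeness/centroid are computed
    within each connected component (with a warning); betweenness is global.
    """
    if convention not in ("centiscape", "classical"):
        raise GlycoscanError(f"unknown convention {convention!r}")
    g = graph.graph if isinstance(graph, PathwayGraph) else graph
    if g.number_of_nodes() == 0:
        raise GlycoscanError("empty graph")
    if not nx.is_connected(g):
        warnings.warn("graph is disconnected; distance centralities computed per component")

    dist = shortest_path_distances(g)
    D = dist.to_numpy()
    nodes = list(dist.index)
    n = len(nodes)
    degree = np.array([g.degree(v) for v in nodes], dtype=float)

    ecc = np.empty(n)
    clo = np.empty(n)
    for i in range(n):
        finite = np.isfinite(D[i]) & (np.arange(n) != i)
        if not finite.any():
            ecc[i] = np.nan
            clo[i] = np.nan
            continue
        e = D[i, finite].max()
        s = D[i, finite].sum()
        ecc[i] = 1.0 / e if convention == "centiscape" else e
        clo[i] = 1.0 / s if convention == "centiscape" else s

    btw_map = nx.betweenness_centrality(g, normalized=False)
    btw = np.array([btw_map[v] for v in nodes])

    centroid = np.empty(n)
    for i in range(n):
        comp = np.isfinite(D[i])
        others = [j for j in range(n) if j != i and comp[j]]
        if not others:
            centroid[i] = np.nan
            continue
        best = None
        for j in others:
            # census over every vertex of the component, v and w included
            gamma_vw = int(np.sum(D[comp, i] < D[comp, j]))
            gamma_wv = int(np.sum(D[comp, j] < D[comp, i]))
            f = gamma_vw - gamma_wv
            best = f if best is None else min(best, f)
        centroid[i] = best

    return pd.DataFrame(
        {
            "gene_id": nodes,
            "degree": degree.astype(int),
            "eccentricity_c": ecc,
            "closeness_c": clo,
            "betweenness": btw,
            "centroid": centroid,
        }
    )


def centrality_association(
    table: pd.DataFrame, significant_gene_set: set[str], n_tests: int = 5, alpha: float = 0.05
) -> pd.DataFrame:
    """Mann-Whitney association of each centrality with the significance call.

    Group 1 holds the non-significant genes, group 2 the significant ones;
    the ``bonferroni_significant`` column flags tests with p x n_tests <= alpha.
    """
    sig_mask = table["gene_id"].isin(significant_gene_set).to_numpy()
    if sig_mask.all() or not sig_mask.any():
        raise GlycoscanError("both significance groups must be non-empty")
    rows = []
    for cent in CENTRALITIES:
        v = table[cent].to_numpy(dtype=float)
        res = mann_whitney(v[~sig_mask], v[sig_mask])
        rows.append(
            {
                "centrality": cent,
                "n1": res.n1,
                "n2": res.n2,
                "rank_sum_1": res.rank_sum_1,
                "rank_sum_2": res.rank_sum_2,
                "u": res.u,
                "z": res.z,
                "p_two_sided": res.p_two_sided,
                "bonferroni_significant": res.p_two_sided * n_tests <= alpha,
            }
        )
    return pd.DataFrame(rows)
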