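"""Thresholded correlation networks over stroma-associates.

Edges are all-pairs Pearson correlations among the associate genes kept
when |r| >= r_min and p < alpha; the sign is retained as an attribute but
the topology is unweighted. Node influence is ranked by closeness
centrality with Wasserman-Faust component scaling,

    C(v) = (|R(v)| / (n - 1)) * (|R(v)| / sum_{u in R(v)} d(v, u)),

where R(v) is the set of nodes reachable from v (isolates score 0), so
values remain comparable across disconnected components. A weighted
variant (shortest paths over distance 1 - |r|) is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dgecorr import pearson_with_p
from .formats import ExpressionMatrix
from .scoring import _frame_samples_by_genes

log = logging.getLogger(__name__)


def pairwise_pearson(values: np.ndarray):
    """All-pairs Pearson r (genes x samples input) with two-sided t-based
    p-values. Rows with zero variance get NaN against every partner."""
    g, n = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    xc = values - values.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc ** 2).sum(axis=1))
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ xc.T) / np.outer(sd, sd)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    from scipy import stats
    p = np.where(np.isnan(r), np.nan,
                 np.where(np.abs(r) >= 1.0, 0.0,
                          2.0 * stats.t.sf(np.abs(t), n - 2)))
    return r, p


class CorrelationNetwork(BaseEstimator):
    """Build and rank a thresholded Pearson network.

    Parameters
    ----------
    r_min
        Minimum |r| for an edge (inclusive). 0.6 is the bulk convention,
        0.2 the single-cell one.
    alpha
        Edge p-value cutoff (strict).
    weighted_closeness
        If True, closeness uses shortest paths over distance 1 - |r|
        instead of the unweighted thresholded topology.

    ``fit(X)`` takes samples x genes expression over the associate genes;
    fitted attributes are ``graph_`` (networkx Graph with r/p/sign edge
    attributes), ``edges_`` (DataFrame) and ``closeness_`` (Series).
    """

    def __init__(self, r_min: float = 0.6, alpha: float = 0.05,
                 weighted_closeness: bool = False):
        self.r_min = r_min
        self.alpha = alpha
        self.weighted_closeness = weighted_closeness

    def fit(self, X, y=None):
        X = _frame_samples_by_genes(X)
        genes = list(X.columns)
        if len(genes) < 2:
            raise ValueError("need at least 2 genes to build a network")
        vals = X.to_numpy(dtype=float).T  # genes x samples
        r, p = pairwise_pearson(vals)
        constant = [g for g, sd in zip(genes, vals.std(axis=1)) if sd == 0]
        if constant:
            log.info("constant genes kept as isolated nodes: %s", constant)

        G = nx.Graph()
        G.add_nodes_from(genes)
        rows = []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                rij, pij = r[i, j], p[i, j]
                if np.isnan(rij):
                    continue
                if abs(rij) >= self.r_min and pij < self.alpha:
                    sign = "negative" if rij < 0 else "positive"
                    G.add_edge(genes[i], genes[j], r=float(rij),
                               p=float(pij), sign=sign,
                               distance=float(1.0 - abs(rij)))
                    rows.append({"gene1": genes[i], "gene2": genes[j],
                                 "r": float(rij), "p": float(pij),
                                 "sign": sign})
        self.graph_ = G
        self.edges_ = pd.DataFrame(rows,
                                   columns=["gene1", "gene2", "r", "p", "sign"])
        dist = "distance" if self.weighted_closeness else None
        self.closeness_ = pd.Series(
            nx.closeness_centrality(G, distance=dist, wf_improved=True),
            name="closeness").reindex(genes)
        nx.set_node_attributes(G, self.closeness_.to_dict(), "closeness")
        return self


def build_network(mat: ExpressionMatrix,
                  genes: Sequence[str] | pd.DataFrame,
                  r_min: float, alpha: float = 0.05,
                  node_attrs: Mapping[str, Mapping[str, str]] | None = None,
                  weighted_closeness: bool = False) -> nx.Graph:
    """Thresholded Pearson network over the given associate genes.

    ``genes`` may be a list or an associate table (index = gene, columns
    including ``class``/``role``, copied onto the nodes). Genes absent from
    the matrix are ignored; fewer than two usable genes is an error.
    """
    attrs: dict[str, dict[str, str]] = {}
    if isinstance(genes, pd.DataFrame):
        for g, row in genes.iterrows():
            attrs[g] = {k: row[k] for k in ("class", "role") if k in genes.columns}
        gene_list = list(genes.index)
    else:
        gene_list = list(genes)
    if node_attrs:
        for g, a in node_attrs.items():
            attrs.setdefault(g, {}).update(a)
    present = [g for g in gene_list if g in set(mat.genes)]
    if len(present) < 2:
        raise ValueError("fewer than 2 associate genes present in the matrix")
    est = CorrelationNetwork(r_min=r_min, alpha=alpha,
                             weighted_closeness=weighted_closeness)
    est.fit(mat.values.loc[present].T)
    G = est.graph_
    for g, a in attrs.items():
        if g in G:
            G.nodes[g].update(a)
    return G


def closeness(net: nx.Graph, weighted: bool = False) -> pd.Series:
    """Per-node closeness centrality (Wasserman-Faust scaled; isolates 0)."""
    dist = "distance" if weighted else None
    return pd.Series(nx.closeness_centrality(net, distance=dist,
                                             wf_improved=True),
                     name="closeness")


def export_edgelist(net: nx.Graph, path) -> None:
    rows = [{"gene1": u, "gene2": v, **d} for u, v, d in net.edges(data=True)]
    df = pd.DataFrame(rows, columns=["gene1", "gene2", "r", "p", "sign"])
    df.to_csv(path, sep="\t", index=False)


def export_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
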