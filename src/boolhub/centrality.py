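"""Seven graph-centrality metrics for implication networks.

For a network G(N, E) with adjacency matrix A:

* degree: ``C_Din(i) = in-neighbors/(N-1)``, ``C_Dout(i) =
  out-neighbors/(N-1)``, ``C_D = C_Din + C_Dout``;
* eigenvector: the principal eigenpair ``A^T x = lambda x`` found by
  power iteration -- a node's score sums the scores of its in-neighbors,
  so regulated genes inherit importance from their regulators (for a
  symmetric network this is the ordinary eigenvector centrality);
* betweenness: shortest-path pair counts normalized by
  ``2/((N-1)(N-2))`` (symmetric) or ``1/((N-1)(N-2))`` (directed);
* closeness: ``((R_i-1)/(N-1)) * (R_i-1)/sum_j d_ij`` over the set
  reachable from i (the Wasserman-Faust component scaling; reduces to
  the classical ``(N-1)/sum d_ij`` on connected networks);
* VoteRank: iterative vote-and-deplete influential-node selection; the
  output is a rank, 1 = most important, ties allowed.

Degree, betweenness and closeness are delegated to networkx; the
eigenvector power iteration and VoteRank rounds are implemented here so
their conventions (left eigenvector, L2 normalization, deterministic
lexicographic tie-breaks, shared trailing ranks) are explicit.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from boolhub.errors import ConvergenceError, DataError
from boolhub.implication_net import ImplicationNetwork

logger = logging.getLogger(__name__)

METRICS: tuple[str, ...] = (
    "c_degree", "c_in", "c_out", "c_eigen", "c_between", "c_close", "c_voterank",
)

#: Metrics where a larger value means more central; VoteRank is a rank
#: (smaller = more important) and is the one exception.
ASCENDING_METRICS: frozenset = frozenset({"c_voterank"})


def _nodes(net: ImplicationNetwork) -> list[str]:
    return list(net.graph.nodes)


def degree_centralities(net: ImplicationNetwork) -> pd.DataFrame:
    """Normalized in-, out- and total degree per gene.

    In- and out-degree are each divided by N-1 (the maximum possible
    neighbor count); total degree is their sum, so it ranges up to 2 in
    a symmetric network.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise DataError("degree centrality needs at least 2 nodes")
    nodes = _nodes(net)
    c_in = np.array([g.in_degree(v) for v in nodes], dtype=float) / (n - 1)
    c_out = np.array([g.out_degree(v) for v in nodes], dtype=float) / (n - 1)
    return pd.DataFrame(
        {"c_in": c_in, "c_out": c_out, "c_degree": c_in + c_out},
        index=pd.Index(nodes, name="gene"),
    )


def eigenvector_centrality(
    net: ImplicationNetwork, tol: float = 1e-10, max_iter: int = 1000
) -> pd.Series:
    """Principal left eigenvector of the adjacency matrix, L2-normalized.

    Power iteration starts from the all-ones vector and repeatedly
    applies ``x <- (A^T + I) x`` (the identity shift breaks the period-2
    oscillation of bipartite graphs without changing the eigenvectors),
    normalizing each step, until the sup-norm change drops below ``tol``.
    Edgeless networks return all zeros.
    """
    g = net.graph
    nodes = _nodes(net)
    if g.number_of_edges() == 0:
        return pd.Series(0.0, index=pd.Index(nodes, name="gene"), name="c_eigen")
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float, format="csr")
    at = a.T.tocsr()
    x = np.ones(len(nodes))
    x /= np.linalg.norm(x)
    for it in range(1, max_iter + 1):
        x_new = x + at @ x
        norm = np.linalg.norm(x_new)
        if norm == 0:
            raise ConvergenceError("eigenvector iteration collapsed to zero")
        x_new /= norm
        resid = np.abs(x_new - x).max()
        x = x_new
        if resid < tol:
            return pd.Series(x, index=pd.Index(nodes, name="gene"), name="c_eigen")
    raise ConvergenceError(
        f"eigenvector centrality did not converge in {max_iter} iterations "
        f"(sup-norm residual {resid:.3e})"
    )


def _analysis_graph(net: ImplicationNetwork) -> nx.Graph | nx.DiGraph:
    """Undirected view for symmetric networks, the digraph otherwise."""
    return net.graph.to_undirected() if net.symmetric else net.graph


def betweenness_centrality(net: ImplicationNetwork) -> pd.Series:
    """Shortest-path betweenness, pair-normalized.

    Symmetric networks use the factor ``2/((N-1)(N-2))`` over unordered
    pairs; directed networks ``1/((N-1)(N-2))`` over ordered pairs.
    Pairs with no connecting path contribute nothing.
    """
    if net.n_nodes < 3:
        raise DataError("betweenness centrality needs at least 3 nodes")
    bc = nx.betweenness_centrality(_analysis_graph(net), normalized=True)
    nodes = _nodes(net)
    return pd.Series(
        [bc[v] for v in nodes], index=pd.Index(nodes, name="gene"), name="c_between"
    )


def closeness_centrality(net: ImplicationNetwork) -> pd.Series:
    """Component-scaled closeness over outgoing distances.

    ``C_C(i) = ((R_i - 1)/(N - 1)) * (R_i - 1)/sum_j d_ij`` where R_i is
    the number of nodes reachable from i.  On a connected network this
    is exactly the classical inverse-average-distance closeness;
    isolated nodes score 0.
    """
    if net.n_nodes < 2:
        raise DataError("closeness centrality needs at least 2 nodes")
    g = _analysis_graph(net)
    # networkx measures incoming distance; reverse to follow edges outward.
    cc = nx.closeness_centrality(g.reverse() if g.is_directed() else g)
    nodes = _nodes(net)
    return pd.Series(
        [cc[v] for v in nodes], index=pd.Index(nodes, name="gene"), name="c_close"
    )


def voterank(net: ImplicationNetwork) -> pd.Series:
    """VoteRank: iterative influential-node ranks (1 = most important).

    Every node starts with voting ability VA = 1.  Each round the voting
    score of an unranked node is the summed VA of its in-neighbors; the
    highest scorer (ties broken by smallest gene id) takes the next
    rank, its VA drops to 0, it stops being scored, and the VA of each
    of its out-neighbors decreases by ``1/<k>`` (floored at 0), where
    ``<k>`` is the mean degree: ``2E/N`` for symmetric networks counting
    undirected edges, ``E/N`` for directed.  Selection stops when the
    best remaining score is 0; all remaining nodes share the next rank.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    series = pd.Series(1, index=pd.Index(_nodes(net), name="gene"), name="c_voterank")
    if g.number_of_edges() == 0:
        logger.warning("voterank: edgeless network; all nodes tied at rank 1")
        return series
    mean_k = 2.0 * net.edge_count / n if net.symmetric else net.edge_count / n
    delta = 1.0 / mean_k
    va = {v: 1.0 for v in nodes}
    rank: dict[str, int] = {}
    next_rank = 1
    unranked = set(nodes)
    while unranked:
        best_v, best_vs = None, 0.0
        for v in nodes:  # lexicographic order makes ties deterministic
            if v not in unranked:
                continue
            vs = sum(va[u] for u in g.predecessors(v) if u not in rank)
            if vs > best_vs + 1e-12:
                best_v, best_vs = v, vs
        if best_v is None:  # max VS == 0: nobody left worth electing
            break
        rank[best_v] = next_rank
        next_rank += 1
        unranked.discard(best_v)
        va[best_v] = 0.0
        for u in g.successors(best_v):
            va[u] = max(0.0, va[u] - delta)
    for v in unranked:
        rank[v] = next_rank
    series.update(pd.Series(rank))
    return series.astype(int)


def centrality_table(net: ImplicationNetwork) -> pd.DataFrame:
    """All seven metrics per gene, with N and E recorded in ``attrs``.

    Networks too small for a metric's definition (fewer than 3 nodes for
    betweenness) propagate that metric's error.
    """
    deg = degree_centralities(net)
    table = pd.DataFrame(
        {
            "c_degree": deg["c_degree"],
            "c_in": deg["c_in"],
            "c_out": deg["c_out"],
            "c_eigen": eigenvector_centrality(net),
            "c_between": betweenness_centrality(net),
            "c_close": closeness_centrality(net),
            "c_voterank": voterank(net),
        }
    )
    table.attrs["N"] = net.n_nodes
    table.attrs["E"] = net.edge_count
    table.attrs["layer_pair"] = net.layer_pair
    return table
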