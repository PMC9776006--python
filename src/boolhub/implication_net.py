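"""Boolean implication rule mining and network assembly.

For an ordered gene pair (A, B) and a state pair (a, b) with a, b in
{-1, 1}, the rule "A = a implies B = b" is scored by

* scope      = n_a / n, the fraction of samples where the antecedent holds;
* precision  = P(B = b | A = a), estimated from co-occurrence counts;
* baseline   = P(B = b), the consequent's marginal;
* z          = (precision - baseline) / sqrt(baseline*(1-baseline)/n_a),

a one-proportion one-tailed z statistic of the precision against the
marginal.  A rule is emitted iff ``n_a > 0``, ``0 < baseline < 1``,
``scope >= scope_min`` and ``z >= z_min`` (default 1.64, one-tailed
p < 0.05).  All significant rules for the same ordered gene pair --
concordant (1,1)/(-1,-1) and discordant (1,-1)/(-1,1) alike -- merge
into a single directed edge, so rule multiplicity never creates
parallel edges.

Same-level networks (CNV-CNV, mRNA and protein co-expression) are
symmetrized; cross-level networks (CNV -> mRNA, mRNA -> protein) direct
edges from the mediating layer's gene to the mediated layer's gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from boolhub.errors import DataError

STATE_PAIRS: tuple[tuple[int, int], ...] = ((1, 1), (-1, -1), (1, -1), (-1, 1))

#: layer_pair -> whether the network relates a layer to itself.
LAYER_PAIRS: dict[str, bool] = {
    "cnv-cnv": True,
    "cnv-mrna": False,
    "mrna-mrna": True,
    "mrna-protein": False,
    "protein-protein": True,
}


class ImplicationRule(NamedTuple):
    """A single significant Boolean implication rule."""

    antecedent: tuple[str, int]
    consequent: tuple[str, int]
    n: int
    n_a: int
    scope: float
    precision: float
    baseline: float
    z: float


def default_scope_min(n: int) -> float:
    """Default scope threshold: at least 10% of samples and >= 5 samples."""
    return max(0.1, 5.0 / n)


def _check_matrices(ante: pd.DataFrame, cons: pd.DataFrame) -> None:
    if ante.size == 0 or cons.size == 0:
        raise DataError("empty matrix passed to rule mining")
    if list(ante.columns) != list(cons.columns):
        raise DataError(
            "antecedent and consequent matrices must share an identical "
            "ordered sample set"
        )


def _state_masks(m: pd.DataFrame) -> dict[int, np.ndarray]:
    vals = m.to_numpy()
    return {s: vals == s for s in (1, -1)}


def _iter_pair_stats(
    ante: pd.DataFrame,
    cons: pd.DataFrame,
    z_min: float,
    scope_min: float | None,
):
    """Yield per-state-pair vectorized statistics and emission masks.

    Yields ``(a, b, n_a, p0, precision, z, emit, evaluated)`` where the
    matrix-shaped arrays are (genes_ante x genes_cons); same-gene pairs
    are always excluded (networks carry no self-edges).
    """
    _check_matrices(ante, cons)
    if z_min <= 0:
        raise DataError("z_min must be > 0")
    n = ante.shape[1]
    if scope_min is None:
        scope_min = default_scope_min(n)
    ante_masks = _state_masks(ante)
    cons_masks = _state_masks(cons)
    same = (
        ante.index.to_numpy()[:, None] == cons.index.to_numpy()[None, :]
    )
    for a, b in STATE_PAIRS:
        ia = ante_masks[a]
        ib = cons_masks[b]
        n_a = ia.sum(axis=1)
        n_b = ib.sum(axis=1)
        p0 = n_b / n
        joint = ia.astype(np.float64) @ ib.T.astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            precision = joint / n_a[:, None]
            z = (precision - p0[None, :]) / np.sqrt(
                p0 * (1.0 - p0) / n_a[:, None]
            )
        evaluated = (
            (n_a[:, None] > 0)
            & (n_b[None, :] > 0)
            & (n_b[None, :] < n)
            & ((n_a / n)[:, None] >= scope_min)
            & ~same
        )
        emit = evaluated & (z >= z_min)
        yield a, b, n_a, p0, precision, z, emit, evaluated


def mine_rules(
    ante: pd.DataFrame,
    cons: pd.DataFrame,
    z_min: float = 1.64,
    scope_min: float | None = None,
) -> list[ImplicationRule]:
    """Mine all significant implication rules between two ternary matrices.

    ``ante`` and ``cons`` are gene x sample ternary matrices over an
    identical ordered sample set (they may be the same matrix for
    same-level mining).  ``scope_min`` defaults to
    ``max(0.1, 5/n_samples)``.  Ordered pairs with identical gene ids
    are never tested.
    """
    n = ante.shape[1]
    a_genes = ante.index.to_numpy()
    c_genes = cons.index.to_numpy()
    rules: list[ImplicationRule] = []
    for a, b, n_a, p0, precision, z, emit, _ in _iter_pair_stats(
        ante, cons, z_min, scope_min
    ):
        for i, j in np.argwhere(emit):
            rules.append(
                ImplicationRule(
                    antecedent=(a_genes[i], a),
                    consequent=(c_genes[j], b),
                    n=n,
                    n_a=int(n_a[i]),
                    scope=n_a[i] / n,
                    precision=float(precision[i, j]),
                    baseline=float(p0[j]),
                    z=float(z[i, j]),
                )
            )
    return rules


class EdgeRateStats(NamedTuple):
    n_edges: int       # ordered pairs with >= 1 significant rule
    n_pairs: int       # all ordered pairs subjected to mining (A != B)
    n_evaluated: int   # pairs where >= 1 state-pair test met its preconditions

    @property
    def edge_rate(self) -> float:
        """Edges per ordered pair tested -- the null-calibration quantity."""
        return self.n_edges / self.n_pairs


def edge_rate_stats(
    ante: pd.DataFrame,
    cons: pd.DataFrame,
    z_min: float = 1.64,
    scope_min: float | None = None,
) -> EdgeRateStats:
    """Edge-rate summary over all ordered gene pairs.

    Every ordered pair is tested by the mining procedure; pairs whose
    four state-pair tests all fail their preconditions (antecedent never
    observed, uninformative baseline, scope below threshold) simply
    yield no rule.  On independent-noise input the edge rate is bounded
    by the summed levels of the per-pair significance tests.
    """
    tested = None
    edge = None
    for *_, emit, evaluated in _iter_pair_stats(ante, cons, z_min, scope_min):
        tested = evaluated if tested is None else (tested | evaluated)
        edge = emit if edge is None else (edge | emit)
    same = ante.index.to_numpy()[:, None] == cons.index.to_numpy()[None, :]
    n_pairs = int((~same).sum())
    return EdgeRateStats(int(edge.sum()), n_pairs, int(tested.sum()))


@dataclass
class ImplicationNetwork:
    """A directed gene network with merged implication-rule edges."""

    graph: nx.DiGraph
    layer_pair: str
    symmetric: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_directed_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edge_count(self) -> int:
        """Association count: undirected edges if symmetric, else directed."""
        m = self.graph.number_of_edges()
        return m // 2 if self.symmetric else m

    def adjacency(self) -> pd.DataFrame:
        a = nx.to_numpy_array(self.graph, nodelist=self.genes, dtype=np.int8)
        return pd.DataFrame(a, index=self.genes, columns=self.genes)


def merge_rules_to_edges(
    rules: Iterable[ImplicationRule],
    genes: Iterable[str] | None = None,
    layer_pair: str = "mrna-mrna",
    symmetric: bool = False,
) -> ImplicationNetwork:
    """Merge rules into one directed edge per ordered gene pair.

    Each edge carries the set of supporting state pairs and the
    statistics of its strongest rule.  ``genes`` fixes the node universe
    (so rule-free genes remain isolated nodes); it defaults to the genes
    referenced by the rules.
    """
    g = nx.DiGraph()
    if genes is not None:
        g.add_nodes_from(genes)
    for r in rules:
        u, a = r.antecedent
        v, b = r.consequent
        if u == v:
            raise DataError(f"self-implication rule for gene {u!r}")
        if genes is None:
            g.add_node(u)
            g.add_node(v)
        if g.has_edge(u, v):
            d = g[u][v]
            d["rule_types"] = tuple(sorted(set(d["rule_types"]) | {(a, b)}))
            if r.z > d["max_z"]:
                d.update(max_z=r.z, scope=r.scope, precision=r.precision)
        else:
            g.add_edge(
                u, v,
                rule_types=((a, b),),
                max_z=r.z,
                scope=r.scope,
                precision=r.precision,
            )
    return ImplicationNetwork(graph=g, layer_pair=layer_pair, symmetric=symmetric)


def _symmetrize(g: nx.DiGraph) -> None:
    for u, v, d in list(g.edges(data=True)):
        if not g.has_edge(v, u):
            g.add_edge(v, u, **dict(d))


def build_network(
    layer_pair: str,
    ante: pd.DataFrame,
    cons: pd.DataFrame | None = None,
    z_min: float = 1.64,
    scope_min: float | None = None,
    symmetrize: bool | None = None,
) -> ImplicationNetwork:
    """Mine rules and assemble the network for one layer pair.

    Same-level pairs (``cnv-cnv``, ``mrna-mrna``, ``protein-protein``)
    take a single matrix and are symmetrized by default (a reciprocal
    edge is added whenever either direction is significant).  Cross-level
    pairs (``cnv-mrna``, ``mrna-protein``) take the mediating layer's
    matrix as ``ante`` and the mediated layer's as ``cons``; edges run
    mediator -> mediated.
    """
    if layer_pair not in LAYER_PAIRS:
        raise DataError(
            f"unknown layer_pair {layer_pair!r}; expected one of {sorted(LAYER_PAIRS)}"
        )
    same_level = LAYER_PAIRS[layer_pair]
    if same_level:
        if cons is not None and cons is not ante:
            raise DataError(f"{layer_pair!r} is same-level: pass a single matrix")
        cons = ante
    elif cons is None:
        raise DataError(f"{layer_pair!r} is cross-level: pass ante and cons matrices")
    if symmetrize is None:
        symmetrize = same_level
    rules = mine_rules(ante, cons, z_min=z_min, scope_min=scope_min)
    universe = list(ante.index)
    universe += [g for g in cons.index if g not in set(universe)]
    net = merge_rules_to_edges(
        rules, genes=universe, layer_pair=layer_pair, symmetric=symmetrize
    )
    if symmetrize:
        _symmetrize(net.graph)
    return net
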