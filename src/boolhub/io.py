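"""Tab-separated file formats for matrices, networks and result tables.

All matrices are written genes-as-rows with a ``gene`` id column and a
header row of sample ids.  Gene identifiers are opaque strings; values
are checked on read (duplicate ids, non-numeric entries, out-of-set
ternary states).  Edge lists carry the supporting rule types and the
strongest rule's statistics; GraphML export is available for graph
tools.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from boolhub.errors import DataError
from boolhub.implication_net import ImplicationNetwork

TERNARY = {-1, 0, 1}


def read_matrix(path: str | Path, kind: str = "continuous") -> pd.DataFrame:
    """Read a gene x sample matrix (``kind``: 'ternary' or 'continuous').

    Continuous matrices may contain ``NA`` (masked as missing); ternary
    matrices must hold only -1/0/1.  Duplicate gene ids are an error
    reported with their line numbers.
    """
    if kind not in ("ternary", "continuous"):
        raise DataError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    df.index.name = "gene"
    dup = df.index.duplicated(keep=False)
    if dup.any():
        lines = [i + 2 for i in np.flatnonzero(dup)]  # +1 header, +1 1-based
        raise DataError(
            f"duplicate gene id(s) {sorted(set(df.index[dup]))[:5]} at line(s) {lines[:5]}"
        )
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric value in matrix {path}: {exc}") from exc
    if kind == "ternary":
        if np.isnan(vals).any():
            raise DataError(f"ternary matrix {path} contains missing values")
        if not np.isin(vals, list(TERNARY)).all():
            i, j = np.argwhere(~np.isin(vals, list(TERNARY)))[0]
            raise DataError(
                f"ternary matrix {path} has value {vals[i, j]!r} at "
                f"(gene {df.index[i]!r}, sample {df.columns[j]!r})"
            )
        return df.astype(np.int8)
    return df.astype(float)


def write_matrix(m: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample matrix as canonical TSV (round-trip stable)."""
    out = m.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_sample_annotation(groups: dict[str, str], path: str | Path) -> None:
    """Write sample id -> group ('tumor' | 'nat') as TSV."""
    pd.Series(groups, name="group").rename_axis("sample").to_csv(path, sep="\t")


def write_truth(truth, path: str | Path) -> None:
    """Write the synthetic ground truth as (gene, role, effect) rows."""
    rows = []
    for h, targets in truth.target_map.items():
        rows.append((h, "hub", len(targets)))
        rows.extend((t, "target_of:" + h, np.nan) for t in targets)
    rows.extend((g, "housekeeping", np.nan) for g in truth.housekeeping_ids)
    rows.extend((g, "oncogene", np.nan) for g in truth.oncogene_ids)
    rows.extend((g, "essential", np.nan) for g in truth.essential_ids)
    rows.extend((g, "hazard", b) for g, b in truth.hazard_ids.items())
    pd.DataFrame(rows, columns=["gene", "role", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    out = surv.copy()
    out.index.name = "patient"
    out.to_csv(path, sep="\t")


def read_survival(path: str | Path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in surv.columns:
            raise DataError(f"survival table {path} lacks a {col!r} column")
    return surv


def _rule_types_str(rule_types) -> str:
    return ",".join(f"{a:+d}=>{b:+d}" for a, b in rule_types)


def write_edges(net: ImplicationNetwork, path: str | Path) -> None:
    """Edge list TSV: source, target, layer_pair, rule_types, max_z, scope, precision."""
    rows = [
        {
            "source": u,
            "target": v,
            "layer_pair": net.layer_pair,
            "rule_types": _rule_types_str(d["rule_types"]),
            "max_z": d["max_z"],
            "scope": d["scope"],
            "precision": d["precision"],
        }
        for u, v, d in net.graph.edges(data=True)
    ]
    cols = ["source", "target", "layer_pair", "rule_types", "max_z", "scope", "precision"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> ImplicationNetwork:
    """Rebuild an ImplicationNetwork from an edge-list TSV."""
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    layer_pair = "mrna-mrna"
    for _, row in df.iterrows():
        layer_pair = row["layer_pair"]
        types = tuple(
            tuple(int(x) for x in t.split("=>")) for t in str(row["rule_types"]).split(",")
        )
        g.add_edge(
            str(row["source"]), str(row["target"]),
            rule_types=types, max_z=row["max_z"],
            scope=row["scope"], precision=row["precision"],
        )
    sym = all(g.has_edge(v, u) for u, v in g.edges)
    return ImplicationNetwork(graph=g, layer_pair=layer_pair, symmetric=sym)


def write_graphml(net: ImplicationNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    for _, _, d in g.edges(data=True):
        d["rule_types"] = _rule_types_str(d["rule_types"])
    nx.write_graphml(g, path)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_centrality_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
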