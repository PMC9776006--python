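"""Hub-gene selection: percentile ranking, top-decile extraction, filters.

A gene is a *hub* when it ranks within the top 10th percentile for all
seven centrality metrics in at least one network.  Hubs are then
filtered for concordant oncogenic evidence (significantly higher mRNA
and protein expression in tumors and a hazard ratio above 1 with its
95% CI lower bound at or above 1) and flagged as proliferation genes
when enough screened cell lines depend on them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from boolhub.centrality import ASCENDING_METRICS, METRICS
from boolhub.errors import DataError

logger = logging.getLogger(__name__)

TOP_DECILE = 10.0
MIN_DEPENDENT_LINES = 41


def percentile_ranks(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene per-metric percentile, 0 = most central.

    ``percentile = 100 * (rank - 1) / N`` with rank 1 the most central
    gene: the largest value for six metrics, the smallest rank number
    for VoteRank.  Ties share the mean rank, so a fully tied metric
    leaves every gene at the same mid percentile.
    """
    if len(table) < 10:
        raise DataError("percentile ranking needs at least 10 genes")
    n = len(table)
    out = {}
    for m in METRICS:
        if m not in table.columns:
            raise DataError(f"metric {m!r} missing from centrality table")
        v = table[m].to_numpy(dtype=float)
        ranks = stats.rankdata(v if m in ASCENDING_METRICS else -v, method="average")
        out[m] = 100.0 * (ranks - 1) / n
    return pd.DataFrame(out, index=table.index)


def top_decile_hubs(
    tables: dict[str, pd.DataFrame], cutoff: float = TOP_DECILE
) -> pd.DataFrame:
    """Genes in the top decile of *all seven* metrics in >= 1 network.

    ``tables`` maps network names to centrality tables.  Returns a
    frame indexed by qualifying gene with a ``networks`` column listing
    the networks where the gene qualifies (boundary percentiles count:
    the comparison is <= cutoff).
    """
    if not tables:
        return pd.DataFrame(columns=["networks"])
    hits: dict[str, list[str]] = {}
    for name, table in tables.items():
        pct = percentile_ranks(table)
        qual = (pct <= cutoff).all(axis=1)
        for gene in pct.index[qual]:
            hits.setdefault(gene, []).append(name)
    out = pd.DataFrame(
        {"networks": [tuple(v) for v in hits.values()]},
        index=pd.Index(hits.keys(), name="gene"),
    )
    return out.sort_index()


def concordant_oncogene_filter(
    hubs: pd.DataFrame, stats_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep hubs with concordant tumorigenesis and survival evidence.

    Retains genes with ``t_mrna > 0`` and ``p_mrna < alpha``,
    ``t_protein > 0`` and ``p_protein < alpha``, ``hr > 1`` and the 95%
    CI lower bound >= 1 at printed (2-decimal) precision, i.e. a
    boundary-touching interval still counts.  Genes with any missing
    statistic are excluded and logged.
    """
    required = ["t_mrna", "p_mrna", "t_protein", "p_protein", "hr", "hr_ci_low"]
    for col in required:
        if col not in stats_table.columns:
            raise DataError(f"statistics table lacks column {col!r}")
    kept = []
    for gene in hubs.index:
        if gene not in stats_table.index:
            logger.info("hub %s excluded: no statistics", gene)
            continue
        row = stats_table.loc[gene]
        if row[required].isna().any():
            logger.info("hub %s excluded: missing statistic", gene)
            continue
        ok = (
            row["t_mrna"] > 0 and row["p_mrna"] < alpha
            and row["t_protein"] > 0 and row["p_protein"] < alpha
            and row["hr"] > 1 and round(row["hr_ci_low"], 2) >= 1.0
        )
        if ok:
            kept.append(gene)
    return hubs.loc[kept]


def proliferation_flag(
    report: pd.DataFrame, min_lines: int = MIN_DEPENDENT_LINES
) -> pd.DataFrame:
    """Flag genes dependent in at least ``min_lines`` screened cell lines.

    Uses the larger of the CRISPR and RNAi dependent-line counts
    (columns ``dep_crispr`` / ``dep_rnai``; a missing column counts 0).
    """
    crispr = report.get("dep_crispr", pd.Series(0, index=report.index)).fillna(0)
    rnai = report.get("dep_rnai", pd.Series(0, index=report.index)).fillna(0)
    out = report.copy()
    out["proliferation_gene"] = np.maximum(crispr, rnai) >= min_lines
    return out


def hub_report(
    tables: dict[str, pd.DataFrame],
    stats_table: pd.DataFrame,
    min_lines: int = MIN_DEPENDENT_LINES,
    cutoff: float = TOP_DECILE,
) -> pd.DataFrame:
    """Full hub report: top-decile hubs joined with their statistics.

    Adds ``concordant_oncogene`` and ``proliferation_gene`` flags; the
    report rows are exactly the top-decile hubs, so the concordant
    subset is always a subset of them.
    """
    hubs = top_decile_hubs(tables, cutoff=cutoff)
    report = hubs.join(stats_table, how="left")
    concordant = concordant_oncogene_filter(hubs, stats_table)
    report["concordant_oncogene"] = report.index.isin(concordant.index)
    report = proliferation_flag(report, min_lines=min_lines)
    return report
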