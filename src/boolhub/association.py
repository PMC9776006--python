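"""Genome-wide correlation of centrality metrics with gene statistics.

Associations are Pearson correlations computed over the intersection of
genes present in a centrality table and a statistic vector; a result is
labelled ``pos`` (r > 0, p < 0.05), ``neg`` (r < 0, p < 0.05) or ``ns``.
VoteRank centrality is an integer rank where smaller means more
important, so when counting cross-network concordance its correlation
sign is inverted to put it on the same footing as the other metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from boolhub.centrality import METRICS
from boolhub.errors import DataError

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    network: str
    metric: str
    statistic: str
    n_genes: int
    r: float
    p: float
    label: str  # 'pos' | 'neg' | 'ns'


def _label(r: float, p: float) -> str:
    if np.isnan(r) or np.isnan(p) or p >= ALPHA:
        return "ns"
    return "pos" if r > 0 else "neg"


def correlate(
    table: pd.DataFrame,
    stat: pd.Series,
    metric: str,
    network: str = "",
    statistic: str = "",
) -> AssociationResult:
    """Pearson correlation of one centrality metric with a gene statistic.

    Genes missing either value are dropped (and logged).  A constant
    vector yields an undefined correlation, flagged as ``ns`` with
    missing r.  Fewer than 3 matched genes is an error.
    """
    if metric not in table.columns:
        raise DataError(f"metric {metric!r} not in centrality table")
    merged = pd.concat([table[metric], stat], axis=1, join="inner").dropna()
    n_dropped = len(table.index.union(stat.index)) - len(merged)
    if n_dropped:
        logger.debug("correlate: %d genes without both values dropped", n_dropped)
    if len(merged) < 3:
        raise DataError(
            f"only {len(merged)} genes have both {metric!r} and the statistic; need >= 3"
        )
    x = merged.iloc[:, 0].to_numpy(dtype=float)
    y = merged.iloc[:, 1].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("correlate: constant vector for %s; correlation undefined", metric)
        return AssociationResult(network, metric, statistic, len(merged), np.nan, np.nan, "ns")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(network, metric, statistic, len(merged), float(r), float(p), _label(r, p))


def correlate_all(
    table: pd.DataFrame, stat: pd.Series, network: str = "", statistic: str = ""
) -> dict[str, AssociationResult]:
    """``correlate`` for all seven metrics of one table."""
    return {
        m: correlate(table, stat, m, network=network, statistic=statistic)
        for m in METRICS
    }


def per_line_correlation_counts(
    table: pd.DataFrame, dep: pd.DataFrame, metric: str
) -> tuple[int, int, int]:
    """Count cell lines whose dependency profile correlates with a metric.

    For each cell line (column of ``dep``) the metric is correlated with
    that line's scores across the matched genes; lines with p < 0.05 are
    counted by correlation sign.  Returns ``(n_pos, n_neg, n_lines)``
    where ``n_lines`` counts the lines actually evaluated (lines with
    fewer than 3 matched genes are skipped and reported).
    """
    if metric not in table.columns:
        raise DataError(f"metric {metric!r} not in centrality table")
    genes = table.index.intersection(dep.index)
    n_pos = n_neg = n_lines = 0
    skipped = 0
    mvals = table.loc[genes, metric]
    for line in dep.columns:
        pair = pd.concat([mvals, dep.loc[genes, line]], axis=1).dropna()
        if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
            skipped += 1
            continue
        r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        n_lines += 1
        if p < ALPHA:
            if r > 0:
                n_pos += 1
            elif r < 0:
                n_neg += 1
    if skipped:
        logger.info("per_line_correlation_counts: %d lines skipped", skipped)
    return n_pos, n_neg, n_lines


def _oriented_label(res: AssociationResult) -> str:
    """Label with VoteRank's sign inverted to match the other metrics."""
    if res.metric == "c_voterank" and res.label in ("pos", "neg"):
        return "neg" if res.label == "pos" else "pos"
    return res.label


def concordance_count(
    a: dict[str, AssociationResult],
    b: dict[str, AssociationResult],
    statistic: str = "",
) -> int:
    """Number of metrics (0-7) concordantly significant in two networks.

    Both result sets must cover the same seven metrics.  A metric counts
    when both labels are significant and, after orienting VoteRank, equal.
    """
    if set(a) != set(b) or set(a) != set(METRICS):
        raise DataError("concordance_count requires results for the same 7 metrics")
    count = 0
    for m in METRICS:
        la, lb = _oriented_label(a[m]), _oriented_label(b[m])
        if la != "ns" and la == lb:
            count += 1
    return count


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format table of association results."""
    return pd.DataFrame(
        [
            {
                "network": r.network, "metric": r.metric, "statistic": r.statistic,
                "n": r.n_genes, "r": r.r, "p": r.p, "label": r.label,
            }
            for r in results
        ]
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
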