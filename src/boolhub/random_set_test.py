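"""Random-gene-set centrality null tests.

Does a designated gene set have higher average centrality than random
sets of the same size?  For each metric the observed mean is compared
with the means of ``n_iter`` (default 1000) gene sets drawn uniformly
without replacement from the table's genes *excluding* the target set;
the empirical p value is the fraction of draws whose mean is at least
the observed mean (ties count against the target).

VoteRank is a rank (smaller = better), so its comparison is a one-tailed
two-sample Wilcoxon rank-sum test of the target ranks against each
draw's ranks (alternative: target ranks are smaller); the empirical p is
the fraction of draws whose test is *not* significant at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from boolhub.centrality import METRICS
from boolhub.errors import DataError

ALPHA = 0.05


@dataclass
class RandomSetTestResult:
    metric: str
    observed: float  # mean centrality, or mean rank for VoteRank
    n_iter: int
    null_means: np.ndarray = field(repr=False)
    p_value: float = np.nan
    mode: str = "mean"  # 'mean' | 'wilcoxon'

    def null_quantiles(self, qs=(0.05, 0.25, 0.5, 0.75, 0.95)) -> dict[float, float]:
        return {q: float(np.quantile(self.null_means, q)) for q in qs}


def _wilcoxon_p(target: np.ndarray, draw: np.ndarray) -> float:
    """One-tailed rank-sum p that target ranks are smaller than draw ranks.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with continuity correction.
    """
    small = min(len(target), len(draw)) < 8
    ties = len(np.unique(np.concatenate([target, draw]))) < len(target) + len(draw)
    method = "exact" if small and not ties else "asymptotic"
    return float(
        stats.mannwhitneyu(target, draw, alternative="less", method=method).pvalue
    )


def random_set_centrality_test(
    table: pd.DataFrame,
    target: Iterable[str],
    n_iter: int = 1000,
    seed: int | None = None,
    metrics: Iterable[str] | None = None,
) -> dict[str, RandomSetTestResult]:
    """Permutation test of a gene set's average centrality, per metric.

    ``target`` must be a subset of the table's genes and no larger than
    its complement (the sampling pool).  Draws are without replacement
    within a draw and independent across draws; results are reproducible
    under a fixed ``seed``.
    """
    if n_iter < 1:
        raise DataError("n_iter must be >= 1")
    target = list(dict.fromkeys(target))
    missing = [g for g in target if g not in table.index]
    if missing:
        raise DataError(f"target genes absent from the table: {missing[:5]}")
    pool = table.index.difference(target)
    k = len(target)
    if k == 0:
        raise DataError("target gene set is empty")
    if k > len(pool):
        raise DataError(
            f"target size {k} exceeds the {len(pool)}-gene complement pool"
        )
    metrics = list(metrics) if metrics is not None else list(METRICS)
    rng = np.random.default_rng(seed)
    draws = np.stack([rng.choice(len(pool), size=k, replace=False) for _ in range(n_iter)])
    results: dict[str, RandomSetTestResult] = {}
    for m in metrics:
        if m not in table.columns:
            raise DataError(f"metric {m!r} not in centrality table")
        obs_vals = table.loc[target, m].to_numpy(dtype=float)
        pool_vals = table.loc[pool, m].to_numpy(dtype=float)
        null_draws = pool_vals[draws]  # (n_iter, k)
        null_means = null_draws.mean(axis=1)
        if m == "c_voterank":
            pvals = np.array([_wilcoxon_p(obs_vals, row) for row in null_draws])
            p = float((pvals >= ALPHA).mean())
            results[m] = RandomSetTestResult(
                metric=m, observed=float(obs_vals.mean()), n_iter=n_iter,
                null_means=null_means, p_value=p, mode="wilcoxon",
            )
        else:
            obs = float(obs_vals.mean())
            p = float((null_means >= obs).mean())
            results[m] = RandomSetTestResult(
                metric=m, observed=obs, n_iter=n_iter,
                null_means=null_means, p_value=p, mode="mean",
            )
    return results
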