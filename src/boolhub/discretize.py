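"""Ternarize continuous expression against a housekeeping reference.

Continuous matrices are converted to three states -- ``1`` up-regulated,
``0`` normal, ``-1`` down-regulated -- by comparing each value with the
per-sample distribution of a designated set of housekeeping genes: state
1 above ``mu_s + k*sigma_s``, state -1 below ``mu_s - k*sigma_s``, else
0.  The default ``k = 1.64`` matches a one-tailed normal test at
p < 0.05.  Externally supplied ternary CNV calls are validated, not
recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from boolhub.errors import DataError

logger = logging.getLogger(__name__)

#: Housekeeping reference genes used for expression ternarization.
HOUSEKEEPING_GENES: tuple[str, ...] = (
    "B2M", "ESD", "FLOT2", "GAPDH", "GRB2", "HPRT1", "HSP90AB1",
    "LDHA", "NONO", "POLR2A", "PPP1CA", "RHOA", "SDCBP", "TFRC",
)

TERNARY_STATES = (-1, 0, 1)


@dataclass(frozen=True)
class DiscretizationConfig:
    """Housekeeping gene ids and the threshold multiplier k."""

    housekeeping_ids: tuple[str, ...] = HOUSEKEEPING_GENES
    k: float = 1.64

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise DataError("threshold multiplier k must be > 0")
        if len(self.housekeeping_ids) < 3:
            raise DataError("at least 3 housekeeping gene ids are required")


def ternarize_expression(
    m: pd.DataFrame, cfg: DiscretizationConfig | None = None
) -> pd.DataFrame:
    """Discretize an expression matrix into {-1, 0, 1} per gene x sample.

    For each sample the mean and SD of the housekeeping genes present in
    the matrix define the "normal" band ``mu_s +/- k*sigma_s``.  Missing
    values map to state 0 (the non-informative state for implication
    mining); their count is logged.

    Raises
    ------
    DataError
        If fewer than 3 housekeeping genes are found or any sample has
        zero housekeeping SD.
    """
    cfg = cfg or DiscretizationConfig()
    hk = [g for g in cfg.housekeeping_ids if g in m.index]
    if len(hk) < 3:
        raise DataError(
            f"only {len(hk)} housekeeping genes found in the matrix; need >= 3"
        )
    ref = m.loc[hk]
    mu = ref.mean(axis=0)
    sigma = ref.std(axis=0, ddof=1)
    bad = sigma[sigma <= 0]
    if len(bad):
        raise DataError(
            f"zero housekeeping standard deviation in sample(s): {list(bad.index)}"
        )
    vals = m.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info("ternarize: %d missing values mapped to state 0", n_missing)
    hi = (mu + cfg.k * sigma).to_numpy()
    lo = (mu - cfg.k * sigma).to_numpy()
    with np.errstate(invalid="ignore"):
        states = (vals > hi[None, :]).astype(np.int8) - (vals < lo[None, :]).astype(
            np.int8
        )
    return pd.DataFrame(states, index=m.index, columns=m.columns)


def validate_cnv_calls(m: pd.DataFrame) -> pd.DataFrame:
    """Check a ternary CNV call matrix and return it unchanged.

    Raises ``DataError`` naming the first offending (gene, sample)
    coordinate if any entry lies outside {-1, 0, 1}; otherwise logs
    per-state frequencies and returns the same matrix.
    """
    vals = m.to_numpy()
    ok = np.isin(vals, TERNARY_STATES)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise DataError(
            f"CNV entry {m.iat[i, j]!r} at (gene {m.index[i]!r}, "
            f"sample {m.columns[j]!r}) is not in {{-1, 0, 1}}"
        )
    total = vals.size
    freqs = {s: int((vals == s).sum()) / total for s in TERNARY_STATES}
    logger.info(
        "CNV calls: %.1f%% deletion, %.1f%% normal, %.1f%% amplification",
        100 * freqs[-1], 100 * freqs[0], 100 * freqs[1],
    )
    return m


def state_frequencies(m: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fraction of each ternary state (columns -1, 0, 1)."""
    vals = m.to_numpy()
    n = m.shape[1]
    return pd.DataFrame(
        {s: (vals == s).sum(axis=1) / n for s in TERNARY_STATES}, index=m.index
    )
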