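"""Per-gene external statistics: differential expression, survival, dependency.

These are the quantities centralities are correlated against:

* unpaired two-tailed pooled-variance t statistics (and tumor/NAT fold
  changes) of differential expression -- positive t means higher
  expression in tumors;
* univariate Cox proportional-hazards ratios with 95% Wald confidence
  intervals (Breslow tie handling; HR > 1 means increased risk per
  expression unit);
* dependency-screen summaries: the number of cell lines whose score
  falls strictly below a threshold (default -0.5, i.e. knockout or
  knockdown significantly impairs growth).
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from boolhub.errors import DataError

logger = logging.getLogger(__name__)

DEPENDENCY_THRESHOLD = -0.5

_BETA_CAP = 30.0  # |log HR| beyond this is treated as monotone likelihood


def tumor_vs_nat_t(tumor: pd.DataFrame, nat: pd.DataFrame) -> pd.DataFrame:
    """Two-sample pooled t statistics and fold changes per gene.

    Operates on the gene intersection of the two matrices (dropped genes
    are logged).  Returns columns ``t``, ``p``, ``fold_change`` (ratio
    of group means on the matrices' scale), ``n_tumor``, ``n_nat`` and
    ``flag`` ('' when the statistic is valid; ``too_few_samples`` or
    ``zero_variance`` when it is undefined and left missing).
    """
    genes = tumor.index.intersection(nat.index)
    dropped = len(tumor.index) + len(nat.index) - 2 * len(genes)
    if dropped:
        logger.info("tumor_vs_nat_t: %d gene ids without a match dropped", dropped)
    if len(genes) == 0:
        raise DataError("tumor and NAT matrices share no gene ids")
    xt = tumor.loc[genes].to_numpy(dtype=float)
    xn = nat.loc[genes].to_numpy(dtype=float)
    nt = (~np.isnan(xt)).sum(axis=1)
    nn = (~np.isnan(xn)).sum(axis=1)
    mt = np.nanmean(xt, axis=1)
    mn = np.nanmean(xn, axis=1)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vt = np.nanvar(xt, axis=1, ddof=1)
        vn = np.nanvar(xn, axis=1, ddof=1)
        df = nt + nn - 2
        pooled = ((nt - 1) * vt + (nn - 1) * vn) / df
        se = np.sqrt(pooled * (1.0 / nt + 1.0 / nn))
        t = (mt - mn) / se
        fc = mt / mn
    too_few = (nt < 2) | (nn < 2)
    degenerate = ~too_few & (pooled <= 0)
    flag = np.where(too_few, "too_few_samples", np.where(degenerate, "zero_variance", ""))
    bad = too_few | degenerate
    t = np.where(bad, np.nan, t)
    p = np.full(len(genes), np.nan)
    ok = ~bad
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "fold_change": fc,
            "n_tumor": nt,
            "n_nat": nn,
            "flag": flag,
        },
        index=pd.Index(genes, name="gene"),
    )


class CoxResult(NamedTuple):
    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    flag: str


def _split_survival(surv: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    for col in ("time", "event"):
        if col not in surv.columns:
            raise DataError(f"survival table lacks a {col!r} column")
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=float)
    if (time <= 0).any():
        raise DataError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise DataError("event indicators must be 0 or 1")
    covars = [c for c in surv.columns if c not in ("time", "event")]
    return time, event.astype(bool), covars


def _breslow_newton(
    time: np.ndarray, event: np.ndarray, x: np.ndarray, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton-Raphson on the Breslow partial likelihood, per row of x.

    ``x`` is (n_genes, n_subjects).  Returns ``(beta, se, flag_code)``
    with flag codes 0 = ok, 1 = constant covariate, 2 = monotone
    likelihood (positive), 3 = monotone likelihood (negative).
    """
    n_genes, n = x.shape
    order = np.argsort(-time, kind="stable")
    ts, ev = time[order], event[order]
    xs = x[:, order]
    # Centering leaves the partial likelihood invariant but keeps exp() tame.
    xs = xs - xs.mean(axis=1, keepdims=True)
    # Risk set of an event at time t is everyone with time >= t; with the
    # descending sort that is the cumulative sum up to the end of t's tie
    # group.
    first = np.ones(n, dtype=bool)
    first[1:] = ts[1:] != ts[:-1]
    grp = np.cumsum(first) - 1
    last = np.cumsum(np.bincount(grp)) - 1
    risk_idx = last[grp]

    const = xs.std(axis=1) == 0
    beta = np.zeros(n_genes)
    info = np.full(n_genes, np.nan)
    active = ~const
    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active][:, None]
        xa = xs[active]
        w = np.exp(b * xa)
        s0 = np.cumsum(w, axis=1)[:, risk_idx]
        s1 = np.cumsum(w * xa, axis=1)[:, risk_idx]
        s2 = np.cumsum(w * xa * xa, axis=1)[:, risk_idx]
        r1 = s1 / s0
        u = (xa[:, ev] - r1[:, ev]).sum(axis=1)
        i_obs = (s2[:, ev] / s0[:, ev] - r1[:, ev] ** 2).sum(axis=1)
        info[active] = i_obs
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(i_obs > 0, u / i_obs, 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta[active] = np.clip(beta[active] + step, -_BETA_CAP, _BETA_CAP)
        still = np.abs(step) > 1e-12
        idx = np.flatnonzero(active)
        active[idx[~still]] = False

    flag = np.zeros(n_genes, dtype=int)
    flag[const] = 1
    mono = ~const & (np.abs(beta) >= _BETA_CAP - 1e-6)
    flag[mono & (beta > 0)] = 2
    flag[mono & (beta < 0)] = 3
    with np.errstate(divide="ignore", invalid="ignore"):
        se = 1.0 / np.sqrt(info)
    bad = flag != 0
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    return beta, se, flag


_FLAG_NAMES = {0: "", 1: "constant_covariate", 2: "monotone_pos", 3: "monotone_neg"}


def cox_batch(surv: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Univariate Cox fits for every covariate column of a survival table.

    Returns per gene: ``hr``, ``hr_ci_low``, ``hr_ci_high`` (95% Wald
    interval), ``p``, ``beta``, ``se`` and ``flag``.  Genes with a
    constant covariate or monotone likelihood are flagged with missing
    estimates; a table with no events flags every gene.
    """
    time, event, covars = _split_survival(surv)
    if genes is not None:
        missing = [g for g in genes if g not in covars]
        if missing:
            raise DataError(f"survival table lacks covariates: {missing[:5]}")
        covars = list(genes)
    idx = pd.Index(covars, name="gene")
    if not event.any():
        logger.warning("cox_batch: no events in the survival table")
        return pd.DataFrame(
            {
                "hr": np.nan, "hr_ci_low": np.nan, "hr_ci_high": np.nan,
                "p": np.nan, "beta": np.nan, "se": np.nan, "flag": "no_events",
            },
            index=idx,
        )
    x = surv[covars].to_numpy(dtype=float).T
    beta, se, flag = _breslow_newton(time, event, x)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "hr": np.exp(beta),
            "hr_ci_low": np.exp(beta - 1.96 * se),
            "hr_ci_high": np.exp(beta + 1.96 * se),
            "p": p,
            "beta": beta,
            "se": se,
            "flag": [_FLAG_NAMES[f] for f in flag],
        },
        index=idx,
    )


def univariate_cox(surv: pd.DataFrame, gene: str) -> CoxResult:
    """Univariate Cox hazard ratio for one gene covariate.

    ``hr = exp(beta_hat)`` with a 95% CI ``exp(beta_hat +/- 1.96 SE)``;
    HR > 1 means increased risk.  Breslow handling of tied event times.
    """
    if gene not in surv.columns:
        raise DataError(f"gene {gene!r} not found in the survival table")
    row = cox_batch(surv, genes=[gene]).iloc[0]
    return CoxResult(
        hr=row["hr"], ci_low=row["hr_ci_low"], ci_high=row["hr_ci_high"],
        p=row["p"], beta=row["beta"], se=row["se"], flag=row["flag"],
    )


def breslow_partial_loglik(
    surv: pd.DataFrame, gene: str, beta: float
) -> float:
    """Breslow log partial likelihood at ``beta`` (for direct maximization)."""
    time, event, _ = _split_survival(surv)
    x = surv[gene].to_numpy(dtype=float)
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


def dependency_summary(
    dep: pd.DataFrame, threshold: float = DEPENDENCY_THRESHOLD
) -> pd.DataFrame:
    """Count cell lines with dependency score strictly below the threshold.

    Returns per gene ``n_dependent`` and ``n_total`` (non-missing
    scores); all-missing genes are flagged.
    """
    if threshold >= 0:
        raise DataError("dependency threshold must be negative")
    vals = dep.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        n_dep = (vals < threshold).sum(axis=1)
    n_tot = (~np.isnan(vals)).sum(axis=1)
    return pd.DataFrame(
        {
            "n_dependent": n_dep,
            "n_total": n_tot,
            "flag": np.where(n_tot == 0, "all_missing", ""),
        },
        index=dep.index,
    )


def gene_stat_table(
    mrna_tumor: pd.DataFrame | None = None,
    mrna_nat: pd.DataFrame | None = None,
    protein_tumor: pd.DataFrame | None = None,
    protein_nat: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
    dep_crispr: pd.DataFrame | None = None,
    dep_rnai: pd.DataFrame | None = None,
    dep_threshold: float = DEPENDENCY_THRESHOLD,
) -> pd.DataFrame:
    """Assemble the per-gene statistic table from whichever inputs exist.

    Columns (present when the corresponding input is given):
    ``t_mrna, p_mrna, fc_mrna``, ``t_protein, p_protein, fc_protein``,
    ``hr, hr_ci_low, hr_ci_high, p_hr``, ``dep_crispr, dep_crispr_total,
    dep_rnai, dep_rnai_total``.
    """
    parts: list[pd.DataFrame] = []
    if mrna_tumor is not None and mrna_nat is not None:
        tt = tumor_vs_nat_t(mrna_tumor, mrna_nat)
        parts.append(
            tt[["t", "p", "fold_change"]].rename(
                columns={"t": "t_mrna", "p": "p_mrna", "fold_change": "fc_mrna"}
            )
        )
    if protein_tumor is not None and protein_nat is not None:
        tp = tumor_vs_nat_t(protein_tumor, protein_nat)
        parts.append(
            tp[["t", "p", "fold_change"]].rename(
                columns={"t": "t_protein", "p": "p_protein", "fold_change": "fc_protein"}
            )
        )
    if survival is not None:
        cox = cox_batch(survival)
        parts.append(
            cox[["hr", "hr_ci_low", "hr_ci_high", "p"]].rename(columns={"p": "p_hr"})
        )
    for dep, name in ((dep_crispr, "crispr"), (dep_rnai, "rnai")):
        if dep is not None:
            d = dependency_summary(dep, threshold=dep_threshold)
            parts.append(
                d[["n_dependent", "n_total"]].rename(
                    columns={
                        "n_dependent": f"dep_{name}",
                        "n_total": f"dep_{name}_total",
                    }
                )
            )
    if not parts:
        raise DataError("gene_stat_table needs at least one input pair")
    out = pd.concat(parts, axis=1)
    out.index.name = "gene"
    return out
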