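"""Planted-hub recovery benchmark: the package's end-to-end study-in-miniature.

Mirrors the multi-cohort design of genome-scale hub-gene studies: several
independent patient cohorts are simulated from the same planted truth
(gene roles are deterministic, so cohorts share identifiers), four
networks are mined per cohort (CNV-mediated expression, mRNA
co-expression, mRNA-mediated protein expression, protein co-expression),
and hub selection unions the top-decile qualification over all of them
-- the analogue of requiring the top 10th percentile for all seven
metrics "in at least one" of the study's networks.  Tumor-vs-NAT t
statistics come from the first cohort; hazard ratios from a separate,
larger survival cohort (survival studies are typically much bigger than
proteogenomic ones); dependency counts from simulated CRISPR (94 lines)
and RNAi (92 lines) screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from boolhub.centrality import centrality_table
from boolhub.discretize import DiscretizationConfig, ternarize_expression
from boolhub.gene_stats import gene_stat_table
from boolhub.hub_select import hub_report
from boolhub.implication_net import ImplicationNetwork, build_network
from boolhub.synthetic_data import (
    SimulationConfig,
    SyntheticTruth,
    simulate_dependency_screen,
    simulate_multiomics,
    simulate_survival_cohort,
)

#: layer pairs mined per cohort in the benchmark.
BENCHMARK_LAYER_PAIRS = ("cnv-mrna", "mrna-mrna", "mrna-protein", "protein-protein")


@dataclass
class RecoveryStudy:
    """All artifacts of one recovery benchmark run."""

    truth: SyntheticTruth
    networks: dict[str, ImplicationNetwork]
    tables: dict[str, pd.DataFrame]
    stats: pd.DataFrame
    report: pd.DataFrame = field(repr=False)

    def hub_recall(self) -> float:
        """Fraction of planted hubs appearing in the hub report."""
        hubs = self.truth.hub_ids
        return sum(h in self.report.index for h in hubs) / len(hubs)


def cohort_networks(
    config: SimulationConfig,
) -> tuple[dict[str, ImplicationNetwork], tuple]:
    """Simulate one cohort and mine its four benchmark networks."""
    cnv, mt, mn, pt, pn, truth = simulate_multiomics(config)
    dcfg = DiscretizationConfig(housekeeping_ids=truth.housekeeping_ids)
    tern_m = ternarize_expression(mt, dcfg)
    tern_p = ternarize_expression(pt, dcfg)
    nets = {
        "cnv-mrna": build_network("cnv-mrna", cnv, tern_m),
        "mrna-mrna": build_network("mrna-mrna", tern_m),
        "mrna-protein": build_network("mrna-protein", tern_m, tern_p),
        "protein-protein": build_network("protein-protein", tern_p),
    }
    return nets, (cnv, mt, mn, pt, pn, truth)


def recovery_study(
    seed: int = 1,
    n_cohorts: int = 3,
    survival_patients: int = 500,
    config: SimulationConfig | None = None,
) -> RecoveryStudy:
    """Run the full recovery benchmark.

    ``config`` defaults to the recovery preset (the
    :class:`SimulationConfig` defaults) with the given seed.  Cohort c
    uses seed ``seed + 101*c``; the survival cohort ``seed + 7919`` and
    the dependency screens ``seed + 17`` / ``seed + 19``.
    """
    base = config or SimulationConfig(seed=seed)
    networks: dict[str, ImplicationNetwork] = {}
    tables: dict[str, pd.DataFrame] = {}
    first = None
    truth = None
    for c in range(n_cohorts):
        cfg = replace(base, seed=seed + 101 * c)
        nets, data = cohort_networks(cfg)
        if truth is None:
            truth = data[-1]
            first = data
        for lp, net in nets.items():
            name = f"cohort{c}:{lp}"
            networks[name] = net
            tables[name] = centrality_table(net)

    _, mt, mn, pt, pn, _ = first
    surv_cfg = replace(base, n_tumor=survival_patients, seed=seed + 7919)
    _, mt_surv, *_, truth_surv = simulate_multiomics(surv_cfg)
    survival = simulate_survival_cohort(truth_surv, mt_surv, seed=seed + 104729)
    dep_crispr = simulate_dependency_screen(truth, n_lines=94, seed=seed + 17)
    dep_rnai = simulate_dependency_screen(truth, n_lines=92, seed=seed + 19)

    stats = gene_stat_table(
        mrna_tumor=mt, mrna_nat=mn, protein_tumor=pt, protein_nat=pn,
        survival=survival, dep_crispr=dep_crispr, dep_rnai=dep_rnai,
    )
    report = hub_report(tables, stats)
    return RecoveryStudy(
        truth=truth, networks=networks, tables=tables, stats=stats, report=report
    )
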