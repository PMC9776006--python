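"""End-to-end orchestration: simulate/read, discretize, mine, rank, report.

A pipeline run is driven by a configuration mapping (usually loaded from
YAML).  Either a ``simulate`` section (parameters of
:class:`~boolhub.synthetic_data.SimulationConfig`) or an ``inputs``
section (paths to matrices and tables) supplies the data; the remaining
keys tune the stages::

    seed: 1
    outdir: results
    simulate: {n_genes: 300, n_hub: 10, fanout: 20}
    layer_pairs: [cnv-mrna, mrna-mrna, mrna-protein]
    z_min: 1.64
    scope_min: null        # default max(0.1, 5/n)
    k: 1.64                # discretization threshold multiplier
    n_iter: 1000           # random-set test iterations
    min_lines: 41          # proliferation flag threshold

Every stage logs its counts; any stage error halts the run naming the
stage.  Reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import yaml

import boolhub
from boolhub import io as bio
from boolhub.association import association_table, correlate_all, concordance_count
from boolhub.centrality import centrality_table
from boolhub.discretize import DiscretizationConfig, ternarize_expression, validate_cnv_calls
from boolhub.errors import BoolhubError, ConfigurationError
from boolhub.gene_stats import gene_stat_table
from boolhub.hub_select import hub_report
from boolhub.implication_net import LAYER_PAIRS, build_network
from boolhub.random_set_test import random_set_centrality_test
from boolhub.synthetic_data import (
    SimulationConfig,
    simulate_dependency_screen,
    simulate_multiomics,
    simulate_survival_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_LAYER_PAIRS = ["cnv-cnv", "cnv-mrna", "mrna-mrna", "mrna-protein", "protein-protein"]


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"pipeline config {path} is not a mapping")
    return cfg


class _Stage:
    """Context manager that renames any stage failure after its stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, BoolhubError):
            raise BoolhubError(f"stage {self.name!r} failed: {exc}") from exc
        if isinstance(exc, BoolhubError) and not str(exc).startswith("stage"):
            raise BoolhubError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def _load_inputs(cfg: dict):
    inputs = cfg.get("inputs")
    if inputs is None:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs.setdefault("seed", cfg.get("seed", 0))
        sim = SimulationConfig(**sim_kwargs)
        cnv, mt, mn, pt, pn, truth = simulate_multiomics(sim)
        dep_c = simulate_dependency_screen(truth, n_lines=94, seed=sim.seed + 1)
        dep_r = simulate_dependency_screen(truth, n_lines=92, seed=sim.seed + 2)
        surv = simulate_survival_cohort(truth, mt, seed=sim.seed + 3)
        hk = list(truth.housekeeping_ids)
        return cnv, mt, mn, pt, pn, surv, dep_c, dep_r, hk, truth
    hk_path = inputs.get("housekeeping_file")
    if hk_path is None:
        raise ConfigurationError("config key inputs.housekeeping_file is required")
    if not Path(hk_path).exists():
        raise ConfigurationError(f"config key inputs.housekeeping_file: {hk_path} not found")
    hk = bio.read_gene_list(hk_path)

    def need(key, kind):
        path = inputs.get(key)
        if path is None:
            return None
        if not Path(path).exists():
            raise ConfigurationError(f"config key inputs.{key}: {path} not found")
        return bio.read_matrix(path, kind=kind)

    cnv = need("cnv", "ternary")
    mt = need("mrna_tumor", "continuous")
    mn = need("mrna_nat", "continuous")
    pt = need("protein_tumor", "continuous")
    pn = need("protein_nat", "continuous")
    surv = bio.read_survival(inputs["survival"]) if inputs.get("survival") else None
    dep_c = need("dep_crispr", "continuous")
    dep_r = need("dep_rnai", "continuous")
    return cnv, mt, mn, pt, pn, surv, dep_c, dep_r, hk, None


def run_pipeline(cfg: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Run the full analysis and write all artifacts to ``outdir``.

    Writes discretized matrices, edge lists, centrality tables, the
    association table, random-set test results, the hub report and a
    ``manifest.json`` recording versions, seeds and parameters.
    Returns the output directory.
    """
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    out = Path(outdir or cfg.get("outdir", "boolhub_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    z_min = float(cfg.get("z_min", 1.64))
    scope_min = cfg.get("scope_min")
    k = float(cfg.get("k", 1.64))
    n_iter = int(cfg.get("n_iter", 1000))
    min_lines = int(cfg.get("min_lines", 41))
    layer_pairs = list(cfg.get("layer_pairs", DEFAULT_LAYER_PAIRS))
    for lp in layer_pairs:
        if lp not in LAYER_PAIRS:
            raise ConfigurationError(f"unknown layer pair {lp!r} in config")

    with _Stage("load"):
        cnv, mt, mn, pt, pn, surv, dep_c, dep_r, hk, truth = _load_inputs(cfg)
        if truth is not None:
            for name, m in (
                ("cnv.tsv", cnv), ("mrna_tumor.tsv", mt), ("mrna_nat.tsv", mn),
                ("protein_tumor.tsv", pt), ("protein_nat.tsv", pn),
            ):
                bio.write_matrix(m, out / name)
            bio.write_truth(truth, out / "truth.tsv")
            bio.write_survival(surv, out / "survival.tsv")
            groups = {s: "tumor" for s in mt.columns} | {s: "nat" for s in mn.columns}
            bio.write_sample_annotation(groups, out / "samples.tsv")

    with _Stage("discretize"):
        dcfg = DiscretizationConfig(housekeeping_ids=tuple(hk), k=k)
        if cnv is not None:
            cnv = validate_cnv_calls(cnv)
        tern = {}
        if mt is not None:
            tern["mrna"] = ternarize_expression(mt, dcfg)
            bio.write_matrix(tern["mrna"], out / "mrna_tumor_ternary.tsv")
        if pt is not None:
            tern["protein"] = ternarize_expression(pt, dcfg)
            bio.write_matrix(tern["protein"], out / "protein_tumor_ternary.tsv")
        if cnv is not None:
            tern["cnv"] = cnv
        logger.info("discretize: %d layers ready", len(tern))

    with _Stage("network"):
        nets = {}
        for lp in layer_pairs:
            a_layer, c_layer = lp.split("-")
            if a_layer not in tern or c_layer not in tern:
                logger.info("network %s skipped: layer not available", lp)
                continue
            if LAYER_PAIRS[lp]:
                nets[lp] = build_network(lp, tern[a_layer], z_min=z_min, scope_min=scope_min)
            else:
                nets[lp] = build_network(
                    lp, tern[a_layer], tern[c_layer], z_min=z_min, scope_min=scope_min
                )
            bio.write_edges(nets[lp], out / f"edges_{lp}.tsv")
            logger.info(
                "network %s: %d nodes, %d associations",
                lp, nets[lp].n_nodes, nets[lp].edge_count,
            )

    with _Stage("centrality"):
        tables = {}
        for lp, net in nets.items():
            tables[lp] = centrality_table(net)
            bio.write_table(tables[lp], out / f"centrality_{lp}.tsv")

    with _Stage("stats"):
        stats_table = gene_stat_table(
            mrna_tumor=mt, mrna_nat=mn, protein_tumor=pt, protein_nat=pn,
            survival=surv, dep_crispr=dep_c, dep_rnai=dep_r,
        )
        bio.write_table(stats_table, out / "gene_stats.tsv")

    with _Stage("associate"):
        results = []
        stat_vectors = {
            name: stats_table[name]
            for name in ("t_mrna", "t_protein", "hr")
            if name in stats_table.columns
        }
        per_net = {}
        for lp, table in tables.items():
            per_net[lp] = {}
            for sname, vec in stat_vectors.items():
                res = correlate_all(table, vec, network=lp, statistic=sname)
                per_net[lp][sname] = res
                results.extend(res.values())
        bio.write_table(association_table(results), out / "associations.tsv", index_label=None)
        net_names = list(tables)
        for sname in stat_vectors:
            conc = pandas.DataFrame(
                [
                    [concordance_count(per_net[a][sname], per_net[b][sname]) for b in net_names]
                    for a in net_names
                ],
                index=net_names, columns=net_names,
            )
            bio.write_table(conc, out / f"concordance_{sname}.tsv", index_label="network")

    with _Stage("permtest"):
        gene_set = None
        if cfg.get("gene_set"):
            gene_set = bio.read_gene_list(cfg["gene_set"])
        elif truth is not None:
            gene_set = list(truth.hub_ids)
        if gene_set and tables:
            lp0 = next(iter(tables))
            target = [g for g in gene_set if g in tables[lp0].index]
            res = random_set_centrality_test(tables[lp0], target, n_iter=n_iter, seed=seed)
            perm = pandas.DataFrame(
                [
                    {
                        "network": lp0, "metric": m, "observed": r.observed,
                        "p": r.p_value, "mode": r.mode, "n_iter": r.n_iter,
                        **{f"null_q{int(100 * q)}": v for q, v in r.null_quantiles().items()},
                    }
                    for m, r in res.items()
                ]
            )
            bio.write_table(perm, out / "random_set_test.tsv", index_label=None)

    with _Stage("hubs"):
        report = hub_report(tables, stats_table, min_lines=min_lines)
        report = report.copy()
        report["networks"] = [";".join(v) for v in report["networks"]]
        bio.write_table(report, out / "hub_report.tsv")
        logger.info(
            "hubs: %d top-decile, %d concordant oncogenes, %d proliferation",
            len(report), int(report["concordant_oncogene"].sum()),
            int(report["proliferation_gene"].sum()),
        )

    with _Stage("manifest"):
        manifest = {
            "boolhub": boolhub.__version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
            "seed": seed,
            "z_min": z_min,
            "scope_min": scope_min,
            "k": k,
            "n_iter": n_iter,
            "min_lines": min_lines,
            "layer_pairs": layer_pairs,
            "simulate": cfg.get("simulate"),
            "networks": {
                lp: {"nodes": nets[lp].n_nodes, "associations": nets[lp].edge_count}
                for lp in nets
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
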