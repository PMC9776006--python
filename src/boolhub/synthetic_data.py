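"""Synthetic multi-omics cohorts with planted regulatory hub structure.

The generator emulates the statistical structure of the NSCLC-style study
data that the downstream analyses expect:

* a ternary CNV call matrix (``-1`` deletion, ``0`` normal, ``1``
  amplification) over tumor samples;
* continuous mRNA and protein matrices for tumor and non-cancerous
  adjacent tissue (NAT) samples, with CNV -> mRNA -> protein effect
  propagation and a tumor-vs-NAT shift for planted oncogenes;
* a set of housekeeping genes simulated as pure baseline + noise, which
  downstream discretization uses as its reference distribution;
* planted regulatory hubs whose ternary mRNA state additively shifts the
  expression of their target genes, so Boolean implication mining has a
  known ground truth to recover;
* matching dependency screens (negative scores for planted essential
  genes) and proportional-hazards survival cohorts (planted hazard genes).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from boolhub.errors import ConfigurationError

# One-tailed z threshold aligned with the discretization default k = 1.64:
# a hub is "up" in a sample when its expression deviates from the
# housekeeping baseline by more than GEN_K generative noise SDs.
GEN_K = 1.64

_BASELINE = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the multi-omics cohort generator.

    The defaults are the hub-recovery study conditions: 300 genes, 10
    regulatory hubs with 20 targets each, a regulatory shift of 2 noise
    SDs, and 60 tumor samples.

    Parameters
    ----------
    n_genes : total number of genes (all roles included).
    n_hub : number of planted regulator hubs.
    fanout : number of regulated target genes per hub.
    n_tumor, n_nat : tumor / NAT sample counts.
    n_housekeeping : number of housekeeping reference genes.
    cnv_rate : per gene x sample probability of amplification, and of
        deletion (each; in [0, 0.5)).
    cnv_effect : additive mRNA shift per CNV unit (expression units).
    reg_effect : additive shift of a target's mRNA per unit of its hub's
        ternary state (expression units).
    protein_slope : mRNA -> protein transfer coefficient.
    noise_sd : residual SD of mRNA and protein (expression units).
    tumor_shift : additive tumor-minus-NAT mRNA shift for planted
        oncogenes (expression units).
    hazard_log_hr : log hazard ratio per expression unit planted on
        hazard genes.
    seed : RNG seed; identical seed gives bit-identical outputs.
    """

    n_genes: int = 300
    n_hub: int = 10
    fanout: int = 20
    n_tumor: int = 60
    n_nat: int = 60
    n_housekeeping: int = 14
    cnv_rate: float = 0.35
    cnv_effect: float = 3.0
    reg_effect: float = 2.0
    protein_slope: float = 1.5
    noise_sd: float = 1.0
    tumor_shift: float = 1.2
    hazard_log_hr: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        for name in ("n_hub", "fanout", "n_housekeeping"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_tumor < 2 or self.n_nat < 2:
            raise ConfigurationError("n_tumor and n_nat must each be >= 2")
        if self.n_hub * self.fanout > self.n_genes - self.n_hub - self.n_housekeeping:
            raise ConfigurationError(
                "planted structure does not fit: require "
                "n_hub*fanout <= n_genes - n_hub - n_housekeeping"
            )
        if not 0.0 <= self.cnv_rate < 0.5:
            raise ConfigurationError("cnv_rate must lie in [0, 0.5)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    hub_ids, housekeeping_ids and the target ids in ``target_map`` are
    disjoint by construction.  By default the planted hubs double as the
    oncogenes (tumor shift) and hazard genes, and the hubs together with
    their regulated targets are the essential genes (negative dependency
    scores) -- regulated genes carrying proliferative potential is the
    qualitative pattern the downstream association stage looks for.
    """

    genes: tuple[str, ...]
    hub_ids: tuple[str, ...]
    target_map: dict[str, tuple[str, ...]] = field(default_factory=dict)
    housekeeping_ids: tuple[str, ...] = ()
    oncogene_ids: tuple[str, ...] = ()
    essential_ids: tuple[str, ...] = ()
    hazard_ids: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        targets = {t for tgts in self.target_map.values() for t in tgts}
        groups = [set(self.hub_ids), set(self.housekeeping_ids), targets]
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                if a & b:
                    raise ConfigurationError(
                        "hub, housekeeping and target ids must be disjoint"
                    )


def _gene_names(cfg: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    from boolhub.discretize import HOUSEKEEPING_GENES

    n_tgt = cfg.n_hub * cfg.fanout
    n_bg = cfg.n_genes - cfg.n_hub - n_tgt - cfg.n_housekeeping
    # Housekeeping genes take the names of the real reference panel so the
    # downstream discretization defaults apply unchanged.
    hk = list(HOUSEKEEPING_GENES[: cfg.n_housekeeping])
    hk += [f"HKG{i:03d}" for i in range(1, cfg.n_housekeeping - len(hk) + 1)]
    roles = {
        "hub": [f"HUB{i:03d}" for i in range(1, cfg.n_hub + 1)],
        "target": [f"TGT{i:04d}" for i in range(1, n_tgt + 1)],
        "housekeeping": hk,
        "background": [f"BGD{i:04d}" for i in range(1, n_bg + 1)],
    }
    order = (
        roles["hub"] + roles["target"] + roles["housekeeping"] + roles["background"]
    )
    return order, roles


def _ternary_state(deviation: np.ndarray, sd: float) -> np.ndarray:
    """Ternary up/normal/down state of a deviation at the generative k."""
    thr = GEN_K * sd
    return (deviation > thr).astype(np.int8) - (deviation < -thr).astype(np.int8)


def simulate_multiomics(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate CNV, mRNA and protein matrices with planted hubs.

    Returns ``(cnv, mrna_tumor, mrna_nat, protein_tumor, protein_nat,
    truth)``.  All matrices are gene x sample DataFrames; ``cnv`` is a
    ternary call matrix over the tumor samples.

    Generative model per gene g and sample s (tumor):

    ``mrna = baseline + cnv_effect*cnv + reg_effect*state(hub(g))
    + tumor_shift*[g oncogene] + N(0, noise_sd)``

    ``protein = protein_slope*mrna + N(0, noise_sd)``

    Hub regulation acts through the ternary state of the hub's own mRNA
    (its deviation from the housekeeping baseline exceeding 1.64 noise
    SDs), which is exactly the structure implication mining can detect.
    Housekeeping genes receive no CNV, regulatory or tumor effects.  NAT
    samples carry no CNV and no tumor shift.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes, roles = _gene_names(cfg)
    idx = pd.Index(genes, name="gene")
    tumor_samples = [f"TUM{i:03d}" for i in range(1, cfg.n_tumor + 1)]
    nat_samples = [f"NAT{i:03d}" for i in range(1, cfg.n_nat + 1)]

    g_pos = {g: i for i, g in enumerate(genes)}
    hk_rows = np.array([g_pos[g] for g in roles["housekeeping"]], dtype=int)

    # CNV: i.i.d. ternary calls; housekeeping genes stay copy-neutral.
    oncogenes = tuple(roles["hub"])
    onco_rows = np.array([g_pos[g] for g in oncogenes], dtype=int)
    cnv = rng.choice(
        np.array([-1, 0, 1], dtype=np.int8),
        size=(cfg.n_genes, cfg.n_tumor),
        p=[cfg.cnv_rate, 1.0 - 2.0 * cfg.cnv_rate, cfg.cnv_rate],
    )
    if hk_rows.size:
        cnv[hk_rows, :] = 0

    noise_mt = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_tumor))
    noise_mn = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_nat))
    noise_pt = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_tumor))
    noise_pn = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_nat))

    mrna_t = np.full((cfg.n_genes, cfg.n_tumor), _BASELINE)
    mrna_t += cfg.cnv_effect * cnv
    if onco_rows.size:
        mrna_t[onco_rows, :] += cfg.tumor_shift
    mrna_t += noise_mt

    mrna_n = np.full((cfg.n_genes, cfg.n_nat), _BASELINE) + noise_mn

    # Hub regulation: targets shift by reg_effect per unit of the hub's
    # realized ternary mRNA state, in tumors and NATs alike.
    target_map: dict[str, tuple[str, ...]] = {}
    for h_i, hub in enumerate(roles["hub"]):
        tgts = roles["target"][h_i * cfg.fanout : (h_i + 1) * cfg.fanout]
        target_map[hub] = tuple(tgts)
        t_rows = np.array([g_pos[t] for t in tgts], dtype=int)
        state_t = _ternary_state(mrna_t[g_pos[hub]] - _BASELINE, cfg.noise_sd)
        state_n = _ternary_state(mrna_n[g_pos[hub]] - _BASELINE, cfg.noise_sd)
        mrna_t[t_rows, :] += cfg.reg_effect * state_t[None, :]
        mrna_n[t_rows, :] += cfg.reg_effect * state_n[None, :]

    prot_t = cfg.protein_slope * mrna_t + noise_pt
    prot_n = cfg.protein_slope * mrna_n + noise_pn

    truth = SyntheticTruth(
        genes=tuple(genes),
        hub_ids=tuple(roles["hub"]),
        target_map=target_map,
        housekeeping_ids=tuple(roles["housekeeping"]),
        oncogene_ids=oncogenes,
        essential_ids=tuple(roles["hub"]) + tuple(roles["target"]),
        hazard_ids={g: cfg.hazard_log_hr for g in roles["hub"]},
    )
    return (
        pd.DataFrame(cnv, index=idx, columns=tumor_samples),
        pd.DataFrame(mrna_t, index=idx, columns=tumor_samples),
        pd.DataFrame(mrna_n, index=idx, columns=nat_samples),
        pd.DataFrame(prot_t, index=idx, columns=tumor_samples),
        pd.DataFrame(prot_n, index=idx, columns=nat_samples),
        truth,
    )


def simulate_dependency_screen(
    truth: SyntheticTruth,
    n_lines: int,
    essential_mean: float = -1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x cell-line dependency scores (CRISPR/RNAi style).

    Planted essential genes score around ``essential_mean`` (negative:
    knockout impairs growth), all other genes around 0, with Gaussian
    noise of SD ``noise_sd``.
    """
    if n_lines < 1:
        raise ConfigurationError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    scores = rng.normal(0.0, noise_sd, size=(len(truth.genes), n_lines))
    ess = set(truth.essential_ids)
    ess_rows = [i for i, g in enumerate(truth.genes) if g in ess]
    scores[ess_rows, :] += essential_mean
    lines = [f"CL{i:03d}" for i in range(1, n_lines + 1)]
    return pd.DataFrame(scores, index=pd.Index(truth.genes, name="gene"), columns=lines)


def simulate_survival_cohort(
    truth: SyntheticTruth,
    expression: pd.DataFrame,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient survival times under a proportional-hazards model.

    Event times are exponential with rate ``baseline_hazard *
    exp(sum_g beta_g * (x_g - mean(x_g)))`` over the planted hazard
    genes; censoring is an independent exponential with rate
    ``censor_rate``.  Covariates are centered per gene so the time scale
    stays near ``1/baseline_hazard`` (a pure reparametrization of the
    baseline; Cox estimates are unaffected).

    Returns a table with one row per patient (the expression columns):
    ``time`` (> 0), ``event`` (1 = observed, 0 = censored), then one
    covariate column per gene.
    """
    if baseline_hazard <= 0 or censor_rate <= 0:
        raise ConfigurationError("baseline_hazard and censor_rate must be > 0")
    missing = [g for g in truth.hazard_ids if g not in expression.index]
    if missing:
        raise ConfigurationError(
            f"expression matrix lacks hazard genes: {missing[:5]}"
        )
    rng = np.random.default_rng(seed)
    n = expression.shape[1]
    lp = np.zeros(n)
    for g, beta in truth.hazard_ids.items():
        x = expression.loc[g].to_numpy(dtype=float)
        lp += beta * (x - x.mean())
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / censor_rate, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    out = pd.DataFrame(
        {"time": time, "event": event},
        index=pd.Index(expression.columns, name="patient"),
    )
    covars = expression.T
    covars.index = out.index
    return pd.concat([out, covars], axis=1)
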