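"""Generator contracts: determinism, planted structure, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boolhub.errors import ConfigurationError
from boolhub.synthetic_data import (
    SimulationConfig,
    SyntheticTruth,
    simulate_dependency_screen,
    simulate_multiomics,
    simulate_survival_cohort,
)

SMALL = dict(n_genes=80, n_hub=3, fanout=10, n_tumor=40, n_nat=20, n_housekeeping=10)


def test_identical_seed_gives_bit_identical_cohorts():
    a = simulate_multiomics(SimulationConfig(seed=7, **SMALL))
    b = simulate_multiomics(SimulationConfig(seed=7, **SMALL))
    for x, y in zip(a[:5], b[:5]):
        pd.testing.assert_frame_equal(x, y)
    assert a[5] == b[5]
    c = simulate_multiomics(SimulationConfig(seed=8, **SMALL))
    assert not a[1].equals(c[1])


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_genes=50, n_hub=5, fanout=10, n_housekeeping=10),  # does not fit
        dict(cnv_rate=0.6),
        dict(cnv_rate=-0.1),
        dict(noise_sd=0.0),
        dict(n_tumor=1),
    ],
)
def test_invalid_config_raises_naming_the_invariant(bad):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**bad)


def test_truth_role_sets_are_disjoint():
    *_, truth = simulate_multiomics(SimulationConfig(seed=0, **SMALL))
    targets = {t for tg in truth.target_map.values() for t in tg}
    assert not set(truth.hub_ids) & targets
    assert not set(truth.hub_ids) & set(truth.housekeeping_ids)
    assert not targets & set(truth.housekeeping_ids)
    with pytest.raises(ConfigurationError):
        SyntheticTruth(genes=("a", "b"), hub_ids=("a",), housekeeping_ids=("a",))


def test_housekeeping_genes_carry_no_cnv_or_shift():
    cnv, mt, mn, *_ , truth = simulate_multiomics(SimulationConfig(seed=3, **SMALL))
    hk = list(truth.housekeeping_ids)
    assert (cnv.loc[hk] == 0).all().all()
    # noise-only: mean stays at the shared baseline within a few SE
    se = 1.0 / np.sqrt(mt.shape[1] * len(hk))
    assert abs(mt.loc[hk].to_numpy().mean() - 10.0) < 5 * se


def test_hub_up_state_shifts_targets_by_reg_effect():
    """Targets average reg_effect higher when their hub is up vs normal."""
    cfg = SimulationConfig(n_genes=300, n_hub=10, fanout=20, reg_effect=2.0,
                           noise_sd=1.0, n_tumor=60, seed=5)
    cnv, mt, *_ , truth = simulate_multiomics(cfg)
    diffs, ses = [], []
    for hub, targets in truth.target_map.items():
        dev = mt.loc[hub] - 10.0
        up = dev > 1.64 * cfg.noise_sd
        normal = dev.abs() <= 1.64 * cfg.noise_sd
        if up.sum() < 5 or normal.sum() < 5:
            continue
        tvals = mt.loc[list(targets)]
        d = tvals.loc[:, up].mean(axis=1) - tvals.loc[:, normal].mean(axis=1)
        diffs.append(d.mean())
        # per-target noise ~ sd(mrna); conservative SE of the block mean
        ses.append(tvals.to_numpy().std() / np.sqrt(len(targets) * min(up.sum(), normal.sum())))
    assert len(diffs) >= 8
    for d, se in zip(diffs, ses):
        assert abs(d - cfg.reg_effect) < 3 * max(se, 0.15)


def test_mrna_protein_correlation_positive_under_propagation():
    _, mt, _, pt, _, truth = simulate_multiomics(SimulationConfig(seed=2, **SMALL))
    r = [stats.pearsonr(mt.loc[g], pt.loc[g])[0] for g in list(truth.genes)[:30]]
    assert all(x > 0 for x in r)


class TestDependencyScreen:
    def test_essential_gene_scores_fall_below_threshold(self):
        *_, truth = simulate_multiomics(SimulationConfig(seed=1, **SMALL))
        dep = simulate_dependency_screen(truth, n_lines=90, essential_mean=-1.0,
                                         noise_sd=0.1, seed=4)
        ess = truth.essential_ids[0]
        assert (dep.loc[ess] < -0.5).sum() >= 85

    def test_background_gene_rarely_below_threshold(self):
        *_, truth = simulate_multiomics(SimulationConfig(seed=1, **SMALL))
        dep = simulate_dependency_screen(truth, n_lines=90, noise_sd=0.1, seed=4)
        bg = [g for g in truth.genes if g not in set(truth.essential_ids)]
        frac = (dep.loc[bg] < -0.5).to_numpy().mean()
        assert frac < 0.01  # Phi(-5) is essentially zero

    def test_deterministic_and_validates_n_lines(self):
        *_, truth = simulate_multiomics(SimulationConfig(seed=1, **SMALL))
        a = simulate_dependency_screen(truth, n_lines=10, seed=9)
        b = simulate_dependency_screen(truth, n_lines=10, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ConfigurationError):
            simulate_dependency_screen(truth, n_lines=0)


class TestSurvivalCohort:
    def _null_truth(self, n_genes=100):
        genes = tuple(f"G{i:03d}" for i in range(n_genes))
        return SyntheticTruth(genes=genes, hub_ids=())

    def test_null_effect_recovers_hr_near_one(self):
        rng = np.random.default_rng(0)
        truth = self._null_truth()
        expr = pd.DataFrame(rng.normal(10, 1, size=(100, 500)),
                            index=truth.genes,
                            columns=[f"P{i}" for i in range(500)])
        surv = simulate_survival_cohort(truth, expr, seed=1)
        from boolhub.gene_stats import univariate_cox

        res = univariate_cox(surv, "G000")
        assert abs(res.beta) < 3 * res.se

    def test_single_hazard_gene_recovered(self):
        rng = np.random.default_rng(1)
        genes = tuple(f"G{i:03d}" for i in range(5))
        truth = SyntheticTruth(genes=genes, hub_ids=(), hazard_ids={"G000": 0.7})
        expr = pd.DataFrame(rng.normal(0, 1, size=(5, 1000)), index=genes,
                            columns=[f"P{i}" for i in range(1000)])
        surv = simulate_survival_cohort(truth, expr, baseline_hazard=0.1,
                                        censor_rate=1e-9, seed=2)
        assert surv["event"].all()  # effectively uncensored
        from boolhub.gene_stats import univariate_cox

        hr = univariate_cox(surv, "G000").hr
        assert np.exp(0.7) * 0.8 < hr < np.exp(0.7) * 1.2

    def test_event_fraction_follows_competing_exponentials(self):
        rng = np.random.default_rng(2)
        truth = self._null_truth(10)
        expr = pd.DataFrame(rng.normal(0, 1, size=(10, 4000)), index=truth.genes,
                            columns=[f"P{i}" for i in range(4000)])
        surv = simulate_survival_cohort(truth, expr, baseline_hazard=0.05,
                                        censor_rate=0.45, seed=3)
        expected = 0.05 / (0.05 + 0.45)
        assert abs(surv["event"].mean() - expected) < 0.025

    def test_nonpositive_rates_rejected(self):
        truth = self._null_truth(2)
        expr = pd.DataFrame(np.ones((2, 4)), index=truth.genes,
                            columns=list("abcd"))
        with pytest.raises(ConfigurationError):
            simulate_survival_cohort(truth, expr, baseline_hazard=0.0)
        with pytest.raises(ConfigurationError):
            simulate_survival_cohort(truth, expr, censor_rate=-1.0)
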