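import math

import numpy as np
import pytest

from mrmediate.estimators import ivw
from mrmediate.harmonization import harmonize_pair, kept_instruments
from mrmediate.sensitivity import (
    SensitivityError,
    cochran_q,
    egger_intercept_test,
    funnel_data,
    leave_one_out,
    mr_presso,
    radial_mr,
    sensitivity_report,
)
from mrmediate.synthetic import SimulationConfig, plant_outliers, simulate_chain

from conftest import make_inst, random_instruments


def null_instruments(seed, theta=0.443, select=True, **overrides):
    """Harmonized instruments from a homogeneous (no-pleiotropy) simulation.

    By default the significance/F-statistic selection funnel is applied
    first, as in the real pipeline; weak unselected instruments can flip
    orientation and distort Egger/funnel diagnostics.
    """
    from mrmediate.instruments import select_instruments

    cfg = SimulationConfig(seed=seed, theta_direct=theta, b1=0.0, b2=0.0,
                           n_snp_mediator=1, **overrides)
    exposure, _, outcome, _ = simulate_chain(cfg)
    if select:
        exposure, _ = select_instruments(exposure)
    insts, _ = harmonize_pair(exposure, outcome.subset(exposure.rsids))
    return kept_instruments(insts)


class TestCochranQ:
    def test_three_snp_hand_arithmetic(self, three_snp_instruments):
        res = cochran_q(three_snp_instruments, "ivw")
        assert res.q_stat == pytest.approx(2.0, abs=1e-10)
        assert res.df == 2
        assert res.pval == pytest.approx(math.exp(-1.0), abs=1e-10)

    def test_identical_ratios_give_zero(self):
        insts = [make_inst(f"rs{j}", 0.1 * (j + 1), 0.04 * (j + 1), 0.01) for j in range(4)]
        res = cochran_q(insts, "ivw")
        assert res.q_stat == pytest.approx(0.0, abs=1e-12) and res.pval == pytest.approx(1.0)

    def test_egger_variant_zero_on_exact_line(self):
        insts = [make_inst(f"rs{j}", x, 0.03 + 0.4 * x, 0.01) for j, x in
                 enumerate([0.05, 0.1, 0.2, 0.3])]
        res = cochran_q(insts, "egger")
        assert res.q_stat == pytest.approx(0.0, abs=1e-10)
        assert res.df == 2

    def test_matches_textbook_sum(self, rng):
        insts = random_instruments(rng, 6, noise=2.0)
        ratios = np.array([h.beta_out / h.beta_exp for h in insts])
        w = np.array([(h.beta_exp / h.se_out) ** 2 for h in insts])
        beta = np.sum(w * ratios) / np.sum(w)
        oracle = np.sum(w * (ratios - beta) ** 2)
        assert cochran_q(insts, "ivw").q_stat == pytest.approx(oracle, abs=1e-10)

    def test_null_pvalues_approximately_uniform(self):
        # Global null (theta = 0): Q is exactly chi-square distributed.
        ps = [cochran_q(null_instruments(s, theta=0.0, n_exposure=300_000,
                                         n_outcome=300_000), "ivw").pval
              for s in range(200)]
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - np.arange(1, 201) / 200))
        assert ks < 0.1


class TestEggerIntercept:
    def test_planted_intercept_detected(self):
        insts = [make_inst(f"rs{j}", x, 0.03 + 0.4 * x, 0.001) for j, x in
                 enumerate(np.linspace(0.05, 0.4, 8))]
        b0, se, p = egger_intercept_test(insts)
        assert b0 == pytest.approx(0.03, abs=1e-8)
        assert p < 1e-6

    def test_directional_pleiotropy_mean_recovered(self):
        # Planted directional pleiotropy mu = 0.02 on every SNP.
        from mrmediate.instruments import select_instruments

        mu, reps = 0.02, 200
        est = []
        for s in range(reps):
            cfg = SimulationConfig(seed=s, theta_direct=0.3, b1=0, b2=0, n_snp_mediator=1,
                                   pleiotropy_fraction=1.0, pleiotropy_mean=mu,
                                   pleiotropy_sd=0.002)
            exposure, _, outcome, _ = simulate_chain(cfg)
            exposure, _ = select_instruments(exposure)
            insts, _ = harmonize_pair(exposure, outcome.subset(exposure.rsids))
            est.append(egger_intercept_test(kept_instruments(insts))[0])
        est = np.array(est)
        mc_se = est.std(ddof=1) / math.sqrt(reps)
        assert abs(est.mean() - mu) < 2 * mc_se


class TestLeaveOneOut:
    def test_row_count_and_homogeneous_betas(self):
        insts = [make_inst(f"rs{j}", 0.1, 0.04, 0.01) for j in range(5)]
        table = leave_one_out(insts)
        assert len(table) == 6
        assert np.allclose(table["beta"], 0.4)

    def test_outlier_omission_is_extreme_and_matches_bruteforce(self, rng):
        insts = random_instruments(rng, 8, noise=1.0)
        h = insts[3]
        insts[3] = make_inst(h.rsid, h.beta_exp, h.beta_out + 0.1, h.se_out, h.se_exp)
        table = leave_one_out(insts, ivw_mode="fixed").set_index("omitted")
        # Brute-force recomputation per omission.
        for omit in [i.rsid for i in insts]:
            sub = [i for i in insts if i.rsid != omit]
            assert table.loc[omit, "beta"] == pytest.approx(ivw(sub, "fixed").beta, abs=1e-12)
        loo_betas = table.drop(index="none (all SNPs)")["beta"]
        assert loo_betas.idxmin() == insts[3].rsid  # removing the high outlier drops the estimate most


class TestFunnel:
    def test_three_snp_precision(self, three_snp_instruments):
        table, refs = funnel_data(three_snp_instruments)
        assert len(table) == 3
        assert np.allclose(table["precision"], 10.0)
        assert "ivw" in refs and "egger" in refs

    def test_empty_set(self):
        table, refs = funnel_data([])
        assert table.empty and refs == {}

    def test_symmetric_set_has_flat_precision_trend(self):
        insts = null_instruments(0)
        table, _ = funnel_data(insts)
        slope = np.polyfit(table["precision"], table["ratio"], 1)[0]
        # ratio should not trend with precision in the absence of pleiotropy
        assert abs(slope) * table["precision"].mean() < 0.05


class TestRadial:
    def test_homogeneous_no_outliers_estimate_matches_ivw(self):
        insts = [make_inst(f"rs{j}", 0.1 * (j + 1), 0.04 * (j + 1), 0.01, 1e-8)
                 for j in range(5)]
        res = radial_mr(insts)
        assert res.outlier_rsids == []
        assert res.beta == pytest.approx(ivw(insts, "fixed").beta, abs=1e-9)

    def test_extreme_ratio_flagged(self):
        insts = [make_inst(f"rs{j}", 0.1, 0.04, 0.01) for j in range(5)]
        insts.append(make_inst("rs_out", 0.1, 0.4, 0.01))
        res = radial_mr(insts)
        assert "rs_out" in res.outlier_rsids

    def test_q_decomposition_identity(self, rng):
        insts = random_instruments(rng, 7, noise=2.0)
        res = radial_mr(insts)
        assert sum(res.q_per_snp.values()) == pytest.approx(res.q_stat, abs=1e-10)


class TestPresso:
    def test_reproducible_given_seed(self):
        insts = null_instruments(3)
        a = mr_presso(insts, n_sim=200, seed=42)
        b = mr_presso(insts, n_sim=200, seed=42)
        assert a.global_p == b.global_p and a.global_rss == b.global_rss
        assert a.outlier_rsids == b.outlier_rsids

    def test_outlier_free_corrected_equals_uncorrected(self):
        insts = null_instruments(4)
        res = mr_presso(insts, n_sim=200, seed=1)
        assert res.outlier_rsids == []
        assert res.corrected.beta == pytest.approx(ivw(insts).beta, abs=1e-12)

    def test_planted_outlier_flagged(self):
        cfg = SimulationConfig(seed=5, theta_direct=0.443, b1=0, b2=0, n_snp_mediator=1)
        exposure, _, outcome, _ = simulate_chain(cfg)
        outcome = outcome.subset(exposure.rsids)
        target = exposure.rsids[0]
        outcome = plant_outliers(outcome, [target], 10 * outcome[target].se)
        insts, _ = harmonize_pair(exposure, outcome)
        res = mr_presso(kept_instruments(insts), n_sim=500, seed=2)
        assert res.global_p < 0.05
        assert target in res.outlier_rsids
        assert res.distortion_p is not None
        # Removing the outlier must not increase heterogeneity on the retained set.
        retained = [h for h in kept_instruments(insts) if h.rsid not in res.outlier_rsids]
        assert cochran_q(retained, "ivw").q_stat < cochran_q(kept_instruments(insts), "ivw").q_stat

    def test_too_few_instruments_rejected(self):
        insts = [make_inst(f"rs{j}", 0.1, 0.04, 0.01) for j in range(3)]
        with pytest.raises(SensitivityError, match="presso"):
            mr_presso(insts, n_sim=200, seed=0)


def test_report_assembles_all_blocks():
    insts = null_instruments(6)
    report = sensitivity_report(insts, n_sim=200, seed=0)
    for key in ("heterogeneity_ivw", "heterogeneity_egger", "egger_intercept",
                "radial", "presso"):
        assert key in report


def test_insufficient_instruments_raise():
    one = [make_inst("rs1", 0.1, 0.04, 0.01)]
    with pytest.raises(SensitivityError):
        cochran_q(one, "ivw")
    with pytest.raises(SensitivityError):
        radial_mr(one)
    with pytest.raises(SensitivityError):
        leave_one_out(one)
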