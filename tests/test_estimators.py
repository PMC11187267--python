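import math

import numpy as np
import pytest

from mrmediate.estimators import (
    EstimatorError,
    ivw,
    mode_estimate,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import make_inst, random_instruments


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(make_inst("rs1", 0.1, 0.05, 0.01))
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.se == pytest.approx(0.1, abs=1e-12)

    def test_zero_outcome_effect(self):
        assert wald_ratio(make_inst("rs1", 0.1, 0.0, 0.01)).beta == 0.0

    def test_sign_symmetry(self):
        a = wald_ratio(make_inst("rs1", 0.1, 0.05, 0.01))
        b = wald_ratio(make_inst("rs1", -0.1, -0.05, 0.01))
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(EstimatorError, match="beta_exp"):
            wald_ratio(make_inst("rs1", 0.0, 0.05, 0.01))


class TestIVW:
    def test_three_snp_hand_example(self, three_snp_instruments):
        est = ivw(three_snp_instruments, mode="fixed")
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.se == pytest.approx(0.1 / math.sqrt(3), abs=1e-10)

    def test_identical_ratios_recovered_regardless_of_weights(self):
        insts = [make_inst(f"rs{j}", 0.05 * (j + 1), 0.02 * (j + 1), 0.001 * (j + 1))
                 for j in range(4)]
        for mode in ("fixed", "multiplicative_random"):
            est = ivw(insts, mode=mode)
            assert est.beta == pytest.approx(0.4, abs=1e-12)

    def test_single_instrument_degrades_to_wald(self):
        inst = make_inst("rs1", 0.1, 0.05, 0.01)
        assert ivw([inst]).beta == wald_ratio(inst).beta

    def test_no_instruments_rejected(self):
        with pytest.raises(EstimatorError, match="no_instruments"):
            ivw([])

    def test_matches_wls_through_origin_oracle(self, rng):
        # IVW with first-order weights equals the weighted least-squares slope
        # of beta_out on beta_exp through the origin, weights 1/se_out^2.
        for k in (3, 4, 6):
            insts = random_instruments(rng, k, noise=1.0)
            bx = np.array([h.beta_exp for h in insts])
            by = np.array([h.beta_out for h in insts])
            w = np.array([1 / h.se_out**2 for h in insts])
            oracle = np.sum(w * bx * by) / np.sum(w * bx**2)
            assert ivw(insts, mode="fixed").beta == pytest.approx(oracle, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        insts = random_instruments(rng, 6, noise=3.0)
        assert ivw(insts, mode="multiplicative_random").se >= ivw(insts, mode="fixed").se


class TestEgger:
    def test_exact_fit_line(self):
        insts = [make_inst(f"rs{j}", x, 0.03 + 0.4 * x, 0.01) for j, x in
                 enumerate([0.05, 0.1, 0.2, 0.3])]
        est = mr_egger(insts)
        assert est.beta == pytest.approx(0.4, abs=1e-10)
        assert est.intercept == pytest.approx(0.03, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        insts = random_instruments(rng, 4, noise=2.0)
        bx = np.array([h.beta_exp for h in insts])
        by = np.array([h.beta_out for h in insts])
        w = np.array([1 / h.se_out**2 for h in insts])
        # Weighted normal equations: [sum w, sum w x; sum w x, sum w x^2] [a; b]
        A = np.array([[w.sum(), (w * bx).sum()], [(w * bx).sum(), (w * bx**2).sum()]])
        rhs = np.array([(w * by).sum(), (w * bx * by).sum()])
        a, b = np.linalg.solve(A, rhs)
        est = mr_egger(insts)
        assert est.beta == pytest.approx(b, abs=1e-10)
        assert est.intercept == pytest.approx(a, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(EstimatorError, match="insufficient"):
            mr_egger([make_inst("rs1", 0.1, 0.05, 0.01), make_inst("rs2", 0.2, 0.1, 0.01)])

    def test_orientation_invariance_of_fit(self, rng):
        # Flipping the sign of one SNP's (beta_exp, beta_out) is an allele
        # relabelling and must not change the fit.
        insts = random_instruments(rng, 5, noise=2.0)
        flipped = list(insts)
        h = flipped[2]
        flipped[2] = make_inst(h.rsid, -h.beta_exp, -h.beta_out, h.se_out, h.se_exp)
        a, b = mr_egger(insts), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        insts = [
            make_inst("rs1", 0.1, 0.04, 0.01),
            make_inst("rs2", 0.1, 0.05, 0.01),
            make_inst("rs3", 0.1, 0.06, 0.01),
        ]
        est = weighted_median(insts, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_computation_oracle(self, rng):
        insts = random_instruments(rng, 6, noise=2.0)
        ratios = np.array([h.beta_out / h.beta_exp for h in insts])
        w = np.array([(abs(h.beta_exp) / h.se_out) ** 2 for h in insts])
        order = np.argsort(ratios)
        r, ws = ratios[order], w[order]
        cum = (np.cumsum(ws) - 0.5 * ws) / ws.sum()
        below = np.where(cum < 0.5)[0][-1]
        frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
        oracle = r[below] + frac * (r[below + 1] - r[below])
        est = weighted_median(insts, n_boot=50, seed=0)
        assert est.beta == pytest.approx(oracle, abs=1e-10)

    def test_robust_to_minority_invalid_instruments(self):
        valid = [make_inst(f"v{j}", 0.1, 0.05, 0.01) for j in range(10)]
        invalid = [make_inst(f"i{j}", 0.1, 0.5, 0.012) for j in range(4)]
        insts = valid + invalid
        est = weighted_median(insts, n_boot=50, seed=0)
        assert abs(est.beta - 0.5) < 0.1
        assert abs(ivw(insts).beta - 0.5) > 0.5  # IVW dragged by the invalid set

    def test_equal_weights_equal_sample_median_odd_sets(self, rng):
        for k in (3, 5, 7):
            bx = 0.1
            by = rng.uniform(0.01, 0.09, k)
            insts = [make_inst(f"rs{j}", bx, float(by[j]), 0.01) for j in range(k)]
            est = weighted_median(insts, n_boot=10, seed=0)
            assert est.beta == pytest.approx(np.median(by / bx), abs=1e-12)

    def test_dominant_weight_returns_its_ratio(self):
        insts = [
            make_inst("rs1", 0.1, 0.05, 1e-6),
            make_inst("rs2", 0.1, 0.09, 10.0),
            make_inst("rs3", 0.1, 0.01, 10.0),
        ]
        est = weighted_median(insts, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-6)


class TestMode:
    def test_majority_cluster(self):
        insts = [make_inst(f"rs{j}", 0.1, b, 0.01) for j, b in
                 enumerate([0.05, 0.05, 0.05, 0.2])]
        est = mode_estimate(insts, "simple", n_boot=20, seed=0)
        assert abs(est.beta - 0.5) < 0.05

    def test_all_identical_ratios_exact(self):
        insts = [make_inst(f"rs{j}", 0.1 * (j + 1), 0.05 * (j + 1), 0.01) for j in range(4)]
        est = mode_estimate(insts, "weighted", n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_dense_grid_oracle(self, rng):
        from scipy import stats

        insts = random_instruments(rng, 7, noise=3.0)
        ratios = np.array([h.beta_out / h.beta_exp for h in insts])
        w = np.array([(abs(h.beta_exp) / h.se_out) ** 2 for h in insts])
        w = w / w.sum()
        n = len(ratios)
        h = 0.9 * min(np.std(ratios, ddof=1),
                      stats.median_abs_deviation(ratios, scale="normal")) * n ** (-0.2)

        def dens(x):
            return np.sum(w * stats.norm.pdf(x, ratios, h))

        grid = np.arange(ratios.min() - 3 * h, ratios.max() + 3 * h, 1e-4)
        best = grid[np.argmax([dens(x) for x in grid])]
        # Independent local refinement of the grid argmax by golden section.
        lo, hi = best - 2e-4, best + 2e-4
        invphi = (math.sqrt(5) - 1) / 2
        c, d = hi - invphi * (hi - lo), lo + invphi * (hi - lo)
        for _ in range(200):
            if dens(c) > dens(d):
                hi, d = d, c
                c = hi - invphi * (hi - lo)
            else:
                lo, c = c, d
                d = lo + invphi * (hi - lo)
        oracle = (lo + hi) / 2
        est = mode_estimate(insts, "weighted", n_boot=10, seed=0)
        assert est.beta == pytest.approx(oracle, abs=1e-8)


class TestOddsRatioTransform:
    def test_identity_at_zero(self):
        or_v, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_v == 1.0
        assert lo * hi == pytest.approx(1.0, abs=1e-12)

    def test_headline_interval_roundtrip(self):
        # beta and se recovered from a printed OR of 1.557 (95% CI 1.097-2.211);
        # the point estimate is the geometric mean of the CI bounds in log space.
        beta = 0.5 * (math.log(2.211) + math.log(1.097))
        se = (math.log(2.211) - math.log(1.097)) / (2 * 1.959964)
        or_v, lo, hi = to_odds_ratio(beta, se)
        assert or_v == pytest.approx(1.557, abs=5e-4)
        assert lo == pytest.approx(1.097, abs=1e-10)
        assert hi == pytest.approx(2.211, abs=1e-10)

    def test_negation_inverts_and_swaps(self):
        or_v, lo, hi = to_odds_ratio(0.3, 0.1)
        or_n, lo_n, hi_n = to_odds_ratio(-0.3, 0.1)
        assert or_n == pytest.approx(1 / or_v, abs=1e-12)
        assert lo_n == pytest.approx(1 / hi, abs=1e-12)
        assert hi_n == pytest.approx(1 / lo, abs=1e-12)


class TestSharedInvariants:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_outcome_scale_equivariance(self, rng, c):
        insts = random_instruments(rng, 5, noise=2.0)
        scaled = [make_inst(h.rsid, h.beta_exp, c * h.beta_out, c * h.se_out, h.se_exp)
                  for h in insts]
        for fn in (lambda i: ivw(i, "fixed"), lambda i: ivw(i), mr_egger,
                   lambda i: weighted_median(i, n_boot=30, seed=1)):
            a, b = fn(insts), fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-9)
            assert b.se == pytest.approx(c * a.se, rel=0.3)  # bootstrap SEs are noisy

    def test_allele_flip_invariance(self, rng):
        insts = random_instruments(rng, 5, noise=2.0)
        flipped = list(insts)
        h = flipped[0]
        flipped[0] = make_inst(h.rsid, -h.beta_exp, -h.beta_out, h.se_out, h.se_exp)
        for fn in (lambda i: ivw(i, "fixed"), mr_egger,
                   lambda i: weighted_median(i, n_boot=30, seed=2),
                   lambda i: mode_estimate(i, "weighted", n_boot=20, seed=2)):
            assert fn(flipped).beta == pytest.approx(fn(insts).beta, abs=1e-9)

    def test_or_value_is_exact_exponential_of_beta(self, rng):
        insts = random_instruments(rng, 4, noise=1.0)
        est = ivw(insts)
        assert est.or_value == math.exp(est.beta)
        assert est.ci_low < est.or_value < est.ci_high
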