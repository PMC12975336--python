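"""Correlated-instrument MR estimators against closed forms and oracles."""

import numpy as np
import pytest
from scipy import stats

from drugmr.errors import CollinearityError, InsufficientInstrumentsError
from drugmr.estimators import (
    Z95,
    cochran_q,
    ivw_correlated,
    mr_egger_correlated,
    mvmr_correlated,
    wald_ratio,
)
from drugmr.ld import InstrumentSet, LDMatrix, condition_psd

from conftest import make_iset, make_variant


class TestWaldRatio:
    def test_direct_ratio(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.ci_low == pytest.approx(0.5 - Z95 * 0.1, abs=1e-9)
        assert est.ci_high == pytest.approx(0.5 + Z95 * 0.1, abs=1e-9)

    def test_null_numerator(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert est.theta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)

    def test_second_order_se_never_smaller(self, rng):
        for _ in range(200):
            bx = rng.uniform(0.01, 0.5) * rng.choice([-1, 1])
            sx, sy = rng.uniform(0.005, 0.1, size=2)
            by = rng.normal(0, 0.2)
            first = wald_ratio(bx, sx, by, sy).se
            second = wald_ratio(bx, sx, by, sy, second_order=True).se
            assert second >= first


class TestIVWCorrelated:
    def test_single_snp_equals_wald(self):
        iset = make_iset([0.1], [0.01], [0.05], [0.01])
        ivw = ivw_correlated(iset)
        wald = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert ivw.theta == pytest.approx(wald.theta, abs=1e-12)
        assert ivw.se == pytest.approx(wald.se, abs=1e-12)

    def test_closed_form_identity_ld(self):
        iset = make_iset([1.0, 1.0], [0.1, 0.1], [1.0, 3.0], [1.0, 1.0])
        est = ivw_correlated(iset, model="fixed")
        assert est.theta == pytest.approx(2.0, abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_matches_textbook_ivw_with_identity_ld(self, rng):
        m = 8
        bx = rng.uniform(0.05, 0.3, m)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.02, 0.08, m)
        iset = make_iset(bx, np.full(m, 0.01), by, sy)
        est = ivw_correlated(iset, model="fixed")
        w = bx ** 2 / sy ** 2
        ratio = by / bx
        textbook = (w * ratio).sum() / w.sum()
        assert est.theta == pytest.approx(textbook, abs=1e-10)
        assert est.se == pytest.approx(w.sum() ** -0.5, abs=1e-10)

    def test_duplicated_snp_collapses_to_single(self):
        variants = [make_variant(1), make_variant(2)]
        r = np.ones((2, 2))
        iset = InstrumentSet(
            variants=variants,
            beta_x=np.array([0.2, 0.2]), se_x=np.array([0.01, 0.01]),
            beta_y=np.array([0.08, 0.08]), se_y=np.array([0.02, 0.02]),
            ld=LDMatrix(variants, condition_psd(r)),
        )
        est = ivw_correlated(iset, model="fixed")
        single = wald_ratio(0.2, 0.01, 0.08, 0.02)
        assert est.theta == pytest.approx(single.theta, rel=1e-6)
        assert est.se == pytest.approx(single.se, rel=1e-4)

    def test_scale_equivariance(self, rng):
        m = 6
        bx = rng.uniform(0.05, 0.3, m)
        by = rng.normal(0, 0.1, m)
        sy = rng.uniform(0.02, 0.08, m)
        r = condition_psd(np.corrcoef(rng.standard_normal((m, m + 3))))
        base = ivw_correlated(make_iset(bx, 0 * bx + 0.01, by, sy, r),
                              model="fixed")
        c = 3.7
        scaled = ivw_correlated(make_iset(c * bx, 0 * bx + 0.01, by, sy, r),
                                model="fixed")
        assert scaled.theta == pytest.approx(base.theta / c, rel=1e-12)

    def test_default_model_switches_on_count(self):
        small = make_iset([0.1] * 3, [0.01] * 3, [0.05, 0.04, 0.06],
                          [0.01] * 3)
        large = make_iset([0.1] * 4, [0.01] * 4, [0.05, 0.04, 0.06, 0.05],
                          [0.01] * 4)
        assert ivw_correlated(small).model == "fixed"
        assert ivw_correlated(large).model == "multiplicative_random"

    def test_random_effects_se_at_least_fixed(self, rng):
        m = 10
        bx = rng.uniform(0.05, 0.3, m)
        by = rng.normal(0.3 * bx, 0.1)
        sy = rng.uniform(0.02, 0.08, m)
        fixed = ivw_correlated(make_iset(bx, 0 * bx + 0.01, by, sy),
                               model="fixed")
        random = ivw_correlated(make_iset(bx, 0 * bx + 0.01, by, sy),
                                model="multiplicative_random")
        assert random.se >= fixed.se
        assert random.theta == pytest.approx(fixed.theta, abs=1e-14)


class TestCochranQ:
    def test_exact_fit_gives_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        iset = make_iset(bx, 0 * bx + 0.01, 0.5 * bx, [0.02] * 3)
        q, p = cochran_q(iset, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_identity_ld_reduction(self, rng):
        m, theta = 5, 0.4
        bx = rng.uniform(0.05, 0.3, m)
        by = rng.normal(theta * bx, 0.05)
        sy = rng.uniform(0.02, 0.08, m)
        iset = make_iset(bx, 0 * bx + 0.01, by, sy)
        q, _ = cochran_q(iset, theta)
        manual = (((by - theta * bx) / sy) ** 2).sum()
        assert q == pytest.approx(manual, rel=1e-10)


class TestEgger:
    def test_constant_outcome_degenerate_regression(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        iset = make_iset(bx, 0 * bx + 0.01, np.full(4, 0.07), [0.02] * 4)
        est = mr_egger_correlated(iset)
        assert est.theta == pytest.approx(0.0, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.07, abs=1e-10)

    def test_orientation_invariance(self, rng):
        m = 6
        bx = rng.uniform(0.05, 0.3, m)
        by = rng.normal(0.3 * bx + 0.02, 0.03)
        sy = rng.uniform(0.02, 0.08, m)
        r = condition_psd(np.corrcoef(rng.standard_normal((m, m + 3))))
        base = mr_egger_correlated(make_iset(bx, 0 * bx + 0.01, by, sy, r))
        # flip the allele coding of SNP 2: beta signs and LD signs co-flip
        s = np.ones(m)
        s[2] = -1
        flipped = mr_egger_correlated(
            make_iset(bx * s, 0 * bx + 0.01, by * s, sy, r * np.outer(s, s)))
        assert flipped.theta == pytest.approx(base.theta, rel=1e-10)
        assert flipped.egger_intercept == pytest.approx(
            base.egger_intercept, rel=1e-10)

    def test_fewer_than_three_instruments_rejected(self):
        iset = make_iset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger_correlated(iset)

    def test_intercept_coverage_under_no_pleiotropy(self, rng):
        """With zero true intercept the intercept CI covers 0 ~95% of the
        time (50 instruments, 400 replicates)."""
        m, theta, n_rep = 50, 0.5, 400
        bx_true = rng.uniform(0.05, 0.3, m)
        covered = 0
        for _ in range(n_rep):
            sy = np.full(m, 0.02)
            by = rng.normal(theta * bx_true, sy)
            est = mr_egger_correlated(
                make_iset(bx_true, np.full(m, 1e-6), by, sy))
            lo = est.egger_intercept - Z95 * est.egger_intercept_se
            hi = est.egger_intercept + Z95 * est.egger_intercept_se
            covered += lo <= 0 <= hi
        assert 0.91 <= covered / n_rep <= 0.98

    def test_slope_with_zero_intercept_equals_ivw(self, rng):
        """Constraining the Egger intercept to zero recovers IVW on the
        same weight matrix (orientation leaves the GLS solution invariant)."""
        m = 7
        bx = rng.uniform(-0.3, 0.3, m)
        bx[np.abs(bx) < 0.05] = 0.1
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.02, 0.08, m)
        r = condition_psd(np.corrcoef(rng.standard_normal((m, m + 3))))
        iset = make_iset(bx, 0 * bx + 0.01, by, sy, r)
        ivw = ivw_correlated(iset, model="fixed")
        # constrained GLS fit on the Egger-oriented system
        s = np.where(bx < 0, -1.0, 1.0)
        omega = condition_psd(r * np.outer(s, s)) * np.outer(sy, sy)
        x_o, y_o = bx * s, by * s
        slope = (x_o @ np.linalg.solve(omega, y_o)) \
            / (x_o @ np.linalg.solve(omega, x_o))
        assert slope == pytest.approx(ivw.theta, rel=1e-10)


class TestMVMR:
    def test_single_exposure_reduces_to_ivw(self, rng):
        m = 6
        bx = rng.uniform(0.05, 0.3, m)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.02, 0.08, m)
        r = condition_psd(np.corrcoef(rng.standard_normal((m, m + 3))))
        iset = make_iset(bx, 0 * bx + 0.01, by, sy, r)
        mv = mvmr_correlated(iset)[0]
        ivw = ivw_correlated(iset, model="fixed")
        assert mv.theta == pytest.approx(ivw.theta, rel=1e-12)
        assert mv.se == pytest.approx(ivw.se, rel=1e-12)

    def test_duplicated_exposure_column_rejected(self, rng):
        m = 5
        bx = rng.uniform(0.05, 0.3, m)
        iset = make_iset(np.column_stack([bx, bx]),
                         np.full((m, 2), 0.01),
                         rng.normal(0, 0.1, m), np.full(m, 0.02))
        with pytest.raises(CollinearityError):
            mvmr_correlated(iset)

    def test_orthogonal_null_exposure_ci_coverage(self, rng):
        """A second exposure with no true outcome effect: its 95% CI covers
        zero at the nominal rate over replicates."""
        m, n_rep = 20, 400
        bx1 = rng.uniform(0.1, 0.3, m)
        bx2 = rng.permutation(rng.uniform(0.1, 0.3, m))
        covered = 0
        for _ in range(n_rep):
            sy = np.full(m, 0.02)
            by = rng.normal(0.4 * bx1 + 0.0 * bx2, sy)
            iset = make_iset(np.column_stack([bx1, bx2]),
                             np.full((m, 2), 1e-6), by, sy)
            iset.exposure_ids = ["x1", "x2"]
            est = next(e for e in mvmr_correlated(iset)
                       if e.exposure_id == "x2")
            covered += est.ci_low <= 0 <= est.ci_high
        assert 0.92 <= covered / n_rep <= 0.98

    def test_more_exposures_than_snps_rejected(self):
        iset = make_iset(np.array([[0.1, 0.2]]), np.array([[0.01, 0.01]]),
                         [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            mvmr_correlated(iset)
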