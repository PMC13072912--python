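"""Calibration metrics, Eurachem limits, agreement protocol: formulas and
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xrfquant.errors import DomainError, ValidationError
from xrfquant.metrics import (
    AgreementRecord,
    IcpLoqInput,
    assess_agreement,
    calibration_metrics,
    category_summary,
    detection_limits,
    icp_loq,
    limits_from_summary,
)


class TestCalibrationMetrics:
    def test_perfect_prediction(self):
        a = np.array([10.0, 50.0, 200.0, 400.0])
        m = calibration_metrics(a, a, working_range=390.0)
        assert m.r2 == pytest.approx(1.0)
        assert m.sec == pytest.approx(0.0)

    def test_constant_offset_closed_form(self):
        # constant +10 offset: residuals all 10, N = 4, divisor N-1
        a = np.array([0.0, 100.0, 200.0, 300.0])
        m = calibration_metrics(a + 10.0, a, working_range=300.0)
        assert m.sec == pytest.approx(10.0 * np.sqrt(4 / 3))
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(10.0)
        # R2 of predicted-vs-actual penalizes the offset via SS_res
        assert m.r2 == pytest.approx(1.0 - 4 * 100.0 / np.sum(
            (a - a.mean()) ** 2))

    def test_relative_sec_printed_pair(self):
        # SEC = 41.20 over a 611.3 working range prints as 6.74 %
        a = np.array([0.0, 100.0, 300.0])
        m = calibration_metrics(a, a, working_range=611.3)
        got = 100.0 * 41.20 / 611.3
        assert got == pytest.approx(6.74, abs=0.005)
        assert m.relative_sec == pytest.approx(0.0)

    def test_zero_variance_actuals_rejected(self):
        with pytest.raises(ValidationError):
            calibration_metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], 1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_against_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 20)
        a = rng.uniform(0, 600, n)
        if np.ptp(a) == 0:
            a[0] += 1.0
        p = a + rng.normal(0, 25, n)
        wr = float(np.ptp(a))
        m = calibration_metrics(p, a, working_range=wr)
        resid = p - a
        sec = np.sqrt(sum(r * r for r in resid) / (n - 1))
        r2 = 1 - sum(r * r for r in resid) / sum((x - a.mean()) ** 2 for x in a)
        assert m.sec == pytest.approx(sec, rel=1e-12)
        assert m.r2 == pytest.approx(r2, rel=1e-12)
        assert m.relative_sec == pytest.approx(100 * sec / wr, rel=1e-12)


class TestDetectionLimits:
    def test_scenario1_printed_row(self):
        # s0 = 9.39 with n = 3 averaged observations
        est = limits_from_summary(s0=9.39, n=3, actual=128.97,
                                  mean_pred=113.69, element="As")
        assert est.lod == pytest.approx(16.26, abs=0.01)
        assert est.loq == pytest.approx(54.20, abs=0.05)
        assert est.bias_abs == pytest.approx(-15.28, abs=0.005)

    def test_scenario2_pb_printed_row(self):
        est = limits_from_summary(s0=14.94, n=3, actual=208.95,
                                  mean_pred=134.87, element="Pb")
        assert est.lod == pytest.approx(25.87, abs=0.02)
        assert est.loq == pytest.approx(86.23, abs=0.05)
        assert est.bias_abs == pytest.approx(-74.08, abs=0.005)

    def test_identical_predictions_zero_limits(self):
        est = detection_limits([5.0] * 10, n=3, actual=5.0)
        assert est.s0 == 0.0
        assert est.lod == 0.0 and est.loq == 0.0

    def test_loq_lod_ratio_is_kq_over_3(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            est = detection_limits(rng.uniform(50, 200, 10),
                                   n=int(rng.integers(1, 10)),
                                   actual=100.0, kQ=10.0)
            assert est.loq / est.lod == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_invalid_n_rejected(self):
        with pytest.raises(DomainError):
            detection_limits([1.0, 2.0], n=0, actual=1.0)

    @given(seed=st.integers(0, 10_000),
           c=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        preds = rng.uniform(50, 200, 10)
        base = detection_limits(preds, n=3, actual=120.0)
        scaled = detection_limits(c * preds, n=3, actual=c * 120.0)
        assert scaled.s0 == pytest.approx(c * base.s0, rel=1e-9)
        assert scaled.lod == pytest.approx(c * base.lod, rel=1e-9)
        assert scaled.loq == pytest.approx(c * base.loq, rel=1e-9)
        assert scaled.bias_abs == pytest.approx(c * base.bias_abs, rel=1e-9,
                                                abs=1e-9)
        assert scaled.bias_pct == pytest.approx(base.bias_pct, rel=1e-9,
                                                abs=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_against_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        preds = rng.uniform(0, 300, int(rng.integers(2, 15)))
        n = int(rng.integers(1, 10))
        est = detection_limits(preds, n=n, actual=150.0)
        mean = sum(preds) / len(preds)
        s0 = (sum((p - mean) ** 2 for p in preds) / (len(preds) - 1)) ** 0.5
        assert est.s0 == pytest.approx(s0, rel=1e-12)
        assert est.lod == pytest.approx(3 * s0 / n ** 0.5, rel=1e-12)
        assert est.loq == pytest.approx(10 * s0 / n ** 0.5, rel=1e-12)


class TestIcpLoq:
    @pytest.mark.parametrize("sd,slope,expected", [
        (0.1, 1.0, 1.0),
        (0.0, 2.0, 0.0),
        (0.659, 1.0, 6.59),
    ])
    def test_formula(self, sd, slope, expected):
        assert icp_loq(IcpLoqInput(sd, slope)) == pytest.approx(expected)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(DomainError):
            icp_loq(IcpLoqInput(0.1, -1.0))


class TestAgreement:
    def test_crm_within_threshold(self):
        rec = assess_agreement(pred=209.50, actual=260.0, loq=54.20)
        assert rec.error_pct == pytest.approx(-19.42, abs=0.01)
        assert rec.agrees is True

    def test_low_content_absolute_error(self):
        # +30.33 % on 56.84 µg kg⁻¹ is only +17.24 µg kg⁻¹ absolute
        pred = 56.84 * 1.3033
        rec = assess_agreement(pred=pred, actual=56.84, loq=54.20)
        assert rec.error_abs == pytest.approx(17.24, abs=0.01)
        assert rec.agrees is False

    def test_exact_prediction(self):
        rec = assess_agreement(pred=100.0, actual=100.0, loq=10.0)
        assert rec.error_pct == 0.0 and rec.agrees is True

    def test_below_loq_not_quantifiable(self):
        rec = assess_agreement(pred=50.0, actual=5.0, loq=86.23)
        assert rec.quantifiable is False
        assert rec.agrees is None
        assert rec.error_abs == pytest.approx(45.0)

    def test_zero_actual_division_guard(self):
        rec = assess_agreement(pred=3.0, actual=0.0, loq=0.0)
        assert rec.error_pct is None
        assert rec.error_abs == 3.0


def _rec(cat, el, pct=None, abs_err=None, actual=100.0):
    if pct is not None:
        pred = actual * (1 + pct / 100.0)
        return assess_agreement(pred, actual, loq=0.0, element=el,
                                category=cat)
    return assess_agreement(actual + abs_err, actual, loq=actual * 10,
                            element=el, category=cat)


class TestCategorySummary:
    def test_single_record(self):
        out = category_summary([_rec("crm", "As", pct=-19.43)])
        s = out[("crm", "As")]
        assert s["mean"] == pytest.approx(19.43)
        assert s["median"] == pytest.approx(19.43)
        assert s["n"] == 1

    def test_mean_and_median(self):
        recs = [_rec("c", "As", pct=p) for p in (10.0, 20.0, 30.0)]
        s = category_summary(recs)[("c", "As")]
        assert s["mean"] == pytest.approx(20.0)
        assert s["median"] == pytest.approx(20.0)

    def test_even_count_median_is_midpoint(self):
        recs = [_rec("c", "As", pct=p) for p in (11.17, 20.0, 30.0, 40.0)]
        s = category_summary(recs)[("c", "As")]
        assert s["median"] == pytest.approx((20.0 + 30.0) / 2)

    def test_nonquantifiable_category_uses_absolute_error(self):
        recs = [_rec("c", "Pb", abs_err=e) for e in (50.0, 100.0)]
        s = category_summary(recs)[("c", "Pb")]
        assert s["unit"] == "ug_kg"
        assert s["mean"] == pytest.approx(75.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            category_summary([])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_against_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pcts = rng.uniform(-50, 50, int(rng.integers(1, 12)))
        recs = [_rec("c", "As", pct=p) for p in pcts]
        s = category_summary(recs)[("c", "As")]
        errs = sorted(abs(p) for p in pcts)
        n = len(errs)
        med = (errs[n // 2] if n % 2 else (errs[n // 2 - 1] + errs[n // 2]) / 2)
        assert s["mean"] == pytest.approx(sum(errs) / n, rel=1e-12)
        assert s["median"] == pytest.approx(med, rel=1e-12)
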