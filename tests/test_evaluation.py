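"""Agreement statistics against hand arithmetic and their exact invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cowbw.evaluation import (
    aic_compare,
    aicc,
    concordance_bias,
    evaluate,
    msep_decompose,
    obs_vs_pred_test,
)
from cowbw.exceptions import DomainError, SingularFitError


class TestJointTest:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        f, p, intercept, slope = obs_vs_pred_test(x, x)
        assert f == 0.0 and p == 1.0
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(1.0, rel=1e-12)

    def test_five_point_hand_arithmetic(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = np.array([1.5, 1.5, 3.5, 4.0, 5.5])
        # explicit OLS of obs on pred
        beta = np.polyfit(pred, obs, 1)
        sse_full = float(np.sum((obs - np.polyval(beta, pred)) ** 2))
        sse_restricted = float(np.sum((obs - pred) ** 2))
        expected_f = ((sse_restricted - sse_full) / 2) / (sse_full / 3)
        f, p, *_ = obs_vs_pred_test(obs, pred)
        assert f == pytest.approx(expected_f, rel=1e-10)
        assert 0.0 < p < 1.0

    def test_constant_shift_detected(self, rng):
        pred = rng.uniform(0, 10, size=20)
        obs = pred + 10.0
        _, p, *_ = obs_vs_pred_test(obs, pred)
        assert p < 0.05

    def test_degenerate_predictions(self):
        with pytest.raises(SingularFitError):
            obs_vs_pred_test([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])

    def test_p_uniform_under_null(self, rng):
        """When observed = predicted + Gaussian noise, the joint-test p-value
        is uniform (the F test is exact)."""
        pred = rng.uniform(100, 200, size=20)
        pvals = [
            obs_vs_pred_test(pred + rng.normal(0, 3, size=20), pred)[1]
            for _ in range(500)
        ]
        grid = np.sort(pvals)
        ks = np.max(np.abs(grid - (np.arange(1, 501) / 500)))
        assert ks < 0.08


class TestConcordanceBias:
    def test_identical_series(self):
        x = np.array([2.0, 4.0, 7.0, 9.0])
        assert concordance_bias(x, x) == pytest.approx(1.0, rel=1e-14)

    def test_shift_decreases_accuracy(self):
        x = np.array([2.0, 4.0, 7.0, 9.0])
        cbs = [concordance_bias(x, x + s) for s in (0.0, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(cbs, cbs[1:]))
        # closed form for a pure shift: 2 / (2 + s^2/var)
        s, var = 2.0, x.var()
        assert concordance_bias(x, x + s) == pytest.approx(2 / (2 + s * s / var), rel=1e-12)

    def test_doubled_scale_mean_centred(self):
        obs = np.array([-1.0, 0.0, 1.0])
        assert concordance_bias(obs, 2 * obs) == pytest.approx(0.8, rel=1e-14)

    def test_constant_series_rejected(self):
        with pytest.raises(SingularFitError):
            concordance_bias([1.0, 1.0], [1.0, 2.0])

    @given(
        obs=arrays(float, 12, elements=st.floats(1, 100)),
        shift=st.floats(-5, 5),
        scale=st.floats(0.5, 2.0),
    )
    @settings(max_examples=80, derandomize=True)
    def test_bounds_and_equality_condition(self, obs, shift, scale):
        pred = scale * obs + shift
        if obs.std() == 0 or pred.std() == 0:
            return
        cb = concordance_bias(obs, pred)
        assert 0.0 < cb <= 1.0 + 1e-12
        if math.isclose(pred.mean(), obs.mean()) and math.isclose(pred.std(), obs.std()):
            assert cb == pytest.approx(1.0, rel=1e-9)


class TestMSEP:
    def test_perfect_predictions(self):
        x = np.array([1.0, 2.0, 3.0])
        assert msep_decompose(x, x) == (0.0, 0.0, 0.0, 0.0)

    def test_pure_translation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        msep, mb, sys_err, rand_err = msep_decompose(x, x + 3.0)
        assert msep == pytest.approx(9.0, rel=1e-12)
        assert mb == pytest.approx(9.0, rel=1e-12)
        assert sys_err == pytest.approx(0.0, abs=1e-12)
        assert rand_err == pytest.approx(0.0, abs=1e-12)

    def test_six_point_term_by_term(self):
        obs = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0])
        pred = np.array([11.0, 11.5, 10.0, 13.0, 12.5, 12.0])
        msep, mb, sys_err, rand_err = msep_decompose(obs, pred)
        # brute-force each published term with population moments
        mo, mp = obs.mean(), pred.mean()
        so, sp = obs.std(), pred.std()
        r = np.mean((obs - mo) * (pred - mp)) / (so * sp)
        assert msep == pytest.approx(np.mean((pred - obs) ** 2), rel=1e-14)
        assert mb == pytest.approx((mp - mo) ** 2, rel=1e-12)
        assert sys_err == pytest.approx((sp - r * so) ** 2, rel=1e-12)
        assert rand_err == pytest.approx((1 - r * r) * so * so, rel=1e-12)

    @given(
        obs=arrays(float, st.integers(2, 30), elements=st.floats(-50, 50)),
        noise=st.floats(-10, 10),
        scale=st.floats(-2, 2),
    )
    @settings(max_examples=100, derandomize=True)
    def test_components_sum_exactly(self, obs, noise, scale):
        pred = scale * obs + noise
        msep, mb, sys_err, rand_err = msep_decompose(obs, pred)
        assert mb + sys_err + rand_err == pytest.approx(msep, rel=1e-10, abs=1e-12)


class TestAICc:
    def test_direct_arithmetic(self):
        # 100*ln(1) + 2*2 + 2*2*3/97
        assert aicc(100.0, 100, 1) == pytest.approx(4.0 + 12.0 / 97.0, rel=1e-14)

    def test_doubling_sse_adds_n_log_two(self):
        n = 50
        assert aicc(20.0, n, 2) - aicc(10.0, n, 2) == pytest.approx(n * math.log(2), rel=1e-12)

    def test_parameter_penalty_closed_form(self):
        n, sse = 50, 30.0
        delta = aicc(sse, n, 3) - aicc(sse, n, 2)
        k3, k2 = 4, 3
        expected = 2 * (k3 - k2) + 2 * k3 * (k3 + 1) / (n - k3 - 1) - 2 * k2 * (k2 + 1) / (n - k2 - 1)
        assert delta == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            aicc(0.0, 30, 2)
        with pytest.raises(DomainError):
            aicc(10.0, 4, 2)


class TestEvidenceRatio:
    def test_equal_models(self):
        assert aic_compare(10.0, 10.0) == (1.0, 0.5)

    def test_delta_two(self):
        ratio, prob = aic_compare(12.0, 10.0)
        assert ratio == pytest.approx(math.e, rel=1e-14)
        assert prob == pytest.approx(math.e / (1 + math.e), rel=1e-14)

    def test_published_comparison(self):
        """The 258.4 vs 250.5 AIC pair: ~52-times more likely, ~98%."""
        ratio, prob = aic_compare(258.4, 250.5)
        assert ratio == pytest.approx(math.exp(7.9 / 2), rel=1e-12)
        assert ratio == pytest.approx(52, abs=1.5)
        assert prob == pytest.approx(0.981, abs=0.002)


def test_evaluate_report_is_internally_consistent(rng):
    obs = rng.uniform(300, 700, size=40)
    pred = obs * (1 + rng.normal(0, 0.02, size=40))
    report = evaluate(obs, pred, k_params=2)
    assert report.msep_mean_bias + report.msep_systematic + report.msep_random == pytest.approx(
        report.msep, rel=1e-10
    )
    assert 0 < report.cb <= 1
    assert report.aicc == pytest.approx(
        aicc(float(np.sum((obs - pred) ** 2)), 40, 2), rel=1e-12
    )
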