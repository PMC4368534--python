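"""Least-squares machinery: closed forms, Gauss-Newton behaviour and
parameter recovery for every model family."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from cowbw.exceptions import BreakpointError, SingularFitError
from cowbw.models import (
    MODEL_FAMILIES,
    fit_gu_model,
    fit_linear_through_origin,
    fit_power,
    fit_segmented_udder,
)
from cowbw.optimize import gauss_newton
from cowbw.simulate import generate_fit_dataset


class TestOriginLinear:
    def test_exact_proportionality(self):
        x = np.linspace(1, 10, 20)
        res = fit_linear_through_origin(x, 2.0 * x)
        assert res.params["slope"] == pytest.approx(2.0, rel=1e-14)
        assert res.sse == pytest.approx(0.0, abs=1e-20)

    def test_two_point_hand_algebra(self):
        # beta = sum(xy)/sum(x^2) = (1 + 2)/(1 + 4)
        res = fit_linear_through_origin([1.0, 2.0], [1.0, 1.0])
        assert res.params["slope"] == pytest.approx(0.6, rel=1e-14)

    def test_noise_free_generator_inversion(self):
        data = generate_fit_dataset("sbw_linear", 40, 0.0, seed=8)
        res = fit_linear_through_origin(data["bw"], data["sbw"])
        assert res.params["slope"] == pytest.approx(0.9763, abs=1e-7)

    def test_degenerate_design(self):
        with pytest.raises(SingularFitError):
            fit_linear_through_origin([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])

    def test_standard_error_shrinks_as_root_n(self, rng):
        """On a replicated design the asymptotic SE scales like 1/sqrt(n)."""
        base_x = np.linspace(300, 700, 30)
        ses = {}
        for factor in (1, 4, 16):
            x = np.tile(base_x, factor)
            y = 0.9763 * x + rng.normal(0, 5.0, size=x.size)
            ses[factor] = fit_linear_through_origin(x, y).std_errors["slope"]
        assert ses[4] == pytest.approx(ses[1] / 2, rel=0.35)
        assert ses[16] == pytest.approx(ses[1] / 4, rel=0.35)


class TestPowerLaw:
    def test_identity_data(self):
        x = np.linspace(1, 5, 30)
        res = fit_power(x, x)
        assert res.params["scale"] == pytest.approx(1.0, abs=1e-9)
        assert res.params["exponent"] == pytest.approx(1.0, abs=1e-9)

    def test_start_invariance_on_clean_data(self):
        data = generate_fit_dataset("sbw_power", 50, 0.0, seed=1)
        from_loglog = fit_power(data["bw"], data["sbw"])
        from_ones = fit_power(data["bw"], data["sbw"], starts=(1.0, 1.0))
        for key in ("scale", "exponent"):
            assert from_ones.params[key] == pytest.approx(from_loglog.params[key], rel=1e-8)

    def test_sse_beats_dense_grid_oracle(self, rng):
        x = rng.uniform(300, 700, size=25)
        y = 0.8084 * x**1.0303 * (1 + rng.normal(0, 0.01, size=25))
        res = fit_power(x, y)
        grid_a = np.linspace(0.8084 * 0.5, 0.8084 * 1.5, 200)
        grid_b = np.linspace(1.0303 * 0.5, 1.0303 * 1.5, 200)
        pred = grid_a[:, None, None] * x[None, None, :] ** grid_b[None, :, None]
        grid_sse = np.sum((y[None, None, :] - pred) ** 2, axis=-1).min()
        assert res.sse <= grid_sse + 1e-9

    def test_matches_scipy_curve_fit_on_noisy_data(self, rng):
        x = rng.uniform(300, 700, size=60)
        y = 0.8084 * x**1.0303 * (1 + rng.normal(0, 0.02, size=60))
        ours = fit_power(x, y)
        (a, b), _ = curve_fit(lambda x, a, b: a * x**b, x, y, p0=(0.8, 1.0))
        assert ours.params["scale"] == pytest.approx(a, rel=1e-5)
        assert ours.params["exponent"] == pytest.approx(b, rel=1e-5)


class TestGravidUterusFit:
    def test_scale_rescaling_identity(self):
        """Dividing the raw DOP-only scale by the 28-kg calf reproduces the
        published per-kg-CBW coefficient."""
        data = generate_fit_dataset("gu_dop", 40, 0.0, seed=3)
        res = fit_gu_model(data["dop"], data["gu"], cbw_scale=28.0)
        assert res.params["scale"] == pytest.approx(0.2106, rel=1e-8)
        assert res.extra["scale_per_cbw"] == pytest.approx(0.007521, abs=1e-6)

    def test_flat_data_gives_zero_rates(self):
        dop = np.linspace(100, 260, 30)
        res = fit_gu_model(dop, np.full(30, 12.5))
        assert res.params["rate_linear"] == pytest.approx(0.0, abs=1e-10)
        assert res.params["rate_quadratic"] == pytest.approx(0.0, abs=1e-12)
        assert res.params["scale"] == pytest.approx(12.5, rel=1e-10)

    def test_pregnant_records_required(self):
        with pytest.raises(SingularFitError):
            fit_gu_model([0.0, 100.0], [1.0, 5.0])


class TestSegmentedUdder:
    def test_no_exponential_phase_is_unidentifiable(self, rng):
        sbw = rng.uniform(400, 600, size=20)
        bcs = rng.choice([3.0, 4.0, 5.0], size=20)
        dop = rng.integers(0, 99, size=20).astype(float)
        ud = sbw * 0.00589 * bcs**0.2043
        with pytest.raises(BreakpointError):
            fit_segmented_udder(sbw, bcs, dop, ud)

    def test_zero_rate_reduces_to_flat_model(self, rng):
        """With no exponential signal the fitted rate is ~0 and the flat-branch
        coefficients match the non-pregnant udder form."""
        sbw = rng.uniform(400, 600, size=30)
        bcs = rng.choice([3.0, 5.0, 7.0], size=30)
        dop = np.concatenate([np.zeros(15), rng.integers(150, 291, size=15)]).astype(float)
        ud = sbw * 0.00589 * bcs**0.2043  # rate fixed at zero in the truth
        res = fit_segmented_udder(sbw, bcs, dop, ud)
        assert abs(res.params["rate"]) < 1e-8
        assert res.params["scale"] == pytest.approx(0.00589, rel=1e-6)
        assert res.params["bcs_exponent"] == pytest.approx(0.2043, rel=1e-6)


@pytest.mark.parametrize("family_name", sorted(MODEL_FAMILIES))
def test_zero_noise_parameter_recovery(family_name):
    """Every family refit on clean synthetic data recovers the published
    coefficients within 1e-6 relative (the breakpoint exactly)."""
    family = MODEL_FAMILIES[family_name]
    data = generate_fit_dataset(family_name, 40, 0.0, seed=17)
    est = family.make().fit(family.design(data), data[family.response].to_numpy())
    for name, truth in family.published.items():
        fitted = est.result_.params[name]
        if name == "breakpoint":
            assert fitted == truth
        else:
            assert fitted == pytest.approx(truth, rel=1e-6), name
    assert est.result_.converged


class TestGaussNewton:
    def test_linear_problem_solved_exactly(self):
        """The very first Gauss-Newton step solves a linear problem exactly;
        only convergence detection adds iterations."""
        x = np.linspace(0, 10, 25)
        y = 3.0 * x + 1.0
        res = gauss_newton(lambda t: t[0] + t[1] * x, [0.0, 0.0], y,
                           param_names=("intercept", "slope"))
        assert res.converged and res.iterations <= 5
        assert res.sse == pytest.approx(0.0, abs=1e-18)
        assert res.params["intercept"] == pytest.approx(1.0, abs=1e-8)
        assert res.params["slope"] == pytest.approx(3.0, abs=1e-9)

    def test_sse_never_exceeds_start(self, rng):
        x = rng.uniform(1, 5, size=30)
        y = 2.0 * x**1.5 + rng.normal(0, 0.5, size=30)
        theta0 = np.array([5.0, 0.2])
        start_sse = float(np.sum((y - theta0[0] * x ** theta0[1]) ** 2))
        res = gauss_newton(lambda t: t[0] * x ** t[1], theta0, y)
        assert res.sse <= start_sse

    def test_residual_form_equivalent_to_y_form(self):
        x = np.linspace(1, 4, 12)
        y = 1.7 * x
        res_y = gauss_newton(lambda t: t[0] * x, [1.0], y)
        res_r = gauss_newton(lambda t: y - t[0] * x, [1.0])
        assert res_y.params["p0"] == pytest.approx(res_r.params["p0"], rel=1e-12)
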