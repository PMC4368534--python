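"""Refittable model families behind the published equations.

Each family is a scikit-learn-style estimator (``fit``/``predict``, fitted
attributes with a trailing underscore) so the models compose with sklearn
pipelines and model selection. ``X`` may be a pandas DataFrame holding the
named predictor columns or a 2-D array in the documented column order. All
nonlinear families are fitted on the original scale with additive error by
:func:`cowbw.optimize.gauss_newton`, starting from a log-linearisation.

Module-level ``fit_*`` functions are thin wrappers returning a
:class:`~cowbw.optimize.FitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import BreakpointError, SingularFitError
from .optimize import FitResult, gauss_newton

__all__ = [
    "OriginLinearModel",
    "PowerLawModel",
    "GravidUterusModel",
    "SegmentedUdderModel",
    "ModelFamily",
    "MODEL_FAMILIES",
    "fit_linear_through_origin",
    "fit_power",
    "fit_gu_model",
    "fit_segmented_udder",
]


def _columns(X, names: tuple[str, ...]) -> list[np.ndarray]:
    """Extract predictor columns from a DataFrame (by name) or array (by order)."""
    if isinstance(X, pd.DataFrame):
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"X lacks required columns {missing}")
        return [X[n].to_numpy(dtype=float) for n in names]
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    if arr.shape[0] == 1 and len(names) == 1:
        arr = arr.T
    if arr.shape[1] != len(names):
        raise ValueError(f"X must have {len(names)} column(s) {names}, got shape {arr.shape}")
    return [arr[:, i] for i in range(len(names))]


def _to_fit_result(est) -> FitResult:
    return est.result_


class OriginLinearModel(RegressorMixin, BaseEstimator):
    """No-intercept linear regression ``y = coef * x``.

    Closed form: ``coef = sum(x*y) / sum(x**2)``, with the asymptotic
    standard error ``sqrt(SSE/(n-1) / sum(x**2))``.
    """

    predictor_names = ("x",)

    def fit(self, X, y):
        (x,) = _columns(X, ("x",))
        y = np.asarray(y, dtype=float)
        if x.size < 2:
            raise SingularFitError("need at least two records")
        sxx = float(x @ x)
        if sxx == 0:
            raise SingularFitError("all predictor values are zero")
        coef = float(x @ y) / sxx
        resid = y - coef * x
        sse = float(resid @ resid)
        n = x.size
        se = float(np.sqrt(sse / (n - 1) / sxx)) if n > 1 else float("nan")
        self.coef_ = coef
        self.result_ = FitResult(
            params={"slope": coef}, std_errors={"slope": se}, sse=sse,
            n=n, k=1, residuals=resid, converged=True, iterations=0,
        )
        return self

    def predict(self, X):
        (x,) = _columns(X, ("x",))
        return self.coef_ * x


class PowerLawModel(RegressorMixin, BaseEstimator):
    """Allometric regression ``y = scale * x**exponent`` (additive error).

    Default starting values come from an ordinary log-log regression; pass
    ``starts`` to override (e.g. to check start invariance).
    """

    predictor_names = ("x",)

    def __init__(self, starts=None, tol=1e-12, max_iter=200):
        self.starts = starts
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        (x,) = _columns(X, ("x",))
        y = np.asarray(y, dtype=float)
        if np.any(x <= 0) or np.any(y <= 0):
            raise SingularFitError("power-law fitting requires positive x and y")
        if self.starts is not None:
            theta0 = np.asarray(self.starts, dtype=float)
        else:
            b, a = np.polyfit(np.log(x), np.log(y), 1)
            theta0 = np.array([np.exp(a), b])
        self.result_ = gauss_newton(
            lambda t: t[0] * np.power(x, t[1]), theta0, y,
            tol=self.tol, max_iter=self.max_iter,
            param_names=("scale", "exponent"),
        )
        self.scale_ = self.result_.params["scale"]
        self.exponent_ = self.result_.params["exponent"]
        return self

    def predict(self, X):
        (x,) = _columns(X, ("x",))
        return self.scale_ * np.power(x, self.exponent_)


class GravidUterusModel(RegressorMixin, BaseEstimator):
    """Gravid-uterus growth curve
    ``gu = scale [* bcs**bcs_exponent] * exp((b1 - b2*dop)*dop)``.

    ``with_bcs`` selects the condition-dependent form; ``cbw_scale`` (kg of
    expected calf birth weight) additionally reports the per-kg-CBW scale
    ``scale / cbw_scale`` as ``scale_per_cbw_``.

    X columns: ``dop`` (and ``bcs`` when ``with_bcs``).
    """

    def __init__(self, with_bcs=True, cbw_scale=None, tol=1e-12, max_iter=300):
        self.with_bcs = with_bcs
        self.cbw_scale = cbw_scale
        self.tol = tol
        self.max_iter = max_iter

    @property
    def predictor_names(self):
        return ("dop", "bcs") if self.with_bcs else ("dop",)

    def fit(self, X, y):
        cols = _columns(X, self.predictor_names)
        dop = cols[0]
        bcs = cols[1] if self.with_bcs else None
        y = np.asarray(y, dtype=float)
        if np.any(dop <= 0):
            raise SingularFitError("gravid-uterus fitting needs pregnant records (dop > 0)")
        if np.any(y <= 0):
            raise SingularFitError("gravid-uterus weights must be positive")

        # log-linearisation for starts: ln y = ln s [+ c*ln bcs] + b1*d - b2*d^2
        design = [np.ones_like(dop), dop, -(dop**2)]
        names = ["scale", "rate_linear", "rate_quadratic"]
        if self.with_bcs:
            design.insert(1, np.log(bcs))
            names.insert(1, "bcs_exponent")
        beta, *_ = np.linalg.lstsq(np.column_stack(design), np.log(y), rcond=None)
        theta0 = beta.copy()
        theta0[0] = np.exp(beta[0])

        if self.with_bcs:
            def model(t):
                return t[0] * np.power(bcs, t[1]) * np.exp((t[2] - t[3] * dop) * dop)
        else:
            def model(t):
                return t[0] * np.exp((t[1] - t[2] * dop) * dop)

        self.result_ = gauss_newton(model, theta0, y, tol=self.tol,
                                    max_iter=self.max_iter, param_names=names)
        p = self.result_.params
        self.scale_ = p["scale"]
        self.rate_linear_ = p["rate_linear"]
        self.rate_quadratic_ = p["rate_quadratic"]
        if self.with_bcs:
            self.bcs_exponent_ = p["bcs_exponent"]
        if self.cbw_scale is not None:
            self.scale_per_cbw_ = self.scale_ / self.cbw_scale
            self.result_.extra["scale_per_cbw"] = self.scale_per_cbw_
        return self

    def predict(self, X):
        cols = _columns(X, self.predictor_names)
        dop = cols[0]
        out = self.scale_ * np.exp((self.rate_linear_ - self.rate_quadratic_ * dop) * dop)
        if self.with_bcs:
            out = out * np.power(cols[1], self.bcs_exponent_)
        return out


class SegmentedUdderModel(RegressorMixin, BaseEstimator):
    """Segmented udder regression with a profiled breakpoint.

    ``ud = sbw_np * scale * bcs**bcs_exponent * exp(rate * max(0, dop - b0))``
    — an allometric plateau before the breakpoint ``b0`` and exponential
    growth after it. ``b0`` is profiled over an integer-day grid (default
    100-280 d); at each candidate the three remaining parameters are fitted by
    nonlinear least squares and the global SSE minimiser is returned.
    Non-pregnant records (dop = 0) inform the plateau branch.

    X columns: ``sbw_np``, ``bcs``, ``dop``.
    """

    predictor_names = ("sbw_np", "bcs", "dop")

    def __init__(self, grid=(100, 280), tol=1e-12, max_iter=200):
        self.grid = grid
        self.tol = tol
        self.max_iter = max_iter

    def _fit_at(self, bp, sbw, bcs, dop, y):
        ramp = np.maximum(dop - bp, 0.0)
        # exact log-linearisation: ln(y/sbw) = ln b1 + b2*ln bcs + b3*ramp
        design = np.column_stack([np.ones_like(dop), np.log(bcs), ramp])
        beta, *_ = np.linalg.lstsq(design, np.log(y / sbw), rcond=None)
        theta0 = np.array([np.exp(beta[0]), beta[1], beta[2]])

        def model(t):
            return sbw * t[0] * np.power(bcs, t[1]) * np.exp(t[2] * ramp)

        return gauss_newton(model, theta0, y, tol=self.tol, max_iter=self.max_iter,
                            param_names=("scale", "bcs_exponent", "rate"))

    def fit(self, X, y):
        sbw, bcs, dop = _columns(X, self.predictor_names)
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0) or np.any(sbw <= 0):
            raise SingularFitError("udder fitting requires positive weights")
        lo, hi = self.grid
        candidates = [
            bp for bp in range(int(lo), int(hi) + 1)
            if np.any(dop <= bp) and np.any(dop > bp)
        ]
        if not candidates:
            raise BreakpointError(
                "records do not span any candidate breakpoint; "
                "the exponential phase is unidentifiable"
            )
        best = None
        for bp in candidates:
            res = self._fit_at(float(bp), sbw, bcs, dop, y)
            if best is None or res.sse < best[1].sse:
                best = (bp, res)
        self.breakpoint_, inner = best
        self.scale_ = inner.params["scale"]
        self.bcs_exponent_ = inner.params["bcs_exponent"]
        self.rate_ = inner.params["rate"]
        self.result_ = FitResult(
            params={"breakpoint": float(self.breakpoint_), **inner.params},
            std_errors={"breakpoint": float("nan"), **inner.std_errors},
            sse=inner.sse, n=inner.n, k=inner.k + 1,
            residuals=inner.residuals, converged=inner.converged,
            iterations=inner.iterations,
            extra={"candidates": len(candidates)},
        )
        return self

    def predict(self, X):
        sbw, bcs, dop = _columns(X, self.predictor_names)
        ramp = np.maximum(dop - self.breakpoint_, 0.0)
        return sbw * self.scale_ * np.power(bcs, self.bcs_exponent_) * np.exp(self.rate_ * ramp)


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_linear_through_origin(x, y) -> FitResult:
    """No-intercept linear fit; see :class:`OriginLinearModel`."""
    return _to_fit_result(OriginLinearModel().fit(np.asarray(x, float).reshape(-1, 1), y))


def fit_power(x, y, starts=None) -> FitResult:
    """Allometric fit on the original scale; see :class:`PowerLawModel`."""
    return _to_fit_result(
        PowerLawModel(starts=starts).fit(np.asarray(x, float).reshape(-1, 1), y)
    )


def fit_gu_model(dop, gu, bcs=None, cbw_scale=None) -> FitResult:
    """Fit a gravid-uterus curve; see :class:`GravidUterusModel`."""
    dop = np.asarray(dop, dtype=float)
    if bcs is not None:
        X = pd.DataFrame({"dop": dop, "bcs": np.asarray(bcs, dtype=float)})
    else:
        X = pd.DataFrame({"dop": dop})
    est = GravidUterusModel(with_bcs=bcs is not None, cbw_scale=cbw_scale).fit(X, gu)
    return _to_fit_result(est)


def fit_segmented_udder(sbw_np, bcs, dop, ud) -> FitResult:
    """Fit the segmented udder model; see :class:`SegmentedUdderModel`."""
    X = pd.DataFrame({
        "sbw_np": np.asarray(sbw_np, dtype=float),
        "bcs": np.asarray(bcs, dtype=float),
        "dop": np.asarray(dop, dtype=float),
    })
    return _to_fit_result(SegmentedUdderModel().fit(X, ud))


# ---------------------------------------------------------------------------
# named family registry (used by cross-validation, the CLI and the generator)

@dataclass(frozen=True)
class ModelFamily:
    """A named, refittable model family: response, predictors and estimator."""

    name: str
    response: str
    predictors: tuple[str, ...]
    make: Callable[[], BaseEstimator]
    published: dict[str, float]

    def design(self, data: pd.DataFrame) -> pd.DataFrame:
        cols = data[list(self.predictors)].copy()
        est_names = self.make().predictor_names
        return cols.rename(columns=dict(zip(self.predictors, est_names)))


MODEL_FAMILIES: dict[str, ModelFamily] = {
    "sbw_linear": ModelFamily(
        "sbw_linear", "sbw", ("bw",), OriginLinearModel,
        {"slope": 0.9763}),
    "sbw_power": ModelFamily(
        "sbw_power", "sbw", ("bw",), PowerLawModel,
        {"scale": 0.8084, "exponent": 1.0303}),
    "ebw_linear": ModelFamily(
        "ebw_linear", "ebw", ("sbw_np",), OriginLinearModel,
        {"slope": 0.9092}),
    "ebw_power": ModelFamily(
        "ebw_power", "ebw", ("sbw_np",), PowerLawModel,
        {"scale": 0.8424, "exponent": 1.0122}),
    "gu_bcs": ModelFamily(
        "gu_bcs", "gu", ("dop", "bcs"),
        lambda: GravidUterusModel(with_bcs=True, cbw_scale=28.0),
        {"scale": 0.2243, "bcs_exponent": 0.3225,
         "rate_linear": 0.02544, "rate_quadratic": 0.0000286}),
    "gu_dop": ModelFamily(
        "gu_dop", "gu", ("dop",),
        lambda: GravidUterusModel(with_bcs=False, cbw_scale=28.0),
        {"scale": 0.2106, "rate_linear": 0.03119, "rate_quadratic": 0.00004117}),
    "ut_np": ModelFamily(
        "ut_np", "ut_np", ("sbw_np",), OriginLinearModel,
        {"slope": 0.0012}),
    "udder_segmented": ModelFamily(
        "udder_segmented", "ud", ("sbw_np", "bcs", "dop"), SegmentedUdderModel,
        {"breakpoint": 238.0, "scale": 0.00589,
         "bcs_exponent": 0.2043, "rate": 0.0109}),
}
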