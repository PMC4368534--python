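"""Gauss-Newton nonlinear least squares with step halving.

This is the fitting procedure behind all nonlinear model families in the
package: minimise SSE(theta) = sum((y - f(x; theta))**2) by iteratively
linearising f. A step-halving safeguard guarantees the returned SSE never
exceeds the SSE at the starting values, and a pseudoinverse step handles
singular Jacobians. Convergence is declared when the relative SSE change in a
step falls below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitResult", "gauss_newton"]


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    ``params``/``std_errors`` are keyed by parameter name; standard errors
    are the usual asymptotic ones, sqrt(diag(s2 * (J'J)^-1)) with
    s2 = SSE/(n - k).
    """

    params: dict[str, float]
    std_errors: dict[str, float]
    sse: float
    n: int
    k: int
    residuals: np.ndarray
    converged: bool
    iterations: int
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"n = {self.n}, k = {self.k}, SSE = {self.sse:.6g}, "
                 f"converged = {self.converged} ({self.iterations} iterations)"]
        for name, value in self.params.items():
            se = self.std_errors.get(name, float("nan"))
            lines.append(f"  {name} = {value:.6g} (+/- {se:.3g})")
        return "\n".join(lines)


def _numeric_jacobian(fun, theta, f0):
    """Forward/central hybrid finite-difference Jacobian of a vector function."""
    theta = np.asarray(theta, dtype=float)
    jac = np.empty((f0.size, theta.size))
    for i in range(theta.size):
        h = (np.finfo(float).eps ** (1 / 3)) * max(abs(theta[i]), 1e-4)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        jac[:, i] = (fun(tp) - fun(tm)) / (2 * h)
    return jac


def gauss_newton(
    model,
    params0,
    y=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    max_halvings: int = 30,
    param_names=None,
) -> FitResult:
    """Fit ``y ~ model(theta)`` by Gauss-Newton iteration.

    Parameters
    ----------
    model : callable(theta) -> predicted values (if ``y`` given) or residuals
        (``y - fitted``, if ``y`` is None).
    params0 : starting values.
    tol : relative SSE change below which convergence is declared.
    max_iter : iteration cap; exceeding it returns ``converged=False``
        rather than raising.
    """
    theta = np.asarray(params0, dtype=float).copy()
    if y is not None:
        y = np.asarray(y, dtype=float)
        resid = lambda t: y - np.asarray(model(t), dtype=float)  # noqa: E731
    else:
        resid = lambda t: np.asarray(model(t), dtype=float)  # noqa: E731

    r = resid(theta)
    sse = float(r @ r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Jacobian of the *fitted values* is -d(residual)/d(theta)
        jac = -_numeric_jacobian(resid, theta, r)
        # Gauss-Newton step: argmin ||r - J*delta||; lstsq tolerates rank
        # deficiency (acts as a pseudoinverse / damped step)
        delta, *_ = np.linalg.lstsq(jac, r, rcond=None)
        if not np.all(np.isfinite(delta)):
            break
        step = delta
        improved = False
        for _ in range(max_halvings):
            cand = theta + step
            rc = resid(cand)
            sc = float(rc @ rc)
            if np.isfinite(sc) and sc <= sse:
                rel_change = (sse - sc) / max(sse, np.finfo(float).tiny)
                theta, r, sse = cand, rc, sc
                improved = True
                break
            step = step / 2
        if not improved:
            # no direction of descent within the halving budget: the SSE is
            # stationary to machine precision
            converged = True
            break
        if rel_change < tol:
            converged = True
            break

    n, k = r.size, theta.size
    jac = -_numeric_jacobian(resid, theta, r)
    std_errors = np.full(k, np.nan)
    if n > k:
        s2 = sse / (n - k)
        jtj = jac.T @ jac
        try:
            cov = s2 * np.linalg.pinv(jtj)
            std_errors = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            pass

    names = list(param_names) if param_names is not None else [f"p{i}" for i in range(k)]
    return FitResult(
        params=dict(zip(names, theta.tolist())),
        std_errors=dict(zip(names, std_errors.tolist())),
        sse=sse,
        n=n,
        k=k,
        residuals=r,
        converged=converged,
        iterations=it,
    )
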