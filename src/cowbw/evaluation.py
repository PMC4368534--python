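"""Model-agreement statistics: joint observed-vs-predicted test, Lin's
accuracy factor, the mean-square-error-of-prediction partition, corrected AIC
and AIC evidence ratios.

Conventions (each unit-tested against hand arithmetic, so an alternative
convention is a one-line change): population (divide-by-n) moments
throughout, so the MSEP components add exactly; the joint test regresses
observed on predicted; AICc counts the error variance as a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, SingularFitError

__all__ = [
    "EvaluationReport",
    "obs_vs_pred_test",
    "concordance_bias",
    "msep_decompose",
    "aicc",
    "aic_compare",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Agreement statistics for one observed/predicted pairing."""

    n: int
    cb: float
    msep: float
    msep_mean_bias: float
    msep_systematic: float
    msep_random: float
    joint_f: float
    joint_p: float
    intercept: float
    slope: float
    aicc: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _pair(obs, pred):
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-D arrays of equal length")
    return obs, pred


def obs_vs_pred_test(obs, pred):
    """Simultaneous test that observed = predicted.

    Regresses observed on predicted and tests (intercept, slope) = (0, 1)
    with the full-vs-restricted F statistic on (2, n-2) degrees of freedom;
    the restricted SSE is simply sum((obs - pred)**2).

    Returns ``(F, p, intercept, slope)``.
    """
    obs, pred = _pair(obs, pred)
    n = obs.size
    if n < 3:
        raise DomainError("need at least 3 records for the joint test")
    if np.ptp(pred) == 0:
        raise SingularFitError("predictions are constant; regression is degenerate")
    design = np.column_stack([np.ones(n), pred])
    beta, *_ = np.linalg.lstsq(design, obs, rcond=None)
    resid_full = obs - design @ beta
    sse_full = float(resid_full @ resid_full)
    d = obs - pred
    sse_restricted = float(d @ d)
    if sse_full == 0.0:
        f_stat = 0.0 if sse_restricted == 0.0 else math.inf
    else:
        f_stat = ((sse_restricted - sse_full) / 2) / (sse_full / (n - 2))
        f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, 2, n - 2)) if math.isfinite(f_stat) else 0.0
    return float(f_stat), p, float(beta[0]), float(beta[1])


def concordance_bias(obs, pred):
    """Lin's accuracy (bias-correction) factor Cb in (0, 1].

    Cb = 2 / (v + 1/v + u**2) with v = sd(pred)/sd(obs) and
    u = (mean(pred) - mean(obs)) / sqrt(sd(pred) * sd(obs)), population
    moments. Cb = 1 exactly when means and variances match.
    """
    obs, pred = _pair(obs, pred)
    if obs.size < 2:
        raise DomainError("need at least 2 records")
    so, sp = obs.std(), pred.std()
    if so == 0 or sp == 0:
        raise SingularFitError("a constant series has no concordance accuracy")
    v = sp / so
    u = (pred.mean() - obs.mean()) / math.sqrt(sp * so)
    return 2.0 / (v + 1.0 / v + u * u)


def msep_decompose(obs, pred):
    """Mean square error of prediction and its three-way partition.

    MSEP = mean((pred - obs)**2) splits exactly (population moments) into
    mean bias (mean(pred) - mean(obs))**2, systematic/slope error
    (sd(pred) - r*sd(obs))**2 and random error (1 - r**2)*var(obs).

    Returns ``(msep, mean_bias, systematic, random)``.
    """
    obs, pred = _pair(obs, pred)
    if obs.size < 2:
        raise DomainError("need at least 2 records")
    d = pred - obs
    msep = float(np.mean(d * d))
    mean_bias = float((pred.mean() - obs.mean()) ** 2)
    so, sp = obs.std(), pred.std()
    if so == 0 or sp == 0:
        r = 0.0
    else:
        r = float(np.mean((obs - obs.mean()) * (pred - pred.mean())) / (so * sp))
    systematic = float((sp - r * so) ** 2)
    random_err = float((1.0 - r * r) * so * so)
    return msep, mean_bias, systematic, random_err


def aicc(sse, n, k_params):
    """Corrected Akaike information criterion from a least-squares fit.

    AICc = n*ln(SSE/n) + 2K + 2K(K+1)/(n-K-1) with K = k_params + 1 (the
    error variance counts as a fitted parameter).
    """
    if sse <= 0:
        raise DomainError("sse must be positive (a perfect fit has no defined AICc)")
    k = k_params + 1
    if n <= k + 1:
        raise DomainError(f"n = {n} too small for K = {k} parameters")
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def aic_compare(aic_worse, aic_better):
    """Evidence ratio and probability from an AIC(c) difference.

    For delta = aic_worse - aic_better: evidence ratio = exp(delta/2), the
    probability the lower-AIC model is the better one = ER/(1+ER). A delta of
    7.9 gives a ratio near 52 and a probability near 98%.
    """
    delta = aic_worse - aic_better
    ratio = math.exp(delta / 2.0)
    return ratio, ratio / (1.0 + ratio)


def evaluate(obs, pred, k_params=None) -> EvaluationReport:
    """Compute the full agreement report for one observed/predicted pairing.

    When ``k_params`` is given, an AICc is included, treating
    sum((obs - pred)**2) as the model's SSE.
    """
    obs, pred = _pair(obs, pred)
    msep, mb, sys_err, rand_err = msep_decompose(obs, pred)
    f_stat, p, intercept, slope = obs_vs_pred_test(obs, pred)
    aicc_value = None
    if k_params is not None:
        aicc_value = aicc(float(np.sum((obs - pred) ** 2)), obs.size, k_params)
    return EvaluationReport(
        n=obs.size,
        cb=concordance_bias(obs, pred),
        msep=msep,
        msep_mean_bias=mb,
        msep_systematic=sys_err,
        msep_random=rand_err,
        joint_f=f_stat,
        joint_p=p,
        intercept=intercept,
        slope=slope,
        aicc=aicc_value,
    )
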