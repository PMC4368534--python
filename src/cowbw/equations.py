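"""Closed-form prediction equations for weight adjustment in beef cows.

The chain converts fed body weight (BW) to shrunk body weight (SBW), predicts
the pregnancy-specific organs — gravid uterus (GU), non-pregnant uterus plus
ovaries (UT_np), udder (UD) — and relates shrunk to empty body weight (EBW).
All functions accept scalars or numpy arrays; weights are kg, time is days of
pregnancy (DOP, 0 = non-pregnant), BCS is the 1-9 body condition scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import DomainError, ExtrapolationWarning, InconsistencyError
from .parameters import DEFAULT_PARAMS, EquationParams, GUModelParams

__all__ = [
    "sbw_from_bw_power",
    "sbw_from_bw_linear",
    "ebw_np_from_sbw_np",
    "gravid_uterus",
    "gravid_uterus_taurus",
    "gu_curve",
    "uterus_np",
    "uterus_np_provisional",
    "udder_np",
    "udder_p",
    "udder_accretion",
    "ebw_pregnant",
]


def _require_positive(value, name):
    if np.any(np.asarray(value) <= 0):
        raise DomainError(f"{name} must be strictly positive")


def _warn_outside(value, lo, hi, name):
    v = np.asarray(value)
    if np.any((v < lo) | (v > hi)):
        warnings.warn(
            f"{name} outside the development range [{lo}, {hi}]; "
            "prediction is an extrapolation",
            ExtrapolationWarning,
            stacklevel=3,
        )


def sbw_from_bw_power(bw, params: EquationParams = DEFAULT_PARAMS):
    """Shrunk body weight from fed body weight, allometric form.

    SBW = 0.8084 * BW**1.0303; the implied SBW/BW ratio rises with weight
    (0.961 at 300 kg, 0.986 at 700 kg).
    """
    _require_positive(bw, "bw")
    _warn_outside(bw, *params.bw_range, name="bw")
    return params.sbw_power_scale * np.power(bw, params.sbw_power_exp)


def sbw_from_bw_linear(bw, params: EquationParams = DEFAULT_PARAMS):
    """Shrunk body weight as a fixed proportion of fed weight (0.9763 * BW).

    Preferred when herd weight variation is driven by age/parity rather than
    size, where a weight-dependent shrink ratio is not appropriate.
    """
    _require_positive(bw, "bw")
    return params.sbw_linear * np.asarray(bw, dtype=float)


def ebw_np_from_sbw_np(sbw_np, mode: str = "power", params: EquationParams = DEFAULT_PARAMS):
    """Empty body weight of a non-pregnant cow from her shrunk weight.

    ``power`` (default): EBW = 0.8424 * SBW**1.0122, the form with better
    support; ``linear``: EBW = 0.9092 * SBW.
    """
    _require_positive(sbw_np, "sbw_np")
    if mode == "power":
        return params.ebw_power_scale * np.power(sbw_np, params.ebw_power_exp)
    if mode == "linear":
        return params.ebw_linear * np.asarray(sbw_np, dtype=float)
    raise ValueError(f"mode must be 'power' or 'linear', got {mode!r}")


def gu_curve(dop, gu_params: GUModelParams, cbw=None, bcs=None):
    """Evaluate a gravid-uterus growth curve at ``dop`` days.

    Weight = scale [* CBW] [* BCS**exponent] * exp((b1 - b2*dop)*dop), a
    logistic-type pulse that is increasing over the whole gestation range for
    the published rates.
    """
    dop = np.asarray(dop, dtype=float)
    if np.any(dop < 0):
        raise DomainError("dop must be non-negative")
    if np.any(dop > 300):
        raise DomainError("dop above 300 d is outside any plausible bovine gestation")
    value = gu_params.scale * np.exp((gu_params.rate_linear - gu_params.rate_quadratic * dop) * dop)
    if gu_params.per_kg_cbw:
        if cbw is None:
            raise DomainError("this gravid-uterus curve is scaled per kg of calf birth weight")
        _require_positive(cbw, "cbw")
        value = value * np.asarray(cbw, dtype=float)
    if gu_params.bcs_exponent is not None:
        if bcs is None:
            raise DomainError("this gravid-uterus curve requires a body condition score")
        b = np.asarray(bcs, dtype=float)
        if np.any((b < 1) | (b > 9)):
            raise DomainError("bcs must lie in [1, 9]")
        value = value * np.power(b, gu_params.bcs_exponent)
    return value


def gravid_uterus(dop, cbw, bcs=None, params: EquationParams = DEFAULT_PARAMS):
    """Gravid uterus weight (kg) of a *B. indicus* cow.

    With a BCS the condition-dependent curve is used; without one the
    DOP-only curve. Both scale linearly with expected calf birth weight.
    """
    gu_params = params.gu_bcs if bcs is not None else params.gu_dop
    return gu_curve(dop, gu_params, cbw=cbw, bcs=bcs)


def gravid_uterus_taurus(dop, cbw, params: EquationParams = DEFAULT_PARAMS):
    """Gravid uterus weight (kg) of a *B. taurus* cow (Ferrell-type curve).

    The curve is parameterised in grams per kg of calf birth weight; the
    result is converted to kg.
    """
    return gu_curve(dop, params.gu_taurus, cbw=cbw) / 1000.0


def uterus_np(sbw_np, params: EquationParams = DEFAULT_PARAMS):
    """Uterus-plus-ovaries weight of a non-pregnant cow: 0.0012 * SBW_np."""
    if np.any(np.asarray(sbw_np) < 0):
        raise DomainError("sbw_np must be non-negative")
    return params.ut_coef * np.asarray(sbw_np, dtype=float)


def uterus_np_provisional(sbw_p, gu, dop, params: EquationParams = DEFAULT_PARAMS):
    """Non-pregnant uterus of a pregnant cow, from a provisional maternal weight.

    The exact maternal shrunk weight is not yet known at this point of the
    chain (circular reference), so SBW_np is approximated by
    SBW_p - GU + 0.6, minus a further 2 kg of udder accretion past 240 days.
    """
    sbw_p = np.asarray(sbw_p, dtype=float)
    gu = np.asarray(gu, dtype=float)
    if np.any(sbw_p <= gu):
        raise InconsistencyError("gravid uterus cannot outweigh the whole cow (sbw_p <= gu)")
    provisional = sbw_p - gu + params.ut_offset
    provisional = provisional - np.where(
        np.asarray(dop) > params.ut_branch_day, params.ut_udder_placeholder, 0.0
    )
    return params.ut_coef * provisional


def udder_np(sbw_np, bcs, params: EquationParams = DEFAULT_PARAMS):
    """Udder weight of a non-pregnant cow: SBW_np * 0.00589 * BCS**0.2043."""
    _require_positive(sbw_np, "sbw_np")
    b = np.asarray(bcs, dtype=float)
    if np.any((b < 1) | (b > 9)):
        raise DomainError("bcs must lie in [1, 9]")
    u = params.udder
    return np.asarray(sbw_np, dtype=float) * u.scale * np.power(b, u.bcs_exponent)


def udder_p(ud_np, dop, params: EquationParams = DEFAULT_PARAMS):
    """Udder weight of a pregnant cow.

    Static at the non-pregnant weight until the fitted 238-d breakpoint, then
    exponential growth at 0.0109/day as secretory parenchyma forms.
    """
    _require_positive(ud_np, "ud_np")
    dop = np.asarray(dop, dtype=float)
    if np.any(dop < 0):
        raise DomainError("dop must be non-negative")
    u = params.udder
    growth = np.exp(u.rate * np.maximum(dop - u.breakpoint, 0.0))
    return np.asarray(ud_np, dtype=float) * growth


def udder_accretion(ud_np, dop, params: EquationParams = DEFAULT_PARAMS):
    """Udder weight gained because of pregnancy: UD_p - UD_np (0 before 238 d)."""
    return udder_p(ud_np, dop, params=params) - np.asarray(ud_np, dtype=float)


def ebw_pregnant(sbw_p, preg, mode: str = "power", params: EquationParams = DEFAULT_PARAMS):
    """Empty body weight of a pregnant cow.

    The pregnancy compound is treated as a separate portion of the cow: the
    shrunk-to-empty relation is applied to the maternal weight only and the
    compound added back whole: EBW_p = 0.8424*(SBW_p - PREG)**1.0122 + PREG.
    """
    sbw_p = np.asarray(sbw_p, dtype=float)
    preg = np.asarray(preg, dtype=float)
    if np.any(preg < 0):
        raise DomainError("preg must be non-negative")
    if np.any(preg >= sbw_p):
        raise InconsistencyError("pregnancy compound cannot equal or exceed shrunk weight")
    return ebw_np_from_sbw_np(sbw_p - preg, mode=mode, params=params) + preg
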