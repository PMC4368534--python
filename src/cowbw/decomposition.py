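"""Decomposition of a pregnant cow's weight into maternal tissue and the
pregnancy compound.

The pregnancy compound (PREG) is the weight genuinely attributable to
pregnancy: the gravid uterus in excess of the non-pregnant uterus, plus the
udder accretion that appears late in gestation. Subtracting PREG from a
pregnant cow's shrunk weight yields her maternal-only (non-pregnant
equivalent) weight, which is what feed-efficiency comparisons need.

The chain, for a cow with shrunk weight SBW_p, condition score BCS, expected
calf birth weight CBW at DOP days of pregnancy:

1. GU from the breed-appropriate gravid-uterus curve.
2. UT_np from the provisional maternal weight SBW_p - GU + 0.6 (- 2 past
   240 d), because the exact maternal weight is not yet known.
3. GU_dp = GU - UT_np (clamped at 0 in very early gestation).
4. UD_np from the same provisional maternal weight and BCS; UD_p grows
   exponentially past the fitted 238-d breakpoint; its accretion UD_dp is
   counted in PREG only past 240 d, as the published chain prescribes.
5. PREG = GU_dp + UD_dp; SBW_np = SBW_p - PREG; EBW_np from the
   shrunk-to-empty relation; EBW_p = EBW_np + PREG.

DOP = 0 encodes non-pregnant: the chain short-circuits to a zero pregnancy
component rather than evaluating the curves at day 0, where the gravid uterus
prediction would fall below the non-pregnant uterus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

from . import equations as eq
from .exceptions import (
    ClampingWarning,
    DomainError,
    FallbackWarning,
    InconsistencyError,
)
from .parameters import DEFAULT_PARAMS, INDICUS, BreedProfile, EquationParams

__all__ = [
    "CowObservation",
    "PregnancyDecomposition",
    "preg_compound",
    "adjust_record",
    "maternal_gain",
]

#: condition score assumed for the udder prediction when none was recorded
#: (the study herd's mean score).
FALLBACK_BCS = 5.6


@dataclass(frozen=True)
class CowObservation:
    """One animal's measured state.

    At least one of ``bw`` (fed weight) and ``sbw`` (shrunk weight) must be
    present; ``dop`` = 0 encodes non-pregnant.
    """

    id: str
    bw: float | None = None
    sbw: float | None = None
    bcs: float | None = None
    dop: int = 0
    cbw: float | None = None
    feeding_level: str | None = None
    breed: str = "indicus"

    def __post_init__(self):
        if self.bw is None and self.sbw is None:
            raise DomainError(f"cow {self.id}: at least one of bw/sbw is required")
        for name in ("bw", "sbw", "cbw"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"cow {self.id}: {name} must be positive, got {v}")
        if self.bcs is not None and not 1 <= self.bcs <= 9:
            raise DomainError(f"cow {self.id}: bcs must lie in [1, 9], got {self.bcs}")
        if not 0 <= self.dop <= 300:
            raise DomainError(f"cow {self.id}: dop must lie in [0, 300], got {self.dop}")


@dataclass(frozen=True)
class PregnancyDecomposition:
    """Full output ledger of the adjustment chain (all weights kg).

    ``ud_dp`` is the udder accretion counted in the pregnancy compound (zero
    at or before the 240-d threshold); ``ud_p`` always reports the udder
    equation's value. The exact identities ``preg = gu_dp + ud_dp``,
    ``sbw_np = sbw_p - preg`` and ``ebw_p = ebw_np + preg`` hold by
    construction.
    """

    gu: float
    ut_np: float
    gu_dp: float
    ud_np: float
    ud_p: float
    ud_dp: float
    preg: float
    sbw_p: float
    sbw_np: float
    ebw_np: float
    ebw_p: float
    warnings: tuple[str, ...] = ()

    @property
    def preg_fraction(self) -> float:
        """Share of the pregnant shrunk weight attributable to pregnancy."""
        return self.preg / self.sbw_p

    def as_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "warnings"}
        out["preg_fraction"] = self.preg_fraction
        out["warnings"] = ";".join(self.warnings)
        return out


def _ebw_np(sbw_np: float, profile: BreedProfile, mode: str, params: EquationParams) -> float:
    if mode == "power" and profile.ebw_power_coefs is not None:
        scale, power = profile.ebw_power_coefs
        return scale * sbw_np**power
    return profile.ebw_linear_coef * sbw_np


def _gravid_uterus(dop, cbw, bcs, profile: BreedProfile, gu_model: str | None,
                   params: EquationParams, notes: list[str]) -> float:
    model = gu_model or profile.gu_model
    if model == "taurus_ferrell":
        return eq.gravid_uterus_taurus(dop, cbw, params=params)
    if model == "indicus_bcs" and bcs is None:
        notes.append("gu_dop_fallback")
        warnings.warn(
            "no condition score available; using the DOP-only gravid-uterus curve",
            FallbackWarning,
            stacklevel=4,
        )
        model = "indicus_dop_only"
    if model == "indicus_bcs":
        return float(eq.gu_curve(dop, params.gu_bcs, cbw=cbw, bcs=bcs))
    if model == "indicus_dop_only":
        return float(eq.gu_curve(dop, params.gu_dop, cbw=cbw))
    raise ValueError(f"unknown gravid-uterus model {model!r}")


def preg_compound(
    sbw_p: float,
    bcs: float | None,
    dop: float,
    cbw: float,
    profile: BreedProfile = INDICUS,
    *,
    gu_model: str | None = None,
    ebw_mode: str = "power",
    params: EquationParams = DEFAULT_PARAMS,
) -> PregnancyDecomposition:
    """Run the full pregnancy-compound chain on one cow.

    Returns the complete :class:`PregnancyDecomposition` ledger. Negative
    intermediate accretions (possible in very early gestation, where the
    curves were never developed) are clamped to zero with a warning.
    """
    if sbw_p <= 0:
        raise DomainError("sbw_p must be positive")
    if dop < 0:
        raise DomainError("dop must be non-negative")

    notes: list[str] = []
    if bcs is not None and not (params.bcs_valid[0] <= bcs <= params.bcs_valid[1]):
        notes.append("bcs_extrapolation")

    if profile.parents is not None:
        # crossbred: unweighted mean of the two pure-breed decompositions,
        # each computed independently with its own defaults
        parts = [
            preg_compound(sbw_p, bcs, dop, cbw, p, gu_model=gu_model,
                          ebw_mode=ebw_mode, params=params)
            for p in profile.parents
        ]
        merged = {
            f.name: 0.5 * (getattr(parts[0], f.name) + getattr(parts[1], f.name))
            for f in fields(PregnancyDecomposition)
            if f.name != "warnings"
        }
        notes += sorted(set(parts[0].warnings) | set(parts[1].warnings))
        return PregnancyDecomposition(warnings=tuple(notes), **merged)

    if dop == 0:
        ut = float(eq.uterus_np(sbw_p, params=params))
        ud = float(eq.udder_np(sbw_p, bcs, params=params)) if bcs is not None else float("nan")
        ebw_np = _ebw_np(sbw_p, profile, ebw_mode, params)
        return PregnancyDecomposition(
            gu=0.0, ut_np=ut, gu_dp=0.0, ud_np=ud, ud_p=ud, ud_dp=0.0,
            preg=0.0, sbw_p=sbw_p, sbw_np=sbw_p, ebw_np=ebw_np, ebw_p=ebw_np,
            warnings=tuple(notes),
        )

    gu = _gravid_uterus(dop, cbw, bcs, profile, gu_model, params, notes)
    ut_np = float(eq.uterus_np_provisional(sbw_p, gu, dop, params=params))
    gu_dp = gu - ut_np
    if gu_dp < 0:
        notes.append("gu_dp_clamped")
        warnings.warn(
            f"gravid uterus below non-pregnant uterus at dop={dop}; accretion clamped to 0",
            ClampingWarning,
            stacklevel=2,
        )
        gu_dp = 0.0

    # provisional maternal weight, as in the published worked chain
    provisional = sbw_p - gu + params.ut_offset
    if dop > params.ut_branch_day:
        provisional -= params.ut_udder_placeholder
    udder_bcs = bcs
    if udder_bcs is None:
        udder_bcs = FALLBACK_BCS
        notes.append("udder_bcs_fallback")
    ud_np = float(eq.udder_np(provisional, udder_bcs, params=params))
    ud_p = float(eq.udder_p(ud_np, dop, params=params))
    ud_dp = ud_p - ud_np if dop > params.preg_udder_day else 0.0

    preg = gu_dp + ud_dp
    if preg >= sbw_p:
        raise InconsistencyError(
            f"pregnancy compound {preg:.1f} kg is not below shrunk weight {sbw_p:.1f} kg"
        )
    sbw_np = sbw_p - preg
    ebw_np = _ebw_np(sbw_np, profile, ebw_mode, params)
    return PregnancyDecomposition(
        gu=gu, ut_np=ut_np, gu_dp=gu_dp, ud_np=ud_np, ud_p=ud_p, ud_dp=ud_dp,
        preg=preg, sbw_p=sbw_p, sbw_np=sbw_np, ebw_np=ebw_np, ebw_p=ebw_np + preg,
        warnings=tuple(notes),
    )


def adjust_record(
    obs: CowObservation,
    profile: BreedProfile | None = None,
    *,
    sbw_mode: str = "power",
    ebw_mode: str = "power",
    gu_model: str | None = None,
    params: EquationParams = DEFAULT_PARAMS,
) -> PregnancyDecomposition:
    """Adjust one herd record, deriving missing inputs from breed defaults.

    A measured shrunk weight always wins over one derived from fed weight;
    the calf birth weight defaults to the breed's typical value. For
    crossbreds the two pure-breed chains are run independently (each with its
    own defaults) and averaged.
    """
    from .parameters import get_breed_profile

    profile = profile or get_breed_profile(obs.breed)
    notes: list[str] = []

    if profile.parents is not None:
        parts = [
            adjust_record(obs, p, sbw_mode=sbw_mode, ebw_mode=ebw_mode,
                          gu_model=gu_model, params=params)
            for p in profile.parents
        ]
        merged = {
            f.name: 0.5 * (getattr(parts[0], f.name) + getattr(parts[1], f.name))
            for f in fields(PregnancyDecomposition)
            if f.name != "warnings"
        }
        notes = sorted(set(parts[0].warnings) | set(parts[1].warnings))
        return PregnancyDecomposition(warnings=tuple(notes), **merged)

    if obs.sbw is not None:
        sbw_p = obs.sbw
        if obs.bw is not None:
            notes.append("derived_sbw_ignored")
    elif sbw_mode == "power" and profile.sbw_power_coefs is not None:
        scale, power = profile.sbw_power_coefs
        sbw_p = scale * obs.bw**power
        if not params.bw_range[0] <= obs.bw <= params.bw_range[1]:
            notes.append("bw_extrapolation")
    else:
        sbw_p = profile.sbw_linear_coef * obs.bw

    cbw = obs.cbw if obs.cbw is not None else profile.default_cbw
    result = preg_compound(
        sbw_p, obs.bcs, obs.dop, cbw, profile,
        gu_model=gu_model, ebw_mode=ebw_mode, params=params,
    )
    if notes:
        result = replace(result, warnings=tuple(list(result.warnings) + notes))
    return result


def maternal_gain(initial_sbw: float, final_decomp: PregnancyDecomposition, days: float) -> float:
    """Real shrunk body gain (kg/d): maternal-tissue gain with the pregnancy
    compound removed. Negative values mean tissue mobilisation."""
    if days <= 0:
        raise DomainError("days must be positive")
    return (final_decomp.sbw_np - initial_sbw) / days
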