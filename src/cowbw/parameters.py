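"""Published coefficient sets for the weight-adjustment equations.

All defaults are the estimates published for mature Nellore (*Bos indicus*)
cows, with the *B. taurus* adaptation factors alongside. Every coefficient can
be overridden through :class:`EquationParams`, and full sets round-trip
through a plain ``key = value`` parameter file so re-fitted coefficients can
be swapped in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "GUModelParams",
    "UdderModelParams",
    "EquationParams",
    "BreedProfile",
    "DEFAULT_PARAMS",
    "INDICUS",
    "TAURUS",
    "CROSSBRED",
    "get_breed_profile",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class GUModelParams:
    """Parameters of the gravid-uterus growth curve.

    The curve is ``scale [* cbw] [* bcs**bcs_exponent]
    * exp((rate_linear - rate_quadratic * dop) * dop)`` with weight in kg.
    ``rate_linear / (2 * rate_quadratic)`` must exceed the gestation length
    (~290 d) so the curve is increasing over the whole range.
    """

    scale: float
    rate_linear: float
    rate_quadratic: float
    bcs_exponent: float | None = None
    per_kg_cbw: bool = True

    def __post_init__(self):
        if self.scale <= 0 or self.rate_linear <= 0 or self.rate_quadratic < 0:
            raise ValueError("gravid-uterus coefficients must be positive")
        if self.rate_quadratic > 0 and self.rate_linear / (2 * self.rate_quadratic) <= 290:
            raise ValueError("curve would turn over inside the gestation range")


#: BCS-dependent curve scaled per kg of expected calf birth weight.
GU_BCS_CBW = GUModelParams(0.008010, 0.02544, 0.0000286, bcs_exponent=0.3225)
#: DOP-only curve scaled per kg of expected calf birth weight.
GU_DOP_CBW = GUModelParams(0.007521, 0.03119, 0.00004117)
#: Unscaled forms as originally fitted (28-kg calf implicit in the scale).
GU_BCS_RAW = GUModelParams(0.2243, 0.02544, 0.0000286, bcs_exponent=0.3225, per_kg_cbw=False)
GU_DOP_RAW = GUModelParams(0.2106, 0.03119, 0.00004117, per_kg_cbw=False)
#: Ferrell-type curve for B. taurus heifers; note the scale is in grams.
GU_TAURUS_G = GUModelParams(19.32, 0.02, 0.0000143)


@dataclass(frozen=True)
class UdderModelParams:
    """Segmented udder model: flat allometric branch up to ``breakpoint``
    days of pregnancy, exponential growth at ``rate``/day beyond it."""

    breakpoint: float = 238.0
    scale: float = 0.00589
    bcs_exponent: float = 0.2043
    rate: float = 0.0109

    def __post_init__(self):
        if not 0 < self.breakpoint < 290:
            raise ValueError("breakpoint must lie inside the gestation range")
        if self.scale <= 0 or self.rate <= 0:
            raise ValueError("udder scale and rate must be positive")


@dataclass(frozen=True)
class EquationParams:
    """Complete coefficient set for the adjustment chain.

    Units: weights kg, rates per day, DOP days, BCS on the 1-9 scale.
    ``ut_branch_day`` is the day beyond which the provisional non-pregnant
    uterus subtracts the 2-kg udder-accretion placeholder; ``preg_udder_day``
    is the day beyond which udder accretion is counted in the pregnancy
    compound. Both are 240 d in the published chain even though the fitted
    udder breakpoint is 238 d.
    """

    sbw_linear: float = 0.9763
    sbw_power_scale: float = 0.8084
    sbw_power_exp: float = 1.0303
    ebw_linear: float = 0.9092
    ebw_power_scale: float = 0.8424
    ebw_power_exp: float = 1.0122
    ut_coef: float = 0.0012
    ut_offset: float = 0.6           # UT_np of a 500-kg cow, kg
    ut_udder_placeholder: float = 2.0  # average late-gestation udder accretion, kg
    ut_branch_day: float = 240.0
    preg_udder_day: float = 240.0
    gu_bcs: GUModelParams = GU_BCS_CBW
    gu_dop: GUModelParams = GU_DOP_CBW
    gu_taurus: GUModelParams = GU_TAURUS_G
    udder: UdderModelParams = UdderModelParams()
    # observed development envelope (extrapolation warnings outside it)
    bw_range: tuple[float, float] = (299.0, 701.0)
    bcs_valid: tuple[float, float] = (3.0, 8.0)
    dop_range: tuple[float, float] = (0.0, 290.0)


DEFAULT_PARAMS = EquationParams()


@dataclass(frozen=True)
class BreedProfile:
    """Breed-specific equation choices for the adjustment chain.

    ``indicus`` uses the Nellore-fitted equations throughout. ``taurus``
    replaces the shrunk-weight relation by the 0.96 factor, the empty-weight
    relation by the 0.851 factor and the gravid-uterus curve by the
    Ferrell-type model, with a 38.5-kg default calf. ``crossbred`` averages
    the two pure-breed decompositions.
    """

    name: str
    sbw_linear_coef: float
    sbw_power_coefs: tuple[float, float] | None
    ebw_linear_coef: float
    ebw_power_coefs: tuple[float, float] | None
    gu_model: str  # {"indicus_bcs", "indicus_dop_only", "taurus_ferrell"}
    default_cbw: float
    parents: tuple["BreedProfile", "BreedProfile"] | None = None

    def __post_init__(self):
        for v in (self.sbw_linear_coef, self.ebw_linear_coef, self.default_cbw):
            if v <= 0:
                raise ValueError("breed coefficients must be strictly positive")


INDICUS = BreedProfile(
    name="indicus",
    sbw_linear_coef=0.9763,
    sbw_power_coefs=(0.8084, 1.0303),
    ebw_linear_coef=0.9092,
    ebw_power_coefs=(0.8424, 1.0122),
    gu_model="indicus_bcs",
    default_cbw=28.0,
)

TAURUS = BreedProfile(
    name="taurus",
    sbw_linear_coef=0.96,
    sbw_power_coefs=None,
    ebw_linear_coef=0.851,
    ebw_power_coefs=None,
    gu_model="taurus_ferrell",
    default_cbw=38.5,
)

CROSSBRED = BreedProfile(
    name="crossbred",
    sbw_linear_coef=(INDICUS.sbw_linear_coef + TAURUS.sbw_linear_coef) / 2,
    sbw_power_coefs=None,
    ebw_linear_coef=(INDICUS.ebw_linear_coef + TAURUS.ebw_linear_coef) / 2,
    ebw_power_coefs=None,
    gu_model="indicus_bcs",
    default_cbw=(INDICUS.default_cbw + TAURUS.default_cbw) / 2,
    parents=(INDICUS, TAURUS),
)

_PROFILES = {"indicus": INDICUS, "taurus": TAURUS, "crossbred": CROSSBRED}


def get_breed_profile(name: str) -> BreedProfile:
    try:
        return _PROFILES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown breed {name!r}; expected one of {sorted(_PROFILES)}") from None


# ---------------------------------------------------------------------------
# parameter-file round trip (flat "section.key = value" text format)

def _flatten(obj, prefix=""):
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        key = f"{prefix}{f.name}"
        if dataclasses.is_dataclass(v):
            out.update(_flatten(v, prefix=key + "."))
        elif isinstance(v, tuple):
            out[key] = " ".join(str(x) for x in v)
        elif isinstance(v, bool):
            out[key] = str(v).lower()
        elif v is None:
            out[key] = "none"
        else:
            out[key] = repr(float(v)) if isinstance(v, float) else str(v)
    return out


def save_params(params: EquationParams, path) -> None:
    """Write a coefficient set as editable ``key = value`` text."""
    lines = ["# cowbw equation parameters (kg, days, 1-9 BCS)", "format_version = 1"]
    lines += [f"{k} = {v}" for k, v in _flatten(params).items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_scalar(text: str):
    t = text.strip()
    if t == "none":
        return None
    if t in ("true", "false"):
        return t == "true"
    parts = t.split()
    if len(parts) > 1:
        return tuple(float(p) for p in parts)
    return float(t)


def load_params(path) -> EquationParams:
    """Read a coefficient set written by :func:`save_params`."""
    flat = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        flat[key.strip()] = _parse_scalar(value)
    flat.pop("format_version", None)

    def build(cls, prefix):
        kwargs = {}
        for f in dataclasses.fields(cls):
            key = f"{prefix}{f.name}"
            if f.name in ("gu_bcs", "gu_dop", "gu_taurus"):
                kwargs[f.name] = build(GUModelParams, key + ".")
            elif f.name == "udder":
                kwargs[f.name] = build(UdderModelParams, key + ".")
            elif key in flat:
                kwargs[f.name] = flat[key]
        return cls(**kwargs)

    return build(EquationParams, "")
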