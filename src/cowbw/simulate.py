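"""Synthetic herds and model-specific datasets.

The generator emulates the design of the study herd the equations were
developed on: 49 multiparous Nellore cows (32 pregnant, slaughtered in groups
at 136/189/239/269 days of pregnancy; 17 non-pregnant at day 0), two feeding
levels with maternal shrunk weights around 543 (HIGH) and 460 kg (LOW),
condition scores on the 0.5 grid between 3 and 8, and a 28-kg expected calf.
Latent truths are computed with the package's own adjustment chain and
observed values add multiplicative Gaussian noise whose coefficients of
variation default to the published cross-validation error percentages
(SBW 1.0%, EBW 2.1%, GU 19%, UT 14%, UD 12%).

Because the chain estimates the non-pregnant uterus from a provisional
maternal weight, the pregnancy compound depends (weakly) on the pregnant
shrunk weight itself; the generator therefore draws the maternal weight and
solves the fixed point ``sbw_p = sbw_np + preg(sbw_p)`` so that, at zero
noise, adjusting a generated record returns the latent truths to machine
precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import PregnancyDecomposition, preg_compound
from .exceptions import DomainError
from .models import MODEL_FAMILIES
from .parameters import DEFAULT_PARAMS, INDICUS, EquationParams

__all__ = ["HerdConfig", "generate_herd", "generate_fit_dataset", "DEFAULT_SEED"]

#: documentation default; any analysis seed overrides it
DEFAULT_SEED = 20150320


def _default_noise_cv() -> dict:
    return {"sbw": 0.010, "ebw": 0.021, "gu": 0.19, "ut": 0.14, "ud": 0.12, "bw": 0.010}


@dataclass
class HerdConfig:
    """Study-design parameters for the synthetic herd."""

    n_total: int = 49
    n_pregnant: int = 32
    dop_groups: tuple[int, ...] = (0, 136, 189, 239, 269)
    sbw_mean_high: float = 543.0
    sbw_mean_low: float = 460.0
    sbw_sd: float = 45.0
    sbw_range: tuple[float, float] = (366.0, 701.0)
    bcs_range: tuple[float, float] = (3.0, 8.0)
    cbw_mean: float = 28.0
    breed: str = "indicus"
    noise_cv: dict = field(default_factory=_default_noise_cv)
    noise_mode: str = "multiplicative"
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_pregnant > self.n_total:
            raise DomainError("n_pregnant cannot exceed n_total")
        if any(cv < 0 for cv in self.noise_cv.values()):
            raise DomainError("noise CVs must be non-negative")
        if self.sbw_range[0] >= self.sbw_range[1] or self.bcs_range[0] >= self.bcs_range[1]:
            raise DomainError("truncation bounds are inconsistent")
        if self.noise_mode not in ("multiplicative", "additive"):
            raise DomainError("noise_mode must be 'multiplicative' or 'additive'")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal; falls back to clipping if the
    window is in a far tail."""
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=size * 2)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
        if filled == size:
            return out
    out[filled:] = np.clip(rng.normal(mean, sd, size=size - filled), lo, hi)
    return out


def _bcs_grid(rng, lo, hi, size):
    grid = np.arange(np.ceil(lo * 2) / 2, hi + 1e-9, 0.5)
    return rng.choice(grid, size=size)


def _solve_decomposition(sbw_np, bcs, dop, cbw, params) -> PregnancyDecomposition:
    """Fixed point of sbw_p = sbw_np + preg(sbw_p) for a pregnant cow."""
    sp = sbw_np
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(200):
            dec = preg_compound(sp, bcs, dop, cbw, INDICUS, params=params)
            new_sp = sbw_np + dec.preg
            if abs(new_sp - sp) < 1e-12:
                sp = new_sp
                break
            sp = new_sp
        return preg_compound(sp, bcs, dop, cbw, INDICUS, params=params)


def _noised(rng, true, cv, mode):
    true = np.asarray(true, dtype=float)
    if cv == 0:
        return true.copy()
    if mode == "multiplicative":
        return true * (1.0 + rng.normal(0.0, cv, size=true.shape))
    return true + rng.normal(0.0, cv * abs(float(np.mean(true))), size=true.shape)


def generate_herd(config: HerdConfig = HerdConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic herd.

    Returns ``(herd, truth)``: ``herd`` has the observation columns
    (cow_id, bw_kg, sbw_kg, bcs, dop, cbw_kg, breed, feeding_level) with
    noise applied; ``truth`` carries the latent decomposition of each cow.
    """
    rng = np.random.default_rng(config.seed)
    params = DEFAULT_PARAMS

    pregnant_groups = [d for d in config.dop_groups if d > 0]
    per_group, remainder = divmod(config.n_pregnant, max(len(pregnant_groups), 1))
    dops = [0] * (config.n_total - config.n_pregnant)
    for i, d in enumerate(pregnant_groups):
        dops += [d] * (per_group + (1 if i < remainder else 0))
    dops = np.array(dops, dtype=int)

    # alternate feeding levels within each pregnancy group (the study split
    # each slaughter group between the two levels)
    levels = np.empty(config.n_total, dtype=object)
    for d in np.unique(dops):
        idx = np.flatnonzero(dops == d)
        levels[idx] = np.where(np.arange(idx.size) % 2 == 0, "HIGH", "LOW")

    means = np.where(levels == "HIGH", config.sbw_mean_high, config.sbw_mean_low)
    lo, hi = config.sbw_range
    # leave room for the pregnancy compound so the pregnant shrunk weight
    # stays inside the observed envelope
    upper = np.where(dops > 0, hi - 60.0, hi)
    sbw_np = np.array([
        _truncated_normal(rng, m, config.sbw_sd, lo, u, 1)[0]
        for m, u in zip(means, upper)
    ])
    bcs_lo, bcs_hi = config.bcs_range
    bcs = np.where(
        levels == "HIGH",
        _bcs_grid(rng, min(bcs_lo + 1.5, bcs_hi), bcs_hi, config.n_total),
        _bcs_grid(rng, bcs_lo, max(bcs_hi - 1.5, bcs_lo), config.n_total),
    )

    decs = [
        _solve_decomposition(w, b, int(d), config.cbw_mean, params)
        if d > 0
        else preg_compound(w, b, 0, config.cbw_mean, INDICUS, params=params)
        for w, b, d in zip(sbw_np, bcs, dops)
    ]
    truth = pd.DataFrame([d.as_dict() for d in decs]).drop(columns=["warnings"])
    truth.insert(0, "cow_id", [f"cow{i + 1:03d}" for i in range(config.n_total)])
    truth["dop"] = dops
    truth["bcs"] = bcs
    truth["feeding_level"] = levels
    # fed weight by inverting the shrunk-weight power relation
    truth["bw"] = (truth["sbw_p"] / params.sbw_power_scale) ** (1.0 / params.sbw_power_exp)

    cv = {**_default_noise_cv(), **config.noise_cv}
    herd = pd.DataFrame({
        "cow_id": truth["cow_id"],
        "bw_kg": np.clip(
            _noised(rng, truth["bw"], cv["bw"], config.noise_mode),
            lo / params.sbw_linear * 0.9, None,
        ),
        "sbw_kg": np.clip(
            _noised(rng, truth["sbw_p"], cv["sbw"], config.noise_mode), lo, hi,
        ),
        "bcs": bcs,
        "dop": dops,
        "cbw_kg": config.cbw_mean,
        "breed": config.breed,
        "feeding_level": levels,
    })
    return herd, truth


def _published_response(name: str, cols: dict) -> np.ndarray:
    p = MODEL_FAMILIES[name].published
    if name in ("sbw_linear", "ebw_linear", "ut_np"):
        (x,) = cols.values()
        return p["slope"] * x
    if name in ("sbw_power", "ebw_power"):
        (x,) = cols.values()
        return p["scale"] * np.power(x, p["exponent"])
    if name in ("gu_bcs", "gu_dop"):
        dop = cols["dop"]
        out = p["scale"] * np.exp((p["rate_linear"] - p["rate_quadratic"] * dop) * dop)
        if "bcs" in cols:
            out = out * np.power(cols["bcs"], p["bcs_exponent"])
        return out
    if name == "udder_segmented":
        ramp = np.maximum(cols["dop"] - p["breakpoint"], 0.0)
        return (cols["sbw_np"] * p["scale"]
                * np.power(cols["bcs"], p["bcs_exponent"]) * np.exp(p["rate"] * ramp))
    raise ValueError(f"unknown model family {name!r}")


def generate_fit_dataset(model_name: str, n: int, noise_cv: float = 0.0,
                         seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Covariates over a family's validity envelope plus a noisy response.

    The response is the published model evaluated at the covariates times
    ``(1 + N(0, noise_cv))``; the noise-free response is kept in
    ``<response>_true`` for recovery experiments.
    """
    if model_name not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {model_name!r}")
    if n < 1:
        raise DomainError("n must be at least 1")
    rng = np.random.default_rng(seed)
    family = MODEL_FAMILIES[model_name]

    cols: dict[str, np.ndarray] = {}
    for pred in family.predictors:
        if pred == "bw":
            cols[pred] = rng.uniform(306.0, 715.0, size=n)
        elif pred == "sbw_np":
            cols[pred] = rng.uniform(300.0, 700.0, size=n)
        elif pred == "bcs":
            cols[pred] = _bcs_grid(rng, 3.0, 8.0, n)
        elif pred == "dop":
            if model_name == "udder_segmented":
                # both branches of the breakpoint must be populated
                dop = rng.integers(0, 291, size=n).astype(float)
                dop[rng.random(n) < 0.3] = 0.0
                if n >= 2:
                    dop[-1] = 270.0
                    dop[-2] = 260.0
                cols[pred] = dop
            else:
                # gravid-uterus data exist only between the first and last
                # slaughter groups (about 135-270 d)
                cols[pred] = rng.integers(135, 271, size=n).astype(float)
        else:  # pragma: no cover - registry and generator kept in sync
            raise ValueError(f"no sampling rule for predictor {pred!r}")

    true = _published_response(model_name, cols)
    response = true * (1.0 + rng.normal(0.0, noise_cv, size=n)) if noise_cv > 0 else true.copy()
    out = pd.DataFrame(cols)
    out[family.response] = response
    out[family.response + "_true"] = true
    return out
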