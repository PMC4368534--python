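"""Repeated random-subsampling cross-validation of the model families.

Protocol: 20 replicates, each a simple random 70% subsample of the records;
the family is refitted on the subsample and deviations d = predicted -
observed are taken on the evaluation records (the held-out 30% by default, or
all records). Summary statistics follow the reporting convention of the
source analysis: RMSE is the standard deviation of the pooled deviations (an
RMS-including-bias variant is available), MAE the mean absolute deviation, R
the per-replicate observed-predicted correlation reported as mean +/- SD, and
R-squared the square of the mean R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .models import MODEL_FAMILIES, ModelFamily

__all__ = ["CVSummary", "make_replicates", "run_cv", "summarize_cv", "cross_validate"]


@dataclass(frozen=True)
class CVSummary:
    """Aggregate cross-validation statistics for one model family."""

    model_name: str
    n: int
    reps: int
    response_mean: float
    rmse: float
    rmse_pct_mean: float
    mae: float
    r_mean: float
    r_sd: float
    r2: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def make_replicates(n: int, frac: float = 0.7, reps: int = 20, seed: int = 0) -> np.ndarray:
    """Boolean selection masks, shape (reps, n): independent simple random
    samples without replacement of round(frac*n) records each."""
    if not 0 < frac < 1:
        raise DomainError("frac must lie strictly between 0 and 1")
    if reps < 1:
        raise DomainError("reps must be at least 1")
    k = round(frac * n)
    if k < 2:
        raise DomainError(f"subsample of {k} records is too small to fit anything")
    rng = np.random.default_rng(seed)
    masks = np.zeros((reps, n), dtype=bool)
    for i in range(reps):
        masks[i, rng.choice(n, size=k, replace=False)] = True
    return masks


def _resolve_family(model) -> ModelFamily:
    if isinstance(model, ModelFamily):
        return model
    try:
        return MODEL_FAMILIES[model]
    except KeyError:
        raise ValueError(
            f"unknown model family {model!r}; expected one of {sorted(MODEL_FAMILIES)}"
        ) from None


def run_cv(data: pd.DataFrame, model, masks: np.ndarray, evaluate_on: str = "holdout"):
    """Fit the family on each replicate's selected records and collect
    deviations on the evaluation records.

    ``evaluate_on``: ``"holdout"`` (the unselected records; default) or
    ``"all"`` (every record, selected included). Replicates whose fit fails
    are excluded with a warning.

    Returns ``(deviations, predictions, observations)`` — lists with one
    array per successful replicate, where deviation = predicted - observed.
    """
    family = _resolve_family(model)
    if evaluate_on not in ("holdout", "all"):
        raise ValueError("evaluate_on must be 'holdout' or 'all'")
    data = data.reset_index(drop=True)
    y = data[family.response].to_numpy(dtype=float)
    X = family.design(data)

    deviations, predictions, observations = [], [], []
    for i, mask in enumerate(np.asarray(masks, dtype=bool)):
        try:
            est = family.make().fit(X[mask], y[mask])
        except Exception as err:  # noqa: BLE001 - any fit failure excludes the replicate
            warnings.warn(f"replicate {i} excluded: fit failed ({err})", stacklevel=2)
            continue
        if getattr(est, "result_", None) is not None and not est.result_.converged:
            warnings.warn(f"replicate {i} excluded: fit did not converge", stacklevel=2)
            continue
        eval_idx = np.ones_like(mask) if evaluate_on == "all" else ~mask
        pred = np.asarray(est.predict(X[eval_idx]), dtype=float)
        obs = y[eval_idx]
        deviations.append(pred - obs)
        predictions.append(pred)
        observations.append(obs)
    return deviations, predictions, observations


def summarize_cv(
    deviations, predictions, observations, *,
    model_name: str = "", n: int | None = None, rmse_mode: str = "sd",
) -> CVSummary:
    """Aggregate per-replicate deviations into a :class:`CVSummary`.

    ``rmse_mode='sd'`` (default) takes RMSE as the standard deviation of the
    pooled deviations; ``'rms'`` as sqrt(mean(d**2)), which includes any mean
    bias.
    """
    if len(deviations) == 0:
        raise DomainError("no successful replicate to summarise")
    d = np.concatenate([np.asarray(v, dtype=float) for v in deviations])
    pooled_obs = np.concatenate([np.asarray(v, dtype=float) for v in observations])
    if rmse_mode == "sd":
        rmse = float(d.std(ddof=1)) if d.size > 1 else 0.0
    elif rmse_mode == "rms":
        rmse = float(np.sqrt(np.mean(d * d)))
    else:
        raise ValueError("rmse_mode must be 'sd' or 'rms'")
    mae = float(np.mean(np.abs(d)))
    rs = []
    for pred, obs in zip(predictions, observations):
        pred = np.asarray(pred, dtype=float)
        obs = np.asarray(obs, dtype=float)
        if pred.std() == 0 or obs.std() == 0:
            continue
        rs.append(float(np.corrcoef(pred, obs)[0, 1]))
    r_mean = float(np.mean(rs)) if rs else float("nan")
    r_sd = float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0
    mean_obs = float(pooled_obs.mean())
    return CVSummary(
        model_name=model_name,
        n=int(n) if n is not None else int(pooled_obs.size),
        reps=len(deviations),
        response_mean=mean_obs,
        rmse=rmse,
        rmse_pct_mean=100.0 * rmse / mean_obs if mean_obs != 0 else float("nan"),
        mae=mae,
        r_mean=r_mean,
        r_sd=r_sd,
        r2=r_mean * r_mean if np.isfinite(r_mean) else float("nan"),
    )


def cross_validate(
    data: pd.DataFrame, model, *,
    reps: int = 20, frac: float = 0.7, seed: int = 0,
    evaluate_on: str = "holdout", rmse_mode: str = "sd",
) -> CVSummary:
    """One-call protocol: build masks, run every replicate, summarise."""
    family = _resolve_family(model)
    masks = make_replicates(len(data), frac=frac, reps=reps, seed=seed)
    devs, preds, obss = run_cv(data, family, masks, evaluate_on=evaluate_on)
    return summarize_cv(devs, preds, obss, model_name=family.name,
                        n=len(data), rmse_mode=rmse_mode)
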