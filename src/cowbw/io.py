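"""Herd CSV reading, validation and adjusted-output writing.

One flat dialect: comma-separated, dot decimal, UTF-8, header mandatory.
Input columns: cow_id, bw_kg, sbw_kg, bcs, dop, cbw_kg, breed, feeding_level
(empty cells = missing). The adjusted output repeats the inputs and appends
the decomposition ledger plus a semicolon-joined warnings column.
"""

from __future__ import annotations

import math

import pandas as pd

from .decomposition import CowObservation, adjust_record
from .exceptions import CowBWError, HerdValidationError

HERD_COLUMNS = ["cow_id", "bw_kg", "sbw_kg", "bcs", "dop", "cbw_kg", "breed", "feeding_level"]
OUTPUT_COLUMNS = HERD_COLUMNS + [
    "sbw_used_kg", "gu_kg", "ut_np_kg", "gu_dp_kg", "ud_np_kg", "ud_p_kg",
    "ud_dp_kg", "preg_kg", "sbw_np_kg", "ebw_np_kg", "ebw_p_kg",
    "preg_fraction", "warnings",
]


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def read_herd_csv(path) -> pd.DataFrame:
    """Read and schema-check a herd CSV; missing optional columns are added
    as empty."""
    df = pd.read_csv(path)
    if "cow_id" not in df.columns or not ("bw_kg" in df.columns or "sbw_kg" in df.columns):
        raise HerdValidationError([(0, "header must include cow_id and bw_kg or sbw_kg")])
    for col in HERD_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df


def row_to_observation(row) -> CowObservation:
    breed = row.get("breed")
    if breed is None or (isinstance(breed, float) and math.isnan(breed)) or breed == "":
        breed = "indicus"
    dop = row.get("dop")
    dop = 0 if dop is None or (isinstance(dop, float) and math.isnan(dop)) else int(dop)
    fl = row.get("feeding_level")
    if isinstance(fl, float) and math.isnan(fl):
        fl = None
    return CowObservation(
        id=str(row["cow_id"]),
        bw=_opt(row.get("bw_kg")),
        sbw=_opt(row.get("sbw_kg")),
        bcs=_opt(row.get("bcs")),
        dop=dop,
        cbw=_opt(row.get("cbw_kg")),
        feeding_level=fl,
        breed=str(breed),
    )


def adjust_table(
    herd: pd.DataFrame, *, sbw_mode="power", ebw_mode="power",
    gu_model=None, params=None, fail_fast=False,
) -> pd.DataFrame:
    """Adjust every row of a herd table.

    Invalid rows raise :class:`HerdValidationError` listing 1-based data row
    numbers (immediately if ``fail_fast``, otherwise after scanning all
    rows); valid rows are returned with the full decomposition ledger.
    """
    from .parameters import DEFAULT_PARAMS

    params = params or DEFAULT_PARAMS
    records, problems = [], []
    for i, row in enumerate(herd.to_dict("records"), start=1):
        try:
            obs = row_to_observation(row)
            dec = adjust_record(obs, sbw_mode=sbw_mode, ebw_mode=ebw_mode,
                                gu_model=gu_model, params=params)
        except CowBWError as err:
            problems.append((i, str(err)))
            if fail_fast:
                raise HerdValidationError(problems) from err
            continue
        out = dict(row)
        out.update({
            "sbw_used_kg": dec.sbw_p,
            "gu_kg": dec.gu,
            "ut_np_kg": dec.ut_np,
            "gu_dp_kg": dec.gu_dp,
            "ud_np_kg": dec.ud_np,
            "ud_p_kg": dec.ud_p,
            "ud_dp_kg": dec.ud_dp,
            "preg_kg": dec.preg,
            "sbw_np_kg": dec.sbw_np,
            "ebw_np_kg": dec.ebw_np,
            "ebw_p_kg": dec.ebw_p,
            "preg_fraction": dec.preg_fraction,
            "warnings": ";".join(dec.warnings),
        })
        records.append(out)
    if problems:
        raise HerdValidationError(problems)
    return pd.DataFrame.from_records(records, columns=OUTPUT_COLUMNS)


def write_output_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
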