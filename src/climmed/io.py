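"""Cohort CSV reading and writing.

The on-disk format is a plain CSV with the fixed header
``province_id,mean_temp_c,sex,age,education,fv_adequate,pa_level,overweight,obesity``;
categories are lower-case tokens and a missing fruit/vegetable value is
an empty field.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .schema import CATEGORY_LEVELS, COHORT_COLUMNS

logger = logging.getLogger("climmed")

__all__ = ["load_cohort_csv", "write_cohort_csv", "validate_cohort"]


def validate_cohort(data: pd.DataFrame) -> None:
    """Validate tokens, missingness rules and within-province temperature
    constancy; raises :class:`SchemaError` naming the first offending row."""
    missing_cols = [c for c in COHORT_COLUMNS if c not in data.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")
    for col, levels in CATEGORY_LEVELS.items():
        allow_missing = col == "fv_adequate"
        values = data[col]
        bad = ~values.isin(levels)
        if allow_missing:
            bad &= values.notna()
        elif values.isna().any():
            row = int(values.index[values.isna()][0])
            raise SchemaError(f"missing value in column {col!r} at row {row}")
        if bad.any():
            row = int(values.index[bad][0])
            raise SchemaError(
                f"unknown token {values[row]!r} in column {col!r} at row {row}"
            )
    for col in ("mean_temp_c", "age"):
        arr = pd.to_numeric(data[col], errors="coerce")
        if arr.isna().any():
            row = int(arr.index[arr.isna()][0])
            raise SchemaError(f"non-numeric value in column {col!r} at row {row}")
    spread = data.groupby("province_id")["mean_temp_c"].nunique()
    if (spread > 1).any():
        pid = spread.index[spread > 1][0]
        raise SchemaError(
            f"mean_temp_c not constant within province {pid!r}"
        )


def load_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; logs row count and missingness."""
    data = pd.read_csv(
        path,
        float_precision="round_trip",  # write∘load must be the identity
        dtype={
            "sex": "object", "education": "object", "fv_adequate": "object",
            "pa_level": "object", "overweight": "object", "obesity": "object",
        },
    )
    validate_cohort(data)
    n_missing = int(data["fv_adequate"].isna().sum())
    logger.info(
        "loaded cohort: %d rows, %d with missing fruit/vegetable status",
        len(data), n_missing,
    )
    return data


def write_cohort_csv(data: pd.DataFrame, path) -> None:
    """Write a validated cohort table; missing M1 becomes an empty field."""
    validate_cohort(data)
    out = data[COHORT_COLUMNS].copy()
    # stable numeric formatting so a load/write cycle is the identity
    out.to_csv(path, index=False, na_rep="")
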