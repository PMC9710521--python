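"""Reading and validating item-response tables.

Tables are plain CSV with a header: one integer column per item, plus
optional ``group`` and ``sex`` columns.  Validation enforces the declared
category range per item (0-3 for PHQ/GAD, 1-5 for YSIS in the default
instrument), integer coding, and no missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ITEM_RANGES

__all__ = [
    "MissingColumnError",
    "InvalidValueError",
    "read_responses",
    "validate_responses",
]


class MissingColumnError(ValueError):
    """A declared column is absent from the file."""


class InvalidValueError(ValueError):
    """A cell is missing, non-integer, or outside its declared range."""


def validate_responses(
    data: pd.DataFrame,
    ranges: dict[str, tuple[int, int]] = ITEM_RANGES,
    group_col: str | None = "group",
    on_invalid: str = "raise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate an in-memory table; returns (clean table, rejection report).

    ``on_invalid="raise"`` raises :class:`InvalidValueError` naming the
    first offending row and column; ``"drop"`` removes offending rows and
    reports them (row index, column, value, reason).
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    for col in ranges:
        if col not in data.columns:
            raise MissingColumnError(f"missing item column {col!r}")
    if group_col is not None and group_col in data.columns:
        if data[group_col].isna().any():
            raise InvalidValueError(f"missing values in {group_col!r} column")
    bad: list[tuple[int, str, object, str]] = []
    for col, (lo, hi) in ranges.items():
        v = data[col]
        isna = v.isna()
        num = pd.to_numeric(v, errors="coerce")
        nonint = (~isna) & (num.isna() | (num != np.floor(num)))
        outr = (~isna) & ~nonint & ((num < lo) | (num > hi))
        for idx in data.index[isna]:
            bad.append((idx, col, None, "missing"))
        for idx in data.index[nonint]:
            bad.append((idx, col, v.loc[idx], "non-integer"))
        for idx in data.index[outr]:
            bad.append((idx, col, v.loc[idx], f"outside [{lo}, {hi}]"))
    report = pd.DataFrame(bad, columns=["row", "column", "value", "reason"])
    if len(report) and on_invalid == "raise":
        r = report.iloc[0]
        raise InvalidValueError(
            f"invalid value in row {r['row']}, column {r['column']!r}: "
            f"{r['value']!r} ({r['reason']})"
        )
    clean = data.drop(index=report["row"].unique()) if len(report) else data
    clean = clean.copy()
    for col in ranges:
        clean[col] = clean[col].astype(np.int64)
    return clean, report


def read_responses(
    path: str | Path,
    ranges: dict[str, tuple[int, int]] = ITEM_RANGES,
    group_col: str | None = "group",
    on_invalid: str = "raise",
) -> pd.DataFrame:
    """Read and validate a response CSV; column order in the file is free."""
    df = pd.read_csv(path)
    clean, _ = validate_responses(df, ranges, group_col, on_invalid)
    ordered = [c for c in ranges] + [
        c for c in (group_col, "sex") if c is not None and c in clean.columns
    ]
    return clean[ordered]
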