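"""Descriptive summaries: mean, SEM, CV% per group and pooled.

Conventions: SEM = s / sqrt(n) and CV% = 100 s / mean with s the n-1
sample standard deviation; the pooled ("overall") row is computed on the
concatenated sample, not by averaging group-level statistics, so its CV
reflects both within- and between-group dispersion.  Groups of size 1
report NaN SEM/CV with a warning rather than failing.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration
from .indices import INDEX_CODES

SUMMARY_COLUMNS = ("variable", "group", "n", "mean", "sem", "cv_pct")


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (table convention, unlike banker's).

    Decimal-based so that a printed half (e.g. 2.345 at 2 dp) rounds up
    even when the binary double sits a hair below it.
    """
    if not math.isfinite(value):
        return value
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _stats(values: np.ndarray) -> tuple[int, float, float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        return 0, math.nan, math.nan, math.nan
    mean = float(values.mean())
    if n == 1:
        warnings.warn("group of size 1: SEM and CV undefined", stacklevel=3)
        return 1, mean, math.nan, math.nan
    sd = float(values.std(ddof=1))
    sem = sd / math.sqrt(n)
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return n, mean, sem, 100.0 * sd / mean


def summarize(
    table: pd.DataFrame,
    variables: Sequence[str],
    *,
    by: Sequence[str] = ("biotype",),
    overall: bool = True,
) -> pd.DataFrame:
    """Per-group and pooled summaries in tidy form.

    Returns columns ``variable, group, n, mean, sem, cv_pct`` with one
    row per (variable, group); the pooled row uses group label
    ``"overall"``.  Group keys with several columns are joined by ``/``.
    """
    by = list(by)
    rows = []
    for variable in variables:
        if variable not in table.columns:
            raise KeyError(f"variable {variable!r} not in table")
        if by:
            for key, chunk in table.groupby(by, sort=False, observed=True):
                label = key if isinstance(key, str) else "/".join(map(str, key))
                n, mean, sem, cv = _stats(chunk[variable].to_numpy())
                rows.append((variable, label, n, mean, sem, cv))
        if overall or not by:
            n, mean, sem, cv = _stats(table[variable].to_numpy())
            rows.append((variable, "overall", n, mean, sem, cv))
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def format_table(
    summaries: pd.DataFrame,
    layout: str = "measurements",
    *,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide report table: one variable per row, one column per group.

    ``layout`` selects the row order: ``measurements`` (17 rows, the
    report order of the calibration) or ``indices`` (10 rows).  Group
    cells show ``mean +/- SEM`` at 2 dp; the pooled column is followed
    by a CV% column.  Variables absent from ``summaries`` show ``--``.
    """
    if layout == "measurements":
        order: Sequence[str] = calibration.MEASUREMENT_REPORT_ORDER
    elif layout == "indices":
        order = INDEX_CODES
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if groups is None:
        groups = [g for g in summaries["group"].unique() if g != "overall"]
    columns = [*groups, "overall"]
    out_rows = []
    for variable in order:
        chunk = summaries[summaries["variable"] == variable]
        row = {"variable": variable}
        for group in columns:
            cell = chunk[chunk["group"] == group]
            if cell.empty:
                row[group] = "--"
                continue
            mean = round_half_away(float(cell["mean"].iloc[0]), 2)
            sem = round_half_away(float(cell["sem"].iloc[0]), 2)
            row[group] = f"{mean:.2f} ± {sem:.2f}"
        pooled = chunk[chunk["group"] == "overall"]
        row["cv_pct"] = (
            "--" if pooled.empty
            else f"{round_half_away(float(pooled['cv_pct'].iloc[0]), 2):.2f}"
        )
        out_rows.append(row)
    return pd.DataFrame(out_rows, columns=["variable", *columns, "cv_pct"])
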