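"""Descriptive profiling of archetypoids on digital foot measurements.

Shape is what is left after removing scale, so measurement columns (mm)
are first divided by foot length (FL) before ranking.  Archetypoids are
then characterized by the empirical percentile of each of their ratio
values within the whole sample — a compact profile a designer can read
without looking at 3D geometry.  Percentiles use the rank-based convention

    percentile = round(100 * (r - 0.5) / n)

with r the 1-based rank (mean rank on ties): the sample minimum of n=100
distinct values sits at percentile 1 and near-extreme cases in samples of
a few hundred map to percentiles 1-2, which is the regime the rectangle
visualization below is built for.  The convention matters when comparing
profiles across software; it is stated here deliberately.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .archetypes import max_alpha_assignment
from .exceptions import (
    DegenerateColumnError,
    InvalidInputError,
    InvalidMeasurementError,
    UnsupportedDimensionError,
)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "normalize_by_length",
    "percentile_profile",
    "rectangle_geometry",
    "ternary_export",
    "zscore",
]

#: Measurement names: Foot Length, Ball Girth, Ball Width, Instep Height,
#: Toe Height, Ball Position, Instep Girth, Instep-to-Heel Girth.
MEASUREMENT_COLUMNS = ("FL", "BG", "BW", "IH", "TH", "BP", "IG", "IHG")

_RATIO_SOURCES = ("BG", "BP", "BW", "IG", "IH", "IHG", "TH")


def normalize_by_length(table: pd.DataFrame) -> pd.DataFrame:
    """Append FL-normalized ratio columns (BG/FL, BP/FL, ... TH/FL).

    Requires an FL column with strictly positive values; only the ratio
    columns whose raw column is present are added.
    """
    if "FL" not in table.columns:
        raise InvalidMeasurementError("measurement table has no FL column")
    fl = pd.to_numeric(table["FL"], errors="coerce")
    if fl.isna().any() or (fl <= 0).any():
        raise InvalidMeasurementError("FL must be positive for every specimen")
    out = table.copy()
    for col in _RATIO_SOURCES:
        if col in table.columns:
            out[f"{col}/FL"] = pd.to_numeric(table[col], errors="coerce") / fl
    return out


def percentile_profile(
    table: pd.DataFrame,
    case_indices: Sequence[int],
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Empirical percentile ranks of selected cases within the sample.

    For each selected case and column, round(100*(r - 0.5)/n) with r the
    1-based rank of the case's value in the column (mean rank on ties).
    Returns integer percentiles in [0, 100], one row per selected case.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    n = len(table)
    idx = [int(i) for i in case_indices]
    if any(i < 0 or i >= n for i in idx):
        raise InvalidInputError("case index out of range")
    out = {}
    for c in cols:
        vals = pd.to_numeric(table[c], errors="coerce").to_numpy()
        r = rankdata(vals, method="average")
        # half-up rounding: the sample minimum of n=100 maps to 1, not 0
        pct = np.floor(100.0 * (r - 0.5) / n + 0.5).astype(int)
        out[c] = pct[idx]
    return pd.DataFrame(out, index=[table.index[i] for i in idx])


def rectangle_geometry(median_value: float, percentile: int) -> int:
    """Scaled side length (mm) for the rectangle visualization.

    A representative's measurement is drawn as the sample median scaled by
    its percentile's offset from the median:
    ``median * (1 + (percentile/100 - 0.5))``, rounded to integer mm.  A
    percentile-1 ball width against a 96 mm median draws as 49 mm — the
    deviation from typical is exaggerated to be legible at a glance.
    """
    if not median_value > 0:
        raise InvalidInputError("median_value must be positive")
    if not 0 <= percentile <= 100:
        raise InvalidInputError(f"percentile must be in [0, 100], got {percentile}")
    return int(np.floor(median_value * (1.0 + (percentile / 100.0 - 0.5)) + 0.5))


def ternary_export(alphas: np.ndarray, row_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Three-part mixture coefficients as ternary-plot coordinates.

    Requires p = 3.  Emits a1, a2, a3, the max-alpha label (0-based) and 2D
    equilateral-triangle coordinates x = a2 + a3/2, y = (sqrt(3)/2) a3, so
    corner 1 is at the origin and balanced mixtures at the centroid.
    """
    a = np.atleast_2d(np.asarray(alphas, dtype=float))
    if a.shape[1] != 3:
        raise UnsupportedDimensionError(
            f"ternary export needs exactly 3 archetypoids, got {a.shape[1]}"
        )
    labels = max_alpha_assignment(a)
    df = pd.DataFrame(
        {
            "a1": a[:, 0],
            "a2": a[:, 1],
            "a3": a[:, 2],
            "label": labels,
            "x": a[:, 1] + a[:, 2] / 2.0,
            "y": (np.sqrt(3.0) / 2.0) * a[:, 2],
        }
    )
    if row_ids is not None:
        df.index = list(row_ids)
    return df


def zscore(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Standardize columns to zero mean, unit (n-1) standard deviation."""
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(table) < 2:
        raise InvalidInputError("need at least 2 rows to standardize")
    out = table.copy()
    for c in cols:
        v = pd.to_numeric(table[c], errors="coerce")
        sd = v.std(ddof=1)
        if not sd > 0:
            raise DegenerateColumnError(f"column {c!r} has zero spread")
        out[c] = (v - v.mean()) / sd
    return out
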