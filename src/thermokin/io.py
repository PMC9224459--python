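"""Reading and writing the delimited activity-table format.

The exchange format is a plain-text delimited table (comma or tab) with a
header row ``temperature_C, time_min, replicate, activity``. Activities may
be residual-activity fractions or absolute units; absolute input (detected
when any value exceeds 1.5, or forced via ``normalize_by``) is normalised
per temperature to the replicate mean at the earliest sampling time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import InputError
from .fitting import ActivityCurve

__all__ = [
    "REQUIRED_COLUMNS",
    "read_activity_table",
    "dataframe_to_curves",
    "curves_to_dataframe",
    "write_activity_table",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("temperature_C", "time_min", "replicate", "activity")

#: activities above this are taken to be absolute units rather than fractions
ABSOLUTE_UNITS_THRESHOLD = 1.5


def read_activity_table(
    path, *, already_normalized: bool = False, normalize_by: float | None = None
) -> list[ActivityCurve]:
    """Parse a delimited activity table into one curve per temperature."""
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, csv.Error):
        raise InputError(
            f"empty or undelimited input: expected columns {', '.join(REQUIRED_COLUMNS)}"
        ) from None
    return dataframe_to_curves(
        df, already_normalized=already_normalized, normalize_by=normalize_by
    )


def dataframe_to_curves(
    df: pd.DataFrame,
    *,
    already_normalized: bool = False,
    normalize_by: float | None = None,
) -> list[ActivityCurve]:
    """Validate, group by temperature and (if needed) normalise."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"missing required columns: {', '.join(missing)}")
    if df.empty:
        raise InputError(
            f"no data rows; expected columns {', '.join(REQUIRED_COLUMNS)}"
        )
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in REQUIRED_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise InputError(
                f"non-numeric value {df.loc[row, col]!r} in column {col!r} (row {row})"
            )
        if converted.isna().any():
            raise InputError(f"missing value in column {col!r}")
        df[col] = converted

    dup = df.duplicated(subset=["temperature_C", "time_min", "replicate"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise InputError(
            "duplicated (temperature, time, replicate) key: "
            f"({row['temperature_C']:g}, {row['time_min']:g}, {row['replicate']:g})"
        )

    curves = []
    for temp, group in df.groupby("temperature_C", sort=True):
        group = group.sort_values(["time_min", "replicate"])
        activities = group["activity"].to_numpy(dtype=float)
        if normalize_by is not None:
            if normalize_by <= 0:
                raise InputError("normalize_by must be positive")
            activities = activities / normalize_by
            logger.info("normalised %g degC curve by %g", temp, normalize_by)
        elif not already_normalized and np.nanmax(activities) > ABSOLUTE_UNITS_THRESHOLD:
            t0 = group["time_min"].min()
            a0 = float(
                group.loc[group["time_min"] == t0, "activity"].mean()
            )
            if a0 <= 0:
                raise InputError(
                    f"cannot normalise {temp:g} degC curve: mean activity at "
                    f"t={t0:g} min is {a0:g}"
                )
            activities = activities / a0
            logger.info(
                "activities at %g degC look absolute (max > %.1f); normalised "
                "by the t=%g min replicate mean %.4g",
                temp, ABSOLUTE_UNITS_THRESHOLD, t0, a0,
            )
        curves.append(
            ActivityCurve(
                temperature=float(temp),
                times=group["time_min"].to_numpy(dtype=float),
                activities=activities,
                replicates=group["replicate"].to_numpy(dtype=int),
            )
        )
    return curves


def curves_to_dataframe(curves: list[ActivityCurve]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "temperature_C": curve.temperature,
                "time_min": curve.times,
                "replicate": curve.replicates,
                "activity": curve.activities,
            }
        )
        for curve in curves
    ]
    return pd.concat(frames, ignore_index=True)


def write_activity_table(curves: list[ActivityCurve], path) -> None:
    curves_to_dataframe(curves).to_csv(path, index=False, float_format="%.10g")
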