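"""Coordinate-quality audits of the tracking data.

Body size is the shoulder-to-rump Euclidean distance.  Two checks gauge
whether XY coordinates are trustworthy enough for proximity networks:

* within-animal repeatability CV of body length (sd/mean per animal,
  averaged per pen) — values near 0.10-0.18 indicate keypoint noise small
  relative to body size;
* the inner-vs-outer pen-area contrast of mean body length, which exposes
  camera-distortion gradients (large values mean position-dependent bias).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tracking_io import PenRoster

#: Distance from any wall (m) below which a position counts as "outer".
OUTER_MARGIN_M = 0.5


def body_length(record) -> float:
    """Shoulder-rump Euclidean distance of a single record (metres)."""
    if hasattr(record, "shoulder"):
        (xs, ys), (xr, yr) = record.shoulder, record.rump
    else:  # a frame row / mapping
        xs, ys, xr, yr = (
            record["shoulder_x"], record["shoulder_y"],
            record["rump_x"], record["rump_y"],
        )
    length = float(np.hypot(xs - xr, ys - yr))
    if length == 0.0:
        warnings.warn("coincident shoulder and rump keypoints (length 0)", stacklevel=2)
    return length


def body_lengths(records: pd.DataFrame) -> pd.Series:
    """Vectorized body length for every record."""
    return np.hypot(
        records["shoulder_x"] - records["rump_x"],
        records["shoulder_y"] - records["rump_y"],
    ).rename("body_length_m")


def area_labels(records: pd.DataFrame, roster: PenRoster,
                margin_m: float = OUTER_MARGIN_M) -> pd.Series:
    """Label each record inner/outer by the body midpoint's wall distance."""
    w, h = roster.pen_dimensions
    mx = (records["shoulder_x"] + records["rump_x"]) / 2.0
    my = (records["shoulder_y"] + records["rump_y"]) / 2.0
    wall = np.minimum.reduce([mx, w - mx, my, h - my])
    return pd.Series(np.where(wall < margin_m, "outer", "inner"),
                     index=records.index, name="area")


def repeatability_cv(records: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-animal body-length CV (sd/mean) and the pen mean of those CVs.

    Animals with fewer than two measurements get NaN and a warning; they are
    excluded from the pen mean.
    """
    lengths = body_lengths(records)
    grp = lengths.groupby(records["animal_id"])
    mean = grp.mean()
    sd = grp.std(ddof=1)
    n = grp.count()
    cv = (sd / mean).rename("cv")
    single = n < 2
    if single.any():
        warnings.warn(
            f"repeatability undefined for single-measurement animal(s): "
            f"{sorted(n.index[single])}",
            stacklevel=2,
        )
        cv[single] = np.nan
    return cv, float(cv.mean(skipna=True))


def area_effect(records: pd.DataFrame, roster: PenRoster,
                margin_m: float = OUTER_MARGIN_M) -> tuple[pd.Series, float]:
    """Per-animal |mean inner - mean outer| body length and the pen maximum.

    Animals observed in only one area are skipped (NaN) with a warning.
    """
    df = records.assign(
        length=body_lengths(records).to_numpy(),
        area=area_labels(records, roster, margin_m).to_numpy(),
    )
    means = df.pivot_table(index="animal_id", columns="area", values="length",
                           aggfunc="mean")
    for col in ("inner", "outer"):
        if col not in means:
            means[col] = np.nan
    diff = (means["inner"] - means["outer"]).abs().rename("area_diff_m")
    missing = diff.isna()
    if missing.any():
        warnings.warn(
            f"area effect undefined (one area unobserved) for: "
            f"{sorted(diff.index[missing])}",
            stacklevel=2,
        )
    return diff, float(diff.max(skipna=True))


def validation_report(records: pd.DataFrame, roster: PenRoster,
                      margin_m: float = OUTER_MARGIN_M) -> pd.DataFrame:
    """Per-animal audit table plus a `__pen__` summary row."""
    lengths = body_lengths(records)
    grp = lengths.groupby(records["animal_id"])
    cv, pen_cv = repeatability_cv(records)
    diff, pen_diff = area_effect(records, roster, margin_m)
    out = pd.DataFrame(
        {
            "pen_id": roster.pen_id,
            "n_records": grp.count(),
            "mean_length_m": grp.mean(),
            "cv": cv,
            "area_diff_m": diff,
        }
    )
    out.loc["__pen__"] = [roster.pen_id, int(len(records)),
                          float(lengths.mean()), pen_cv, pen_diff]
    out.index.name = "animal_id"
    return out.reset_index()
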