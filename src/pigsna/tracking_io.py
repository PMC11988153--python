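"""Reading, validating and writing automated pig-tracking records.

The tracking system emits one row per animal per frame: pen, ear-tag ID,
calendar day, seconds since midnight, posture label, and shoulder / rump
XY coordinates in metres from the pen's top-left corner.  The canonical
in-memory container is a :class:`pandas.DataFrame` with the columns in
:data:`TRACKING_COLUMNS`; :class:`TrackingRecord` is the row-level view
used when constructing records programmatically.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Fixed column order of the tracking CSV schema.
TRACKING_COLUMNS = (
    "pen_id",
    "animal_id",
    "day",
    "t",
    "posture",
    "shoulder_x",
    "shoulder_y",
    "rump_x",
    "rump_y",
)

POSTURES = ("standing", "lying", "sitting")


@dataclass(frozen=True)
class TrackingRecord:
    """One animal observed at one timestamp."""

    pen_id: str
    animal_id: str
    day: int
    t: float  # seconds since 00:00 of `day`
    posture: str
    shoulder: tuple[float, float]
    rump: tuple[float, float]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t}")
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")

    def as_row(self) -> dict:
        return {
            "pen_id": self.pen_id,
            "animal_id": self.animal_id,
            "day": self.day,
            "t": self.t,
            "posture": self.posture,
            "shoulder_x": self.shoulder[0],
            "shoulder_y": self.shoulder[1],
            "rump_x": self.rump[0],
            "rump_y": self.rump[1],
        }


@dataclass(frozen=True)
class PenRoster:
    """The animals housed in one pen and the pen's footprint in metres."""

    pen_id: str
    animal_ids: tuple[str, ...]
    pen_dimensions: tuple[float, float] = (6.0, 3.0)

    def __post_init__(self) -> None:
        if not self.animal_ids:
            raise ValueError("roster must contain at least one animal")
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal IDs in roster")
        w, h = self.pen_dimensions
        if w <= 0 or h <= 0:
            raise ValueError("pen dimensions must be positive")
        object.__setattr__(self, "animal_ids", tuple(str(a) for a in self.animal_ids))

    @property
    def n(self) -> int:
        return len(self.animal_ids)


def _parse_clock(value) -> float:
    """'HH:MM[:SS]' or a number -> seconds since midnight."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = [int(p) for p in str(value).split(":")]
    while len(parts) < 3:
        parts.append(0)
    h, m, s = parts[:3]
    return float(h * 3600 + m * 60 + s)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the proximity-network pipeline.

    Defaults follow the study protocol: 0.5 m shoulder-to-shoulder
    proximity between standing animals inside the 06:00-18:00 window,
    three observation days per growing period.
    """

    proximity_distance_m: float = 0.5
    window_start: float = 6 * 3600.0  # seconds since midnight
    window_end: float = 18 * 3600.0
    days_per_period: int = 3
    posture_filter: frozenset = frozenset({"standing"})
    gap_tolerance_s: float = 10.0
    sampling_interval_s: float = 5.0
    min_clique_size: int = 2
    mantel_permutations: int = 999
    coordinate_tolerance_m: float = 0.2
    mean_bout_mode: str = "pooled"  # or "per_dyad"
    closeness_mode: str = "standard"  # or "strength"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.window_start = _parse_clock(self.window_start)
        self.window_end = _parse_clock(self.window_end)
        self.posture_filter = frozenset(self.posture_filter)
        if self.proximity_distance_m <= 0:
            raise ValueError("proximity_distance_m must be positive")
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.days_per_period < 1:
            raise ValueError("days_per_period must be >= 1")
        if self.mantel_permutations < 99:
            raise ValueError("mantel_permutations must be >= 99")
        bad = self.posture_filter - set(POSTURES)
        if bad:
            raise ValueError(f"unknown postures in filter: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["posture_filter"] = sorted(self.posture_filter)
        return d


def records_to_frame(records: Iterable[TrackingRecord]) -> pd.DataFrame:
    """Materialize a sequence of TrackingRecord into the canonical frame."""
    rows = [r.as_row() for r in records]
    if not rows:
        return pd.DataFrame(columns=list(TRACKING_COLUMNS))
    return pd.DataFrame(rows, columns=list(TRACKING_COLUMNS))


def _validate_frame(df: pd.DataFrame, roster: PenRoster | None, tol: float) -> pd.DataFrame:
    """Shared validation: postures, coordinates, bounds, unknown animals.

    Row numbers in error messages are 1-based data rows (header = line 1,
    first data row = line 2), matching what a user sees in the CSV.
    """
    bad_posture = ~df["posture"].isin(POSTURES)
    if bad_posture.any():
        lines = [int(i) + 2 for i in df.index[bad_posture][:10]]
        raise ValueError(
            f"invalid posture label(s) at line(s) {lines}: "
            f"{sorted(df.loc[bad_posture, 'posture'].unique())}"
        )
    coord_cols = ["shoulder_x", "shoulder_y", "rump_x", "rump_y"]
    coords = df[coord_cols].apply(pd.to_numeric, errors="coerce")
    bad_coord = coords.isna().any(axis=1)
    if bad_coord.any():
        lines = [int(i) + 2 for i in df.index[bad_coord][:10]]
        raise ValueError(f"non-numeric or non-finite coordinate at line(s) {lines}")
    df[coord_cols] = coords
    if not np.isfinite(df[coord_cols].to_numpy(dtype=float)).all():
        raise ValueError("non-finite coordinate values present")
    if (df["t"] < 0).any():
        lines = [int(i) + 2 for i in df.index[df["t"] < 0][:10]]
        raise ValueError(f"negative timestamp at line(s) {lines}")

    if roster is not None:
        unknown = ~df["animal_id"].isin(roster.animal_ids)
        if unknown.any():
            ids = sorted(df.loc[unknown, "animal_id"].unique())
            warnings.warn(
                f"dropping {int(unknown.sum())} records for animal IDs not in "
                f"roster {roster.pen_id}: {ids}",
                stacklevel=3,
            )
            df = df[~unknown].copy()
        w, h = roster.pen_dimensions
        for cols, hi in ((["shoulder_x", "rump_x"], w), (["shoulder_y", "rump_y"], h)):
            for c in cols:
                out = (df[c] < -tol) | (df[c] > hi + tol)
                if out.any():
                    lines = [int(i) + 2 for i in df.index[out][:10]]
                    raise ValueError(
                        f"coordinate {c} outside pen bounds by more than "
                        f"{tol} m at line(s) {lines}"
                    )
                clamped = df[c].clip(0.0, hi)
                n_clamped = int((clamped != df[c]).sum())
                if n_clamped:
                    logger.info("clamped %d out-of-pen values in %s", n_clamped, c)
                df[c] = clamped
    return df


def read_tracking(path, roster: PenRoster | None = None,
                  coordinate_tolerance_m: float = 0.2) -> pd.DataFrame:
    """Read a tracking CSV, validate it, and return records sorted by (animal, t).

    Unknown animal IDs (when a roster is given) are dropped with a warning;
    malformed rows raise ``ValueError`` naming the offending line numbers.
    Coordinates up to ``coordinate_tolerance_m`` outside the pen are clamped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"pen_id": str, "animal_id": str, "posture": str},
                     float_precision="round_trip")
    missing = set(TRACKING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    df = df[list(TRACKING_COLUMNS)]
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    df["t"] = pd.to_numeric(df["t"], errors="raise").astype(float)
    df = _validate_frame(df, roster, coordinate_tolerance_m)
    return df.sort_values(["animal_id", "day", "t"], kind="mergesort").reset_index(drop=True)


def write_tracking(records, path) -> Path:
    """Write records (DataFrame or TrackingRecord sequence) as CSV.

    Deterministic column order; floats use the shortest round-tripping
    representation, so write -> read -> write is byte-identical.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    else:
        missing = set(TRACKING_COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"records missing column(s) {sorted(missing)}")
        records = records[list(TRACKING_COLUMNS)]
    path = Path(path)
    records.to_csv(path, index=False)
    return path


def filter_window(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Keep records whose posture is allowed and whose clock time is in-window.

    The observation window is half-open: ``window_start <= t < window_end``
    (seconds since midnight of the record's day).  Row order is preserved,
    so the operation is idempotent and its output a subset of its input.
    """
    mask = (
        records["posture"].isin(config.posture_filter)
        & (records["t"] >= config.window_start)
        & (records["t"] < config.window_end)
    )
    return records[mask].copy()
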