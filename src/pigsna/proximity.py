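"""Proximity-bout detection and contact-network construction.

An interaction is defined spatially and temporally: two standing animals are
"in proximity" whenever their shoulders are within 0.5 m (Euclidean), and a
bout only contributes to the network if it is sustained for longer than the
average bout duration of its pen-day.  Daily networks are undirected and
weighted by the summed seconds of qualifying proximity per dyad.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .tracking_io import AnalysisConfig, PenRoster

BOUT_COLUMNS = ("pen_id", "day", "animal_a", "animal_b", "start_s", "end_s", "duration_s")


@dataclass(frozen=True)
class ProximityBout:
    pen_id: str
    day: int
    dyad: frozenset
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self) -> None:
        if len(self.dyad) != 2:
            raise ValueError("dyad must contain two distinct animals")
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive duration")


@dataclass
class ContactNetwork:
    """One pen-day weighted undirected proximity network over the full roster."""

    pen_id: str
    day: int
    period: str
    graph: nx.Graph
    roster: PenRoster

    def __post_init__(self) -> None:
        missing = set(self.roster.animal_ids) - set(self.graph.nodes)
        if missing:
            raise ValueError(f"roster animals missing from graph: {sorted(missing)}")

    @property
    def n(self) -> int:
        return self.roster.n

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.roster.animal_ids

    def weight_matrix(self) -> pd.DataFrame:
        order = list(self.roster.animal_ids)
        m = nx.to_pandas_adjacency(self.graph, nodelist=order, weight="weight")
        return m

    def binarized(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.roster.animal_ids)
        g.add_edges_from(
            (u, v) for u, v, d in self.graph.edges(data=True) if d.get("weight", 0) > 0
        )
        return g

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def _pair_samples(ta, pa, tb, pb, tol):
    """Nearest-sample pairing of two animals' time series within ``tol`` s.

    Returns common times (from animal a's clock) and the paired positions.
    """
    if len(ta) == 0 or len(tb) == 0:
        return np.empty(0), np.empty((0, 2)), np.empty((0, 2))
    idx = np.searchsorted(tb, ta)
    idx_lo = np.clip(idx - 1, 0, len(tb) - 1)
    idx_hi = np.clip(idx, 0, len(tb) - 1)
    d_lo = np.abs(ta - tb[idx_lo])
    d_hi = np.abs(ta - tb[idx_hi])
    nearest = np.where(d_lo <= d_hi, idx_lo, idx_hi)
    dist = np.minimum(d_lo, d_hi)
    ok = dist <= tol
    return ta[ok], pa[ok], pb[nearest[ok]]


def _runs_to_bouts(times: np.ndarray, qualify: np.ndarray, gap_tolerance_s: float):
    """Split qualifying common samples into bouts.

    A non-qualifying common sample always ends a bout; a missing-data gap
    (no common sample in between) is bridged when it is <= gap_tolerance_s.
    Zero-length bouts (single isolated samples) are discarded.
    """
    bouts = []
    start = prev_t = prev_k = None
    for k in np.flatnonzero(qualify):
        t = times[k]
        if start is None:
            start = t
        else:
            # contiguous iff no failing common sample intervenes and the
            # time gap (missing samples only) is within tolerance
            contiguous = (k == prev_k + 1) and (t - prev_t <= gap_tolerance_s)
            if not contiguous:
                if prev_t > start:
                    bouts.append((start, prev_t))
                start = t
        prev_t, prev_k = t, k
    if start is not None and prev_t > start:
        bouts.append((start, prev_t))
    return bouts


def detect_bouts(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Find all raw proximity bouts in (already filtered) records of one pen.

    For each dyad, samples of the two animals are paired by nearest timestamp
    (within half a sampling interval); a bout is a maximal interval over which
    the shoulder-shoulder distance is <= ``proximity_distance_m`` at every
    common sample, with dropout gaps up to ``gap_tolerance_s`` bridged.
    Duration runs from the first to the last qualifying sample.
    """
    pens = records["pen_id"].unique()
    if len(pens) > 1:
        raise ValueError(f"records mix multiple pens: {sorted(pens)}")
    rows = []
    if len(records) == 0:
        return pd.DataFrame(columns=list(BOUT_COLUMNS))
    pen = pens[0]
    tol = config.sampling_interval_s / 2.0
    for day, day_df in records.groupby("day"):
        series = {}
        for animal, adf in day_df.groupby("animal_id"):
            t = adf["t"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"timestamps not strictly increasing for {animal}")
            series[animal] = (t, adf[["shoulder_x", "shoulder_y"]].to_numpy(dtype=float))
        for a, b in itertools.combinations(sorted(series), 2):
            ta, pa = series[a]
            tb, pb = series[b]
            tc, xa, xb = _pair_samples(ta, pa, tb, pb, tol)
            if len(tc) == 0:
                continue
            dist = np.hypot(xa[:, 0] - xb[:, 0], xa[:, 1] - xb[:, 1])
            qualify = dist <= config.proximity_distance_m
            for s, e in _runs_to_bouts(tc, qualify, config.gap_tolerance_s):
                rows.append((pen, day, a, b, s, e, e - s))
    out = pd.DataFrame(rows, columns=list(BOUT_COLUMNS))
    return out.sort_values(["day", "animal_a", "animal_b", "start_s"]).reset_index(drop=True)


def mean_bout_duration(bouts: pd.DataFrame, mode: str = "pooled") -> float:
    """Average raw-bout duration of one pen-day — the qualifying threshold.

    ``pooled`` (default) averages over all bouts of the pen-day; ``per_dyad``
    first averages within each dyad, then across dyads.  With no bouts the
    threshold is 0 (everything qualifies).
    """
    if len(bouts) == 0:
        return 0.0
    if len(bouts["day"].unique()) > 1 or len(bouts["pen_id"].unique()) > 1:
        raise ValueError("mean_bout_duration expects bouts of a single pen-day")
    if mode == "pooled":
        return float(bouts["duration_s"].mean())
    if mode == "per_dyad":
        return float(bouts.groupby(["animal_a", "animal_b"])["duration_s"].mean().mean())
    raise ValueError(f"unknown mean_bout_mode {mode!r}")


def qualify_bouts(bouts: pd.DataFrame, threshold_s: float) -> pd.DataFrame:
    """Keep bouts sustained strictly longer than ``threshold_s``."""
    if threshold_s < 0:
        raise ValueError("threshold must be non-negative")
    return bouts[bouts["duration_s"] > threshold_s].reset_index(drop=True)


def build_network(
    bouts: pd.DataFrame, roster: PenRoster, day: int, period: str = ""
) -> ContactNetwork:
    """Sum qualifying bout durations into a weighted pen-day network.

    Every roster animal is a node even if isolated; edge weights are seconds.
    """
    g = nx.Graph(pen_id=roster.pen_id, day=int(day), period=period)
    g.add_nodes_from(roster.animal_ids)
    known = set(roster.animal_ids)
    for row in bouts.itertuples(index=False):
        if row.animal_a not in known or row.animal_b not in known:
            raise ValueError(
                f"bout references animal(s) outside roster: {row.animal_a}, {row.animal_b}"
            )
        if g.has_edge(row.animal_a, row.animal_b):
            g[row.animal_a][row.animal_b]["weight"] += float(row.duration_s)
        else:
            g.add_edge(row.animal_a, row.animal_b, weight=float(row.duration_s))
    return ContactNetwork(roster.pen_id, int(day), period, g, roster)


def daily_networks(
    records: pd.DataFrame,
    roster: PenRoster,
    config: AnalysisConfig,
    period: str = "",
) -> tuple[dict[int, ContactNetwork], pd.DataFrame, pd.DataFrame]:
    """Full per-day pipeline: detect -> threshold by pen-day mean -> build.

    ``records`` must already be window/posture filtered.  Returns the
    per-day networks plus the raw and qualifying bout tables.
    """
    raw = detect_bouts(records, config)
    nets: dict[int, ContactNetwork] = {}
    qual_frames = []
    days = sorted(records["day"].unique())
    for day in days:
        day_bouts = raw[raw["day"] == day]
        thr = mean_bout_duration(day_bouts, config.mean_bout_mode) if len(day_bouts) else 0.0
        q = qualify_bouts(day_bouts, thr)
        qual_frames.append(q)
        nets[int(day)] = build_network(q, roster, int(day), period)
    qual = (
        pd.concat(qual_frames, ignore_index=True)
        if qual_frames
        else pd.DataFrame(columns=list(BOUT_COLUMNS))
    )
    return nets, raw, qual
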