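"""Larval swim-track metrics and distribution-free group comparison.

Tracks are timestamped 2-D point series digitized from 1-minute video
recordings against a 1 x 1 cm grid. Per-fish metrics are the total distance
travelled (cm) and the time spent in the upper half of the tank (s); groups
are compared with the two-sample Kolmogorov-Smirnov test, which makes no
assumption about the shape of the metric distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special


@dataclass
class TrackSeries:
    """One fish's track: strictly increasing times, points in tank bounds."""

    fish_id: str
    group: str
    t: np.ndarray               # seconds
    x: np.ndarray               # raw units (e.g. pixels)
    y: np.ndarray               # raw units, larger = higher in the tank
    scale: float = 1.0          # cm per raw unit
    tank_height: float | None = None   # raw units
    boundary: float | None = None      # raw units; default half tank height
    duration: float = 60.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) == 0:
            raise ValueError("track must contain at least one point")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("track times must be strictly increasing")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.boundary is None and self.tank_height is not None:
            self.boundary = self.tank_height / 2.0


def track_distance(track: TrackSeries) -> float:
    """Total path length in cm: summed Euclidean steps times the scale."""
    if len(track.t) < 2:
        return 0.0
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    return float(np.sum(np.hypot(dx, dy)) * track.scale)


def time_upper_half(track: TrackSeries) -> float:
    """Seconds spent above the half-height line, out of the recording.

    Each inter-sample interval is attributed to the half occupied at its
    starting point (no interpolation at boundary crossings). The total never
    exceeds the recording duration.
    """
    if track.boundary is None:
        raise ValueError("track needs a boundary (or tank_height) to classify")
    if len(track.t) < 2:
        return 0.0
    dt = np.diff(track.t)
    above = track.y[:-1] > track.boundary
    return float(min(np.sum(dt[above]), track.duration))


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """D = sup |Fx - Fy|, evaluating both ECDFs at all pooled points."""
    pooled = np.concatenate([x, y])
    pooled.sort(kind="mergesort")
    fx = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
    fy = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))


def ks_two_sample(x, y, mode: str = "auto") -> tuple:
    """Two-sample Kolmogorov-Smirnov test, returning (D, p).

    ``exact`` enumerates all assignments of the pooled values to the two
    groups (feasible for n1 + n2 <= 12); ``asymptotic`` evaluates the
    Kolmogorov limiting distribution at sqrt(n1*n2/(n1+n2)) * D; ``auto``
    picks exact when the enumeration is feasible. The exact p is the tail probability P(D* >= D) under the null
    that both samples come from one distribution (permutation distribution,
    ties handled naturally through the pooled values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    d = _ks_statistic(x, y)
    n1, n2 = len(x), len(y)
    if mode == "auto":
        mode = "exact" if n1 + n2 <= 12 else "asymptotic"
    if mode == "exact":
        if n1 + n2 > 12:
            raise ValueError("exact enumeration limited to n1+n2 <= 12")
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        count = 0
        total = 0
        for pick in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            d_perm = _ks_statistic(pooled[mask], pooled[~mask])
            count += d_perm >= d - 1e-12
            total += 1
        return d, count / total
    if mode == "asymptotic":
        en = n1 * n2 / (n1 + n2)
        p = float(special.kolmogorov(math.sqrt(en) * d))
        return d, min(max(p, 0.0), 1.0)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    mean: float
    sd: float
    min: float
    max: float
    sd_defined: bool = True


def summarize(groups: dict) -> pd.DataFrame:
    """Per-group summary (median, mean, sample SD, range) plus boxplot data.

    ``groups`` maps a group label to its per-fish metric values. A group of
    one has no sample SD; it is reported as 0 with ``sd_defined=False``.
    """
    rows = []
    for label, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if len(v) == 0:
            raise ValueError(f"group {label!r} is empty")
        sd_defined = len(v) > 1
        rows.append(GroupSummary(
            group=label, n=len(v), median=float(np.median(v)),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)) if sd_defined else 0.0,
            min=float(np.min(v)), max=float(np.max(v)),
            sd_defined=sd_defined))
    return pd.DataFrame([r.__dict__ for r in rows])


def read_tracks_csv(path, scale: float = 1.0, tank_height: float | None = None,
                    duration: float = 60.0) -> list:
    """Read tracks from CSV with columns fish_id, group, t, x, y."""
    df = pd.read_csv(path)
    tracks = []
    for (fid, grp), sub in df.groupby(["fish_id", "group"], sort=False):
        sub = sub.sort_values("t")
        tracks.append(TrackSeries(
            fish_id=str(fid), group=str(grp),
            t=sub["t"].to_numpy(), x=sub["x"].to_numpy(),
            y=sub["y"].to_numpy(), scale=scale,
            tank_height=tank_height, duration=duration))
    return tracks
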