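"""Open-field, freezing, and habituation/dishabituation behavioral metrics.

Covers the three behavioral assays around the imaging experiments:

* open-field avoidance — dwell time in each of the 9 arena zones and mean
  distance from each odor corner over a 5-min session;
* freezing tests — percent immobility over the scored 90-s window of each
  120-s odor session (the first 30 s are excluded as acclimation), plus the
  >= 5-point CS+-specificity exclusion rule applied before imaging;
* habituation/dishabituation — per-trial investigation times across the
  14-trial sequence (mineral oil + 4 x 3 odors + return to the first odor)
  and the T4-vs-odor-switch dishabituation contrasts.

Dwell accrual is left-Riemann: each inter-sample interval is assigned to
the zone (or position) of its *starting* sample, so the final sample
carries no weight.  All zone math is invariant to rescaling the arena
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arena as _arena
from ._exceptions import ValidationError


@dataclass
class Trajectory:
    """Timestamped arena centroid path."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena: tuple[float, float] = _arena.DEFAULT_ARENA
    corner_odors: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_arena.DEFAULT_CORNER_ODORS))

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if len(self.t) < 1:
            raise ValidationError("empty trajectory")
        bad = np.nonzero(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"time must be strictly increasing; violations after rows {bad.tolist()[:20]}"
            )
        w, h = self.arena
        oob = np.nonzero((self.x < 0) | (self.x > w) | (self.y < 0) | (self.y > h))[0]
        if oob.size:
            raise ValidationError(f"out-of-bounds samples at indices {oob.tolist()[:20]}")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def zones(self) -> np.ndarray:
        return _arena.zone_index(self.x, self.y, self.arena)

    def speed(self) -> np.ndarray:
        """Per-interval centroid speed (length n-1)."""
        dt = np.diff(self.t)
        return np.hypot(np.diff(self.x), np.diff(self.y)) / dt


@dataclass
class ZoneOccupancy:
    """Dwell time per each of the 9 zones of the 3x3 arena partition."""

    dwell_s: np.ndarray  # (9,)
    labels: list[str]

    def __post_init__(self):
        self.dwell_s = np.asarray(self.dwell_s, dtype=float)
        if self.dwell_s.shape != (9,):
            raise ValidationError("dwell_s must have 9 entries")

    @property
    def total_s(self) -> float:
        return float(self.dwell_s.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.dwell_s / self.total_s

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, index=self.labels, name="fraction")


def time_in_zones(traj: Trajectory) -> ZoneOccupancy:
    """Per-zone dwell times; each inter-sample interval accrues to the zone
    of its starting sample."""
    if len(traj.t) < 2:
        raise ValidationError("need at least two samples to accrue dwell time")
    zones = traj.zones()[:-1]
    dt = np.diff(traj.t)
    dwell = np.bincount(zones, weights=dt, minlength=9)
    return ZoneOccupancy(dwell_s=dwell, labels=_arena.zone_labels(traj.corner_odors))


def mean_corner_distance(traj: Trajectory) -> pd.Series:
    """Time-weighted mean Euclidean distance from each of the four corners,
    keyed by the odor assigned to that corner."""
    if len(traj.t) < 2:
        raise ValidationError("need at least two samples")
    dt = np.diff(traj.t)
    w = dt / dt.sum()
    out = {}
    for odor, frac in traj.corner_odors.items():
        cx, cy = _arena.corner_position(frac, traj.arena)
        d = np.hypot(traj.x[:-1] - cx, traj.y[:-1] - cy)
        out[odor] = float((d * w).sum())
    return pd.Series(out, name="mean_distance")


def zone_time_difference_map(conditioned: ZoneOccupancy,
                             control: ZoneOccupancy) -> np.ndarray:
    """Per-zone difference in percent time (conditioned − control)."""
    if conditioned.labels != control.labels:
        raise ValidationError("occupancy vectors are on mismatched zone partitions")
    return 100.0 * (conditioned.fractions - control.fractions)


# ---------------------------------------------------------------------------
# freezing


@dataclass
class FreezingRecord:
    """Per-odor immobility percentage over the scored 90-s window."""

    immobility_pct: dict[str, float]

    def __post_init__(self):
        for odor, v in self.immobility_pct.items():
            if not 0 <= v <= 100:
                raise ValidationError(f"immobility % out of [0, 100] for {odor}: {v}")


SESSION_S = 120.0
EXCLUDED_S = 30.0  # acclimation period dropped from scoring


def immobility_percent(sessions: dict[str, pd.DataFrame],
                       speed_threshold: float = 2.0,
                       min_still_duration: float = 1.0) -> FreezingRecord:
    """Percent immobile time in the final 90 s of each 120-s odor session.

    Each session table needs a ``time_s`` column plus either ``speed`` or
    ``x``/``y`` (speed is then computed from the centroid path).  Immobility
    is operationalized as bouts with speed < `speed_threshold`
    (length-units/s) sustained for at least `min_still_duration` seconds;
    bouts are detected over the whole session and intersected with the
    scored window, so stillness beginning during the excluded 30 s still
    counts once the window opens.
    """
    if speed_threshold <= 0 or min_still_duration <= 0:
        raise ValidationError("thresholds must be > 0")
    out = {}
    for odor, df in sessions.items():
        if "time_s" not in df.columns:
            raise ValidationError(f"session {odor}: missing time_s column")
        t = df["time_s"].to_numpy(dtype=float)
        if t[-1] - t[0] < SESSION_S:
            raise ValidationError(
                f"session {odor} shorter than {SESSION_S} s ({t[-1] - t[0]:.1f} s)")
        if "speed" in df.columns:
            speed = df["speed"].to_numpy(dtype=float)[:-1]
        elif {"x", "y"} <= set(df.columns):
            dt = np.diff(t)
            speed = np.hypot(np.diff(df["x"].to_numpy(float)),
                             np.diff(df["y"].to_numpy(float))) / dt
        else:
            raise ValidationError(f"session {odor}: need speed or x/y columns")
        still = speed < speed_threshold
        win_lo, win_hi = t[0] + EXCLUDED_S, t[0] + SESSION_S
        immobile = 0.0
        i = 0
        n = len(still)
        while i < n:
            if not still[i]:
                i += 1
                continue
            j = i
            while j < n and still[j]:
                j += 1
            bout_lo, bout_hi = t[i], t[j]  # interval [t_i, t_j) is still
            if bout_hi - bout_lo >= min_still_duration:
                immobile += max(0.0, min(bout_hi, win_hi) - max(bout_lo, win_lo))
            i = j
        out[odor] = 100.0 * immobile / (win_hi - win_lo)
    return FreezingRecord(immobility_pct=out)


def exclusion_check(record: FreezingRecord, cs_plus_odor: str = "MV",
                    min_difference: float = 5.0) -> bool:
    """Retention rule for fear-conditioned animals entering imaging.

    Retained iff CS+ immobility exceeds the *highest* other-odor immobility
    by at least `min_difference` percentage points (boundary inclusive:
    exactly 5.0 retains).
    """
    if cs_plus_odor not in record.immobility_pct:
        raise ValidationError(f"record has no CS+ odor {cs_plus_odor!r}")
    others = [v for o, v in record.immobility_pct.items() if o != cs_plus_odor]
    if not others:
        raise ValidationError("record needs at least one non-CS+ odor")
    return record.immobility_pct[cs_plus_odor] - max(others) >= min_difference


# ---------------------------------------------------------------------------
# habituation / dishabituation


@dataclass
class InvestigationSeries:
    """Investigation time (s) per trial of the 14-trial habituation sequence:
    1 mineral-oil trial, then 4 trials each of three odors, then a final
    return to the first odor."""

    times_s: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.shape != (14,):
            raise ValidationError(
                f"series must have 14 entries, got {self.times_s.shape}")
        if ((self.times_s < 0) | (self.times_s > 50)).any():
            raise ValidationError("investigation times must lie in [0, 50] s")


def habituation_summary(series: InvestigationSeries,
                        odor_order: tuple[str, str, str]) -> pd.DataFrame:
    """Trial-type table plus dishabituation (T4 vs switch) contrasts.

    Returns one row per trial with columns trial (0-based), odor,
    position (habituation position 1–4 within the odor; 0 for mineral oil
    and the final return trial), is_switch, investigation_s, and
    dishabituation_delta (switch-trial investigation minus the preceding
    T4; NaN elsewhere).  Positive deltas indicate dishabituation.
    """
    if len(set(odor_order)) != 3:
        raise ValidationError("odor_order must name three distinct odors")
    v = series.times_s
    rows = []
    rows.append({"trial": 0, "odor": "MO", "position": 0, "is_switch": False,
                 "investigation_s": v[0], "dishabituation_delta": np.nan})
    for block, odor in enumerate(odor_order):
        for pos in range(1, 5):
            idx = 1 + block * 4 + (pos - 1)
            is_switch = pos == 1 and block > 0
            delta = v[idx] - v[idx - 1] if is_switch else np.nan
            rows.append({"trial": idx, "odor": odor, "position": pos,
                         "is_switch": is_switch, "investigation_s": v[idx],
                         "dishabituation_delta": delta})
    rows.append({"trial": 13, "odor": odor_order[0], "position": 0,
                 "is_switch": True, "investigation_s": v[13],
                 "dishabituation_delta": v[13] - v[12]})
    return pd.DataFrame(rows)
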