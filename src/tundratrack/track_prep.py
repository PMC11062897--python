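"""Telemetry cleaning and seasonal phase segmentation.

Raw Argos fixes are cleaned with a forward-sweep speed filter (cruising
threshold 5 km/h, with burst allowance of 10 km/h for fixes less than
10 min apart), reduced to the best fix per day (smallest nominal error
class, ties to the earliest fix), segmented into summer residency / fall
relocation / winter residency from rolling daily movement rates, and
regularized to exactly one location per day by linear interpolation within
the relocation interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ARGOS_ERROR_RADII

__all__ = [
    "PhaseLabels",
    "speed_filter",
    "best_daily_fix",
    "segment_phases",
    "regularize_daily",
    "prep_individual",
]

#: Smaller is better: class 3 (250 m) beats 2 (500 m) beats 1/A (1500 m,
#: with A carrying no accuracy estimate and ranked last).
CLASS_PRIORITY = {"3": 0, "2": 1, "1": 2, "A": 3}


@dataclass
class PhaseLabels:
    """Per-individual date intervals (inclusive) of the annual phases.

    Intervals are ordered summer < relocation < winter; any may be absent
    (residents have only a summer interval).
    """

    individual_id: str
    summer: tuple[pd.Timestamp, pd.Timestamp] | None = None
    relocation: tuple[pd.Timestamp, pd.Timestamp] | None = None
    winter: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        present = [iv for iv in (self.summer, self.relocation, self.winter)
                   if iv is not None]
        for a, b in present:
            if a > b:
                raise ValueError("interval start after end")
        for (_, e), (s, _) in zip(present, present[1:]):
            if e >= s:
                raise ValueError("phase intervals must be ordered and "
                                 "non-overlapping")

    @property
    def is_resident(self) -> bool:
        return self.relocation is None


def _require_single_individual(traj: pd.DataFrame) -> None:
    if traj["individual_id"].nunique() > 1:
        raise ValueError("one individual per trajectory")


def speed_filter(traj: pd.DataFrame, v_cruise: float = 5.0,
                 v_burst: float = 10.0, burst_gap_min: float = 10.0
                 ) -> pd.DataFrame:
    """Forward-sweep speed filter.

    Starting from the first fix, a fix is removed when the straight-line
    speed from the last *retained* fix exceeds ``v_cruise`` km/h, unless the
    time gap is shorter than ``burst_gap_min`` minutes and the speed does
    not exceed ``v_burst`` km/h (acceleration bouts). Idempotent.
    """
    _require_single_individual(traj)
    traj = traj.sort_values("timestamp").reset_index(drop=True)
    if len(traj) <= 1:
        return traj
    t = traj["timestamp"].to_numpy()
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    keep = [0]
    for i in range(1, len(traj)):
        j = keep[-1]
        dt_h = (t[i] - t[j]) / np.timedelta64(1, "h")
        if dt_h <= 0:
            continue
        speed = np.hypot(x[i] - x[j], y[i] - y[j]) / 1000.0 / dt_h
        ok = speed <= v_cruise or (
            dt_h * 60.0 < burst_gap_min and speed <= v_burst)
        if ok:
            keep.append(i)
    return traj.iloc[keep].reset_index(drop=True)


def best_daily_fix(traj: pd.DataFrame) -> pd.DataFrame:
    """Keep one fix per calendar day: smallest nominal error class
    (3 > 2 > 1 > A), ties broken by earliest timestamp."""
    _require_single_individual(traj)
    traj = traj.sort_values("timestamp").reset_index(drop=True)
    prio = traj["argos_class"].map(CLASS_PRIORITY)
    if prio.isna().any():
        bad = sorted(traj.loc[prio.isna(), "argos_class"].unique())
        raise ValueError(f"unknown Argos classes {bad}")
    day = traj["timestamp"].dt.normalize()
    order = np.lexsort((traj["timestamp"].to_numpy(), prio.to_numpy()))
    ranked = traj.iloc[order]
    out = ranked.loc[~day.iloc[order].duplicated()].sort_values("timestamp")
    return out.reset_index(drop=True)


def segment_phases(traj: pd.DataFrame, rate_window: int = 5,
                   rate_threshold_km: float = 2.0,
                   merge_gap: int = 45) -> PhaseLabels:
    """Label summer / relocation / winter from daily movement rates.

    The relocation interval is the maximal contiguous run of days whose
    centered rolling mean (window ``rate_window`` days) of net daily
    displacement exceeds ``rate_threshold_km`` km/day; summer precedes it,
    winter follows. Individuals with no super-threshold run are residents.

    Relocating animals pause for days at stopovers, which drags the rolling
    rate below threshold mid-relocation; super-threshold runs separated by
    sub-threshold gaps of at most ``merge_gap`` days are therefore merged
    before taking the maximal run (``merge_gap=0`` disables merging).
    """
    _require_single_individual(traj)
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    traj = traj.sort_values("timestamp").reset_index(drop=True)
    ind = str(traj["individual_id"].iloc[0])
    days = traj["timestamp"].dt.normalize()
    first, last = days.iloc[0], days.iloc[-1]
    if len(traj) < rate_window:
        warnings.warn(f"{ind}: trajectory shorter than the rate window; "
                      "treated as a single (summer) phase")
        return PhaseLabels(ind, summer=(first, last))
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    dt_d = days.diff().dt.days.to_numpy(dtype=float)[1:]
    rate = np.hypot(np.diff(x), np.diff(y)) / 1000.0 / np.maximum(dt_d, 1.0)
    roll = (pd.Series(rate)
            .rolling(rate_window, center=True, min_periods=1).mean()
            .to_numpy())
    above = roll > rate_threshold_km
    if not above.any():
        return PhaseLabels(ind, summer=(first, last))
    # contiguous runs of True
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs whose gap (in calendar days) is short enough to be a
    # stopover pause rather than a return to residency
    merged = [runs[0]]
    for s0, s1 in runs[1:]:
        p0, p1 = merged[-1]
        gap_days = (days.iloc[s0] - days.iloc[p1]).days
        if gap_days <= merge_gap:
            merged[-1] = (p0, s1)
        else:
            merged.append((s0, s1))
    i0, i1 = max(merged, key=lambda r: r[1] - r[0])
    # rate k belongs to the move from fix k to fix k+1
    r_start, r_end = days.iloc[i0], days.iloc[i1 + 1]
    summer = (first, days.iloc[max(i0 - 1, 0)]) if r_start > first else None
    winter = (days.iloc[min(i1 + 2, len(traj) - 1)], last) \
        if r_end < last else None
    if summer is not None and summer[1] >= r_start:
        summer = None if summer[0] >= r_start else (summer[0], r_start - pd.Timedelta(days=1))
    if winter is not None and winter[0] <= r_end:
        winter = None if winter[1] <= r_end else (r_end + pd.Timedelta(days=1), winter[1])
    return PhaseLabels(ind, summer=summer, relocation=(r_start, r_end),
                       winter=winter)


def regularize_daily(traj: pd.DataFrame,
                     interval: tuple[pd.Timestamp, pd.Timestamp]
                     ) -> tuple[pd.DataFrame, float]:
    """Regularize daily best fixes to exactly one location per day.

    Missing days inside ``interval`` are filled by linear interpolation
    between the flanking fixes; interpolated fixes are flagged, carry class
    'A' and its widest (1500 m) error radius. Days at either end of the
    interval without a flanking fix are truncated with a warning. Returns
    the regularized trajectory and the fraction of interpolated days.
    """
    _require_single_individual(traj)
    traj = traj.sort_values("timestamp").reset_index(drop=True)
    day = traj["timestamp"].dt.normalize()
    lo, hi = pd.Timestamp(interval[0]).normalize(), \
        pd.Timestamp(interval[1]).normalize()
    sel = traj[(day >= lo) & (day <= hi)].copy()
    if len(sel) == 0:
        raise ValueError("no fixes inside the interval")
    sel_day = sel["timestamp"].dt.normalize()
    if sel_day.iloc[0] > lo or sel_day.iloc[-1] < hi:
        warnings.warn("interval ends have no flanking fix; truncated to the "
                      "observed span")
        lo, hi = sel_day.iloc[0], sel_day.iloc[-1]
    full = pd.date_range(lo, hi, freq="D")
    sel = sel.set_index(sel_day)
    out = sel.reindex(full)
    missing = out["x"].isna()
    t_num = full.view("int64").astype(float)
    for col in ("x", "y"):
        out[col] = np.interp(t_num, t_num[~missing],
                             out.loc[~missing, col].to_numpy(dtype=float))
    out.loc[missing, "argos_class"] = "A"
    out.loc[missing, "error_radius"] = ARGOS_ERROR_RADII["A"]
    out["interpolated"] = out["interpolated"].astype(object)
    out.loc[missing, "interpolated"] = True
    out["interpolated"] = out["interpolated"].astype(bool)
    out["individual_id"] = str(traj["individual_id"].iloc[0])
    out.loc[missing, "timestamp"] = full[missing] + pd.Timedelta(hours=12)
    out = out.reset_index(drop=True)
    frac = float(missing.mean())
    return out, frac


def prep_individual(traj: pd.DataFrame, v_cruise: float = 5.0,
                    v_burst: float = 10.0, burst_gap_min: float = 10.0,
                    rate_window: int = 5, rate_threshold_km: float = 2.0,
                    merge_gap: int = 45):
    """Full cleaning chain for one individual: speed filter, best daily
    fix, phase segmentation, relocation regularization.

    Returns (daily trajectory, PhaseLabels, regularized relocation
    trajectory or None, log dict).
    """
    filt = speed_filter(traj, v_cruise, v_burst, burst_gap_min)
    daily = best_daily_fix(filt)
    phases = segment_phases(daily, rate_window, rate_threshold_km,
                            merge_gap)
    reloc, frac = (None, 0.0)
    if phases.relocation is not None:
        reloc, frac = regularize_daily(daily, phases.relocation)
    log = {
        "individual_id": phases.individual_id,
        "n_raw": len(traj),
        "n_removed_speed": len(traj) - len(filt),
        "n_daily": len(daily),
        "fraction_interpolated": frac,
        "resident": phases.is_resident,
    }
    return daily, phases, reloc, log
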