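"""Chronological lifespan (CLS) from outgrowth OD600 curves.

A non-dividing (stationary-phase) yeast culture is sampled on a grid of
aging days; each sample seeds a fresh outgrowth well whose OD600 is read
every 10 minutes for 12 hours.  The more viable cells the inoculum
contains, the earlier the subculture crosses a fixed OD threshold.  The
pipeline is:

1. subtract the plate background measured in cell-free blank wells;
2. quality-filter technical replicates by coefficient of variation (CV)
   of the OD at a reference timepoint (t = 50 min), averaging the kept
   curves;
3. estimate the doubling time ``delta_n = ln2 * (t2 - t1)/(ln X2 - ln X1)``
   over all ordered point pairs within the exponential OD window;
4. find ``t_n``, the first sampled time at which the t50-normalized OD
   reaches the threshold (0.3), extrapolating past the 12-h horizon with
   the doubling time when the culture never crosses;
5. convert to a survival fraction relative to the first aging day,
   ``S_n = 2^(-(t_n - t_2)/delta_2)``;
6. integrate survival over aging days with the trapezoid rule; this
   "survival integral" is the CLS.

Biological replicates are CV-filtered on their CLS values and averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClsConfig",
    "ReplicateFilterResult",
    "subtract_background",
    "cv_filter",
    "doubling_time",
    "time_to_threshold",
    "survival_fraction",
    "survival_integral",
    "estimate_cls",
]

BLANK_STRAIN = "BLANK"


@dataclass(frozen=True)
class ClsConfig:
    """Tunable constants of the outgrowth protocol.

    All times are in minutes.  ``od_window`` applies to background-
    corrected (not t50-normalized) OD values, the convention under which
    the doubling time is computed before the normalization step; set
    ``window_on_normalized`` to flip that convention.
    """

    threshold: float = 0.3
    t_ref: float = 50.0
    horizon: float = 720.0
    od_window: tuple[float, float] = (0.2, 0.5)
    dt_statistic: str = "min"
    cv_max: float = 0.2
    blank_strain: str = BLANK_STRAIN
    window_on_normalized: bool = False


@dataclass(frozen=True)
class ReplicateFilterResult:
    """Outcome of the CV <= threshold replicate filter."""

    kept: np.ndarray
    dropped: np.ndarray
    kept_idx: np.ndarray
    dropped_idx: np.ndarray
    reason: str  # all-kept | dropped-outlier | all-discarded


def _cv(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.mean(values))


def cv_filter(values, cv_max: float = 0.2) -> ReplicateFilterResult:
    """Trim replicate sets whose coefficient of variation exceeds ``cv_max``.

    If CV <= cv_max all values are kept.  Otherwise the value farthest
    from the mean of the others is dropped (ties: lowest index) and the
    set is retested; up to floor(k/3) values may be dropped — one retest
    for the standard three-replicate protocol — after which a still-
    failing set is discarded entirely.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 replicate values")
    if np.any(values <= 0):
        raise ValueError("replicate values must be positive")
    idx = np.arange(len(values))
    max_drops = len(values) // 3
    kept_idx = idx.copy()
    drops = 0
    while True:
        kept = values[kept_idx]
        if _cv(kept) <= cv_max:
            reason = "all-kept" if drops == 0 else "dropped-outlier"
            dropped_idx = np.setdiff1d(idx, kept_idx)
            return ReplicateFilterResult(
                kept, values[dropped_idx], kept_idx, dropped_idx, reason
            )
        if drops >= max_drops:
            return ReplicateFilterResult(
                np.array([]), values, np.array([], dtype=int), idx, "all-discarded"
            )
        # distance of each value from the mean of the remaining ones
        dists = np.array(
            [abs(v - np.mean(np.delete(kept, i))) for i, v in enumerate(kept)]
        )
        worst = int(np.argmax(dists))  # argmax takes the lowest index on ties
        kept_idx = np.delete(kept_idx, worst)
        drops += 1


def subtract_background(
    plate_df: pd.DataFrame, blank_strain: str = BLANK_STRAIN
) -> pd.DataFrame:
    """Subtract the per-timepoint mean OD of cell-free blank wells.

    Blank wells are rows with ``strain == blank_strain``.  If a ``plate``
    column is present the subtraction is per plate.  Negative corrected
    readings are retained.  Raises if a plate has no blanks or sample
    timepoints missing from the blank grid.
    """
    df = plate_df.copy()
    group_cols = ["plate"] if "plate" in df.columns else []
    out = []
    for _, grp in df.groupby(group_cols) if group_cols else [((), df)]:
        blanks = grp[grp["strain"] == blank_strain]
        if blanks.empty:
            raise ValueError("no blank wells found for background subtraction")
        bg = blanks.groupby("time_min")["od600"].mean()
        missing = set(grp["time_min"].unique()) - set(bg.index)
        if missing:
            raise ValueError(f"blank wells lack timepoints {sorted(missing)[:5]}")
        corrected = grp.copy()
        corrected["od600"] = grp["od600"].to_numpy() - bg.reindex(grp["time_min"]).to_numpy()
        out.append(corrected)
    return pd.concat(out, ignore_index=True)


_DT_STATS: dict[str, Callable[[np.ndarray], float]] = {
    "min": np.min,
    "mean": np.mean,
    "median": np.median,
}


def doubling_time(
    times,
    od,
    od_window: tuple[float, float] = (0.2, 0.5),
    statistic: str = "min",
) -> float:
    """Doubling time from all ordered in-window point pairs.

    For every pair (t1, X1), (t2, X2) with t1 < t2, both X inside
    ``od_window`` and X2 > X1, the pairwise doubling time
    ``ln2 * (t2 - t1)/(ln X2 - ln X1)`` is computed; the chosen statistic
    (min by default) reduces them.  Returns NaN when fewer than two
    in-window points or no increasing pair exists.
    """
    if statistic not in _DT_STATS:
        raise ValueError(f"statistic must be one of {sorted(_DT_STATS)}")
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    lo, hi = od_window
    mask = (od >= lo) & (od <= hi)
    t = times[mask]
    x = od[mask]
    if len(t) < 2:
        return math.nan
    dt = t[None, :] - t[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        dlnx = np.log(x)[None, :] - np.log(x)[:, None]
        pairs = math.log(2) * dt / dlnx
    valid = (dt > 0) & (dlnx > 0)
    if not valid.any():
        return math.nan
    return float(_DT_STATS[statistic](pairs[valid]))


def time_to_threshold(
    times,
    od,
    threshold: float = 0.3,
    t_ref: float = 50.0,
    horizon: float = 720.0,
    delta: float | None = None,
) -> float:
    """First sampled time at which t_ref-normalized OD reaches ``threshold``.

    The OD reading at ``t_ref`` is subtracted from the whole curve to
    control for inoculum-density differences between wells.  If the
    normalized curve never reaches the threshold within ``horizon``, the
    crossing time is extrapolated from the value X at the horizon as
    ``horizon + (ln threshold - ln X) * delta / ln 2``.  Returns NaN when
    extrapolation is needed but X <= 0 or ``delta`` is unavailable.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    ref = np.nonzero(times == t_ref)[0]
    if len(ref) == 0:
        raise ValueError(f"curve has no reading at t_ref={t_ref}")
    if not np.any(times == horizon):
        raise ValueError(f"curve has no reading at horizon={horizon}")
    norm = od - od[ref[0]]
    within = times <= horizon
    crossed = within & (norm >= threshold)
    if crossed.any():
        return float(times[crossed][0])
    x_h = float(norm[times == horizon][0])
    if x_h <= 0 or delta is None or math.isnan(delta):
        return math.nan
    return horizon + (math.log(threshold) - math.log(x_h)) * delta / math.log(2)


def survival_fraction(t_n: float, t_2: float, delta_2: float) -> float:
    """Fraction of surviving cells relative to the reference day,
    ``S_n = 2^(-(t_n - t_2)/delta_2)``."""
    if not delta_2 > 0:
        raise ValueError(f"delta_2 must be positive, got {delta_2}")
    return float(2.0 ** (-(t_n - t_2) / delta_2))


def survival_integral(days, survivals) -> float:
    """Trapezoid-rule area under the day-vs-survival curve (the CLS)."""
    days = np.asarray(days, dtype=float)
    survivals = np.asarray(survivals, dtype=float)
    if len(days) < 2:
        raise ValueError("need at least 2 aging days")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly ascending")
    return float(np.trapezoid(survivals, days))


def _bio_rep_cls(
    grp: pd.DataFrame, config: ClsConfig
) -> tuple[float, dict]:
    """CLS for one biological replicate; returns (cls, audit)."""
    audit: dict = {"flags": [], "days": {}}
    days = np.sort(grp["aging_day"].unique())
    day_curves: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for day in days:
        dgrp = grp[grp["aging_day"] == day]
        wide = dgrp.pivot_table(index="time_min", columns="tech_rep", values="od600")
        wide = wide.sort_index()
        at_ref = wide.loc[config.t_ref]
        values = at_ref.to_numpy(dtype=float)
        if len(values) >= 2:
            try:
                res = cv_filter(values, config.cv_max)
            except ValueError:
                audit["flags"].append(f"day{day}:cv-filter-error")
                continue
            if res.reason == "all-discarded":
                audit["flags"].append(f"day{day}:tech-all-discarded")
                continue
            kept_cols = wide.columns[res.kept_idx]
            audit["days"][day] = {"tech_kept": list(kept_cols), "reason": res.reason}
        else:
            kept_cols = wide.columns
            audit["days"][day] = {"tech_kept": list(kept_cols), "reason": "single-tech"}
            audit["flags"].append(f"day{day}:single-tech-rep")
        avg = wide[kept_cols].mean(axis=1)
        day_curves[day] = (avg.index.to_numpy(dtype=float), avg.to_numpy(dtype=float))

    ref_day = days[0]
    if ref_day not in day_curves:
        audit["flags"].append("reference-day-missing")
        return math.nan, audit

    deltas: dict[float, float] = {}
    for day, (t, x) in day_curves.items():
        win_x = x
        if config.window_on_normalized:
            win_x = x - x[t == config.t_ref][0]
        deltas[day] = doubling_time(t, win_x, config.od_window, config.dt_statistic)
    delta_2 = deltas.get(ref_day, math.nan)
    if math.isnan(delta_2):
        audit["flags"].append("no-reference-doubling-time")
        return math.nan, audit

    t_by_day: dict[float, float] = {}
    for day, (t, x) in day_curves.items():
        d = deltas[day]
        fallback = d if not math.isnan(d) else delta_2
        t_n = time_to_threshold(
            t, x, config.threshold, config.t_ref, config.horizon, fallback
        )
        if math.isnan(t_n):
            audit["flags"].append(f"day{day}:no-threshold-crossing")
            continue
        t_by_day[day] = t_n
    if ref_day not in t_by_day:
        audit["flags"].append("reference-day-no-crossing")
        return math.nan, audit

    used_days = sorted(t_by_day)
    surv = []
    for day in used_days:
        if day == ref_day:
            surv.append(1.0)
        else:
            s = survival_fraction(t_by_day[day], t_by_day[ref_day], delta_2)
            if s > 1:
                audit["flags"].append(f"day{day}:survival-above-1")
            surv.append(s)
    if len(used_days) < 2:
        audit["flags"].append("fewer-than-2-days")
        return math.nan, audit
    cls = survival_integral(used_days, surv)
    audit.update(
        {
            "delta_2": delta_2,
            "t_n": t_by_day,
            "survival": dict(zip(used_days, surv)),
            "cls": cls,
        }
    )
    return cls, audit


def estimate_cls(
    plate_df: pd.DataFrame, config: ClsConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-strain CLS from a long-format plate table.

    Expects columns strain, bio_rep, tech_rep, aging_day, time_min, od600
    (plus optional plate/well).  Background is subtracted when blank
    wells (strain == config.blank_strain) are present.  Returns a
    per-strain table (strain, cls_mean, cls_sd, n_bio_reps_kept, flags)
    and a nested audit dict with per-replicate detail.  Strains whose
    biological replicates all fail QC are omitted from the table but
    recorded in the audit.
    """
    config = config or ClsConfig()
    df = plate_df
    if (df["strain"] == config.blank_strain).any():
        df = subtract_background(df, config.blank_strain)
    df = df[df["strain"] != config.blank_strain]

    rows = []
    audit: dict = {}
    for strain, sgrp in df.groupby("strain", sort=True):
        strain_audit: dict = {}
        cls_values: list[float] = []
        bio_ids: list = []
        for bio, bgrp in sgrp.groupby("bio_rep", sort=True):
            cls, rep_audit = _bio_rep_cls(bgrp, config)
            strain_audit[bio] = rep_audit
            if not math.isnan(cls):
                cls_values.append(cls)
                bio_ids.append(bio)
        audit[strain] = strain_audit
        flags = []
        if not cls_values:
            audit[strain]["strain_flag"] = "all-bio-reps-failed"
            continue
        values = np.array(cls_values)
        if len(values) >= 2:
            try:
                res = cv_filter(values, config.cv_max)
            except ValueError:
                audit[strain]["strain_flag"] = "bio-cv-filter-error"
                continue
            if res.reason == "all-discarded":
                audit[strain]["strain_flag"] = "bio-all-discarded"
                continue
            kept = res.kept
            if res.reason == "dropped-outlier":
                flags.append("bio-rep-dropped")
        else:
            kept = values
            flags.append("single-bio-rep")
        rows.append(
            {
                "strain": strain,
                "cls_mean": float(np.mean(kept)),
                "cls_sd": float(np.std(kept, ddof=1)) if len(kept) > 1 else math.nan,
                "n_bio_reps_kept": len(kept),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows), audit
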