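"""5-minute gridding of irregular observations and the forward-fill policies."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .schema import GRID_STEP_MIN, MAX_GRID_BINS, FillMode, Schema, StayRecord

_STEP_NS = GRID_STEP_MIN * 60 * 1_000_000_000


class SchemaError(ValueError):
    pass


class RejectStay(ValueError):
    """Stay excluded from the cohort (e.g. no heart-rate data)."""


@dataclass
class GriddedStay:
    """One ICU stay resampled onto the 5-minute grid.

    For every schema variable there are three aligned tracks:

    ``values``        latest in-bin observation, NaN where the bin is empty
                      (until imputation fills it);
    ``measured``      1 iff at least one raw observation fell into the bin;
    ``time_since``    minutes since the most recent raw observation at or
                      before the bin (0 at a measured bin), -1 if none yet.
    """

    patient_id: str
    grid_start: pd.Timestamp
    n_steps: int
    values: dict[str, np.ndarray]
    measured: dict[str, np.ndarray]
    time_since: dict[str, np.ndarray]
    statics: dict
    admission_time: pd.Timestamp = None
    discharge_time: pd.Timestamp = None
    death_time: Optional[pd.Timestamp] = None
    pre_2009_era: bool = False
    pre_2010: bool = False
    raw_times_min: dict[str, np.ndarray] = field(default_factory=dict)
    raw_values: dict[str, np.ndarray] = field(default_factory=dict)
    imputed: Optional[str] = None  # None | "dense" | "feature"

    def bin_times(self) -> pd.DatetimeIndex:
        return self.grid_start + pd.to_timedelta(
            np.arange(self.n_steps) * GRID_STEP_MIN, unit="m"
        )

    def copy(self) -> "GriddedStay":
        return GriddedStay(
            patient_id=self.patient_id,
            grid_start=self.grid_start,
            n_steps=self.n_steps,
            values={k: v.copy() for k, v in self.values.items()},
            measured={k: v.copy() for k, v in self.measured.items()},
            time_since={k: v.copy() for k, v in self.time_since.items()},
            statics=dict(self.statics),
            admission_time=self.admission_time,
            discharge_time=self.discharge_time,
            death_time=self.death_time,
            pre_2009_era=self.pre_2009_era,
            pre_2010=self.pre_2010,
            raw_times_min={k: v.copy() for k, v in self.raw_times_min.items()},
            raw_values={k: v.copy() for k, v in self.raw_values.items()},
            imputed=self.imputed,
        )

    def truncate(self, n_steps: int) -> "GriddedStay":
        """Return a copy keeping only bins [0, n_steps) and raw data before
        the end of the last kept bin. Used by causality tests."""
        n = int(min(n_steps, self.n_steps))
        end_min = n * GRID_STEP_MIN
        out = self.copy()
        out.n_steps = n
        out.values = {k: v[:n] for k, v in out.values.items()}
        out.measured = {k: v[:n] for k, v in out.measured.items()}
        out.time_since = {k: v[:n] for k, v in out.time_since.items()}
        for k in list(out.raw_times_min):
            t = out.raw_times_min[k]
            keep = t < end_min
            out.raw_times_min[k] = t[keep]
            out.raw_values[k] = out.raw_values[k][keep]
        return out


def _mean_same_timestamp(times_ns: np.ndarray, values: np.ndarray):
    """Average observations that share an exact timestamp."""
    if len(times_ns) == 0:
        return times_ns, values
    uniq, inv = np.unique(times_ns, return_inverse=True)
    sums = np.bincount(inv, weights=values)
    counts = np.bincount(inv)
    return uniq, sums / counts


def adaptive_horizon(observation_intervals) -> float:
    """Data-adaptive forward-fill horizon: 2*median + IQR of the intervals.

    IQR is the 75th minus 25th percentile with linear interpolation.
    """
    iv = np.asarray(list(observation_intervals), dtype=float)
    if iv.size == 0:
        raise ValueError("adaptive_horizon needs at least one interval")
    q25, q75 = np.percentile(iv, [25, 75])
    return float(2.0 * np.median(iv) + (q75 - q25))


def build_grid(stay: StayRecord, schema: Schema) -> GriddedStay:
    """Resample a stay onto the 5-minute grid anchored at the first HR
    observation, truncated at 28 days.

    Bin ``t`` covers ``[grid_start + 5t, grid_start + 5(t+1))`` minutes.
    Same-timestamp duplicates are averaged before binning; a measured bin
    carries the latest in-bin observation.
    """
    for vid in stay.observations:
        if vid not in schema:
            raise SchemaError(f"unknown variable id {vid!r}")
    hr = stay.observations.get("hr")
    if hr is None or len(hr[0]) == 0:
        raise RejectStay(f"{stay.patient_id}: no heart-rate data")

    hr_ns = pd.DatetimeIndex(hr[0]).asi8
    start_ns = int(hr_ns.min())
    end_ns = int(hr_ns.max())
    grid_start = pd.Timestamp(start_ns)
    n_steps = int((end_ns - start_ns) // _STEP_NS) + 1
    n_steps = min(n_steps, MAX_GRID_BINS)

    values, measured, time_since = {}, {}, {}
    raw_times_min, raw_values = {}, {}
    for vid in schema.variable_ids:
        val = np.full(n_steps, np.nan)
        meas = np.zeros(n_steps, dtype=np.int8)
        tsm = np.full(n_steps, -1.0)
        obs = stay.observations.get(vid)
        if obs is not None and len(obs[0]) > 0:
            t_ns = pd.DatetimeIndex(obs[0]).asi8.astype(np.int64)
            v = np.asarray(obs[1], dtype=float)
            t_ns, v = _mean_same_timestamp(t_ns, v)
            rel_min = (t_ns - start_ns) / 60e9
            keep = rel_min < n_steps * GRID_STEP_MIN
            rel_min, v = rel_min[keep], v[keep]
            raw_times_min[vid] = rel_min
            raw_values[vid] = v
            if rel_min.size == 0:
                values[vid] = val
                measured[vid] = meas
                time_since[vid] = tsm
                continue
            in_grid = rel_min >= 0
            bins = np.floor(rel_min[in_grid] / GRID_STEP_MIN).astype(np.int64)
            # latest observation in each bin wins
            val[bins] = v[in_grid]
            meas[bins] = 1
            # time since last observation, relative to the bin start
            bin_starts = np.arange(n_steps, dtype=float) * GRID_STEP_MIN
            bin_ends = bin_starts + GRID_STEP_MIN
            idx = np.searchsorted(rel_min, bin_ends, side="left") - 1
            has_prev = idx >= 0
            last_t = np.where(has_prev, rel_min[np.clip(idx, 0, None)], np.nan)
            tsm = np.where(has_prev, np.maximum(bin_starts - last_t, 0.0), -1.0)
        else:
            raw_times_min[vid] = np.empty(0)
            raw_values[vid] = np.empty(0)
        values[vid] = val
        measured[vid] = meas
        time_since[vid] = tsm

    return GriddedStay(
        patient_id=stay.patient_id,
        grid_start=grid_start,
        n_steps=n_steps,
        values=values,
        measured=measured,
        time_since=time_since,
        statics=stay.statics(),
        admission_time=stay.admission_time,
        discharge_time=stay.discharge_time,
        death_time=stay.death_time,
        pre_2009_era=stay.pre_2009_era,
        pre_2010=stay.pre_2010,
        raw_times_min=raw_times_min,
        raw_values=raw_values,
    )


class TrainingStats:
    """Training-set statistics consumed by imputation and feature extraction.

    Computed once on training stays and serialized; never derived from the
    data being transformed, so no information leaks across splits.
    """

    def __init__(
        self,
        median_intervals_min: dict[str, float],
        adaptive_horizons_min: dict[str, float],
        static_fill: dict[str, float | str],
    ):
        self.median_intervals_min = median_intervals_min
        self.adaptive_horizons_min = adaptive_horizons_min
        self.static_fill = static_fill

    @classmethod
    def fit(cls, stays: list[StayRecord], schema: Schema) -> "TrainingStats":
        intervals: dict[str, list[np.ndarray]] = {v: [] for v in schema.variable_ids}
        static_rows = []
        for stay in stays:
            static_rows.append(stay.statics())
            for vid, (t, v) in stay.observations.items():
                if vid not in schema:
                    continue
                t_ns = pd.DatetimeIndex(t).asi8
                if len(t_ns) > 1:
                    intervals[vid].append(np.diff(np.unique(t_ns)) / 60e9)
        med, hor = {}, {}
        for vid in schema.variable_ids:
            iv = (
                np.concatenate(intervals[vid])
                if intervals[vid]
                else np.empty(0)
            )
            if iv.size:
                med[vid] = float(np.median(iv))
                hor[vid] = adaptive_horizon(iv)
            else:
                med[vid] = float("inf")
                hor[vid] = 0.0
        statics = pd.DataFrame(static_rows)
        fill: dict[str, float | str] = {}
        for col in statics.columns:
            if statics[col].dtype == object:
                mode = statics[col].mode()
                fill[col] = str(mode.iloc[0]) if len(mode) else ""
            else:
                fill[col] = float(statics[col].median())
        return cls(med, hor, fill)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "median_intervals_min": self.median_intervals_min,
                    "adaptive_horizons_min": self.adaptive_horizons_min,
                    "static_fill": self.static_fill,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "TrainingStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["median_intervals_min"], d["adaptive_horizons_min"], d["static_fill"]
        )


def _fill_horizon_min(spec, stats: Optional[TrainingStats]) -> float:
    if spec.fill_mode is FillMode.INDEFINITE:
        return float("inf")
    if spec.fill_mode is FillMode.FIXED:
        return float(spec.fill_horizon_min)
    if spec.fill_mode is FillMode.ADAPTIVE:
        if stats is None:
            raise SchemaError(
                f"{spec.variable_id}: adaptive forward fill needs training statistics"
            )
        return float(stats.adaptive_horizons_min.get(spec.variable_id, 0.0))
    return 0.0  # EXACT: handled separately


def impute(
    grid: GriddedStay,
    schema: Schema,
    mode: str,
    stats: Optional[TrainingStats] = None,
) -> GriddedStay:
    """Apply per-variable forward filling; ``mode`` is "dense" or "feature".

    Dense mode guarantees a finite value at every grid point (normal values
    before the first observation and beyond the fill horizon, training-set
    median/mode for statics); feature mode preserves missingness.
    """
    if mode not in ("dense", "feature"):
        raise ValueError(f"mode must be 'dense' or 'feature', got {mode!r}")
    out = grid.copy()
    for spec in schema:
        vid = spec.variable_id
        val = out.values[vid]
        if spec.fill_mode is FillMode.EXACT:
            filled = val.copy()  # value lives only at the measured bin
        else:
            horizon = _fill_horizon_min(spec, stats)
            tsm = out.time_since[vid]
            rel = out.raw_times_min.get(vid, np.empty(0))
            rv = out.raw_values.get(vid, np.empty(0))
            if rel.size:
                bin_ends = (np.arange(out.n_steps) + 1.0) * GRID_STEP_MIN
                idx = np.searchsorted(rel, bin_ends, side="left") - 1
                last_val = np.where(idx >= 0, rv[np.clip(idx, 0, None)], np.nan)
                within = (tsm >= 0) & (tsm <= horizon)
                filled = np.where(within, last_val, val)
            else:
                filled = val.copy()
        if mode == "dense":
            if spec.normal_value is None:
                raise SchemaError(
                    f"{vid}: dense imputation requires a normal value"
                )
            filled = np.where(np.isnan(filled), spec.normal_value, filled)
        out.values[vid] = filled
    if mode == "dense" and stats is not None:
        for k, v in out.statics.items():
            if v is None or (isinstance(v, float) and np.isnan(v)):
                out.statics[k] = stats.static_fill.get(k, v)
    out.imputed = mode
    return out
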