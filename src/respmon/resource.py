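"""ICU-level ventilator-demand forecasting from per-patient scores plus
hourly census features, with the persistence baseline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
)

from .schema import GRID_STEP_MIN

SUPPORTED_HORIZONS = {(4, 8), (4, 12), (8, 12), (8, 16), (16, 24)}


@dataclass
class StayCensusInfo:
    """Per-stay payload needed by the census and planner."""

    stay_id: str
    admission_time: pd.Timestamp
    discharge_time: pd.Timestamp
    elective: bool
    grid_start: pd.Timestamp
    vent: np.ndarray  # per 5-min bin
    scores: Optional[dict[str, np.ndarray]] = None  # task -> per-bin score


def _bin_at(info: StayCensusInfo, when: pd.Timestamp) -> Optional[int]:
    b = int((when - info.grid_start).total_seconds() // (GRID_STEP_MIN * 60))
    if 0 <= b < len(info.vent):
        return b
    return None


def _vent_at(info: StayCensusInfo, when: pd.Timestamp) -> bool:
    b = _bin_at(info, when)
    return bool(info.vent[b]) if b is not None else False


def build_census(stays: list[StayCensusInfo]) -> pd.DataFrame:
    """Hourly unit-level counts: patients present, ventilated non-elective
    patients, new non-elective admissions and new (eventually) ventilated
    non-elective admissions in the past hour, plus calendar fields."""
    if not stays:
        raise ValueError("no stays")
    for s in stays:
        if s.admission_time is None:
            raise ValueError(f"{s.stay_id}: missing admission time")
    start = min(s.admission_time for s in stays).floor("h")
    end = max(s.discharge_time for s in stays).ceil("h")
    hours = pd.date_range(start, end, freq="h")
    present = np.zeros(len(hours), dtype=np.int64)
    vent_ne = np.zeros(len(hours), dtype=np.int64)
    new_adm = np.zeros(len(hours), dtype=np.int64)
    new_vent_adm = np.zeros(len(hours), dtype=np.int64)
    for s in stays:
        ever_vent = bool(np.any(s.vent))
        i0 = int(np.searchsorted(hours.values, np.datetime64(s.admission_time), side="left"))
        i1 = int(np.searchsorted(hours.values, np.datetime64(s.discharge_time), side="left"))
        for i in range(i0, min(i1, len(hours))):
            present[i] += 1
            if not s.elective and _vent_at(s, hours[i]):
                vent_ne[i] += 1
        if not s.elective:
            # admission falls in the hour ending at hours[k]
            k = int(np.searchsorted(hours.values, np.datetime64(s.admission_time), side="left"))
            if 0 <= k < len(hours):
                new_adm[k] += 1
                if ever_vent:
                    new_vent_adm[k] += 1
    return pd.DataFrame(
        {
            "present": present,
            "vent_nonelective": vent_ne,
            "new_admissions": new_adm,
            "new_vent_admissions": new_vent_adm,
            "hour_of_day": hours.hour,
            "weekday": hours.weekday,
        },
        index=hours,
    )


SCORE_TASKS = ("RF", "EF", "MVStart", "MVEnd")


def patient_level_features(info: StayCensusInfo, when: pd.Timestamp) -> np.ndarray:
    """(RF, EF, MVStart, MVEnd scores, ventilation flag, hours in stay);
    a score missing at the hour is carried forward up to 1 h."""
    b = _bin_at(info, when)
    feats = []
    for task in SCORE_TASKS:
        val = np.nan
        if info.scores is not None and task in info.scores:
            track = info.scores[task]
            if b is not None:
                lo = max(0, b - 60 // GRID_STEP_MIN)
                window = track[lo: b + 1]
                good = window[~np.isnan(window)]
                if len(good):
                    val = float(good[-1])
        feats.append(val)
    feats.append(float(_vent_at(info, when)))
    feats.append((when - info.admission_time).total_seconds() / 3600.0)
    return np.asarray(feats, dtype=float)


def realized_max_vent(census: pd.DataFrame, h_idx: int, horizon: tuple[int, int]) -> Optional[float]:
    lo, hi = h_idx + horizon[0], h_idx + horizon[1]
    if hi >= len(census):
        return None
    return float(census["vent_nonelective"].iloc[lo: hi + 1].max())


@dataclass
class ResourceModel:
    horizon: tuple[int, int]
    patient_clf: HistGradientBoostingClassifier
    admission_reg: HistGradientBoostingRegressor

    def forecast(
        self, stays: list[StayCensusInfo], census: pd.DataFrame, h_idx: int
    ) -> float:
        when = census.index[h_idx]
        rows, n_cur = [], 0
        for s in stays:
            if s.elective or not (s.admission_time <= when < s.discharge_time):
                continue
            rows.append(patient_level_features(s, when))
            n_cur += 1
        part_a = 0.0
        if rows:
            part_a = float(self.patient_clf.predict_proba(np.vstack(rows))[:, 1].sum())
        part_b = float(
            self.admission_reg.predict(_icu_features(census, h_idx)[None, :])[0]
        )
        return max(part_a + max(part_b, 0.0), 0.0)


def _icu_features(census: pd.DataFrame, h_idx: int) -> np.ndarray:
    row = census.iloc[h_idx]
    return np.asarray(
        [
            row["hour_of_day"],
            row["weekday"],
            row["present"],
            row["vent_nonelective"],
            row["new_admissions"],
            row["new_vent_admissions"],
        ],
        dtype=float,
    )


def train_resource_model(
    stays: list[StayCensusInfo],
    census: pd.DataFrame,
    horizon: tuple[int, int],
    seed: int = 0,
    min_hours: int = 30 * 24,
    params: Optional[dict] = None,
) -> ResourceModel:
    """Two sub-models: a per-patient classifier for ventilation within the
    horizon window (probabilities summed over admitted non-elective
    patients) and an ICU-level regressor for ventilated new admissions."""
    if tuple(horizon) not in SUPPORTED_HORIZONS:
        raise ValueError(f"unsupported horizon {horizon}")
    if len(census) < min_hours:
        raise ValueError(f"need at least {min_hours} hours of census data")
    params = params or dict(max_iter=100, max_leaf_nodes=15, learning_rate=0.1)
    lo, hi = horizon
    Xa, ya, Xb, yb = [], [], [], []
    hours = census.index
    for h_idx in range(len(hours) - hi):
        when = hours[h_idx]
        w_start, w_end = hours[h_idx + lo], hours[h_idx + hi]
        window = pd.date_range(w_start, w_end, freq="h")
        n_new_vent = 0
        for s in stays:
            if s.elective:
                continue
            if s.admission_time <= when < s.discharge_time:
                Xa.append(patient_level_features(s, when))
                ya.append(int(any(_vent_at(s, w) for w in window)))
            elif when < s.admission_time <= w_end:
                if any(_vent_at(s, w) for w in window):
                    n_new_vent += 1
        Xb.append(_icu_features(census, h_idx))
        yb.append(n_new_vent)
    ya = np.asarray(ya)
    if len(np.unique(ya)) < 2:
        raise ValueError("per-patient ventilation target is single-class")
    clf = HistGradientBoostingClassifier(random_state=seed, **params).fit(
        np.vstack(Xa), ya
    )
    reg = HistGradientBoostingRegressor(random_state=seed, **params).fit(
        np.vstack(Xb), np.asarray(yb, dtype=float)
    )
    return ResourceModel(tuple(horizon), clf, reg)


def persistence_baseline(census: pd.DataFrame, h_idx: int) -> float:
    """Forecast: the ventilated non-elective count stays at its current value."""
    return float(census["vent_nonelective"].iloc[h_idx])


def evaluate_resource(
    forecasts: np.ndarray,
    baselines: np.ndarray,
    realized: np.ndarray,
    hours: pd.DatetimeIndex,
    usage: Optional[np.ndarray] = None,
    diff_levels: Sequence[int] = (1, 2, 3, 4),
) -> dict:
    """MAE table: overall, by hour-of-day, by current-usage bin, plus the
    head-to-head share of hours each method is better by >= k ventilators."""
    f = np.asarray(forecasts, dtype=float)
    b = np.asarray(baselines, dtype=float)
    r = np.asarray(realized, dtype=float)
    err_f, err_b = np.abs(f - r), np.abs(b - r)
    out = {
        "mae_model": float(np.mean(err_f)),
        "mae_baseline": float(np.mean(err_b)),
        "by_hour": {},
        "by_usage": {},
        "head_to_head": {},
    }
    hod = np.asarray(hours.hour)
    for h in range(24):
        m = hod == h
        if m.any():
            out["by_hour"][h] = (float(np.mean(err_f[m])), float(np.mean(err_b[m])))
    if usage is not None:
        usage = np.asarray(usage, dtype=float)
        edges = np.unique(np.quantile(usage, [0, 0.25, 0.5, 0.75, 1.0]))
        for i in range(len(edges) - 1):
            m = (usage >= edges[i]) & (
                usage <= edges[i + 1] if i == len(edges) - 2 else usage < edges[i + 1]
            )
            if m.any():
                out["by_usage"][f"[{edges[i]:g},{edges[i+1]:g}]"] = (
                    float(np.mean(err_f[m])),
                    float(np.mean(err_b[m])),
                    int(m.sum()),
                )
    for k in diff_levels:
        out["head_to_head"][k] = {
            "model_better": float(np.mean(err_b - err_f >= k)),
            "baseline_better": float(np.mean(err_f - err_b >= k)),
        }
    return out
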