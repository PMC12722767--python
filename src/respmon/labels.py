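"""Machine-learning label construction for the four prediction tasks.

Per-bin labels live in {POSITIVE, NEGATIVE, UNDEFINED}; extubation-failure
labels attach to extubation events and their 30-min augmentation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .endpoints import RF_MILD, RF_MODERATE, RF_STABLE, RF_UNKNOWN, vent_events
from .gridding import GriddedStay
from .schema import BINS_PER_HOUR, GRID_STEP_MIN

LBL_UNDEFINED = -1
LBL_NEGATIVE = 0
LBL_POSITIVE = 1

EF_SUCCESS = 0
EF_FAILURE = 1
EF_UNCERTAIN = 2

HORIZON_BINS = 24 * BINS_PER_HOUR  # 24 h
MV_START_EXCLUSION_BINS = 6  # 30 min before ventilation onset
EF_AUGMENT_BINS = 6  # 30 min before an extubation
EF_HORIZON_BINS = 48 * BINS_PER_HOUR  # 48 h re-intubation window


@dataclass
class LabelTrack:
    task: str
    label: np.ndarray  # per-bin, int codes above
    extubation_events: list[tuple[int, int]] = field(default_factory=list)  # (bin, EF_*)


def _future_any(flags: np.ndarray, horizon: int) -> np.ndarray:
    """True at t iff any flag in (t, t+horizon], clipped at the end."""
    f = np.asarray(flags, dtype=np.int64)
    n = len(f)
    c = np.concatenate([[0], np.cumsum(f)])
    t = np.arange(n)
    end = np.minimum(t + 1 + horizon, n)
    return (c[end] - c[t + 1]) > 0


def _future_all(flags: np.ndarray, horizon: int) -> np.ndarray:
    """True at t iff every bin in (t, t+horizon] (clipped) is flagged; False
    when the window is empty (last bin)."""
    f = np.asarray(flags, dtype=np.int64)
    n = len(f)
    c = np.concatenate([[0], np.cumsum(f)])
    t = np.arange(n)
    end = np.minimum(t + 1 + horizon, n)
    width = end - (t + 1)
    return (c[end] - c[t + 1]) == np.maximum(width, 0)


def label_rf_onset(rf_status: np.ndarray, horizon: int = HORIZON_BINS) -> LabelTrack:
    """Positive where currently stable/mild and moderate-or-severe failure
    occurs within the next 24 h; undefined while already in failure, while
    unknown, or when the whole future window is unknown."""
    st = np.asarray(rf_status)
    n = len(st)
    label = np.full(n, LBL_UNDEFINED, dtype=np.int64)
    eligible = (st == RF_STABLE) | (st == RF_MILD)
    event = st >= RF_MODERATE
    fut_event = _future_any(event, horizon)
    fut_all_unknown = _future_all(st == RF_UNKNOWN, horizon)
    # empty future window (stay end): not "entirely unknown"
    last = np.zeros(n, dtype=bool)
    if n:
        last[-1] = True
    defined = eligible & ~(fut_all_unknown & ~last)
    label[defined & fut_event] = LBL_POSITIVE
    label[defined & ~fut_event] = LBL_NEGATIVE
    return LabelTrack("RF", label)


def label_mv_start(vent: np.ndarray, horizon: int = HORIZON_BINS) -> LabelTrack:
    """Positive where currently not ventilated and ventilation starts within
    24 h; the 30 min just before each onset are undefined."""
    v = np.asarray(vent, dtype=bool)
    n = len(v)
    label = np.full(n, LBL_UNDEFINED, dtype=np.int64)
    fut_vent = _future_any(v, horizon)
    eligible = ~v
    label[eligible & fut_vent] = LBL_POSITIVE
    label[eligible & ~fut_vent] = LBL_NEGATIVE
    onsets = [s for s, e in vent_events(v)]
    for s in onsets:
        label[max(0, s - MV_START_EXCLUSION_BINS): s] = LBL_UNDEFINED
    label[v] = LBL_UNDEFINED
    return LabelTrack("MVStart", label)


def label_mv_end(vent: np.ndarray, rext: np.ndarray, horizon: int = HORIZON_BINS) -> LabelTrack:
    """Positive where ventilated-and-not-ready and readiness occurs within
    24 h; undefined elsewhere."""
    v = np.asarray(vent, dtype=bool)
    r = np.asarray(rext, dtype=bool)
    n = len(v)
    label = np.full(n, LBL_UNDEFINED, dtype=np.int64)
    eligible = v & ~r
    fut_ready = _future_any(r, horizon)
    label[eligible & fut_ready] = LBL_POSITIVE
    label[eligible & ~fut_ready] = LBL_NEGATIVE
    return LabelTrack("MVEnd", label)


def _offunit_fraction(hr_near: np.ndarray, start: int, end: int) -> float:
    w = hr_near[max(0, start):end]
    if len(w) == 0:
        return 0.0
    return float(np.mean(~w))


def label_extubations(
    vent: np.ndarray,
    grid: GriddedStay,
    hr_near: np.ndarray,
    trach_track: Optional[np.ndarray] = None,
) -> LabelTrack:
    """Extubation-failure event labels plus the augmented per-bin track.

    An extubation is a ventilated-to-non-ventilated transition that is not a
    tracheostomy decannulation. Failure: a valid re-intubation within 48 h
    (re-intubations preceded by an off-unit hour are procedural and are
    ignored). Death within 48 h without re-intubation: uncertain. The 6 bins
    before the extubation share its label; uncertain maps to undefined in
    the per-bin track.
    """
    v = np.asarray(vent, dtype=bool)
    n = len(v)
    if trach_track is None:
        trach_track = grid.values["trach"]
    trach = np.nan_to_num(np.asarray(trach_track, float)) > 0
    label = np.full(n, LBL_UNDEFINED, dtype=np.int64)
    events = vent_events(v)
    ev_labels: list[tuple[int, int]] = []

    death_bin = None
    if grid.death_time is not None:
        death_bin = (grid.death_time - grid.grid_start).total_seconds() / 60.0 / GRID_STEP_MIN

    for i, (s, e) in enumerate(events):
        if e >= n:  # ventilated to the end of the stay: no extubation
            continue
        ext_bin = e - 1  # last ventilated bin
        if trach[ext_bin]:  # decannulation from tracheostomy
            continue
        outcome = EF_SUCCESS
        for s2, _e2 in events[i + 1:]:
            if s2 - e >= EF_HORIZON_BINS:
                break
            # off-unit in the hour immediately prior to the re-intubation?
            if _offunit_fraction(hr_near, s2 - BINS_PER_HOUR, s2) > 2.0 / 3.0:
                continue  # procedural; ignore this re-intubation
            outcome = EF_FAILURE
            break
        if outcome == EF_SUCCESS and death_bin is not None:
            if e <= death_bin <= e + EF_HORIZON_BINS:
                outcome = EF_UNCERTAIN
        ev_labels.append((ext_bin, outcome))
        fill = {EF_SUCCESS: LBL_NEGATIVE, EF_FAILURE: LBL_POSITIVE, EF_UNCERTAIN: LBL_UNDEFINED}[outcome]
        label[max(0, ext_bin - EF_AUGMENT_BINS): ext_bin + 1] = fill
    return LabelTrack("EF", label, extubation_events=ev_labels)
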