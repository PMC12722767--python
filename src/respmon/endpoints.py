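"""Endpoint annotators: respiratory-failure severity, ventilation status and
readiness-to-extubate, all on the 5-minute grid."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gridding import GriddedStay
from .schema import (
    AIRWAY_HELMET,
    AIRWAY_INTUBATED,
    AIRWAY_MASK,
    AIRWAY_MOUTHPIECE,
    AIRWAY_NASAL,
    AIRWAY_TRACHEOSTOMY,
    BINS_PER_HOUR,
    GRID_STEP_MIN,
    MODE_CONTROLLED,
    MODE_CPAP,
    MODE_HIGHFLOW,
    MODE_NIV,
    MODE_SPONTANEOUS,
    MODE_STANDBY,
)

# respiratory-failure status codes
RF_UNKNOWN = -1
RF_STABLE = 0
RF_MILD = 1
RF_MODERATE = 2
RF_SEVERE = 3

#: Severity band upper P/F thresholds (mmHg), exclusive.
RF_THRESHOLDS = {RF_MILD: 300.0, RF_MODERATE: 200.0, RF_SEVERE: 100.0}

RF_WINDOW_BINS = BINS_PER_HOUR  # forward 1 h
REXT_WINDOW_BINS = BINS_PER_HOUR  # trailing 1 h
REXT_CUTOFF = 9
VENT_VOTE_CUTOFF = 4


def runs(track: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal constant runs as (start, end, value) with end exclusive."""
    x = np.asarray(track)
    if len(x) == 0:
        return []
    change = np.where(x[1:] != x[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(x)]])
    return [(int(s), int(e), x[s]) for s, e in zip(starts, ends)]


def _forward_window_counts(flags: np.ndarray, window: int):
    """Count of True in [t, t+window) clipped at the end, plus window sizes."""
    f = np.asarray(flags, dtype=np.int64)
    n = len(f)
    c = np.concatenate([[0], np.cumsum(f)])
    t = np.arange(n)
    end = np.minimum(t + window, n)
    return c[end] - c[t], end - t


def _two_thirds(window_sizes: np.ndarray) -> np.ndarray:
    return np.ceil(2.0 * window_sizes / 3.0)


# ---------------------------------------------------------------------------
# respiratory failure
# ---------------------------------------------------------------------------

def consistent_vent_state(vent: np.ndarray, peep: np.ndarray, peep_min: float = 4.0) -> np.ndarray:
    """A bin qualifies for RF counting if the patient is not ventilated, or
    is ventilated with PEEP unavailable, or ventilated with PEEP >= 4."""
    vent = np.asarray(vent, dtype=bool)
    peep = np.asarray(peep, dtype=float)
    return (~vent) | np.isnan(peep) | (peep >= peep_min)


def annotate_rf(
    pf: np.ndarray,
    vent: np.ndarray,
    peep: np.ndarray,
    moderate_threshold: float = 200.0,
    window: int = RF_WINDOW_BINS,
) -> np.ndarray:
    """Tentative per-bin severity using the forward 1-h two-thirds rule.

    ``moderate_threshold`` supports the sensitivity variant (150 mmHg); the
    mild and severe bands scale with their printed values by default.
    """
    pf = np.asarray(pf, dtype=float)
    cons = consistent_vent_state(vent, peep)
    missing = np.isnan(pf)

    thresholds = {
        RF_SEVERE: RF_THRESHOLDS[RF_SEVERE],
        RF_MODERATE: moderate_threshold,
        RF_MILD: RF_THRESHOLDS[RF_MILD],
    }
    n = len(pf)
    out = np.full(n, RF_STABLE, dtype=np.int64)
    cnt_missing, wsize = _forward_window_counts(missing, window)
    need = _two_thirds(wsize)
    unknown = cnt_missing >= need
    decided = unknown.copy()
    out[unknown] = RF_UNKNOWN
    for level in (RF_SEVERE, RF_MODERATE, RF_MILD):
        qualifying = (~missing) & cons & (pf < thresholds[level])
        cnt, _ = _forward_window_counts(qualifying, window)
        hit = (~decided) & (cnt >= need)
        out[hit] = level
        decided |= hit
    return out


def correct_right_edges(
    rf_status: np.ndarray, pf: np.ndarray, moderate_threshold: float = 200.0
) -> np.ndarray:
    """Extend each event rightwards over bins whose instantaneous P/F still
    satisfies the event's severity criterion; the scan stops at the first
    non-satisfying or missing P/F bin."""
    out = np.asarray(rf_status).copy()
    pf = np.asarray(pf, dtype=float)
    thresholds = {
        RF_SEVERE: RF_THRESHOLDS[RF_SEVERE],
        RF_MODERATE: moderate_threshold,
        RF_MILD: RF_THRESHOLDS[RF_MILD],
    }
    n = len(out)
    for start, end, level in runs(np.asarray(rf_status)):
        if level <= RF_STABLE:
            continue
        thr = thresholds[int(level)]
        k = end
        while k < n and out[k] < level and not np.isnan(pf[k]) and pf[k] < thr:
            out[k] = level
            k += 1
    return out


def postprocess_rf(rf_status: np.ndarray, max_sandwich_bins: int = 4 * BINS_PER_HOUR) -> np.ndarray:
    """Relabel runs no longer than 4 h sandwiched between two equal-status
    runs, at least one of which is longer; iterated to a fixed point (both
    deletes spurious short events and merges event gaps)."""
    out = np.asarray(rf_status).copy()
    while True:
        rr = runs(out)
        changed = False
        for i in range(1, len(rr) - 1):
            s, e, v = rr[i]
            ls, le, lv = rr[i - 1]
            ns, ne, nv = rr[i + 1]
            if (
                (e - s) <= max_sandwich_bins
                and lv == nv
                and lv != v
                and ((le - ls) > (e - s) or (ne - ns) > (e - s))
            ):
                out[s:e] = lv
                changed = True
                break
        if not changed:
            return out


def rf_events(rf_status: np.ndarray, min_level: int = RF_MODERATE) -> list[tuple[int, int, int]]:
    """Maximal runs with severity >= min_level, as (start, end, level-of-run)."""
    return [(s, e, int(v)) for s, e, v in runs(np.asarray(rf_status)) if v >= min_level]


# ---------------------------------------------------------------------------
# ventilation
# ---------------------------------------------------------------------------

def vote_ventilation(
    pre_2009: bool,
    etco2_window: bool,
    mode: float,
    tidal_volume: float,
    trach: float,
    intub: float,
    airway: float,
) -> tuple[int, bool]:
    """Point table for one grid bin; NaN / unknown inputs contribute 0."""
    score = 0
    if pre_2009:
        score += 1
    if etco2_window:
        score += 2
    if not np.isnan(mode):
        if mode in (MODE_CONTROLLED, MODE_SPONTANEOUS):
            score += 1
        elif mode == MODE_STANDBY:
            score -= 1
        elif mode in (MODE_NIV, MODE_HIGHFLOW, MODE_CPAP):
            score -= 2
    if not np.isnan(tidal_volume) and tidal_volume > 0:
        score += 1
    airway_pos = (not np.isnan(airway)) and airway in (AIRWAY_INTUBATED, AIRWAY_TRACHEOSTOMY)
    if (not np.isnan(trach) and trach > 0) or (not np.isnan(intub) and intub > 0) or airway_pos:
        score += 2
    if (not np.isnan(airway)) and airway in (
        AIRWAY_MASK,
        AIRWAY_HELMET,
        AIRWAY_MOUTHPIECE,
        AIRWAY_NASAL,
    ):
        score -= 1
    return score, score >= VENT_VOTE_CUTOFF


def etco2_window_flags(grid: GriddedStay, half_window_min: float = 15.0, threshold: float = 0.5) -> np.ndarray:
    """True where at least one raw EtCO2 observation above threshold falls in
    the centered 30-min window around the bin start."""
    t = grid.raw_times_min.get("etco2", np.empty(0))
    v = grid.raw_values.get("etco2", np.empty(0))
    t = t[v > threshold]
    bin_start = np.arange(grid.n_steps, dtype=float) * GRID_STEP_MIN
    if not t.size:
        return np.zeros(grid.n_steps, dtype=bool)
    lo = np.searchsorted(t, bin_start - half_window_min, side="left")
    hi = np.searchsorted(t, bin_start + half_window_min, side="right")
    return hi > lo


def vote_ventilation_track(grid: GriddedStay) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised point table over a (feature-imputed) gridded stay."""
    n = grid.n_steps
    score = np.zeros(n, dtype=np.int64)
    if grid.pre_2009_era:
        score += 1
    score += 2 * etco2_window_flags(grid).astype(np.int64)
    mode = grid.values["vent_mode"]
    score += np.isin(mode, (MODE_CONTROLLED, MODE_SPONTANEOUS)).astype(np.int64)
    score -= (mode == MODE_STANDBY).astype(np.int64)
    score -= 2 * np.isin(mode, (MODE_NIV, MODE_HIGHFLOW, MODE_CPAP)).astype(np.int64)
    tv = grid.values["tidal_volume"]
    score += ((~np.isnan(tv)) & (tv > 0)).astype(np.int64)
    trach = grid.values["trach"]
    intub = grid.values["intub"]
    airway = grid.values["airway"]
    pos_dev = (
        ((~np.isnan(trach)) & (trach > 0))
        | ((~np.isnan(intub)) & (intub > 0))
        | np.isin(airway, (AIRWAY_INTUBATED, AIRWAY_TRACHEOSTOMY))
    )
    score += 2 * pos_dev.astype(np.int64)
    score -= np.isin(
        airway, (AIRWAY_MASK, AIRWAY_HELMET, AIRWAY_MOUTHPIECE, AIRWAY_NASAL)
    ).astype(np.int64)
    return score, score >= VENT_VOTE_CUTOFF


def hr_nearby_flags(grid: GriddedStay, tolerance_min: float = 10.0) -> np.ndarray:
    """True where a raw HR observation lies within tolerance of the bin start."""
    t = grid.raw_times_min.get("hr", np.empty(0))
    bin_start = np.arange(grid.n_steps, dtype=float) * GRID_STEP_MIN
    if not t.size:
        return np.zeros(grid.n_steps, dtype=bool)
    lo = np.searchsorted(t, bin_start - tolerance_min, side="left")
    hi = np.searchsorted(t, bin_start + tolerance_min, side="right")
    return hi > lo


def postprocess_ventilation(
    vent: np.ndarray,
    grid: GriddedStay,
    trach_track: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Sequential clean-up of the voted track:

    1. close gaps where the patient was likely off-unit (HR coverage < 50%),
    2. merge gaps shorter than 15 min,
    3. close gaps shorter than 24 h flanked by tracheotomy indicators,
    4. delete events shorter than 45 min unless at the start of the stay.
    """
    out = np.asarray(vent, dtype=bool).copy()
    hr_near = hr_nearby_flags(grid)
    if trach_track is None:
        trach_track = grid.values["trach"]
    trach = np.nan_to_num(np.asarray(trach_track, float)) > 0

    def gaps():
        rr = runs(out.astype(np.int64))
        return [
            (s, e)
            for i, (s, e, v) in enumerate(rr)
            if v == 0 and 0 < i < len(rr) - 1
        ]

    # 1. off-unit gaps
    for s, e in gaps():
        if np.mean(hr_near[s:e]) < 0.5:
            out[s:e] = True
    # 2. short gaps (< 15 min)
    for s, e in gaps():
        if (e - s) * GRID_STEP_MIN < 15:
            out[s:e] = True
    # 3. tracheostomy weaning gaps (< 24 h)
    for s, e in gaps():
        if (e - s) * GRID_STEP_MIN < 24 * 60 and trach[s - 1] and trach[min(e, len(out) - 1)]:
            out[s:e] = True
    # 4. spurious short events
    hr_t = grid.raw_times_min.get("hr", np.empty(0))
    for s, e, v in runs(out.astype(np.int64)):
        if v == 1 and (e - s) * GRID_STEP_MIN < 45:
            hr_before = np.any(hr_t < s * GRID_STEP_MIN)
            if hr_before:
                out[s:e] = False
    return out


def vent_events(vent: np.ndarray) -> list[tuple[int, int]]:
    return [(s, e) for s, e, v in runs(np.asarray(vent, dtype=np.int64)) if v == 1]


# ---------------------------------------------------------------------------
# readiness to extubate
# ---------------------------------------------------------------------------

def rext_violation_score(
    mode: float,
    peep: float,
    pressure_support: float,
    fio2: float,
    rr: float,
    tidal_volume: float,
    minute_volume: float,
    pf: float,
    paco2: float,
    gcs: float,
    map_: float,
    norepinephrine: float,
    inotrope: float,
    lactate: float,
    pre_2010: bool = False,
) -> int:
    """Sum of the 13 extubation-criteria violation scores for one bin.

    Missing (NaN) inputs contribute 0. The ventilator-mode criterion is
    skipped for stays admitted before 2010.
    """

    def ok(x):
        return x is not None and not np.isnan(x)

    score = 0
    if not pre_2010 and ok(mode) and mode != MODE_SPONTANEOUS and mode != 0:
        score += 9
    if ok(peep) and peep > 7:
        score += 3
    if ok(pressure_support) and pressure_support > 10:
        score += 3
    if ok(fio2) and fio2 > 0.4:
        score += 3
    if ok(rr) and ok(tidal_volume) and tidal_volume > 0 and 1000.0 * rr / tidal_volume >= 105:
        score += 3
    if ok(rr) and rr >= 35:
        score += 3
    if ok(minute_volume) and minute_volume >= 10:
        score += 3
    if ok(pf) and pf <= 150:
        score += 3
    if ok(paco2) and paco2 >= 50:
        score += 3
    if ok(gcs) and gcs <= 8:
        score += 1
    if ok(map_) and map_ <= 60:
        score += 1
    if (ok(norepinephrine) and norepinephrine > 0.05) or (ok(inotrope) and inotrope > 0):
        score += 1
    if ok(lactate) and lactate >= 2.5:
        score += 1
    return score


def rext_violation_track(grid: GriddedStay, pf: np.ndarray, fio2_est: np.ndarray) -> np.ndarray:
    """Vectorised 13-criteria score over a stay (dense-imputed tracks)."""
    v = grid.values
    n = grid.n_steps
    score = np.zeros(n, dtype=np.int64)

    def col(name):
        return np.asarray(v[name], dtype=float)

    mode = col("vent_mode")
    if not grid.pre_2010:
        score += 9 * ((~np.isnan(mode)) & (mode != MODE_SPONTANEOUS) & (mode != 0)).astype(np.int64)
    peep, ps = col("peep"), col("pressure_support")
    rr, tv, mv = col("rr"), col("tidal_volume"), col("minute_volume")
    paco2, gcs, map_ = col("paco2"), col("gcs"), col("map")
    nore, ino, lact = col("norepinephrine"), col("inotrope"), col("lactate")
    fio2 = np.asarray(fio2_est, dtype=float)
    pf = np.asarray(pf, dtype=float)

    def flag(x, cond):
        return ((~np.isnan(x)) & cond).astype(np.int64)

    score += 3 * flag(peep, peep > 7)
    score += 3 * flag(ps, ps > 10)
    score += 3 * flag(fio2, fio2 > 0.4)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsbi = 1000.0 * rr / tv
    score += 3 * ((~np.isnan(rsbi)) & (tv > 0) & (rsbi >= 105)).astype(np.int64)
    score += 3 * flag(rr, rr >= 35)
    score += 3 * flag(mv, mv >= 10)
    score += 3 * flag(pf, pf <= 150)
    score += 3 * flag(paco2, paco2 >= 50)
    score += flag(gcs, gcs <= 8)
    score += flag(map_, map_ <= 60)
    score += (flag(nore, nore > 0.05) | flag(ino, ino > 0)).astype(np.int64)
    score += flag(lact, lact >= 2.5)
    return score


def annotate_rext(
    violation_scores: np.ndarray,
    vent: np.ndarray,
    window: int = REXT_WINDOW_BINS,
    cutoff: int = REXT_CUTOFF,
) -> np.ndarray:
    """Ready iff ventilated and at least two thirds of the trailing 1-h
    window (inclusive of the current bin, truncated at stay start) score
    below the cutoff."""
    vent = np.asarray(vent, dtype=bool)
    scores = np.asarray(violation_scores, dtype=float)
    satisfied = vent & ~np.isnan(scores) & (scores < cutoff)
    c = np.concatenate([[0], np.cumsum(satisfied.astype(np.int64))])
    n = len(vent)
    t = np.arange(n)
    start = np.maximum(t - window + 1, 0)
    cnt = c[t + 1] - c[start]
    wsize = t + 1 - start
    return vent & (cnt >= _two_thirds(wsize))


@dataclass
class EndpointTracks:
    rf_status: np.ndarray
    vent: np.ndarray
    vent_score: np.ndarray
    rext: np.ndarray
    rext_violation: np.ndarray

    @property
    def rf_event_list(self):
        return rf_events(self.rf_status)

    @property
    def vent_event_list(self):
        return vent_events(self.vent)
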