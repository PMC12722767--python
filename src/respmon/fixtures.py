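"""Hand-designed miniature stays, each exercising exactly one annotation or
labelling rule, with golden expected outputs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .endpoints import (
    RF_MODERATE,
    RF_STABLE,
    correct_right_edges,
    postprocess_rf,
    postprocess_ventilation,
    hr_nearby_flags,
    rext_violation_score,
)
from .gridding import build_grid
from .labels import EF_SUCCESS, EF_UNCERTAIN, LBL_NEGATIVE, LBL_UNDEFINED, label_extubations
from .schema import GRID_STEP_MIN, StayRecord, default_schema

_T0 = pd.Timestamp("2014-03-01 12:00:00")


@dataclass
class Scenario:
    name: str
    run: Callable[[], object]
    expected: object

    def check(self) -> bool:
        got = self.run()
        exp = self.expected
        if isinstance(exp, np.ndarray):
            return bool(np.array_equal(np.asarray(got), exp))
        return got == exp


def _grid(n_bins: int, hr_gap_bins=(), extra_obs=None, death_bin=None, schema=None):
    """Minimal stay: HR at every bin start except the listed gap bins."""
    schema = schema or default_schema()
    hr_bins = [b for b in range(n_bins) if b not in set(hr_gap_bins)]
    obs = {
        "hr": (
            _T0 + pd.to_timedelta([b * GRID_STEP_MIN for b in hr_bins], unit="m"),
            np.full(len(hr_bins), 80.0),
        )
    }
    # the grid is anchored at the first/last HR observation
    assert 0 in hr_bins and (n_bins - 1) in hr_bins
    if extra_obs:
        for vid, pairs in extra_obs.items():
            bins = [b for b, _ in pairs]
            vals = [v for _, v in pairs]
            obs[vid] = (
                _T0 + pd.to_timedelta([b * GRID_STEP_MIN for b in bins], unit="m"),
                np.asarray(vals, dtype=float),
            )
    stay = StayRecord(
        patient_id="fixture",
        admission_time=_T0,
        discharge_time=_T0 + pd.Timedelta(minutes=n_bins * GRID_STEP_MIN),
        death_time=(
            _T0 + pd.Timedelta(minutes=death_bin * GRID_STEP_MIN)
            if death_bin is not None
            else None
        ),
        observations=obs,
    )
    return build_grid(stay, schema)


def _vent(segments, n_bins):
    v = np.zeros(n_bins, dtype=bool)
    for s, e in segments:
        v[s:e] = True
    return v


def _scenarios() -> list[Scenario]:
    out = []

    # --- sandwiched-run post-processing -------------------------------
    merge_in = np.concatenate(
        [np.full(72, RF_MODERATE), np.full(24, RF_STABLE), np.full(60, RF_MODERATE)]
    )
    out.append(
        Scenario(
            "sandwich-merge",
            lambda: postprocess_rf(merge_in),
            np.full(156, RF_MODERATE),
        )
    )
    delete_in = np.concatenate(
        [np.full(72, RF_STABLE), np.full(36, RF_MODERATE), np.full(72, RF_STABLE)]
    )
    out.append(
        Scenario(
            "sandwich-delete",
            lambda: postprocess_rf(delete_in),
            np.full(180, RF_STABLE),
        )
    )
    keep_in = np.concatenate(
        [np.full(72, RF_MODERATE), np.full(60, RF_STABLE), np.full(72, RF_MODERATE)]
    )
    out.append(Scenario("sandwich-keep", lambda: postprocess_rf(keep_in), keep_in.copy()))

    # --- right-edge correction ---------------------------------------
    pf = np.concatenate([np.full(24, 150.0), np.full(24, 250.0)])
    tentative = np.concatenate([np.full(17, RF_MODERATE), np.full(31, RF_STABLE)])
    expected = np.concatenate([np.full(24, RF_MODERATE), np.full(24, RF_STABLE)])
    out.append(
        Scenario("right-edge", lambda: correct_right_edges(tentative, pf), expected)
    )

    # --- ventilation gap / event rules --------------------------------
    def _run_vent(segments, n, hr_gap=(), trach=None):
        g = _grid(n, hr_gap_bins=hr_gap)
        trach_track = np.zeros(n) if trach is None else trach
        return postprocess_ventilation(_vent(segments, n), g, trach_track=trach_track)

    out.append(
        Scenario(
            "gap-15min",
            lambda: _run_vent([(0, 24), (26, 48)], 48),
            _vent([(0, 48)], 48),
        )
    )
    out.append(
        Scenario(
            "gap-24h-trach",
            lambda: _run_vent([(0, 36), (72, 96)], 96, trach=np.ones(96)),
            _vent([(0, 96)], 96),
        )
    )
    out.append(
        Scenario(
            "gap-24h-no-trach",
            lambda: _run_vent([(0, 36), (72, 96)], 96),
            _vent([(0, 36), (72, 96)], 96),
        )
    )
    out.append(
        Scenario(
            "off-unit-gap",
            lambda: _run_vent([(0, 24), (48, 72)], 72, hr_gap=range(24, 48)),
            _vent([(0, 72)], 72),
        )
    )
    out.append(
        Scenario(
            "short-event-midstay",
            lambda: _run_vent([(36, 42)], 96),
            _vent([], 96),
        )
    )
    out.append(
        Scenario(
            "short-event-start",
            lambda: _run_vent([(0, 6)], 96),
            _vent([(0, 6)], 96),
        )
    )

    # --- extubation labelling -----------------------------------------
    def _ef(vent_segments, n, death_bin=None, trach=None, hr_gap=()):
        g = _grid(n, hr_gap_bins=hr_gap, death_bin=death_bin)
        hr_near = hr_nearby_flags(g)
        trach_track = np.zeros(n) if trach is None else trach
        return label_extubations(_vent(vent_segments, n), g, hr_near, trach_track=trach_track)

    def _ef_expected(n, ext_bin, fill):
        lbl = np.full(n, LBL_UNDEFINED, dtype=np.int64)
        lbl[ext_bin - 6: ext_bin + 1] = fill
        return lbl

    out.append(
        Scenario(
            "label-augmentation-30min",
            lambda: _ef([(0, 48)], 120).label,
            _ef_expected(120, 47, LBL_NEGATIVE),
        )
    )
    out.append(
        Scenario(
            "death-censored-ef",
            lambda: _ef([(0, 48)], 160, death_bin=150).extubation_events,
            [(47, EF_UNCERTAIN)],
        )
    )
    out.append(
        Scenario(
            "trach-decannulation",
            lambda: _ef([(0, 48)], 120, trach=np.ones(120)).extubation_events,
            [],
        )
    )
    # re-intubation at bin 200 with the prior hour off-unit -> procedural
    out.append(
        Scenario(
            "procedural-reintubation",
            lambda: _ef(
                [(0, 48), (200, 220)], 300, hr_gap=range(186, 200)
            ).extubation_events,
            [(47, EF_SUCCESS), (219, EF_SUCCESS)],
        )
    )

    # --- era handling --------------------------------------------------
    normal = dict(
        peep=5.0,
        pressure_support=8.0,
        fio2=0.3,
        rr=16.0,
        tidal_volume=480.0,
        minute_volume=7.0,
        pf=300.0,
        paco2=40.0,
        gcs=15.0,
        map_=75.0,
        norepinephrine=0.0,
        inotrope=0.0,
        lactate=1.0,
    )
    out.append(
        Scenario(
            "pre-2010-era",
            lambda: (
                rext_violation_score(mode=2.0, pre_2010=False, **normal),
                rext_violation_score(mode=2.0, pre_2010=True, **normal),
            ),
            (9, 0),
        )
    )
    return out


def list_scenarios() -> list[str]:
    return [s.name for s in _scenarios()]


def make_fixtures(name: str) -> Scenario:
    for s in _scenarios():
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario {name!r}")
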