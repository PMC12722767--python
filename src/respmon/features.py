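"""Feature-matrix construction from feature-imputed gridded stays.

Feature categories: current value, time since admission, endpoint-derived
(estimated FIO2 and ventilation status), multi-resolution summaries,
measurement intensity, instability history, and statics. The current PaO2
estimate is deliberately excluded (future-information leakage through the
annotation pipeline).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridding import GriddedStay, TrainingStats
from .schema import BINS_PER_HOUR, GRID_STEP_MIN, Schema, VarKind

#: Trailing summary horizons (hours). These are the 20/40/60/80 percentiles
#: of available history in the reference cohort — fixed constants here.
MULTIRES_HORIZONS_H = (10, 26, 63, 156)
MIN_EXPECTED_MEASUREMENTS = 5
INSTABILITY_WINDOW_BINS = 8 * BINS_PER_HOUR
NEVER_MEASURED_SENTINEL = 1e5  # minutes

APACHE_GROUPS = (
    "cardiovascular",
    "respiratory",
    "gastrointestinal",
    "neurologic",
    "trauma",
    "metabolic",
    "renal",
    "other",
)


@dataclass
class FeatureMatrix:
    frame: pd.DataFrame  # index: (stay id, bin)
    manifest: list[dict]  # per column: name, category, variable, horizon

    @property
    def feature_columns(self) -> list[str]:
        return [m["name"] for m in self.manifest]

    def variable_of(self, column: str) -> str:
        for m in self.manifest:
            if m["name"] == column:
                return m["variable"]
        raise KeyError(column)


def _rolling_sum(a: np.ndarray, window: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(a, dtype=float)])
    t = np.arange(len(a))
    start = np.maximum(t + 1 - window, 0)
    return c[t + 1] - c[start]


def admitted_horizons(
    variable_id: str, schema: Schema, stats: TrainingStats, horizons_h=MULTIRES_HORIZONS_H
) -> list[int]:
    """Hours from ``horizons_h`` whose expected measurement count (horizon /
    training-set median interval) reaches 5. Important variables keep every
    admissible horizon, others only the shortest one."""
    med = stats.median_intervals_min.get(variable_id, float("inf"))
    ok = [h for h in horizons_h if med > 0 and (h * 60.0) / med >= MIN_EXPECTED_MEASUREMENTS]
    if not ok:
        return []
    if schema[variable_id].is_important:
        return ok
    return [ok[0]]


def multires_summaries(
    values: np.ndarray, kind: VarKind, horizons_h, prefix: str
) -> dict[str, np.ndarray]:
    """Trailing median/IQR/trend (ordinal), mean (binary) or mode
    (categorical) per admitted horizon; windows are clipped at admission and
    skip missing values; empty windows yield NaN."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    out: dict[str, np.ndarray] = {}
    s = pd.Series(v)
    mask = (~np.isnan(v)).astype(float)
    x = np.arange(n, dtype=float)
    vf = np.nan_to_num(v)
    for h in horizons_h:
        w = h * BINS_PER_HOUR
        if kind is VarKind.ORDINAL:
            r = s.rolling(w, min_periods=1)
            out[f"{prefix}|med{h}h"] = r.median().to_numpy()
            out[f"{prefix}|iqr{h}h"] = (
                r.quantile(0.75).to_numpy() - r.quantile(0.25).to_numpy()
            )
            # OLS slope over non-missing points, per 5-min bin
            sm = _rolling_sum(mask, w)
            sx = _rolling_sum(x * mask, w)
            sy = _rolling_sum(vf * mask, w)
            sxy = _rolling_sum(x * vf * mask, w)
            sxx = _rolling_sum(x * x * mask, w)
            with np.errstate(divide="ignore", invalid="ignore"):
                denom = sxx - sx * sx / sm
                slope = (sxy - sx * sy / sm) / denom
            slope[(sm < 2) | ~np.isfinite(slope)] = np.nan
            slope[(sm >= 2) & np.isclose(np.nan_to_num(denom), 0)] = np.nan
            out[f"{prefix}|trend{h}h"] = slope
        elif kind is VarKind.BINARY:
            out[f"{prefix}|mean{h}h"] = s.rolling(w, min_periods=1).mean().to_numpy()
        else:  # categorical: rolling mode, lowest code on ties
            codes = np.unique(v[~np.isnan(v)])
            if codes.size == 0:
                out[f"{prefix}|mode{h}h"] = np.full(n, np.nan)
            else:
                counts = np.stack(
                    [_rolling_sum((v == c).astype(float), w) for c in codes]
                )
                best = np.argmax(counts, axis=0)
                mode = codes[best]
                mode[counts.sum(axis=0) == 0] = np.nan
                out[f"{prefix}|mode{h}h"] = mode
    return out


def intensity_features(
    measured: np.ndarray, time_since: np.ndarray, horizons_h, prefix: str
) -> dict[str, np.ndarray]:
    """Time-to-last-measurement (sentinel when never measured) and the
    per-horizon measurement density in observations per hour."""
    tsm = np.asarray(time_since, dtype=float).copy()
    tsm[tsm < 0] = NEVER_MEASURED_SENTINEL
    out = {f"{prefix}|tsl": tsm}
    m = np.asarray(measured, dtype=float)
    for h in horizons_h:
        w = h * BINS_PER_HOUR
        out[f"{prefix}|dens{h}h"] = _rolling_sum(m, w) / float(h)
    return out


def instability_history(
    dense_values: np.ndarray, variable_id: str, schema: Schema, prefix: str
) -> dict[str, np.ndarray]:
    """Fraction of time in each declared severity level over the trailing
    8 h (current bin included) and over the stay so far."""
    spec = schema[variable_id]
    if not spec.severity_levels:
        return {}
    levels = schema.severity_level_of(variable_id, dense_values)
    n = len(levels)
    t = np.arange(n, dtype=float)
    out: dict[str, np.ndarray] = {}
    for k in range(1, len(spec.severity_levels) + 1):
        flag = (levels >= k).astype(float)
        w = INSTABILITY_WINDOW_BINS
        wsize = np.minimum(t + 1, w)
        out[f"{prefix}|frac_l{k}_8h"] = _rolling_sum(flag, w) / wsize
        out[f"{prefix}|frac_l{k}_stay"] = np.cumsum(flag) / (t + 1)
    return out


def _encode_static(name: str, value) -> float:
    if name == "sex":
        return {"M": 1.0, "F": 0.0}.get(value, np.nan)
    if name == "apache_group":
        try:
            return float(APACHE_GROUPS.index(value))
        except ValueError:
            return float(len(APACHE_GROUPS))
    try:
        return float(value)
    except (TypeError, ValueError):
        return np.nan


def assemble_features(
    grid_feature: GriddedStay,
    schema: Schema,
    stats: TrainingStats,
    vent: np.ndarray,
    fio2_est: np.ndarray,
    grid_dense: GriddedStay | None = None,
) -> FeatureMatrix:
    """Full feature matrix for one stay.

    ``grid_feature`` supplies current values and summaries (missingness
    preserved); ``grid_dense`` (optional) supplies the instability-history
    level tracks.
    """
    n = grid_feature.n_steps
    cols: dict[str, np.ndarray] = {}
    manifest: list[dict] = []

    def add(name, arr, category, variable, horizon=None):
        cols[name] = np.asarray(arr, dtype=float)
        manifest.append(
            {"name": name, "category": category, "variable": variable, "horizon": horizon}
        )

    # time since admission (minutes)
    offset = (grid_feature.grid_start - grid_feature.admission_time).total_seconds() / 60.0
    add(
        "time_since_admission",
        offset + np.arange(n, dtype=float) * GRID_STEP_MIN,
        "time_since_admission",
        "time_since_admission",
    )
    # endpoint-derived
    add("fio2_est", fio2_est, "endpoint_derived", "fio2_est")
    add("vent_status", np.asarray(vent, dtype=float), "endpoint_derived", "vent_status")

    for spec in schema:
        vid = spec.variable_id
        add(vid, grid_feature.values[vid], "current", vid)
        horizons = admitted_horizons(vid, schema, stats)
        if horizons:
            for name, arr in multires_summaries(
                grid_feature.values[vid], spec.kind, horizons, vid
            ).items():
                h = int(re.search(r"(\d+)h$", name).group(1))
                add(name, arr, "multires", vid, h)
        for name, arr in intensity_features(
            grid_feature.measured[vid], grid_feature.time_since[vid], horizons, vid
        ).items():
            add(name, arr, "intensity", vid)
        if spec.severity_levels and spec.is_important and grid_dense is not None:
            for name, arr in instability_history(
                grid_dense.values[vid], vid, schema, vid
            ).items():
                add(name, arr, "instability", vid)

    for sname in ("age", "apache_group", "sex", "emergency", "surgical", "height"):
        val = _encode_static(sname, grid_feature.statics.get(sname))
        add(f"static|{sname}", np.full(n, val), "static", sname)

    frame = pd.DataFrame(cols)
    frame.insert(0, "stay_id", grid_feature.patient_id)
    frame.insert(1, "bin", np.arange(n))
    return FeatureMatrix(frame=frame, manifest=manifest)


def concat_features(mats: list[FeatureMatrix]) -> FeatureMatrix:
    if not mats:
        raise ValueError("no feature matrices")
    names = [m["name"] for m in mats[0].manifest]
    for fm in mats[1:]:
        if [m["name"] for m in fm.manifest] != names:
            raise ValueError("inconsistent feature columns across stays")
    frame = pd.concat([fm.frame for fm in mats], ignore_index=True)
    return FeatureMatrix(frame=frame, manifest=mats[0].manifest)
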