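"""Long-format table ingestion/serialisation (CSV or Parquet by extension)."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .pipeline import ProcessedCohort
from .schema import StayRecord

OBS_COLUMNS = ["patientid", "datetime", "variableid", "value"]
STATIC_COLUMNS = [
    "patientid",
    "admissiontime",
    "dischargetime",
    "deathtime",
    "age",
    "sex",
    "height",
    "emergency",
    "surgical",
    "apache_group",
    "elective",
]


def _write(df: pd.DataFrame, path) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def _read(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def stays_to_tables(stays: list[StayRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    obs_rows = []
    static_rows = []
    for s in stays:
        for vid, (t, v) in s.observations.items():
            obs_rows.append(
                pd.DataFrame(
                    {
                        "patientid": s.patient_id,
                        "datetime": pd.DatetimeIndex(t),
                        "variableid": vid,
                        "value": v,
                    }
                )
            )
        static_rows.append(
            {
                "patientid": s.patient_id,
                "admissiontime": s.admission_time,
                "dischargetime": s.discharge_time,
                "deathtime": s.death_time,
                "age": s.age,
                "sex": s.sex,
                "height": s.height,
                "emergency": s.emergency,
                "surgical": s.surgical,
                "apache_group": s.apache_group,
                "elective": s.elective,
            }
        )
    obs = (
        pd.concat(obs_rows, ignore_index=True)
        if obs_rows
        else pd.DataFrame(columns=OBS_COLUMNS)
    )
    obs = obs.sort_values(["patientid", "variableid", "datetime"], kind="stable")
    return obs.reset_index(drop=True), pd.DataFrame(static_rows)


def write_stays(stays: list[StayRecord], obs_path, statics_path) -> None:
    obs, statics = stays_to_tables(stays)
    _write(obs, obs_path)
    _write(statics, statics_path)


def read_stays(obs_path, statics_path) -> list[StayRecord]:
    obs = _read(obs_path)
    statics = _read(statics_path)
    obs["datetime"] = pd.to_datetime(obs["datetime"])
    out = []
    grouped = dict(tuple(obs.groupby("patientid")))
    for _, row in statics.iterrows():
        pid = row["patientid"]
        g = grouped.get(pid)
        observations = {}
        if g is not None:
            for vid, sub in g.groupby("variableid"):
                sub = sub.sort_values("datetime", kind="stable")
                observations[vid] = (
                    pd.DatetimeIndex(sub["datetime"]),
                    sub["value"].to_numpy(dtype=float),
                )
        death = row.get("deathtime")
        if pd.isna(death):
            death = None
        out.append(
            StayRecord(
                patient_id=str(pid),
                admission_time=pd.Timestamp(row["admissiontime"]),
                discharge_time=pd.Timestamp(row["dischargetime"]),
                death_time=death,
                age=float(row["age"]),
                sex=str(row["sex"]),
                height=float(row["height"]),
                emergency=bool(row["emergency"]),
                surgical=bool(row["surgical"]),
                apache_group=str(row["apache_group"]),
                elective=bool(row["elective"]),
                observations=observations,
            )
        )
    return out


def gridded_frame(cohort: ProcessedCohort) -> pd.DataFrame:
    """Gridded stays with endpoint and P/F tracks as one tall frame."""
    frames = []
    for p in cohort.stays:
        g = p.grid_dense
        df = pd.DataFrame({vid: g.values[vid] for vid in cohort.schema.variable_ids})
        df.insert(0, "stay_id", p.stay_id)
        df.insert(1, "bin", np.arange(g.n_steps))
        df["pf"] = p.pf.pf
        df["pao2_est"] = p.pf.pao2_est
        df["fio2_est"] = p.pf.fio2_est
        df["rf_status"] = p.endpoints.rf_status
        df["vent"] = p.endpoints.vent.astype(int)
        df["rext"] = p.endpoints.rext.astype(int)
        for task, lt in p.labels.items():
            df[f"label_{task}"] = lt.label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_gridded(cohort: ProcessedCohort, out_dir, n_batches: int = 1, fmt: str = "csv") -> list[pathlib.Path]:
    """Batched export of the gridded cohort (mirrors batched processing)."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = gridded_frame(cohort)
    ids = frame["stay_id"].unique()
    paths = []
    for b, chunk in enumerate(np.array_split(ids, max(1, n_batches))):
        part = frame[frame["stay_id"].isin(chunk)]
        path = out_dir / f"gridded_batch{b:03d}.{fmt}"
        _write(part, path)
        paths.append(path)
    return paths


def event_table(cohort: ProcessedCohort) -> pd.DataFrame:
    """BED-like interval export of respiratory-failure and ventilation events."""
    rows = []
    for p in cohort.stays:
        for s, e, lvl in p.endpoints.rf_event_list:
            rows.append((p.stay_id, s, e, f"rf_level_{lvl}"))
        for s, e in p.endpoints.vent_event_list:
            rows.append((p.stay_id, s, e, "ventilation"))
    return pd.DataFrame(rows, columns=["stay_id", "start_bin", "end_bin", "status"])
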