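"""Seeded end-to-end experiments used by the acceptance suite and report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .alarms import detectable_prevalence, event_pr_curve
from .gridding import TrainingStats
from .modeling import make_splits, train_task_model
from .pipeline import process_cohort
from .resource import (
    StayCensusInfo,
    build_census,
    persistence_baseline,
    realized_max_vent,
    train_resource_model,
)
from .schema import default_schema
from .simulate import SimConfig, simulate_cohort


@dataclass
class RFExperimentResult:
    event_auprc: float
    shuffled_auprc: float
    detectable_prevalence: float
    n_stays: int
    n_events: int
    val_auprc: float


def run_rf_experiment(
    n_stays: int = 2000,
    seed: int = 1,
    row_stride: int = 2,
    n_prevalence_sim: int = 20,
    sim_config: Optional[SimConfig] = None,
) -> RFExperimentResult:
    """simulate -> grid -> annotate -> label -> featurize -> train ->
    event-based evaluation of the failure-onset model on validation stays,
    against a shuffled-label control and the detectable-prevalence floor."""
    cfg = sim_config or SimConfig(n_stays=n_stays, seed=seed)
    stays, _truth = simulate_cohort(cfg)
    schema = default_schema()
    splits = make_splits([s.patient_id for s in stays], n_replicates=1, seed=seed)
    train_ids, val_ids = splits.replicates[0]
    train_set, val_set = set(train_ids), set(val_ids)
    stats = TrainingStats.fit([s for s in stays if s.patient_id in train_set], schema)

    # stream stays: keep float32 frames only (thinned for training stays,
    # full resolution for validation stays); held-out test stays are unused
    from .features import FeatureMatrix
    from .pipeline import process_stay

    frames, labels_parts = [], []
    val_frames: dict[str, pd.DataFrame] = {}
    val_eval: dict[str, tuple[np.ndarray, list[int]]] = {}
    manifest = None
    for s in stays:
        if s.patient_id not in train_set and s.patient_id not in val_set:
            continue
        p = process_stay(s, schema, stats, with_features=True)
        fm = p.features
        manifest = fm.manifest
        cast = {m["name"]: np.float32 for m in fm.manifest}
        lab = p.labels["RF"].label
        if s.patient_id in val_set:
            f32 = fm.frame.astype(cast)
            val_frames[s.patient_id] = f32
            val_eval[s.patient_id] = (p.rf_in_event(), p.rf_onsets())
            frames.append(f32)
            labels_parts.append(lab)
        else:
            keep = np.arange(len(fm.frame)) % row_stride == 0
            frames.append(fm.frame[keep].astype(cast))
            labels_parts.append(lab[keep])
        del p, fm
    fm_thin = FeatureMatrix(frame=pd.concat(frames, ignore_index=True), manifest=manifest)
    del frames
    labels_thin = np.concatenate(labels_parts)

    tm = train_task_model("RF", fm_thin, labels_thin, train_ids, val_ids, seed=seed)

    rng = np.random.default_rng(seed + 17)
    labels_shuffled = labels_thin.copy()
    defined = labels_shuffled >= 0
    labels_shuffled[defined] = rng.permutation(labels_shuffled[defined])
    tm_null = train_task_model(
        "RF-null", fm_thin, labels_shuffled, train_ids, val_ids, seed=seed, max_rounds=60
    )
    del fm_thin

    scores, null_scores, in_event, onsets = [], [], [], []
    for sid, frame in val_frames.items():
        scores.append(tm.predict_scores(frame))
        null_scores.append(tm_null.predict_scores(frame))
        ev, on = val_eval[sid]
        in_event.append(ev)
        onsets.append(on)
    curve = event_pr_curve(scores, in_event, onsets)
    null_curve = event_pr_curve(null_scores, in_event, onsets)
    prev = detectable_prevalence(in_event, onsets, n_sim=n_prevalence_sim, seed=seed)
    return RFExperimentResult(
        event_auprc=curve.auprc,
        shuffled_auprc=null_curve.auprc,
        detectable_prevalence=prev,
        n_stays=len(stays),
        n_events=sum(len(o) for o in onsets),
        val_auprc=tm.val_auprc,
    )


def heuristic_scores(processed) -> dict[str, np.ndarray]:
    """Cheap rule-based stand-ins for the four task scores, used to feed the
    resource planner without training four upstream models."""
    pf = processed.pf.pf
    vent = processed.endpoints.vent.astype(float)
    rext = processed.endpoints.rext.astype(float)
    rf = np.clip((300.0 - pf) / 250.0, 0.0, 1.0)
    return {
        "RF": rf,
        "EF": np.clip(processed.endpoints.rext_violation / 20.0, 0, 1),
        "MVStart": np.clip(rf * (1.0 - vent), 0, 1),
        "MVEnd": rext,
    }


@dataclass
class ResourceRunResult:
    mae_model: float
    mae_baseline: float
    n_hours: int


def run_resource_experiment(
    n_stays: int = 420,
    seed: int = 0,
    horizon: tuple[int, int] = (8, 16),
    admission_days: float = 28.0,
    train_fraction: float = 0.6,
) -> ResourceRunResult:
    """Simulated unit with diurnal admission/ventilation cycles; the trained
    forecaster is compared with the persistence baseline out-of-time (the
    model is fitted on the first part of the census period)."""
    cfg = SimConfig(
        n_stays=n_stays,
        seed=seed,
        admission_days=admission_days,
        diurnal_amplitude=0.8,
    )
    stays, _ = simulate_cohort(cfg)
    schema = default_schema()
    cohort = process_cohort(stays, schema, with_features=False)
    by_raw = {s.patient_id: s for s in stays}
    infos = []
    for p in cohort.stays:
        raw = by_raw[p.stay_id]
        infos.append(
            StayCensusInfo(
                stay_id=p.stay_id,
                admission_time=raw.admission_time,
                discharge_time=raw.discharge_time,
                elective=raw.elective,
                grid_start=p.grid_dense.grid_start,
                vent=p.endpoints.vent,
                scores=heuristic_scores(p),
            )
        )
    census = build_census(infos)
    n_train = int(train_fraction * len(census))
    census_train = census.iloc[:n_train]
    model = train_resource_model(
        infos, census_train, horizon, seed=seed, min_hours=min(n_train, 30 * 24)
    )
    errs_m, errs_b = [], []
    for h_idx in range(n_train, len(census) - horizon[1]):
        realized = realized_max_vent(census, h_idx, horizon)
        if realized is None:
            continue
        errs_m.append(abs(model.forecast(infos, census, h_idx) - realized))
        errs_b.append(abs(persistence_baseline(census, h_idx) - realized))
    return ResourceRunResult(
        mae_model=float(np.mean(errs_m)),
        mae_baseline=float(np.mean(errs_b)),
        n_hours=len(errs_m),
    )
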