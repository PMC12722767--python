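"""End-to-end orchestration: raw stay -> gridded -> annotated -> labelled ->
feature matrix, plus cohort-level helpers used by the CLI and experiments."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .endpoints import (
    EndpointTracks,
    annotate_rext,
    annotate_rf,
    correct_right_edges,
    hr_nearby_flags,
    postprocess_rf,
    postprocess_ventilation,
    rext_violation_track,
    rf_events,
    vote_ventilation_track,
)
from .features import FeatureMatrix, assemble_features, concat_features
from .gridding import GriddedStay, TrainingStats, build_grid, impute
from .labels import (
    LabelTrack,
    label_extubations,
    label_mv_end,
    label_mv_start,
    label_rf_onset,
)
from .oxygenation import PaO2Estimator, PFTrack, build_pf_track
from .schema import Schema, StayRecord


@dataclass
class PipelineConfig:
    moderate_pf_threshold: float = 200.0  # sensitivity variant: 150
    pf_bandwidth: float = 20.0
    use_sf_ratio: bool = False  # S/F-based annotation variant
    sf_threshold: float = 235.0


@dataclass
class ProcessedStay:
    stay_id: str
    grid_dense: GriddedStay
    grid_feature: GriddedStay
    pf: PFTrack
    endpoints: EndpointTracks
    labels: dict[str, LabelTrack]
    features: Optional[FeatureMatrix] = None

    @property
    def n_steps(self) -> int:
        return self.grid_dense.n_steps

    def rf_onsets(self) -> list[int]:
        return [s for s, _e, _v in rf_events(self.endpoints.rf_status)]

    def rf_in_event(self) -> np.ndarray:
        return self.endpoints.rf_status >= 2


def process_stay(
    stay: StayRecord,
    schema: Schema,
    stats: TrainingStats,
    estimator: Optional[PaO2Estimator] = None,
    config: Optional[PipelineConfig] = None,
    with_features: bool = True,
) -> ProcessedStay:
    """Run the full annotation pipeline on one stay.

    Ventilation voting and the readiness criteria read the feature-imputed
    grid (missing inputs contribute nothing); P/F-based rules read the
    densely imputed tracks.
    """
    cfg = config or PipelineConfig()
    grid = build_grid(stay, schema)
    gd = impute(grid, schema, "dense", stats)
    gf = impute(grid, schema, "feature", stats)

    vent_score, vent_raw = vote_ventilation_track(gf)
    vent = postprocess_ventilation(vent_raw, grid, trach_track=gd.values["trach"])

    pf = build_pf_track(gd, vent, estimator=estimator, bandwidth=cfg.pf_bandwidth)
    if cfg.use_sf_ratio:
        # annotate directly on the (smoothed) S/F ratio with its own cutoff
        from .oxygenation import pf_track as _smooth

        sf = _smooth(gd.values["spo2"], pf.fio2_est, bandwidth=cfg.pf_bandwidth)
        rf_input, moderate_thr = sf, cfg.sf_threshold
    else:
        rf_input, moderate_thr = pf.pf, cfg.moderate_pf_threshold

    rf0 = annotate_rf(rf_input, vent, gf.values["peep"], moderate_threshold=moderate_thr)
    rf1 = correct_right_edges(rf0, rf_input, moderate_threshold=moderate_thr)
    rf = postprocess_rf(rf1)

    rext_scores = rext_violation_track(gf, pf.pf, pf.fio2_est)
    rext = annotate_rext(rext_scores, vent)

    endpoints = EndpointTracks(
        rf_status=rf,
        vent=vent,
        vent_score=vent_score,
        rext=rext,
        rext_violation=rext_scores,
    )
    hr_near = hr_nearby_flags(grid)
    labels = {
        "RF": label_rf_onset(rf),
        "MVStart": label_mv_start(vent),
        "MVEnd": label_mv_end(vent, rext),
        "EF": label_extubations(vent, gd, hr_near, trach_track=gd.values["trach"]),
    }
    features = None
    if with_features:
        features = assemble_features(
            gf, schema, stats, vent, pf.fio2_est, grid_dense=gd
        )
    return ProcessedStay(
        stay_id=stay.patient_id,
        grid_dense=gd,
        grid_feature=gf,
        pf=pf,
        endpoints=endpoints,
        labels=labels,
        features=features,
    )


@dataclass
class ProcessedCohort:
    stays: list[ProcessedStay]
    schema: Schema
    stats: TrainingStats

    def by_id(self) -> dict[str, ProcessedStay]:
        return {p.stay_id: p for p in self.stays}

    def feature_matrix(self) -> FeatureMatrix:
        return concat_features([p.features for p in self.stays if p.features is not None])

    def label_array(self, task: str) -> np.ndarray:
        return np.concatenate([p.labels[task].label for p in self.stays])


def process_cohort(
    stays: list[StayRecord],
    schema: Schema,
    stats: Optional[TrainingStats] = None,
    estimator: Optional[PaO2Estimator] = None,
    config: Optional[PipelineConfig] = None,
    with_features: bool = True,
    stats_stays: Optional[list[StayRecord]] = None,
) -> ProcessedCohort:
    """Process a cohort; training statistics default to being fitted on
    ``stats_stays`` (or, failing that, on the cohort itself)."""
    if stats is None:
        stats = TrainingStats.fit(stats_stays if stats_stays is not None else stays, schema)
    processed = [
        process_stay(s, schema, stats, estimator, config, with_features) for s in stays
    ]
    return ProcessedCohort(stays=processed, schema=schema, stats=stats)


def fit_pao2_estimator_on_cohort(
    train_stays: list[StayRecord],
    val_stays: list[StayRecord],
    schema: Schema,
    stats: TrainingStats,
) -> PaO2Estimator:
    """Grid the raw stays and fit the nested PaO2 estimator."""
    gtr = [impute(build_grid(s, schema), schema, "dense", stats) for s in train_stays]
    gva = [impute(build_grid(s, schema), schema, "dense", stats) for s in val_stays]
    est = PaO2Estimator()
    est.fit(gtr, gva)
    return est
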