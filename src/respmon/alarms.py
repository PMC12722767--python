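"""Alarm generation policy and event-based evaluation.

Alarms fire outside failure events when the score crosses a threshold, are
silenced for 4 h, and the silencing state resets on event recovery with a
30-min re-arm delay. Evaluation pairs alarms and event onsets within the
task horizon (event recall / alarm precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .schema import BINS_PER_HOUR

SILENCE_BINS = 4 * BINS_PER_HOUR  # 4 h
REARM_BINS = 30 // 5  # 30 min after event recovery
EVAL_HORIZON_BINS = 24 * BINS_PER_HOUR


@dataclass
class AlarmTrace:
    alarm_bins: np.ndarray
    n_bins: int


def generate_alarms(
    scores: np.ndarray,
    in_event: np.ndarray,
    threshold: float,
    silence_bins: int = SILENCE_BINS,
    rearm_bins: int = REARM_BINS,
) -> AlarmTrace:
    """Scan one stay: fire where not in an event, the score reaches the
    threshold, and the system is neither silenced (4 h after an alarm) nor
    within the 30-min re-arm window after event recovery."""
    s = np.asarray(scores, dtype=float)
    ev = np.asarray(in_event, dtype=bool)
    n = len(s)
    alarms = []
    allowed_from = 0  # re-arm gate after recovery
    silenced_until = 0
    prev_in_event = False
    for t in range(n):
        if ev[t]:
            prev_in_event = True
            continue
        if prev_in_event:
            # recovery: reset silencing, allow firing 30 min later
            allowed_from = t + rearm_bins
            silenced_until = 0
            prev_in_event = False
        if t < allowed_from or t < silenced_until:
            continue
        if not np.isnan(s[t]) and s[t] >= threshold:
            alarms.append(t)
            silenced_until = t + silence_bins
    return AlarmTrace(alarm_bins=np.asarray(alarms, dtype=np.int64), n_bins=n)


@dataclass
class EventPRPoint:
    threshold: float
    recall: float
    precision: Optional[float]
    tp_alarms: int
    fp_alarms: int
    caught_events: int
    total_events: int

    @property
    def n_alarms(self) -> int:
        return self.tp_alarms + self.fp_alarms


def event_metrics(
    alarm_bins_per_stay: list[np.ndarray],
    event_onsets_per_stay: list[Sequence[int]],
    horizon: int = EVAL_HORIZON_BINS,
    threshold: float = np.nan,
) -> EventPRPoint:
    """An alarm is true iff an event onset occurs within ``horizon`` bins
    after it; an event is caught iff at least one alarm precedes its onset
    by at most ``horizon``. Precision is undefined (None) with no alarms."""
    tp = fp = caught = total = 0
    for alarms, onsets in zip(alarm_bins_per_stay, event_onsets_per_stay):
        alarms = np.asarray(alarms, dtype=np.int64)
        onsets = np.asarray(list(onsets), dtype=np.int64)
        total += len(onsets)
        for a in alarms:
            if np.any((onsets > a) & (onsets <= a + horizon)):
                tp += 1
            else:
                fp += 1
        for o in onsets:
            if np.any((alarms < o) & (alarms >= o - horizon)):
                caught += 1
    recall = caught / total if total else 0.0
    precision = tp / (tp + fp) if (tp + fp) else None
    return EventPRPoint(
        threshold=float(threshold),
        recall=float(recall),
        precision=precision,
        tp_alarms=tp,
        fp_alarms=fp,
        caught_events=caught,
        total_events=total,
    )


@dataclass
class EventPRCurve:
    points: list[EventPRPoint]

    @property
    def auprc(self) -> float:
        """Step integration of precision over recall (threshold-descending)."""
        pts = [p for p in self.points if p.precision is not None]
        # ties in recall resolve to the highest-threshold point (stable sort)
        pts = sorted(pts, key=lambda p: (-p.threshold if np.isfinite(p.threshold) else 0.0))
        area, prev_r = 0.0, 0.0
        for p in sorted(pts, key=lambda p: p.recall):
            if p.recall > prev_r:
                area += (p.recall - prev_r) * p.precision
                prev_r = p.recall
        return area

    def precision_at_recall(self, target: float) -> Optional[float]:
        pts = [p for p in self.points if p.precision is not None and p.recall >= target]
        if not pts:
            return None
        return max(p.precision for p in pts)

    def threshold_at_recall(self, target: float) -> Optional[float]:
        pts = [p for p in self.points if p.recall >= target]
        if not pts:
            return None
        return max(p.threshold for p in pts)


def event_pr_curve(
    scores_per_stay: list[np.ndarray],
    in_event_per_stay: list[np.ndarray],
    event_onsets_per_stay: list[Sequence[int]],
    thresholds: Optional[np.ndarray] = None,
    horizon: int = EVAL_HORIZON_BINS,
) -> EventPRCurve:
    if thresholds is None:
        alls = np.concatenate([np.asarray(s)[~np.isnan(s)] for s in scores_per_stay])
        thresholds = np.quantile(alls, np.linspace(0.01, 0.99, 40))
        thresholds = np.unique(thresholds)
    points = []
    for thr in thresholds:
        alarms = [
            generate_alarms(s, ev, thr).alarm_bins
            for s, ev in zip(scores_per_stay, in_event_per_stay)
        ]
        points.append(event_metrics(alarms, event_onsets_per_stay, horizon, threshold=thr))
    return EventPRCurve(points=points)


def earliness_fractions(
    alarm_bins_per_stay: list[np.ndarray],
    event_onsets_per_stay: list[Sequence[int]],
    stability_bins_per_stay: Optional[list[np.ndarray]] = None,
    cutoffs_h: Sequence[float] = (0, 2, 4, 6, 8, 10, 12, 16, 20),
    horizon: int = EVAL_HORIZON_BINS,
    stability_min_bins: int = 24 * BINS_PER_HOUR,
) -> dict[float, float]:
    """Per cutoff h: fraction of qualifying events whose earliest in-horizon
    alarm precedes onset by at least h hours. Qualifying events have at
    least ``stability_min_bins`` of non-event time immediately before onset
    (always true when no stability track is given)."""
    lead_times = []
    for si, (alarms, onsets) in enumerate(zip(alarm_bins_per_stay, event_onsets_per_stay)):
        alarms = np.asarray(alarms, dtype=np.int64)
        for o in onsets:
            if stability_bins_per_stay is not None:
                stable = stability_bins_per_stay[si]
                pre = stable[max(0, o - stability_min_bins): o]
                if len(pre) < stability_min_bins or not np.all(pre):
                    continue
            in_h = alarms[(alarms < o) & (alarms >= o - horizon)]
            lead_times.append((o - in_h.max()) if len(in_h) else -1)
    lead_times = np.asarray(lead_times, dtype=float)
    out = {}
    n = len(lead_times)
    for h in cutoffs_h:
        if n == 0:
            out[float(h)] = 0.0
        else:
            out[float(h)] = float(np.mean(lead_times >= h * BINS_PER_HOUR))
    return out


def detectable_prevalence(
    in_event_per_stay: list[np.ndarray],
    event_onsets_per_stay: list[Sequence[int]],
    n_sim: int = 50,
    seed: int = 0,
    horizon: int = EVAL_HORIZON_BINS,
    thresholds: Optional[np.ndarray] = None,
) -> float:
    """Chance floor: mean event-based AUPRC of uniform random scores."""
    total_events = sum(len(list(o)) for o in event_onsets_per_stay)
    if total_events == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    if thresholds is None:
        thresholds = np.linspace(0.025, 0.975, 20)
    aucs = []
    for _ in range(n_sim):
        scores = [rng.uniform(size=len(ev)) for ev in in_event_per_stay]
        curve = event_pr_curve(
            scores, in_event_per_stay, event_onsets_per_stay, thresholds, horizon
        )
        aucs.append(curve.auprc)
    return float(np.mean(aucs))


def prevalence_scaling_factor(prev_target: float, prev_source: float) -> float:
    """s = (1/prev_target - 1) / (1/prev_source - 1)."""
    for p in (prev_target, prev_source):
        if not (0.0 < p < 1.0):
            raise ValueError("prevalences must lie strictly between 0 and 1")
    return (1.0 / prev_target - 1.0) / (1.0 / prev_source - 1.0)


def prevalence_correct(curve: EventPRCurve, prev_source: float, prev_target: float) -> EventPRCurve:
    """Rescale false-alarm counts so precision is comparable at the target
    prevalence; recall is unchanged."""
    s = prevalence_scaling_factor(prev_target, prev_source)
    points = []
    for p in curve.points:
        if p.precision is None:
            points.append(p)
            continue
        fp_scaled = s * p.fp_alarms
        denom = p.tp_alarms + fp_scaled
        prec = p.tp_alarms / denom if denom > 0 else None
        points.append(
            EventPRPoint(
                threshold=p.threshold,
                recall=p.recall,
                precision=prec,
                tp_alarms=p.tp_alarms,
                fp_alarms=fp_scaled,  # carried so the correction is invertible
                caught_events=p.caught_events,
                total_events=p.total_events,
            )
        )
    return EventPRCurve(points=points)


# ---------------------------------------------------------------------------
# subgroup / fairness bootstrap
# ---------------------------------------------------------------------------

@dataclass
class SubgroupResult:
    group: str
    n_stays: int
    metric_samples: np.ndarray
    p_value: Optional[float]
    worse_off: bool


def subgroup_bootstrap(
    metric_fn,
    stay_ids: Sequence,
    grouping: dict,
    n_boot: int = 100,
    seed: int = 0,
    alpha: float = 0.001,
) -> list[SubgroupResult]:
    """Patient-level bootstrap of a metric per group vs its complement.

    ``metric_fn(selected_ids)`` recomputes the metric (with any per-group
    threshold recalibration inside); groups significantly worse than their
    complement under a one-sided Mann-Whitney U test (Bonferroni-corrected
    across groups) are flagged.
    """
    ids = np.asarray(list(stay_ids), dtype=object)
    groups = sorted(set(grouping.values()))
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {g: [] for g in groups}
    comp_samples: dict[str, list[float]] = {g: [] for g in groups}
    for _ in range(n_boot):
        boot = rng.choice(ids, size=len(ids), replace=True)
        for g in groups:
            sel = [i for i in boot if grouping.get(i) == g]
            other = [i for i in boot if grouping.get(i) != g]
            m = metric_fn(sel)
            mo = metric_fn(other)
            if m is not None:
                samples[g].append(m)
            if mo is not None:
                comp_samples[g].append(mo)
    results = []
    n_tests = max(1, len(groups))
    for g in groups:
        a = np.asarray(samples[g], dtype=float)
        b = np.asarray(comp_samples[g], dtype=float)
        n_g = sum(1 for i in ids if grouping.get(i) == g)
        if len(a) == 0 or len(b) == 0:
            results.append(SubgroupResult(g, n_g, a, None, False))
            continue
        try:
            stat = mannwhitneyu(a, b, alternative="less")
            p = float(stat.pvalue)
        except ValueError:
            p = 1.0
        p_corr = min(1.0, p * n_tests)
        results.append(SubgroupResult(g, n_g, a, p_corr, p_corr < alpha))
    return results
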