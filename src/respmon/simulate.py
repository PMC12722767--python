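"""Synthetic ICU cohort generator with known ground truth.

A per-stay latent respiratory state chain (stable, deteriorating, failure,
ventilated, weaning, ready, extubated) drives an Ornstein-Uhlenbeck-style
latent P/F trajectory. Observations are emitted at variable-specific
irregular rates; SpO2 derives from latent PaO2 through the haemoglobin
dissociation curve with a pH-dependent shift, so the oxygenation stack can
be validated against the latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .endpoints import runs
from .oxygenation import severinghaus
from .schema import (
    AIRWAY_INTUBATED,
    AIRWAY_TRACHEOSTOMY,
    GRID_STEP_MIN,
    MODE_CONTROLLED,
    MODE_SPONTANEOUS,
    StayRecord,
)

# latent states
ST_STABLE = 0
ST_DETER = 1
ST_RF = 2  # failure, not ventilated
ST_VENT = 3  # acute ventilation
ST_WEAN = 4
ST_READY = 5
ST_EXT = 6  # extubated, recovering in unit
N_STATES = 7

PF_TARGET = {
    ST_STABLE: 420.0,
    ST_DETER: 280.0,
    ST_RF: 140.0,
    ST_VENT: 170.0,
    ST_WEAN: 240.0,
    ST_READY: 310.0,
    ST_EXT: 360.0,
}


@dataclass
class SimConfig:
    n_stays: int = 100
    seed: int = 0
    start_date: str = "2014-01-06"  # a Monday
    admission_days: float = 30.0
    max_stay_bins: int = 4 * 24 * 12
    min_stay_bins: int = 6 * 12
    # per-5-min transition probabilities
    p_stable_deter: float = 0.004
    p_stable_discharge: float = 0.004
    p_deter_rf: float = 0.02
    p_deter_recover: float = 0.012
    p_rf_vent: float = 0.02
    p_rf_recover: float = 0.006
    p_vent_wean: float = 0.01
    p_wean_ready: float = 0.015
    p_wean_setback: float = 0.0015
    p_ready_extubate: float = 0.03
    p_ext_discharge: float = 0.01
    p_death_rf: float = 0.0004
    p_death_vent: float = 0.0002
    p_death_ext: float = 0.0002
    # latent dynamics
    ou_theta: float = 0.08
    ou_sigma: float = 4.0
    ph_sigma: float = 0.004
    ph_sick_drop: float = 0.05  # pH depression while in failure/ventilated
    # emission noise scales
    spo2_noise: float = 0.4
    pao2_noise: float = 2.5
    obs_dropout: float = 0.05  # missingness of dense vitals
    abga_rate_stable: float = 1.0 / 48.0
    abga_rate_unstable: float = 1.0 / 10.0
    # extubation failure logistic on (vent days, pf deficit, lactate)
    ef_intercept: float = -2.5
    ef_beta_vent_days: float = 0.5
    ef_beta_pf: float = 0.012  # per mmHg below 300 at extubation
    ef_beta_lactate: float = 0.4
    reintubation_min_bins: int = 24
    reintubation_max_bins: int = 40 * 12
    extubation_day_factor: float = 3.0  # day/night extubation-rate ratio
    # cohort composition
    elective_frac: float = 0.3
    trach_frac: float = 0.08
    pre2009_frac: float = 0.0
    offunit_gap_frac: float = 0.12
    # admission process (nonhomogeneous Poisson)
    diurnal_amplitude: float = 0.6
    weekend_factor: float = 0.6

    def validate(self):
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if isinstance(v, float) and f.startswith("p_") and not (0 <= v <= 1):
                raise ValueError(f"transition probability {f} out of [0,1]")
        if self.n_stays <= 0:
            raise ValueError("n_stays must be positive")


@dataclass
class StayTruth:
    states: np.ndarray
    pf_latent: np.ndarray
    fio2_latent: np.ndarray
    vent_latent: np.ndarray
    rf_intervals: list[tuple[int, int]]
    vent_intervals: list[tuple[int, int]]
    extubations: list[dict]  # bin, outcome in {"failure","success","death"}
    death_bin: Optional[int]


@dataclass
class SimTruth:
    stays: dict[str, StayTruth] = field(default_factory=dict)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _extubation_prob(cfg: SimConfig, hod0: float, t: int) -> float:
    """Extubations cluster in daytime (diurnal ventilation cycle)."""
    hod = (hod0 + t / 12.0) % 24.0
    f = cfg.extubation_day_factor
    return cfg.p_ready_extubate * (f if 8.0 <= hod < 20.0 else 1.0 / f)


def _latent_path(cfg: SimConfig, rng: np.random.Generator, elective: bool, hod0: float = 12.0):
    """Simulate the latent chain; returns (states, extubation events,
    death bin, reintubation bins)."""
    max_bins = int(cfg.max_stay_bins)
    states = np.empty(max_bins, dtype=np.int64)
    st = ST_STABLE
    vent_bins = 0
    exts: list[dict] = []
    death_bin = None
    reintubation_at = None
    t = 0
    while t < max_bins:
        states[t] = st
        u = rng.random()
        if st in (ST_VENT, ST_WEAN, ST_READY):
            vent_bins += 1
        if st == ST_STABLE:
            if u < cfg.p_stable_deter and not elective:
                st = ST_DETER
            elif t >= cfg.min_stay_bins and u < cfg.p_stable_deter + cfg.p_stable_discharge:
                t += 1
                break
        elif st == ST_DETER:
            if u < cfg.p_deter_rf:
                st = ST_RF
            elif u < cfg.p_deter_rf + cfg.p_deter_recover:
                st = ST_STABLE
        elif st == ST_RF:
            if u < cfg.p_death_rf:
                death_bin = t
                t += 1
                break
            elif u < cfg.p_death_rf + cfg.p_rf_vent:
                st = ST_VENT
            elif u < cfg.p_death_rf + cfg.p_rf_vent + cfg.p_rf_recover:
                st = ST_STABLE
        elif st == ST_VENT:
            if u < cfg.p_death_vent:
                death_bin = t
                t += 1
                break
            elif u < cfg.p_death_vent + cfg.p_vent_wean:
                st = ST_WEAN
        elif st == ST_WEAN:
            if u < cfg.p_wean_setback:
                st = ST_VENT
            elif u < cfg.p_wean_setback + cfg.p_wean_ready:
                st = ST_READY
        elif st == ST_READY:
            if u < _extubation_prob(cfg, hod0, t):
                # extubation outcome via the configured logistic model
                exts.append({"bin": t, "vent_bins": vent_bins})
                st = ST_EXT
                reintubation_at = None
        elif st == ST_EXT:
            if reintubation_at is None and exts and "fails" in exts[-1]:
                if exts[-1]["fails"]:
                    delay = rng.integers(
                        cfg.reintubation_min_bins, cfg.reintubation_max_bins
                    )
                    reintubation_at = exts[-1]["bin"] + 1 + delay
                else:
                    reintubation_at = -1
            if u < cfg.p_death_ext:
                death_bin = t
                t += 1
                break
            if reintubation_at is not None and reintubation_at >= 0 and t >= reintubation_at:
                st = ST_VENT
                reintubation_at = None
            elif u < cfg.p_ext_discharge and (
                reintubation_at is None or reintubation_at < 0
            ):
                t += 1
                break
        t += 1
    return states[:t], exts, death_bin


def _decide_extubation_outcomes(cfg, rng, states, exts, pf, lactate_latent):
    """Assign failure flags using the logistic model; mutates ``exts``."""
    for e in exts:
        b = e["bin"]
        z = (
            cfg.ef_intercept
            + cfg.ef_beta_vent_days * (e["vent_bins"] / (24.0 * 12.0))
            + cfg.ef_beta_pf * max(300.0 - pf[b], 0.0)
            + cfg.ef_beta_lactate * (lactate_latent[b] - 1.0)
        )
        e["p_fail"] = float(_sigmoid(z))
        e["fails"] = bool(rng.random() < e["p_fail"])


def ef_failure_probability(cfg: SimConfig, vent_bins: int, pf_at_ext: float, lactate: float) -> float:
    """Analytic failure probability of the generator's logistic model."""
    z = (
        cfg.ef_intercept
        + cfg.ef_beta_vent_days * (vent_bins / (24.0 * 12.0))
        + cfg.ef_beta_pf * max(300.0 - pf_at_ext, 0.0)
        + cfg.ef_beta_lactate * (lactate - 1.0)
    )
    return float(_sigmoid(z))


def _simulate_stay_path(cfg: SimConfig, rng, elective: bool, hod0: float = 12.0):
    """Two-pass simulation: a provisional path fixes extubation outcomes
    (which depend on the latent P/F), then the chain is re-run so failed
    extubations lead to re-intubation."""
    # pass 1: path without outcome knowledge
    state_rng = np.random.default_rng(rng.integers(2**63))
    states, exts, death_bin = _latent_path(cfg, state_rng, elective, hod0)
    pf, lact, ph = _latent_physiology(cfg, rng, states)
    _decide_extubation_outcomes(cfg, rng, states, exts, pf, lact)
    if any(e["fails"] for e in exts):
        # pass 2: replay the chain; failure flags now trigger re-intubation
        states2, exts2, death_bin = _latent_path_with_outcomes(
            cfg, np.random.default_rng(rng.integers(2**63)), elective, exts, hod0
        )
        states, exts = states2, exts2
        pf, lact, ph = _latent_physiology(cfg, rng, states)
    return states, exts, death_bin, pf, lact, ph


def _latent_path_with_outcomes(cfg, rng, elective, planned_exts, hod0: float = 12.0):
    """Replay the chain consuming pre-decided extubation outcomes in order."""
    max_bins = int(cfg.max_stay_bins)
    states = np.empty(max_bins, dtype=np.int64)
    st = ST_STABLE
    vent_bins = 0
    exts: list[dict] = []
    death_bin = None
    reintubation_at = None
    plan = list(planned_exts)
    t = 0
    while t < max_bins:
        states[t] = st
        u = rng.random()
        if st in (ST_VENT, ST_WEAN, ST_READY):
            vent_bins += 1
        if st == ST_STABLE:
            if u < cfg.p_stable_deter and not elective:
                st = ST_DETER
            elif t >= cfg.min_stay_bins and u < cfg.p_stable_deter + cfg.p_stable_discharge:
                t += 1
                break
        elif st == ST_DETER:
            if u < cfg.p_deter_rf:
                st = ST_RF
            elif u < cfg.p_deter_rf + cfg.p_deter_recover:
                st = ST_STABLE
        elif st == ST_RF:
            if u < cfg.p_death_rf:
                death_bin = t
                t += 1
                break
            elif u < cfg.p_death_rf + cfg.p_rf_vent:
                st = ST_VENT
            elif u < cfg.p_death_rf + cfg.p_rf_vent + cfg.p_rf_recover:
                st = ST_STABLE
        elif st == ST_VENT:
            if u < cfg.p_death_vent:
                death_bin = t
                t += 1
                break
            elif u < cfg.p_death_vent + cfg.p_vent_wean:
                st = ST_WEAN
        elif st == ST_WEAN:
            if u < cfg.p_wean_setback:
                st = ST_VENT
            elif u < cfg.p_wean_setback + cfg.p_wean_ready:
                st = ST_READY
        elif st == ST_READY:
            if u < _extubation_prob(cfg, hod0, t):
                planned = plan[len(exts)] if len(exts) < len(plan) else {}
                fails = bool(planned.get("fails", False))
                exts.append(
                    {
                        "bin": t,
                        "vent_bins": vent_bins,
                        "fails": fails,
                        "p_fail": planned.get("p_fail"),
                    }
                )
                if fails:
                    delay = rng.integers(
                        cfg.reintubation_min_bins, cfg.reintubation_max_bins
                    )
                    reintubation_at = t + 1 + delay
                else:
                    reintubation_at = -1
                st = ST_EXT
        elif st == ST_EXT:
            if u < cfg.p_death_ext:
                death_bin = t
                t += 1
                break
            if reintubation_at is not None and reintubation_at >= 0 and t >= reintubation_at:
                st = ST_VENT
                reintubation_at = None
            elif u < cfg.p_ext_discharge and (
                reintubation_at is None or reintubation_at < 0
            ):
                t += 1
                break
        t += 1
    return states[:t], exts, death_bin


def _latent_physiology(cfg: SimConfig, rng, states):
    """Latent P/F (OU around state targets), lactate and pH tracks."""
    n = len(states)
    pf = np.empty(n)
    targets = np.array([PF_TARGET[s] for s in range(N_STATES)])[states]
    pf[0] = targets[0]
    noise = rng.normal(0, cfg.ou_sigma, size=n)
    for t in range(1, n):
        pf[t] = pf[t - 1] + cfg.ou_theta * (targets[t] - pf[t - 1]) + noise[t]
    pf = np.clip(pf, 40.0, 500.0)
    sick = np.isin(states, (ST_RF, ST_VENT)).astype(float)
    lact = 1.0 + 1.5 * pd.Series(sick).rolling(24, min_periods=1).mean().to_numpy()
    ph = 7.4 - cfg.ph_sick_drop * pd.Series(sick).rolling(24, min_periods=1).mean().to_numpy()
    ph = ph + rng.normal(0, cfg.ph_sigma, size=n)
    return pf, lact, ph


def _true_rf_intervals(pf_latent, threshold=200.0, min_bins=49, max_gap=48):
    """Ground-truth failure intervals: runs of latent P/F below threshold,
    gaps <= 4 h merged, events no longer than 4 h dropped (mirroring the
    annotation's short-event deletion)."""
    below = (np.asarray(pf_latent) < threshold).astype(np.int64)
    iv = [(s, e) for s, e, v in runs(below) if v == 1]
    merged = []
    for s, e in iv:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_bins]


def _emit(cfg, rng, times_min, mask, values):
    t = times_min[mask]
    v = values[mask]
    return t, v


def _admission_times(cfg: SimConfig, rng) -> list[pd.Timestamp]:
    """Nonhomogeneous Poisson by thinning: diurnal + weekday intensity."""
    start = pd.Timestamp(cfg.start_date)
    base = cfg.n_stays / (cfg.admission_days * 24.0)
    lam_max = base * (1 + cfg.diurnal_amplitude)
    out = []
    t = 0.0
    horizon_h = cfg.admission_days * 24.0
    while len(out) < cfg.n_stays:
        t += rng.exponential(1.0 / lam_max)
        if t > horizon_h:
            t = rng.uniform(0, horizon_h)  # wrap: keep the cohort size exact
        ts = start + pd.Timedelta(hours=t)
        lam = base * (1 + cfg.diurnal_amplitude * np.sin(2 * np.pi * (ts.hour - 8) / 24.0))
        if ts.weekday() >= 5:
            lam *= cfg.weekend_factor
        if rng.random() < lam / lam_max:
            out.append(ts)
    return sorted(out[: cfg.n_stays])


APACHE_CHOICES = (
    "cardiovascular",
    "respiratory",
    "gastrointestinal",
    "neurologic",
    "trauma",
    "other",
)


def simulate_cohort(cfg: SimConfig) -> tuple[list[StayRecord], SimTruth]:
    """Generate ``cfg.n_stays`` stays with observations and ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    admissions = _admission_times(cfg, rng)
    stays: list[StayRecord] = []
    truth = SimTruth()
    for i, adm in enumerate(admissions):
        sid = f"sim{i:05d}"
        elective = rng.random() < cfg.elective_frac
        if cfg.pre2009_frac > 0 and rng.random() < cfg.pre2009_frac:
            adm = pd.Timestamp("2009-06-01") + pd.Timedelta(hours=float(rng.uniform(0, 24 * 90)))
        stay, st_truth = _simulate_one(cfg, rng, sid, adm, elective)
        stays.append(stay)
        truth.stays[sid] = st_truth
    return stays, truth


def _simulate_one(cfg: SimConfig, rng, sid: str, adm: pd.Timestamp, elective: bool):
    states, exts, death_bin, pf, lact, ph = _simulate_stay_path(
        cfg, rng, elective, hod0=adm.hour + adm.minute / 60.0
    )
    n = len(states)
    trach_stay = (not elective) and rng.random() < cfg.trach_frac
    vent_latent = np.isin(states, (ST_VENT, ST_WEAN, ST_READY))

    # --- FIO2 policy: ambient / supplemental / ventilator-controlled
    fio2 = np.full(n, 0.21)
    supp = np.isin(states, (ST_DETER, ST_RF, ST_EXT))
    fio2[supp] = 0.35
    vent_fio2 = np.clip(0.3 + (200.0 - pf) / 500.0, 0.25, 0.9)
    # ventilator FIO2 is adjusted every 30 min (step function)
    step_idx = (np.arange(n) // 6) * 6
    fio2[vent_latent] = vent_fio2[step_idx][vent_latent]
    pao2 = pf * fio2
    # pH-shifted dissociation curve
    sat = severinghaus(pao2 * 10 ** (0.48 * (ph - 7.4)))

    times_min = np.arange(n, dtype=float) * GRID_STEP_MIN

    obs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def put(vid, mask, values, jitter=0.0):
        m = np.asarray(mask, bool)
        if not m.any():
            return
        t = times_min[m]
        if jitter:
            t = t + rng.uniform(0, jitter, size=m.sum())
        obs[vid] = (adm + pd.to_timedelta(t, unit="m"), np.asarray(values)[m])

    dense = rng.random(n) >= cfg.obs_dropout
    hr_val = 80 + 15 * np.isin(states, (ST_DETER, ST_RF, ST_VENT)) + rng.normal(0, 3, n)
    put("hr", dense, hr_val)
    put("spo2", rng.random(n) >= cfg.obs_dropout,
        np.clip(100 * sat + rng.normal(0, cfg.spo2_noise, n), 50, 100))
    rr_val = 15 + 8 * np.isin(states, (ST_DETER, ST_RF)) - 2 * (states == ST_VENT) + rng.normal(0, 1.5, n)
    put("rr", rng.random(n) >= 0.1, np.clip(rr_val, 6, 50))
    put("map", rng.random(n) >= 0.1,
        80 - 12 * np.isin(states, (ST_RF, ST_VENT)) + rng.normal(0, 5, n))
    put("gcs", (np.arange(n) % 48 == 3),
        np.where(vent_latent, 8, 15) - (states == ST_VENT) * 2.0)

    # blood gas panel (event-driven)
    unstable = np.isin(states, (ST_DETER, ST_RF, ST_VENT, ST_WEAN))
    abga_rate = np.where(unstable, cfg.abga_rate_unstable, cfg.abga_rate_stable)
    abga = rng.random(n) < abga_rate
    abga[0] = True  # admission panel
    put("pao2", abga, pao2 + rng.normal(0, cfg.pao2_noise, n))
    put("sao2", abga, np.clip(100 * sat + rng.normal(0, 0.3, n), 50, 100))
    put("paco2", abga, 40 + 8 * np.isin(states, (ST_RF, ST_VENT)) + rng.normal(0, 2, n))
    put("ph", abga, ph + rng.normal(0, 0.01, n))
    put("lactate", abga, np.clip(lact + rng.normal(0, 0.2, n), 0.3, None))

    # ventilator channels
    if vent_latent.any():
        mode_val = np.where(states == ST_READY, MODE_SPONTANEOUS, MODE_CONTROLLED)
        samp30 = vent_latent & (np.arange(n) % 6 == 0)
        put("vent_mode", samp30, mode_val.astype(float))
        peep_val = np.select(
            [states == ST_VENT, states == ST_WEAN, states == ST_READY],
            [9.0, 6.0, 4.5], default=5.0,
        ) + rng.normal(0, 0.3, n)
        put("peep", samp30, peep_val)
        ps_val = np.select(
            [states == ST_VENT, states == ST_WEAN, states == ST_READY],
            [12.0, 9.0, 8.0], default=8.0,
        ) + rng.normal(0, 0.5, n)
        put("pressure_support", samp30, ps_val)
        put("tidal_volume", samp30, 450 + rng.normal(0, 30, n))
        put("minute_volume", samp30,
            np.where(states == ST_READY, 7.0, 8.5) + rng.normal(0, 0.5, n))
        put("etco2", vent_latent & (np.arange(n) % 2 == 0), 35 + rng.normal(0, 2, n))
        put("peak_pressure", samp30, 20 + rng.normal(0, 2, n))
        put("fio2", vent_latent & (np.arange(n) % 3 == 0),
            vent_fio2[step_idx] + rng.normal(0, 0.005, n))
        put("intub", vent_latent & (np.arange(n) % 48 == 0) & ~trach_stay, np.ones(n))
        put(
            "airway",
            vent_latent & (np.arange(n) % 48 == 0),
            np.full(n, AIRWAY_TRACHEOSTOMY if trach_stay else AIRWAY_INTUBATED, dtype=float),
        )
        if trach_stay:
            put("trach", vent_latent & (np.arange(n) % 24 == 0), np.ones(n))

    put("supp_fio2", supp & (np.arange(n) % 24 == 1), np.full(n, 0.35))
    noradr = np.isin(states, (ST_RF, ST_VENT))
    put("norepinephrine", noradr & (np.arange(n) % 24 == 2), np.full(n, 0.12))

    # off-unit gap: strip all observations in a random 1-3 h window
    if rng.random() < cfg.offunit_gap_frac and n > 72:
        g0 = int(rng.integers(12, n - 40))
        g1 = g0 + int(rng.integers(12, 36))
        lo_t = adm + pd.Timedelta(minutes=g0 * GRID_STEP_MIN)
        hi_t = adm + pd.Timedelta(minutes=g1 * GRID_STEP_MIN)
        for vid in list(obs):
            t, v = obs[vid]
            keep = (pd.DatetimeIndex(t) < lo_t) | (pd.DatetimeIndex(t) >= hi_t)
            if keep.sum() == 0:
                del obs[vid]
            else:
                obs[vid] = (pd.DatetimeIndex(t)[keep], v[np.asarray(keep)])

    discharge = adm + pd.Timedelta(minutes=n * GRID_STEP_MIN)
    death_time = None
    if death_bin is not None:
        death_time = adm + pd.Timedelta(minutes=int(death_bin) * GRID_STEP_MIN)
    stay = StayRecord(
        patient_id=sid,
        admission_time=adm,
        discharge_time=discharge,
        age=float(np.clip(rng.normal(65, 12), 18, 95)),
        sex="M" if rng.random() < 0.63 else "F",
        height=float(np.clip(rng.normal(170, 10), 145, 200)),
        emergency=not elective,
        surgical=bool(rng.random() < 0.4),
        apache_group=str(rng.choice(APACHE_CHOICES)),
        elective=elective,
        death_time=death_time,
        observations=obs,
    )
    ext_records = []
    for e in exts:
        outcome = "failure" if e.get("fails") else "success"
        if death_bin is not None and not e.get("fails") and death_bin - e["bin"] <= 576:
            outcome = "death"
        ext_records.append({"bin": e["bin"], "outcome": outcome, "p_fail": e.get("p_fail")})
    st_truth = StayTruth(
        states=states,
        pf_latent=pf,
        fio2_latent=fio2,
        vent_latent=vent_latent,
        rf_intervals=_true_rf_intervals(pf),
        vent_intervals=[(s, e) for s, e, v in runs(vent_latent.astype(np.int64)) if v == 1],
        extubations=ext_records,
        death_bin=death_bin,
    )
    return stay, st_truth


def noiseless_config(**overrides) -> SimConfig:
    """Configuration with emission noise switched off; used by annotation
    recovery tests."""
    base = SimConfig(
        ou_sigma=0.5,
        ph_sigma=0.0,
        spo2_noise=0.0,
        pao2_noise=0.0,
        obs_dropout=0.0,
        abga_rate_stable=1.0 / 6.0,
        abga_rate_unstable=1.0 / 3.0,
        offunit_gap_frac=0.0,
    )
    return replace(base, **overrides)
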