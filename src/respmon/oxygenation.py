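"""Continuous PaO2 / FIO2 / P/F-ratio estimation on the 5-minute grid.

PaO2 is estimated from pulse-oximetry via the closed-form inversion of the
haemoglobin-oxygen dissociation curve, refined by a pair of nested robust
ridge regressions that exploit recent blood-gas context and the model's own
past mistakes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import HuberRegressor
from sklearn.preprocessing import PolynomialFeatures

from .gridding import GriddedStay
from .schema import GRID_STEP_MIN, MODE_NIV

AMBIENT_FIO2 = 0.21
DEFAULT_ALPHA_GRID = (1.0, 0.1, 0.01, 0.001, 0.0001)
N_PRIOR_ERRORS = 10

SOURCE_MEASURED = 0
SOURCE_MODEL = 1
SOURCE_FORWARD_FILL = 2


# ---------------------------------------------------------------------------
# dissociation curve
# ---------------------------------------------------------------------------

def severinghaus(pao2_mmhg):
    """Forward dissociation curve S(p) = 1 / (23400 / (p^3 + 150 p) + 1)."""
    p = np.asarray(pao2_mmhg, dtype=float)
    return 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)


def ellis_pao2(spo2_fraction):
    """Closed-form inverse of the dissociation curve (Cardano solution).

    Accepts saturation as a fraction in (0, 1); values >= 1 are clamped to
    0.9995 (the curve is asymptotic there), values <= 0 are an error.
    """
    s = np.asarray(spo2_fraction, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s).copy()
    if np.any(s <= 0):
        raise ValueError("saturation must be positive")
    s[s >= 1.0] = 0.9995
    # p^3 + 150 p - c = 0 with c = 23400 s / (1 - s)
    c = 23400.0 * s / (1.0 - s)
    disc = np.sqrt(c**2 / 4.0 + 125000.0)
    p = np.cbrt(c / 2.0 + disc) + np.cbrt(c / 2.0 - disc)
    return float(p[0]) if scalar else p


def smooth_spo2(raw: np.ndarray, window_min: float = 30.0, q: float = 75.0) -> np.ndarray:
    """Percentile smoother: value at t is the q-th percentile of the
    non-missing SpO2 values in the centered window of ``window_min`` minutes."""
    v = np.asarray(raw, dtype=float)
    half = int(round(window_min / 2.0 / GRID_STEP_MIN))
    pad = np.full(half, np.nan)
    vp = np.concatenate([pad, v, pad])
    W = np.lib.stride_tricks.sliding_window_view(vp, 2 * half + 1)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out = np.nanpercentile(W, q, axis=1)
    return out


def pao2_sample_weight(true_pao2):
    """Loss weight emphasising values near the failure decision boundaries:
    10 + 100 / (1 + exp(0.025 (PaO2 - 110)))."""
    p = np.asarray(true_pao2, dtype=float)
    return 10.0 + 100.0 / (1.0 + np.exp(0.025 * (p - 110.0)))


# ---------------------------------------------------------------------------
# hand-crafted feature state
# ---------------------------------------------------------------------------

@dataclass
class OxygenationState:
    """Snapshot of blood-gas context at one grid point."""

    last_spo2: float
    last_pao2: float
    last_sao2: float
    last_ph: float
    dt_last_spo2: float  # minutes
    dt_last_pao2: float  # minutes
    spo2_at_last_pao2: float
    prior_errors: list[float] = field(default_factory=list)  # oldest -> newest

    def base_features(self) -> np.ndarray:
        return np.array(
            [
                self.last_spo2,
                self.last_pao2,
                self.last_sao2,
                self.last_ph,
                self.dt_last_spo2,
                self.dt_last_pao2,
                self.spo2_at_last_pao2,
            ]
        )

    def padded_errors(self) -> np.ndarray:
        e = np.asarray(self.prior_errors[-N_PRIOR_ERRORS:], dtype=float)
        return np.concatenate([np.zeros(N_PRIOR_ERRORS - len(e)), e])


_POLY = PolynomialFeatures(degree=3, include_bias=True)
_POLY.fit(np.zeros((1, 7)))


def pao2_feature_vector(state: OxygenationState) -> np.ndarray:
    """All monomials of total degree <= 3 (with bias) over the 7 base
    features: C(7+3, 3) = 120 columns, deterministic order."""
    return _POLY.transform(state.base_features()[None, :])[0]


def _poly_expand(base: np.ndarray) -> np.ndarray:
    return _POLY.transform(base)


# ---------------------------------------------------------------------------
# per-stay feature assembly (vectorised over bins)
# ---------------------------------------------------------------------------

def _last_before(times: np.ndarray, values: np.ndarray, at_min: np.ndarray):
    """Latest observation strictly before each query time; (value, time)."""
    idx = np.searchsorted(times, at_min, side="left") - 1
    ok = idx >= 0
    safe = np.clip(idx, 0, None)
    val = np.where(ok, values[safe] if len(values) else np.nan, np.nan)
    t = np.where(ok, times[safe] if len(times) else np.nan, np.nan)
    return val, t


def _stay_bin_features(grid: GriddedStay):
    """Per-bin 7-feature matrix plus bookkeeping for the PaO2 estimator.

    A bin is eligible for model prediction when every one of SpO2 / PaO2 /
    SaO2 / pH has at least one observation strictly before the bin start.
    """
    n = grid.n_steps
    bin_start = np.arange(n, dtype=float) * GRID_STEP_MIN
    t_sp, v_sp = grid.raw_times_min["spo2"], grid.raw_values["spo2"]
    t_pa, v_pa = grid.raw_times_min["pao2"], grid.raw_values["pao2"]
    t_sa, v_sa = grid.raw_times_min["sao2"], grid.raw_values["sao2"]
    t_ph, v_ph = grid.raw_times_min["ph"], grid.raw_values["ph"]

    last_spo2, tt_sp = _last_before(t_sp, v_sp, bin_start)
    last_pao2, tt_pa = _last_before(t_pa, v_pa, bin_start)
    last_sao2, _ = _last_before(t_sa, v_sa, bin_start)
    last_ph, _ = _last_before(t_ph, v_ph, bin_start)

    dt_spo2 = bin_start - tt_sp
    dt_pao2 = bin_start - tt_pa

    # closest SpO2 observation to the time of the last PaO2 measurement
    if len(t_sp):
        pos = np.searchsorted(t_sp, np.nan_to_num(tt_pa, nan=-1e18))
        left = np.clip(pos - 1, 0, len(t_sp) - 1)
        right = np.clip(pos, 0, len(t_sp) - 1)
        choose_right = np.abs(t_sp[right] - tt_pa) < np.abs(t_sp[left] - tt_pa)
        sp_at_pa = np.where(choose_right, v_sp[right], v_sp[left])
        sp_at_pa = np.where(np.isnan(tt_pa), np.nan, sp_at_pa)
    else:
        sp_at_pa = np.full(n, np.nan)

    base = np.column_stack(
        [last_spo2, last_pao2, last_sao2, last_ph, dt_spo2, dt_pao2, sp_at_pa]
    )
    eligible = ~np.isnan(base).any(axis=1)
    return base, eligible, bin_start


def _measurement_context(grid: GriddedStay):
    """Base-feature matrix evaluated at each PaO2 measurement time, with the
    measured value as the regression label."""
    t_pa = grid.raw_times_min["pao2"]
    v_pa = grid.raw_values["pao2"]
    keep = t_pa >= 0
    t_pa, v_pa = t_pa[keep], v_pa[keep]
    t_sp, v_sp = grid.raw_times_min["spo2"], grid.raw_values["spo2"]
    t_sa, v_sa = grid.raw_times_min["sao2"], grid.raw_values["sao2"]
    t_ph, v_ph = grid.raw_times_min["ph"], grid.raw_values["ph"]

    last_spo2, tt_sp = _last_before(t_sp, v_sp, t_pa)
    last_pao2, tt_pa_prev = _last_before(t_pa, v_pa, t_pa)
    last_sao2, _ = _last_before(t_sa, v_sa, t_pa)
    last_ph, _ = _last_before(t_ph, v_ph, t_pa)
    if len(t_sp):
        pos = np.searchsorted(t_sp, np.nan_to_num(tt_pa_prev, nan=-1e18))
        left = np.clip(pos - 1, 0, len(t_sp) - 1)
        right = np.clip(pos, 0, len(t_sp) - 1)
        choose_right = np.abs(t_sp[right] - tt_pa_prev) < np.abs(t_sp[left] - tt_pa_prev)
        sp_at_pa = np.where(choose_right, v_sp[right], v_sp[left])
        sp_at_pa = np.where(np.isnan(tt_pa_prev), np.nan, sp_at_pa)
    else:
        sp_at_pa = np.full(len(t_pa), np.nan)
    base = np.column_stack(
        [
            last_spo2,
            last_pao2,
            last_sao2,
            last_ph,
            t_pa - tt_sp,
            t_pa - tt_pa_prev,
            sp_at_pa,
        ]
    )
    eligible = ~np.isnan(base).any(axis=1)
    return base, v_pa, t_pa, eligible


# ---------------------------------------------------------------------------
# nested estimator
# ---------------------------------------------------------------------------

class _ScaledHuber:
    """Huber (robust) loss with L2 penalty on standardised inputs."""

    def __init__(self, alpha: float):
        self.alpha = alpha
        self.model = HuberRegressor(alpha=alpha, max_iter=3000, tol=1e-6)
        self.mu: Optional[np.ndarray] = None
        self.sd: Optional[np.ndarray] = None

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        Xs = (X - self.mu) / self.sd
        try:
            self.model.fit(Xs, y, sample_weight=sample_weight)
        except ValueError:
            # degenerate problems (e.g. constant target) can abort the
            # Huber solver; fall back to a plain ridge fit
            from sklearn.linear_model import Ridge

            self.model = Ridge(alpha=self.alpha)
            self.model.fit(Xs, y, sample_weight=sample_weight)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.model.predict((X - self.mu) / self.sd)


class PaO2Estimator:
    """Base model on polynomial blood-gas context features nested inside a
    meta-model that additionally sees the base prediction and up to 10
    signed base-model residuals at earlier PaO2 measurements."""

    MIN_TRAIN_SAMPLES = 50

    def __init__(self, alpha_grid=DEFAULT_ALPHA_GRID):
        self.alpha_grid = tuple(alpha_grid)
        self.base_: Optional[_ScaledHuber] = None
        self.meta_: Optional[_ScaledHuber] = None
        self.base_alpha_: Optional[float] = None
        self.meta_alpha_: Optional[float] = None

    # -- training sample extraction --------------------------------------

    @staticmethod
    def _samples(stays: list[GriddedStay]):
        rows, labels, stay_idx, times = [], [], [], []
        for si, g in enumerate(stays):
            base, y, t, ok = _measurement_context(g)
            rows.append(base[ok])
            labels.append(y[ok])
            times.append(t[ok])
            stay_idx.append(np.full(ok.sum(), si))
        if not rows:
            return (np.empty((0, 7)),) * 1 + (np.empty(0),) * 3
        return (
            np.concatenate(rows),
            np.concatenate(labels),
            np.concatenate(stay_idx),
            np.concatenate(times),
        )

    @staticmethod
    def _prior_error_matrix(residuals, stay_idx, n_prior=N_PRIOR_ERRORS):
        """Row i gets the residuals of the previous <=10 measurements of the
        same stay, zero-padded on the left, oldest first."""
        out = np.zeros((len(residuals), n_prior))
        for si in np.unique(stay_idx):
            loc = np.where(stay_idx == si)[0]
            r = residuals[loc]
            for j in range(len(loc)):
                prev = r[max(0, j - n_prior): j]
                if len(prev):
                    out[loc[j], n_prior - len(prev):] = prev
        return out

    def _select_alpha(self, X, y, w, Xv, yv, wv):
        best, best_err = None, np.inf
        for a in self.alpha_grid:
            m = _ScaledHuber(a).fit(X, y, sample_weight=w)
            err = np.average((m.predict(Xv) - yv) ** 2, weights=wv)
            if err < best_err:
                best, best_err = m, err
        return best

    def fit(self, train_stays: list[GriddedStay], val_stays: list[GriddedStay]):
        Xb, y, sidx, _ = self._samples(train_stays)
        Xbv, yv, sidxv, _ = self._samples(val_stays)
        if len(y) < self.MIN_TRAIN_SAMPLES:
            raise ValueError(
                f"refusing to fit: {len(y)} eligible samples < {self.MIN_TRAIN_SAMPLES}"
            )
        w, wv = pao2_sample_weight(y), pao2_sample_weight(yv)
        Xp, Xpv = _poly_expand(Xb), _poly_expand(Xbv)
        self.base_ = self._select_alpha(Xp, y, w, Xpv, yv, wv)
        self.base_alpha_ = self.base_.alpha

        res = y - self.base_.predict(Xp)
        resv = yv - self.base_.predict(Xpv)
        E = self._prior_error_matrix(res, sidx)
        Ev = self._prior_error_matrix(resv, sidxv)
        M = np.column_stack([Xp, self.base_.predict(Xp), E])
        Mv = np.column_stack([Xpv, self.base_.predict(Xpv), Ev])
        self.meta_ = self._select_alpha(M, y, w, Mv, yv, wv)
        self.meta_alpha_ = self.meta_.alpha
        return self

    def predict(self, base_features: np.ndarray, prior_errors: np.ndarray) -> np.ndarray:
        Xp = _poly_expand(np.atleast_2d(base_features))
        b = self.base_.predict(Xp)
        M = np.column_stack([Xp, b, np.atleast_2d(prior_errors)])
        return self.meta_.predict(M)

    def predict_base(self, base_features: np.ndarray) -> np.ndarray:
        return self.base_.predict(_poly_expand(np.atleast_2d(base_features)))

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Serialise the fitted estimator to a versioned model file."""
        import pickle

        with open(path, "wb") as fh:
            pickle.dump({"format_version": self.FORMAT_VERSION, "estimator": self}, fh)

    @classmethod
    def load(cls, path) -> "PaO2Estimator":
        import pickle

        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
        return payload["estimator"]


class EllisEstimator:
    """Baseline: invert the dissociation curve on the smoothed SpO2."""

    def predict_from_spo2(self, spo2_percent: np.ndarray) -> np.ndarray:
        s = np.asarray(spo2_percent, dtype=float) / 100.0
        out = np.full(s.shape, np.nan)
        ok = ~np.isnan(s) & (s > 0)
        if ok.any():
            out[ok] = ellis_pao2(np.clip(s[ok], 1e-6, 0.9995))
        return out


# ---------------------------------------------------------------------------
# track estimation
# ---------------------------------------------------------------------------

@dataclass
class PFTrack:
    pao2_est: np.ndarray
    fio2_est: np.ndarray
    pf: np.ndarray
    pao2_source: np.ndarray  # int codes SOURCE_*


def estimate_pao2_track(
    grid: GriddedStay,
    estimator: Optional[PaO2Estimator],
    dense_pao2: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin PaO2 estimate with provenance.

    Measured bins carry the measurement; bins after the first PaO2
    measurement carry the meta-model prediction; earlier bins fall back to
    the (dense) imputation track. Prior-error context updates only at
    measured bins.
    """
    n = grid.n_steps
    est = np.full(n, np.nan)
    source = np.full(n, SOURCE_FORWARD_FILL, dtype=np.int8)

    measured = grid.measured["pao2"].astype(bool)
    est[measured] = grid.values["pao2"][measured]
    source[measured] = SOURCE_MEASURED

    if dense_pao2 is None:
        dense_pao2 = grid.values["pao2"]
    ffill_mask = ~measured
    est[ffill_mask] = dense_pao2[ffill_mask]

    if estimator is not None and estimator.meta_ is not None:
        base, eligible, bin_start = _stay_bin_features(grid)
        # prior residuals at each measurement of this stay
        mctx, y_m, t_m, ok_m = _measurement_context(grid)
        resid = np.zeros(len(t_m))
        if ok_m.any():
            resid[ok_m] = y_m[ok_m] - estimator.predict_base(mctx[ok_m])
        # number of prior measurements per bin
        k = np.searchsorted(t_m, bin_start, side="left")
        model_mask = eligible & ~measured & (k > 0)
        if model_mask.any():
            E = np.zeros((int(model_mask.sum()), N_PRIOR_ERRORS))
            ks = k[model_mask]
            for row, kk in enumerate(ks):
                prev = resid[max(0, kk - N_PRIOR_ERRORS): kk]
                if len(prev):
                    E[row, N_PRIOR_ERRORS - len(prev):] = prev
            est[model_mask] = estimator.predict(base[model_mask], E)
            source[model_mask] = SOURCE_MODEL
    return est, source


def estimate_fio2_track(grid: GriddedStay, vent: np.ndarray) -> np.ndarray:
    """Rule cascade: recent ventilator FIO2 while ventilated (or NIV), else
    supplemental then high-flow oxygen seen in the last 12 h, else ambient
    air (0.21). Clipped to [0.21, 1.0]."""
    n = grid.n_steps
    out = np.full(n, AMBIENT_FIO2)

    def _ffilled(vid):
        rel = grid.raw_times_min.get(vid, np.empty(0))
        rv = grid.raw_values.get(vid, np.empty(0))
        if not rel.size:
            return np.full(n, np.nan)
        bin_ends = (np.arange(n) + 1.0) * GRID_STEP_MIN
        idx = np.searchsorted(rel, bin_ends, side="left") - 1
        return np.where(idx >= 0, rv[np.clip(idx, 0, None)], np.nan)

    tsm_vent = grid.time_since["fio2"]
    tsm_supp = grid.time_since["supp_fio2"]
    tsm_hf = grid.time_since["hiflo_fio2"]
    v_vent, v_supp, v_hf = _ffilled("fio2"), _ffilled("supp_fio2"), _ffilled("hiflo_fio2")

    mode = grid.values["vent_mode"]
    niv = mode == MODE_NIV
    rule1 = (tsm_vent >= 0) & (tsm_vent <= 30.0) & (np.asarray(vent, bool) | niv) & ~np.isnan(v_vent)
    rule2 = ~rule1 & (tsm_supp >= 0) & (tsm_supp <= 720.0) & ~np.isnan(v_supp)
    rule3 = ~rule1 & ~rule2 & (tsm_hf >= 0) & (tsm_hf <= 720.0) & ~np.isnan(v_hf)
    out[rule3] = v_hf[rule3]
    out[rule2] = v_supp[rule2]
    out[rule1] = v_vent[rule1]
    return np.clip(out, AMBIENT_FIO2, 1.0)


def pf_track(
    pao2_est: np.ndarray, fio2_est: np.ndarray, bandwidth: float = 20.0
) -> np.ndarray:
    """Tentative PaO2/FIO2 ratio smoothed with a Nadaraya-Watson kernel
    regressor (Gaussian kernel, bandwidth in grid steps)."""
    ratio = np.asarray(pao2_est, float) / np.asarray(fio2_est, float)
    if bandwidth <= 0:
        return ratio
    n = len(ratio)
    half = int(np.ceil(4 * bandwidth))
    x = np.arange(-half, half + 1, dtype=float)
    kern = np.exp(-0.5 * (x / bandwidth) ** 2)
    mask = (~np.isnan(ratio)).astype(float)
    filled = np.nan_to_num(ratio)
    pad = np.zeros(half)
    num = np.convolve(np.concatenate([pad, filled * mask, pad]), kern, mode="valid")
    den = np.convolve(np.concatenate([pad, mask, pad]), kern, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def build_pf_track(
    grid_dense: GriddedStay,
    vent: np.ndarray,
    estimator: Optional[PaO2Estimator] = None,
    bandwidth: float = 20.0,
) -> PFTrack:
    """Convenience: PaO2 + FIO2 + smoothed P/F for one (densely imputed) stay."""
    pao2, source = estimate_pao2_track(grid_dense, estimator)
    fio2 = estimate_fio2_track(grid_dense, vent)
    pf = pf_track(pao2, fio2, bandwidth=bandwidth)
    return PFTrack(pao2_est=pao2, fio2_est=fio2, pf=pf, pao2_source=source)
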