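"""Extraction of the 51-element aerobic feature vector from a CPET recording.

Direct features are smoothed maxima / terminal values of the measured
channels; calculated features combine channels, minute-wise windows, the
V-slope ventilatory threshold (VAT) anatomy, and treadmill intensity
composites.  Maxima are taken on a rolling mean over a configurable breath
window (default 10 breaths) because raw breath-by-breath maxima are noise
dominated.

Standardization (column mean 0, sample SD 1 with the n-1 denominator) is
provided by :class:`FeatureStandardizer`, a scikit-learn transformer whose
fitted parameters serialize into prediction equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientDataError, ZeroVarianceError
from .recording import CpetRecording
from .registry import DEFAULT_REGISTRY, FeatureRegistry
from .vat import VatPoint, detect_vat_vslope

__all__ = [
    "FeatureVector",
    "extract_features",
    "extract_feature_matrix",
    "FeatureStandardizer",
    "standardize",
]

log = logging.getLogger(__name__)

DEFAULT_SMOOTHING_WINDOW = 10


@dataclass
class FeatureVector:
    """One subject's feature values keyed by registry name.

    ``missing`` lists names whose value could not be computed (NaN in
    ``values``); ``provenance`` records the smoothing window and VAT
    reliability so downstream artifacts can state how they were produced.
    """

    subject_id: str
    values: dict[str, float]
    missing: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.subject_id)


def _smooth(series: pd.Series, window: int) -> pd.Series:
    return series.rolling(window, min_periods=1).mean()


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    den = float(xc @ xc)
    if den <= 1e-12:
        return float("nan")
    return float(xc @ (y - y.mean()) / den)


def extract_features(
    recording: CpetRecording,
    registry: FeatureRegistry | None = None,
    *,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    vat_min_improvement: float = 0.05,
    overrides: Mapping[str, Callable[[dict], float]] | None = None,
) -> FeatureVector:
    """Compute all 51 registry features for one recording.

    Parameters
    ----------
    recording
        Validated breath-by-breath recording.
    registry
        Feature registry; defaults to the canonical 51-entry registry.
    smoothing_window
        Breath window of the rolling mean used for channel maxima.
    vat_min_improvement
        Reliability threshold of the V-slope fit (relative SSE improvement of
        the two-segment over the single-line fit).
    overrides
        Optional ``{name: formula}`` replacing the provisional formula of a
        registry entry.  Each formula receives the internal context dict
        (smoothed channels, VAT point, ...) and returns a float.

    Notes
    -----
    When the V-slope fit is unreliable every VAT-anchored feature is reported
    missing (NaN) and :func:`extract_feature_matrix` excludes the subject.
    """
    registry = registry or DEFAULT_REGISTRY
    b = recording.breaths
    inc = recording.incremental()
    if len(inc) < 10:
        raise InsufficientDataError("fewer than 10 incremental breaths")

    w = smoothing_window
    sm = {c: _smooth(b[c], w) for c in ("ve_l_min", "vo2_ml_min", "vco2_ml_min",
                                        "vt_l", "rf_per_min", "hr_bpm")}
    rr = recording.respiratory_rate()
    rr_sm = _smooth(rr, w)
    rer = b["vco2_ml_min"] / b["vo2_ml_min"]
    rer_sm = _smooth(rer, w)
    veq_o2 = b["ve_l_min"] / (b["vo2_ml_min"] / 1000.0)
    veq_co2 = b["ve_l_min"] / (b["vco2_ml_min"] / 1000.0)

    t = b["t_s"].to_numpy(dtype=float)
    mass = recording.mass_kg
    max_time = float(t[-1])

    # V-slope threshold (may be unreliable)
    try:
        vat: VatPoint | None = detect_vat_vslope(recording, min_improvement=vat_min_improvement)
    except InsufficientDataError:
        vat = None
    vat_ok = vat is not None and vat.reliable

    inc_t = inc["t_s"].to_numpy(dtype=float) - recording.warmup_s
    inc_vo2 = inc["vo2_ml_min"].to_numpy(dtype=float)
    inc_vco2 = inc["vco2_ml_min"].to_numpy(dtype=float)
    inc_ve = inc["ve_l_min"].to_numpy(dtype=float)

    values: dict[str, float] = {}
    missing: set[str] = set()
    nan = float("nan")

    # ------------------------------------------------------------- direct
    values["max time"] = max_time
    values["max VE"] = float(sm["ve_l_min"].max())
    values["max VO2"] = float(sm["vo2_ml_min"].max())
    values["max VCO2"] = float(sm["vco2_ml_min"].max())
    values["max VT"] = float(sm["vt_l"].max())
    values["max RF"] = float(sm["rf_per_min"].max())
    values["max RR"] = float(rr_sm.max())
    values["max HR"] = float(sm["hr_bpm"].max())
    values["max speed"] = float(b["speed_kmh"].max())
    values["max slope"] = float(b["grade_pct"].max())
    values["max RER"] = float(rer_sm.max())
    values["max VO2 [ml/min/kg]"] = values["max VO2"] / mass

    # ------------------------------------------------- ventilatory ratios
    values["max VE/VO2"] = float(_smooth(veq_o2, w).max())
    values["max VE/VCO2"] = float(_smooth(veq_co2, w).max())
    values["slope VCO2 versus VE"] = _ols_slope(inc_ve, inc_vco2)
    values["slope VO2 versus VE"] = _ols_slope(inc_ve, inc_vo2)

    # --------------------------------------------------- minute-wise (1-4)
    for k in (1, 2, 3, 4):
        name_v = f"VO2 at {['1st', '2nd', '3rd', '4th'][k - 1]} min"
        name_s = f"slope {['1st', '2nd', '3rd', '4th'][k - 1]} min of VO2 vs. time"
        mask = (inc_t >= 60.0 * (k - 1)) & (inc_t < 60.0 * k)
        if mask.sum() >= 3:
            values[name_v] = float(inc_vo2[mask].mean())
            values[name_s] = _ols_slope(inc_t[mask] / 60.0, inc_vo2[mask])
        else:
            values[name_v] = nan
            values[name_s] = nan
            missing.update({name_v, name_s})

    # -------------------------------------------------------- VAT-anchored
    if vat_ok:
        assert vat is not None
        t_vat = vat.time_at_vat
        values["time to reach VAT"] = t_vat - recording.warmup_s
        values["time from VAT to the end"] = max_time - t_vat
        values["relative time of VAT"] = t_vat / max_time
        values["time at VAT"] = t_vat
        values["ratio of VAT (VO2) to the max time"] = vat.vo2_at_vat / max_time
        vo2_at_max_rer = float(b["vo2_ml_min"].iloc[int(rer_sm.idxmax())])
        values["ratio of VAT to the max value of RER (VO2)"] = vat.vo2_at_vat / vo2_at_max_rer
        values["Slope A"] = vat.slope_below
        values["Slope B"] = vat.slope_above

        # areas of the VO2-as-a-function-of-VCO2 graph, split at the VAT
        order = np.argsort(inc_vo2, kind="stable")
        xs = inc_vco2[order]
        ys = inc_vo2[order]
        s = int(np.nonzero(order == vat.breath_index)[0][0])
        values["area A of graph VO2 as a function of VCO2"] = float(np.trapezoid(ys[: s + 1], xs[: s + 1]))
        values["area B of graph VO2 as a function of VCO2"] = float(np.trapezoid(ys[s:], xs[s:]))

        values["VE at VAT"] = vat.ve_at_vat
        values["VCO2 [ml/min] at VAT"] = vat.vco2_at_vat
        values["VO2 [ml/min/kg] at VAT"] = vat.vo2_at_vat / mass
        values["RF at VAT"] = vat.rf_at_vat
        values["RR at VAT"] = vat.rr_at_vat
        values["VO2-1 at VAT"] = vat.vo2_at_vat
        values["VO2-2 at VAT"] = vat.vo2_at_vat / values["max VO2"]
        values["VCO2-1 at VAT"] = vat.vco2_at_vat
        values["VCO2-2 at VAT"] = vat.vco2_at_vat / values["max VCO2"]

        below = inc_t + recording.warmup_s < t_vat
        if below.sum() >= 3:
            slope_bt = _ols_slope(inc_t[below], inc_vo2[below])
            icept_bt = float(inc_vo2[below].mean() - slope_bt * inc_t[below].mean())
            values["predicted VO2"] = icept_bt + slope_bt * (max_time - recording.warmup_s)
            pred_at_vat = icept_bt + slope_bt * (t_vat - recording.warmup_s)
            values["predicted VO2 at VAT/the real VO2 at VAT"] = pred_at_vat / vat.vo2_at_vat
        else:
            values["predicted VO2"] = nan
            values["predicted VO2 at VAT/the real VO2 at VAT"] = nan
            missing.update({"predicted VO2", "predicted VO2 at VAT/the real VO2 at VAT"})
    else:
        for name in registry.vat_dependent_names():
            values[name] = nan
            missing.add(name)

    values["VSLOPE"] = _ols_slope(inc_vo2, inc_vco2)

    # ------------------------------------------------- intensity composites
    sxsp = values["max slope"] * values["max speed"]
    values["max slope * max speed"] = sxsp
    values["max slope * max speed * max time"] = sxsp * max_time
    if sxsp > 0:
        values["VEmax/(max slope * max speed)"] = values["max VE"] / sxsp
        values["VO2max/(max slope * max speed)"] = values["max VO2"] / sxsp
    else:
        values["VEmax/(max slope * max speed)"] = nan
        values["VO2max/(max slope * max speed)"] = nan
        missing.update({"VEmax/(max slope * max speed)", "VO2max/(max slope * max speed)"})

    crossed = np.nonzero(rer_sm.to_numpy() >= 1.0)[0]
    if crossed.size:
        values["time to RER=1"] = float(t[crossed[0]])
    else:
        values["time to RER=1"] = nan
        missing.add("time to RER=1")

    # ------------------------------------------------------------ overrides
    if overrides:
        ctx = {
            "recording": recording,
            "breaths": b,
            "incremental": inc,
            "smoothed": sm,
            "vat": vat,
            "values": values,
        }
        for name, formula in overrides.items():
            canonical = registry.resolve(name)
            values[canonical] = float(formula(ctx))
            missing.discard(canonical)

    # order by registry, sanity-check completeness
    ordered = {name: values[name] for name in registry.names}
    return FeatureVector(
        subject_id=recording.subject_id,
        values=ordered,
        missing=missing,
        provenance={
            "smoothing_window": w,
            "vat_reliable": vat_ok,
            "vat_sse": None if vat is None else vat.sse,
        },
    )


def extract_feature_matrix(
    recordings: Iterable[CpetRecording],
    registry: FeatureRegistry | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Extract features for a cohort.

    Subjects with any missing feature (typically an unreliable VAT) are
    dropped from the matrix with a logged reason; the second return value
    maps dropped subject ids to that reason.
    """
    registry = registry or DEFAULT_REGISTRY
    rows, dropped = [], {}
    for rec in recordings:
        vec = extract_features(rec, registry, **kwargs)
        if vec.missing:
            reason = f"missing features: {sorted(vec.missing)}"
            if not vec.provenance.get("vat_reliable", True):
                reason = "unreliable VAT (V-slope fit); " + reason
            dropped[rec.subject_id] = reason
            log.info("dropping subject %s: %s", rec.subject_id, reason)
            continue
        rows.append(vec.to_series())
    matrix = pd.DataFrame(rows, columns=registry.names)
    matrix.index.name = "id"
    return matrix, dropped


class FeatureStandardizer(BaseEstimator, TransformerMixin):
    """Column-wise standardizer with the sample (n-1) SD.

    Unlike :class:`sklearn.preprocessing.StandardScaler` this uses the n-1
    denominator, raises a named error on zero-variance columns, and keeps a
    feature-keyed parameter dict (``params_``) that serializes into
    prediction equations and inverts exactly.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        X = self._as_frame(X)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=self.ddof)
        zero = sd[sd <= 0].index.tolist()
        nan_cols = X.columns[X.isna().any()].tolist()
        if nan_cols:
            raise ZeroVarianceError(nan_cols)  # pragma: no cover - upstream drops NaN rows
        if zero:
            raise ZeroVarianceError(zero)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.mean_ = mean.to_numpy(dtype=float)
        self.scale_ = sd.to_numpy(dtype=float)
        self.params_ = {c: {"mean": float(m), "sd": float(s)}
                        for c, m, s in zip(X.columns, self.mean_, self.scale_)}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        X = self._as_frame(X)
        X = X[list(self.feature_names_in_)]
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        Z = self._as_frame(Z)
        return Z[list(self.feature_names_in_)] * self.scale_ + self.mean_

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "params_")
        return np.asarray(self.feature_names_in_, dtype=object)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    @classmethod
    def from_params(cls, params: Mapping[str, Mapping[str, float]]) -> "FeatureStandardizer":
        """Rebuild a fitted standardizer from a serialized parameter dict."""
        obj = cls()
        names = list(params)
        obj.feature_names_in_ = np.asarray(names, dtype=object)
        obj.n_features_in_ = len(names)
        obj.mean_ = np.array([params[c]["mean"] for c in names], dtype=float)
        obj.scale_ = np.array([params[c]["sd"] for c in names], dtype=float)
        obj.params_ = {c: {"mean": float(params[c]["mean"]), "sd": float(params[c]["sd"])}
                       for c in names}
        return obj


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, FeatureStandardizer]:
    """Standardize a feature matrix; returns the matrix and fitted scaler."""
    scaler = FeatureStandardizer().fit(matrix)
    return scaler.transform(matrix), scaler
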