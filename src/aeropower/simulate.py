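"""Synthetic cohort generator with planted generative structure.

The simulator produces paired CPET recordings and Wingate outcomes whose
statistical structure matches what the downstream analysis assumes:

* an incremental treadmill protocol (speed +1 km/h per minute; once the
  respiratory exchange ratio reaches 1.0 the grade starts rising 2% per
  minute),
* a two-segment V-slope structure of VCO2 vs VO2 with the break planted at a
  known fraction of VO2max,
* breath-level multiplicative noise on every channel,
* anaerobic outcomes generated as a known linear function of the cohort's
  standardized aerobic features plus Gaussian noise.

Because the planted coefficients and feature names are returned alongside
the data, selection, clustering and evaluation can all be tested against a
known truth.  One master seed deterministically spawns independent
per-subject streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortTooSmallError, DataValidationError, InvalidShapeError
from .features import FeatureStandardizer, extract_feature_matrix
from .profiles import (
    GenerativeSpec,
    ProtocolSpec,
    SubjectProfile,
    WingateResult,
    WingateShape,
    sample_profiles,
)
from .recording import BREATH_COLUMNS, CpetRecording

__all__ = [
    "CpetModel",
    "Cohort",
    "simulate_cpet",
    "simulate_wingate",
    "simulate_cohort",
    "default_generative_specs",
    "make_planted_regression",
]


@dataclass
class CpetModel:
    """Physiological response model underlying the breath simulator.

    VO2 rises linearly from ``vo2_warm_frac`` x VO2max to VO2max over the
    subject's ramp; VCO2 follows VO2 with slope ``slope_below`` under the
    planted VAT and ``slope_above`` over it; ventilation is piecewise linear
    in VO2 with a steeper response above the VAT (reaching ``ve_vat_ratio``
    of max VE at the threshold); heart rate is linear in %VO2max and the
    test terminates when it reaches the subject's maximum.
    """

    vo2_warm_frac: float = 0.30
    slope_below: float = 0.90
    slope_above: float = 1.30
    ve_vat_ratio: float = 0.60
    hr_rest: float = 70.0
    rf_rest: float = 18.0
    rf_max_mean: float = 50.0
    rf_max_sd: float = 4.0
    ramp_pace_ml_kg_min: float = 5.5  # ramp minutes = (VO2max/kg) / pace
    ramp_min_bounds: tuple[float, float] = (6.0, 14.0)
    noise_vo2: float = 0.02  # relative SD
    noise_vco2: float = 0.02
    noise_ve: float = 0.03
    noise_rf: float = 1.0  # absolute SD, breaths/min
    noise_hr: float = 2.0  # absolute SD, bpm

    def ramp_minutes(self, profile: SubjectProfile) -> float:
        per_kg = profile.vo2max_true / profile.mass
        return float(np.clip(per_kg / self.ramp_pace_ml_kg_min, *self.ramp_min_bounds))


def simulate_cpet(
    profile: SubjectProfile,
    protocol: ProtocolSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    model: CpetModel | None = None,
) -> CpetRecording:
    """Simulate one breath-by-breath incremental CPET recording.

    The recording starts with a constant low-intensity warm-up, ramps VO2
    linearly toward the subject's true VO2max, and ends at the breath where
    the modeled heart rate reaches ``hr_max``.  The grade increment latches
    on the first breath whose *measured* (noisy) RER reaches the protocol
    trigger, as a metabolic cart would.
    """
    protocol = protocol or ProtocolSpec()
    model = model or CpetModel()
    rng = np.random.default_rng(seed)

    vo2max = profile.vo2max_true
    vat = profile.vat_fraction * vo2max
    ramp_s = model.ramp_minutes(profile) * 60.0
    ve_max = profile.ve_max_true
    ve_vat = model.ve_vat_ratio * ve_max
    rf_max = float(rng.normal(model.rf_max_mean, model.rf_max_sd))

    def vco2_true(v: float) -> float:
        if v <= vat:
            return model.slope_below * v
        return model.slope_below * vat + model.slope_above * (v - vat)

    def ve_true(v: float) -> float:
        if v <= vat:
            return ve_vat * v / vat
        return ve_vat + (ve_max - ve_vat) * (v - vat) / (vo2max - vat)

    rows = []
    t = 0.0
    triggered_at: float | None = None
    minute_schedule: dict[int, tuple[float, float]] = {}
    while True:
        t += protocol.breath_interval_mean + rng.uniform(
            -protocol.breath_interval_jitter, protocol.breath_interval_jitter
        )
        tt = t - protocol.warmup_s  # time in the incremental phase
        if tt < 0:
            frac = model.vo2_warm_frac
            speed = protocol.warmup_speed
        else:
            frac = model.vo2_warm_frac + (1.0 - model.vo2_warm_frac) * min(tt / ramp_s, 1.0)
            speed = protocol.speed_start + protocol.speed_increment * np.floor(tt / 60.0)
        if triggered_at is None:
            grade = 0.0
        else:
            grade = protocol.grade_increment_pct * (1.0 + np.floor((t - triggered_at) / 60.0))

        v = frac * vo2max
        vo2 = v * (1.0 + model.noise_vo2 * rng.standard_normal())
        vco2 = vco2_true(v) * (1.0 + model.noise_vco2 * rng.standard_normal())
        ve = ve_true(v) * (1.0 + model.noise_ve * rng.standard_normal())
        rf = model.rf_rest + (rf_max - model.rf_rest) * frac + model.noise_rf * rng.standard_normal()
        rf = max(rf, 5.0)
        vt = ve / rf
        hr_model = model.hr_rest + (profile.hr_max - model.hr_rest) * frac
        hr = hr_model + model.noise_hr * rng.standard_normal()
        rows.append((t, max(vo2, 1.0), max(vco2, 1.0), max(ve, 0.1), rf, vt, hr, speed, grade))

        if triggered_at is None and vco2 / vo2 >= protocol.rq_trigger:
            triggered_at = t
        if tt >= 0:
            minute_schedule.setdefault(int(tt // 60.0), (float(speed), float(grade)))
        if hr_model >= profile.hr_max:  # termination on modeled HR reaching max
            break

    breaths = pd.DataFrame(rows, columns=list(BREATH_COLUMNS))
    meta = {
        "profile_id": profile.id,
        "sex": profile.sex,
        "vo2max_true": vo2max,
        "vat_fraction_true": profile.vat_fraction,
        "ramp_s": ramp_s,
        "rq_trigger_time_s": triggered_at,
        "schedule": {str(k): {"speed_kmh": v[0], "grade_pct": v[1]}
                     for k, v in sorted(minute_schedule.items())},
    }
    return CpetRecording(
        subject_id=profile.id,
        mass_kg=profile.mass,
        warmup_s=protocol.warmup_s,
        breaths=breaths,
        meta=meta,
    )


def simulate_wingate(
    profile: SubjectProfile,
    shape: WingateShape,
    seed: int | np.random.SeedSequence = 0,
) -> WingateResult:
    """Simulate one 30-s Wingate test from a power-curve shape.

    Peak power is the curve maximum, mean power the trapezoidal time average
    over the 30 s, fatigue the percent drop from maximal to minimal power.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 30.0 + 1e-9, shape.dt_s)
    if shape.mid_w is None:
        power = shape.peak_w + (shape.end_w - shape.peak_w) * t / 30.0
    else:
        power = np.where(
            t <= 15.0,
            shape.peak_w + (shape.mid_w - shape.peak_w) * t / 15.0,
            shape.mid_w + (shape.end_w - shape.mid_w) * (t - 15.0) / 15.0,
        )
    if shape.noise_sd > 0:
        power = power + shape.noise_sd * rng.standard_normal(power.shape)
    if np.any(power <= 0):
        raise InvalidShapeError("power curve is not strictly positive")
    pp = float(power.max())
    mp = float(np.trapezoid(power, t) / 30.0)
    fatigue = 100.0 * (power.max() - power.min()) / power.max()
    return WingateResult(
        pp=pp, mp=mp, fatigue=float(fatigue),
        power_curve=np.column_stack([t, power]),
    )


def default_generative_specs() -> dict[str, GenerativeSpec]:
    """Planted outcome models for the default simulated cohort.

    Peak and mean power use the six- and four-feature reference equations'
    feature sets and coefficients so the simulated cohort carries a signal
    of the same shape the selection procedure is meant to find; the
    population R^2 defaults to 0.9, matching the predictive strength the
    method is designed to achieve.  The fatigue index is generated with a
    weak signal (population R^2 = 0.16, i.e. r = 0.4) since fatigue is
    essentially unpredictable from aerobic features.
    """
    return {
        "pp_w": GenerativeSpec(
            signal_features=[
                "max VE", "max RF", "max VO2", "max slope * max speed",
                "slope VCO2 versus VE", "VO2max/(max slope * max speed)",
            ],
            coefficients=[170.3, -43.5, -77.5, 98.6, 39.3, 53.0],
            intercept=638.4,
            target_r2=0.9,
        ),
        "mp_w": GenerativeSpec(
            signal_features=[
                "max VE", "slope 1st min of VO2 vs. time", "max VO2",
                "max slope * max speed",
            ],
            coefficients=[105.5, 36.4, -33.8, 27.6],
            intercept=476.8,
            target_r2=0.9,
        ),
        "fatigue_pct": GenerativeSpec(
            signal_features=["max RER"],
            coefficients=[5.0],
            intercept=49.9,
            target_r2=0.16,
        ),
    }


@dataclass
class Cohort:
    """A simulated cohort: paired recordings, outcomes, and planted truth."""

    profiles: list[SubjectProfile]
    recordings: list[CpetRecording]
    features: pd.DataFrame  # subjects x 51, raw units
    features_z: pd.DataFrame  # standardized (cohort-level scaler)
    scaler: FeatureStandardizer
    outcomes: pd.DataFrame  # columns pp_w, mp_w, fatigue_pct
    wingate: list[WingateResult]
    truth: dict[str, dict] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.profiles)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for p, w in zip(self.profiles, self.wingate):
            rows.append({
                "id": p.id, "sex": p.sex, "age": p.age, "mass_kg": p.mass,
                "height_cm": p.height,
                "pp_w": self.outcomes.loc[p.id, "pp_w"],
                "mp_w": self.outcomes.loc[p.id, "mp_w"],
                "fatigue_pct": self.outcomes.loc[p.id, "fatigue_pct"],
            })
        return pd.DataFrame(rows).set_index("id")


def simulate_cohort(
    n: int,
    gen: GenerativeSpec | dict[str, GenerativeSpec] | None = None,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    *,
    sex_counts: tuple[int, int] | None = None,
    model: CpetModel | None = None,
    max_retries: int = 5,
) -> Cohort:
    """Simulate a paired cohort of ``n`` subjects.

    Parameters
    ----------
    n
        Cohort size (>= 10, so the 40/30/30 split stays populated).
    gen
        Either a single :class:`GenerativeSpec` (applied to the ``pp_w``
        outcome) or a mapping of outcome name to spec.  Defaults to
        :func:`default_generative_specs`.
    protocol, model
        Treadmill protocol and physiological response model.
    seed
        Master seed; per-subject breath streams and the outcome noise are
        spawned deterministically from it.
    sex_counts
        (n_female, n_male); defaults to the proportional 36:52 mix.
    max_retries
        A subject whose simulated recording yields an unreliable V-slope fit
        is re-simulated with a fresh spawned stream up to this many times so
        the returned cohort always has exactly ``n`` members.

    Returns
    -------
    Cohort
        Recordings, raw and standardized feature matrices, planted outcomes,
        Wingate results, and a ``truth`` dict (per outcome: signal features,
        coefficients, intercept, resolved noise SD) for recovery testing.
    """
    if n < 10:
        raise CohortTooSmallError(f"need at least 10 subjects, got {n}")
    if gen is None:
        specs = default_generative_specs()
    elif isinstance(gen, GenerativeSpec):
        specs = {"pp_w": gen}
    else:
        specs = dict(gen)

    protocol = protocol or ProtocolSpec()
    model = model or CpetModel()
    master = np.random.SeedSequence(seed)
    ss_profiles, ss_subjects, ss_outcomes, ss_wingate = master.spawn(4)
    rng_profiles = np.random.default_rng(ss_profiles)
    profiles = sample_profiles(n, rng_profiles, sex_counts=sex_counts)

    subject_streams = ss_subjects.spawn(n)
    recordings: list[CpetRecording] = []
    for p, stream in zip(profiles, subject_streams):
        tries = stream.spawn(max_retries + 1)
        rec = None
        for attempt in tries:
            rec = simulate_cpet(p, protocol, attempt, model)
            matrix, dropped = extract_feature_matrix([rec])
            if not dropped:
                break
        assert rec is not None
        recordings.append(rec)

    features, dropped = extract_feature_matrix(recordings)
    if dropped:
        raise DataValidationError(
            f"simulated subjects with unextractable features after retries: {sorted(dropped)}"
        )
    features_z, scaler = _standardize(features)

    rng_out = np.random.default_rng(ss_outcomes)
    outcomes = pd.DataFrame(index=features.index)
    truth: dict[str, dict] = {}
    for outcome, spec in specs.items():
        missing = [f for f in spec.signal_features if f not in features_z.columns]
        if missing:
            raise DataValidationError(f"signal features not in feature matrix: {missing}")
        Z = features_z[spec.signal_features].to_numpy()
        coefs = np.asarray(spec.coefficients, dtype=float)
        signal = spec.intercept + Z @ coefs
        noise_sd = spec.resolve_noise_sd(Z @ coefs)
        y = signal + (rng_out.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
        outcomes[outcome] = y
        truth[outcome] = {
            "signal_features": list(spec.signal_features),
            "coefficients": [float(c) for c in coefs],
            "intercept": float(spec.intercept),
            "noise_sd": float(noise_sd),
        }

    wingate = _wingate_from_outcomes(profiles, outcomes, ss_wingate)
    return Cohort(
        profiles=profiles,
        recordings=recordings,
        features=features,
        features_z=features_z,
        scaler=scaler,
        outcomes=outcomes,
        wingate=wingate,
        truth=truth,
    )


def _standardize(features: pd.DataFrame):
    from .features import standardize

    return standardize(features)


def _wingate_from_outcomes(profiles, outcomes: pd.DataFrame, ss) -> list[WingateResult]:
    """Build per-subject power curves consistent with the planted outcomes."""
    results = []
    streams = ss.spawn(len(profiles))
    for p, stream in zip(profiles, streams):
        pp = float(outcomes.loc[p.id].get("pp_w", 650.0))
        mp = float(outcomes.loc[p.id].get("mp_w", 0.75 * pp))
        fat = float(np.clip(outcomes.loc[p.id].get("fatigue_pct", 50.0), 1.0, 99.0))
        pp = max(pp, 50.0)
        end = pp * (1.0 - fat / 100.0)
        # mid point chosen so the curve's 30-s average approximates mp
        mid = float(np.clip((4.0 * mp - pp - end) / 2.0, end, pp))
        shape = WingateShape(peak_w=pp, end_w=end, mid_w=mid)
        results.append(simulate_wingate(p, shape, stream))
    return results


def make_planted_regression(
    n: int,
    p: int,
    coefs: dict[str, float],
    *,
    rho: float = 0.2,
    snr: float | None = None,
    noise_sd: float | None = None,
    intercept: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Plant a sparse linear signal in an exchangeably correlated design.

    Features ``f1..fp`` are multivariate normal with unit variance and
    pairwise correlation ``rho``.  The outcome is
    ``intercept + sum(coefs) + noise``; the noise SD is either given
    directly or derived from ``snr`` (variance ratio of planted signal to
    noise).  Used for fast selection tests that do not need the full breath
    simulator.
    """
    if (snr is None) == (noise_sd is None):
        raise DataValidationError("give exactly one of snr or noise_sd")
    rng = np.random.default_rng(seed)
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, p)) @ L.T
    names = [f"f{i + 1}" for i in range(p)]
    Xdf = pd.DataFrame(X, columns=names)
    beta = np.zeros(p)
    for name, c in coefs.items():
        beta[names.index(name)] = c
    signal = X @ beta
    if noise_sd is None:
        assert snr is not None
        noise_sd = float(np.sqrt(max(np.var(signal), 1e-300) / snr))
    y = intercept + signal + rng.normal(0.0, noise_sd, size=n)
    truth = {"signal_features": [k for k in coefs], "coefficients": dict(coefs),
             "intercept": intercept, "noise_sd": noise_sd}
    return Xdf, y, truth
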