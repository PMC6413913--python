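"""Subject profiles, treadmill protocol, and generative specifications.

Cohort anthropometrics and aerobic capacity are sampled, per sex, from
truncated normal distributions whose means and SDs match the study-population
summary used throughout this package (36 women / 52 men; e.g. maximal oxygen
uptake 2585.9 +/- 382.7 ml/min for women, 4169.2 +/- 605.8 for men).
Truncation is at +/-3 SD with physiologic floors so that no draw yields a
negative mass or an impossible VO2max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError, InvalidProtocolError, InvalidShapeError
from .registry import DEFAULT_REGISTRY

__all__ = [
    "SubjectProfile",
    "ProtocolSpec",
    "WingateShape",
    "WingateResult",
    "GenerativeSpec",
    "POPULATION",
    "sample_profiles",
]


@dataclass
class SubjectProfile:
    """Latent physiological truth for one simulated subject."""

    id: str
    sex: str  # "female" | "male"
    age: float  # years
    mass: float  # kg
    height: float  # cm
    vo2max_true: float  # ml/min
    vat_fraction: float  # VAT as a fraction of VO2max, in (0, 1)
    ve_max_true: float  # l/min
    hr_max: float  # beats/min

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise DataValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.mass <= 0:
            raise DataValidationError("mass must be positive")
        if not 0.0 < self.vat_fraction < 1.0:
            raise DataValidationError("vat_fraction must lie in (0, 1)")
        if self.vo2max_true <= 0:
            raise DataValidationError("vo2max_true must be positive")


@dataclass
class ProtocolSpec:
    """Incremental treadmill protocol.

    Speed increases by ``speed_increment`` km/h every minute.  Once the
    respiratory exchange ratio reaches ``rq_trigger`` the treadmill grade
    starts increasing by ``grade_increment_pct`` per minute (first increment
    applied immediately at the trigger).  Breaths arrive every
    ``breath_interval_mean`` seconds with uniform jitter of
    ``+/- breath_interval_jitter`` seconds.
    """

    warmup_s: float = 120.0
    warmup_speed: float = 4.0  # km/h; the study does not report this value
    speed_start: float = 7.0  # km/h; configurable, not inferred from the study
    speed_increment: float = 1.0  # km/h per minute
    grade_increment_pct: float = 2.0
    rq_trigger: float = 1.0
    breath_interval_mean: float = 2.0  # s
    breath_interval_jitter: float = 0.5  # s, uniform half-width

    def __post_init__(self) -> None:
        if self.speed_increment <= 0:
            raise InvalidProtocolError("speed_increment must be positive")
        if self.grade_increment_pct < 0:
            raise InvalidProtocolError("grade_increment_pct must be non-negative")
        if self.breath_interval_mean <= self.breath_interval_jitter:
            raise InvalidProtocolError("breath interval jitter exceeds the mean interval")


@dataclass
class WingateShape:
    """Parameters of a 30-s Wingate power curve.

    A monotone-decay curve from ``peak_w`` to ``end_w``; if ``mid_w`` is
    given the decay is piecewise linear through ``mid_w`` at 15 s (used to
    match a prescribed mean power), otherwise a single linear ramp.
    """

    peak_w: float
    end_w: float
    mid_w: float | None = None
    noise_sd: float = 0.0
    dt_s: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_w <= 0:
            raise InvalidShapeError("peak power must be positive")
        if self.end_w <= 0 or self.end_w > self.peak_w:
            raise InvalidShapeError("end power must be positive and <= peak power")
        if self.mid_w is not None and not self.end_w <= self.mid_w <= self.peak_w:
            raise InvalidShapeError("mid power must lie between end and peak power")
        if self.noise_sd < 0:
            raise InvalidShapeError("noise_sd must be non-negative")


@dataclass
class WingateResult:
    """Wingate anaerobic test outcome for one subject.

    ``pp`` is the curve maximum, ``mp`` the 30-s time average, ``fatigue``
    the percent drop from maximal to minimal power.  ``resistance`` is the
    braking load as a fraction of body mass (conventional 0.075).
    """

    pp: float  # W
    mp: float  # W
    fatigue: float  # %
    power_curve: np.ndarray  # shape (n, 2): columns (t_s, power_w)
    resistance: float = 0.075

    def __post_init__(self) -> None:
        if not 0.0 <= self.fatigue <= 100.0:
            raise DataValidationError("fatigue must lie in [0, 100] %")
        dur = float(self.power_curve[-1, 0] - self.power_curve[0, 0])
        if abs(dur - 30.0) > 1e-9:
            raise DataValidationError("power curve must span exactly 30 s")


@dataclass
class GenerativeSpec:
    """Planted linear model generating an anaerobic outcome.

    outcome = intercept + sum(coefficients * standardized signal features)
              + Normal(0, noise_sd)

    Exactly one of ``noise_sd`` / ``target_r2`` must be given; with
    ``target_r2`` the noise SD is derived at simulation time from the
    realized signal variance so the population R^2 matches the target.
    """

    signal_features: list[str]
    coefficients: list[float]
    intercept: float
    noise_sd: float | None = None
    target_r2: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.signal_features) != len(self.coefficients):
            raise DataValidationError("signal_features and coefficients length mismatch")
        self.signal_features = [DEFAULT_REGISTRY.resolve(f) if f in DEFAULT_REGISTRY else f
                                for f in self.signal_features]
        if (self.noise_sd is None) == (self.target_r2 is None):
            raise DataValidationError("give exactly one of noise_sd or target_r2")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise DataValidationError("noise_sd must be non-negative")
        if self.target_r2 is not None and not 0.0 < self.target_r2 <= 1.0:
            raise DataValidationError("target_r2 must lie in (0, 1]")

    def resolve_noise_sd(self, signal: np.ndarray) -> float:
        """Noise SD, deriving it from ``target_r2`` and the realized signal."""
        if self.noise_sd is not None:
            return float(self.noise_sd)
        var_sig = float(np.var(signal))
        assert self.target_r2 is not None
        return float(np.sqrt(var_sig * (1.0 - self.target_r2) / self.target_r2))


# --------------------------------------------------------------------------
# Population defaults (means, SDs) per sex, with physiologic floors.
# --------------------------------------------------------------------------
POPULATION: dict[str, dict[str, tuple[float, float]]] = {
    "female": {
        "age": (25.0, 4.0),
        "height": (164.3, 6.4),
        "mass": (60.7, 8.7),
        "vo2max_true": (2585.9, 382.7),
        "ve_max_true": (87.2, 14.5),
        "hr_max": (183.0, 7.8),
    },
    "male": {
        "age": (28.0, 6.0),
        "height": (176.6, 6.8),
        "mass": (75.8, 10.2),
        "vo2max_true": (4169.2, 605.8),
        "ve_max_true": (146.5, 20.6),
        "hr_max": (186.0, 7.3),
    },
}

#: Sex mix of the reference cohort (women : men).
DEFAULT_SEX_RATIO = (36, 52)

_FLOORS = {
    "age": 18.0,
    "height": 140.0,
    "mass": 35.0,
    "vo2max_true": 1000.0,
    "ve_max_true": 40.0,
    "hr_max": 150.0,
}

#: VAT as a fraction of VO2max: mean, SD, (lower, upper) truncation.
VAT_FRACTION = (0.63, 0.05, 0.50, 0.72)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))  # pragma: no cover - pathological bounds


def sample_profiles(
    n: int,
    rng: np.random.Generator,
    *,
    sex_counts: tuple[int, int] | None = None,
) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles from the sex-specific population defaults.

    ``sex_counts`` is (n_female, n_male); by default the reference 36:52 mix
    is applied proportionally (female count rounded to nearest).
    """
    if sex_counts is None:
        nf = int(round(n * DEFAULT_SEX_RATIO[0] / sum(DEFAULT_SEX_RATIO)))
        sex_counts = (nf, n - nf)
    if sum(sex_counts) != n:
        raise DataValidationError("sex_counts must sum to n")
    profiles: list[SubjectProfile] = []
    sexes = ["female"] * sex_counts[0] + ["male"] * sex_counts[1]
    for i, sex in enumerate(sexes):
        pop = POPULATION[sex]
        draws = {}
        for key, (mean, sd) in pop.items():
            lo = max(_FLOORS[key], mean - 3 * sd)
            hi = mean + 3 * sd
            draws[key] = _trunc_normal(rng, mean, sd, lo, hi)
        m, s, lo, hi = VAT_FRACTION
        vat = _trunc_normal(rng, m, s, lo, hi)
        profiles.append(
            SubjectProfile(
                id=f"s{i + 1:03d}",
                sex=sex,
                vat_fraction=vat,
                **draws,
            )
        )
    return profiles
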