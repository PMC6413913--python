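"""Canonical registry of the 51 aerobic CPET features.

The registry fixes the feature *names*, their class (directly measured on the
metabolic cart vs. calculated from the measured channels), and the protocol
stage they belong to: ``full_test`` features need the whole incremental test,
``early_minutes`` features are computable from the first four minutes only.

Twelve features are direct channel maxima / terminal values; thirty-nine are
calculated.  Several calculated features are anchored at the ventilatory
anaerobic threshold (VAT) found by the V-slope method and are flagged
``requires_vat``: when the two-segment V-slope fit is unreliable for a
subject those entries are reported missing and the subject is excluded from
the feature matrix.

A handful of names circulating in the field have ambiguous definitions
("VO2-1 at VAT" vs "VO2-2 at VAT", "VSLOPE", "predicted VO2", ...).  The
registry ships explicit provisional formulas for them (documented per entry
and in docs/methods.md) and :func:`aeropower.features.extract_features`
accepts per-name formula overrides, so an alternative reading never requires
touching library code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "FeatureDef",
    "FeatureRegistry",
    "DEFAULT_REGISTRY",
    "ALIASES",
    "resolve_name",
]

FeatureClass = Literal["direct", "calculated"]
Stage = Literal["full_test", "early_minutes"]


@dataclass(frozen=True)
class FeatureDef:
    """Definition of a single aerobic feature."""

    name: str
    kind: FeatureClass
    stage: Stage = "full_test"
    requires_vat: bool = False
    description: str = ""


def _direct(name: str, desc: str) -> FeatureDef:
    return FeatureDef(name, "direct", "full_test", False, desc)


def _calc(name: str, desc: str, stage: Stage = "full_test", vat: bool = False) -> FeatureDef:
    return FeatureDef(name, "calculated", stage, vat, desc)


_DEFS: tuple[FeatureDef, ...] = (
    # ------------------------------------------------------------------ direct
    _direct("max time", "total test duration [s] (last breath timestamp)"),
    _direct("max VE", "maximal minute ventilation [l/min], smoothed"),
    _direct("max VO2", "maximal oxygen uptake [ml/min], smoothed"),
    _direct("max VCO2", "maximal carbon-dioxide output [ml/min], smoothed"),
    _direct("max VT", "maximal tidal volume [l], smoothed"),
    _direct("max RF", "maximal respiratory frequency [breaths/min], cart channel, smoothed"),
    _direct("max RR", "maximal respiratory rate [breaths/min], derived from breath timestamps, smoothed"),
    _direct("max HR", "maximal heart rate [beats/min], smoothed"),
    _direct("max speed", "maximal treadmill speed [km/h]"),
    _direct("max slope", "maximal treadmill grade [%]"),
    _direct("max RER", "maximal respiratory exchange ratio VCO2/VO2, smoothed"),
    _direct("max VO2 [ml/min/kg]", "maximal oxygen uptake per body mass [ml/min/kg]"),
    # ------------------------------------------------------- calculated, ratios
    _calc("max VE/VO2", "maximal ventilatory equivalent for O2 (VE / VO2, both in l/min)"),
    _calc("max VE/VCO2", "maximal ventilatory equivalent for CO2"),
    _calc("slope VCO2 versus VE", "OLS slope of VCO2 [ml/min] on VE [l/min] over the incremental phase"),
    _calc("slope VO2 versus VE", "OLS slope of VO2 [ml/min] on VE [l/min] over the incremental phase"),
    # -------------------------------------------------- calculated, early stage
    _calc("VO2 at 1st min", "mean VO2 [ml/min] in minute 1 of the incremental phase", "early_minutes"),
    _calc("VO2 at 2nd min", "mean VO2 [ml/min] in minute 2", "early_minutes"),
    _calc("VO2 at 3rd min", "mean VO2 [ml/min] in minute 3", "early_minutes"),
    _calc("VO2 at 4th min", "mean VO2 [ml/min] in minute 4", "early_minutes"),
    _calc("slope 1st min of VO2 vs. time", "OLS slope of VO2 [ml/min] vs time [min] within minute 1", "early_minutes"),
    _calc("slope 2nd min of VO2 vs. time", "OLS slope of VO2 vs time within minute 2", "early_minutes"),
    _calc("slope 3rd min of VO2 vs. time", "OLS slope of VO2 vs time within minute 3", "early_minutes"),
    _calc("slope 4th min of VO2 vs. time", "OLS slope of VO2 vs time within minute 4", "early_minutes"),
    # --------------------------------------------------- calculated, VAT timing
    _calc("time to reach VAT", "time from incremental-phase start to the VAT [s]", vat=True),
    _calc("time from VAT to the end", "time from the VAT to test termination [s]", vat=True),
    _calc("relative time of VAT", "VAT clock time / total test duration, in (0,1)", vat=True),
    _calc("time at VAT", "clock time of the VAT breath from test start [s]", vat=True),
    _calc("ratio of VAT (VO2) to the max time", "VO2 at VAT [ml/min] / test duration [s]", vat=True),
    _calc("ratio of VAT to the max value of RER (VO2)",
          "VO2 at VAT / VO2 at the breath of maximal RER", vat=True),
    # ---------------------------------------------- calculated, V-slope anatomy
    _calc("Slope A", "VCO2-vs-VO2 slope below the VAT (lower V-slope segment)", vat=True),
    _calc("Slope B", "VCO2-vs-VO2 slope above the VAT (upper V-slope segment)", vat=True),
    _calc("area A of graph VO2 as a function of VCO2",
          "trapezoidal area under VO2(VCO2) below the VAT breakpoint", vat=True),
    _calc("area B of graph VO2 as a function of VCO2",
          "trapezoidal area under VO2(VCO2) above the VAT breakpoint", vat=True),
    # ------------------------------------------------ calculated, values at VAT
    _calc("VE at VAT", "minute ventilation at the VAT breath [l/min]", vat=True),
    _calc("VCO2 [ml/min] at VAT", "VCO2 at the VAT breath [ml/min]", vat=True),
    _calc("VO2 [ml/min/kg] at VAT", "VO2 at VAT per body mass [ml/min/kg]", vat=True),
    _calc("RF at VAT", "respiratory frequency at the VAT breath [breaths/min]", vat=True),
    _calc("RR at VAT", "timestamp-derived respiratory rate at the VAT breath [breaths/min]", vat=True),
    _calc("VO2-1 at VAT", "VO2 at the VAT breakpoint [ml/min] (provisional formula)", vat=True),
    _calc("VO2-2 at VAT", "VO2 at VAT relative to max VO2 (provisional formula)", vat=True),
    _calc("VCO2-1 at VAT", "VCO2 at the VAT breakpoint [ml/min] (provisional formula)", vat=True),
    _calc("VCO2-2 at VAT", "VCO2 at VAT relative to max VCO2 (provisional formula)", vat=True),
    _calc("VSLOPE", "single-segment OLS slope of VCO2 on VO2 over the incremental phase (provisional)"),
    _calc("predicted VO2",
          "below-VAT VO2-vs-time line extrapolated to test end [ml/min] (provisional)", vat=True),
    _calc("predicted VO2 at VAT/the real VO2 at VAT",
          "below-VAT VO2-vs-time line evaluated at the VAT time, divided by measured VO2 at VAT (provisional)",
          vat=True),
    # ------------------------------------------- calculated, intensity composites
    _calc("max slope * max speed", "peak treadmill grade [%] x peak speed [km/h]"),
    _calc("max slope * max speed * max time", "grade x speed x duration composite"),
    _calc("VEmax/(max slope * max speed)", "max VE / (max grade x max speed)"),
    _calc("VO2max/(max slope * max speed)", "max VO2 / (max grade x max speed)"),
    _calc("time to RER=1", "time from test start until smoothed RER first reaches 1.0 [s]"),
)

#: Spelling variants seen in published tables mapped to canonical registry names.
ALIASES: dict[str, str] = {
    "slop VCO2 versus VE": "slope VCO2 versus VE",
    "slope VCO2 vs VE": "slope VCO2 versus VE",
    "slope VO2 vs VE": "slope VO2 versus VE",
    "Rf": "max RF",
    "max Rf": "max RF",
    "VO2max": "max VO2",
    "VEmax": "max VE",
    "max VO2 (ml/min/kg)": "max VO2 [ml/min/kg]",
    "VO2 [ml/min/kg] at the VAT": "VO2 [ml/min/kg] at VAT",
    "max slope time max speed": "max slope * max speed",
    "max slope time max speed time max time": "max slope * max speed * max time",
    "VEmax/slope*speed": "VEmax/(max slope * max speed)",
    "VO2max/slope*speed": "VO2max/(max slope * max speed)",
    "VO2max/(max slope*max speed)": "VO2max/(max slope * max speed)",
    "slope at 1st min increase VO2": "slope 1st min of VO2 vs. time",
    "slope at 2nd min increase VO2": "slope 2nd min of VO2 vs. time",
    "slope at 3rd min increase VO2": "slope 3rd min of VO2 vs. time",
    "slope at 4th min increase VO2": "slope 4th min of VO2 vs. time",
    "VO2 at 1 min": "VO2 at 1st min",
    "Time at VAT": "time at VAT",
    "time to the VAT": "time to reach VAT",
    "area A": "area A of graph VO2 as a function of VCO2",
    "area B": "area B of graph VO2 as a function of VCO2",
    "VCO2 at VAT": "VCO2 [ml/min] at VAT",
}


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered collection of :class:`FeatureDef` with lookup helpers.

    Invariants (enforced on construction): exactly 51 entries, 12 direct and
    39 calculated, unique names.
    """

    features: tuple[FeatureDef, ...] = _DEFS
    aliases: dict[str, str] = field(default_factory=lambda: dict(ALIASES))

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("registry feature names must be unique")
        if len(self.features) != 51:
            raise ValueError(f"registry must contain 51 features, got {len(self.features)}")
        n_direct = sum(1 for f in self.features if f.kind == "direct")
        if n_direct != 12:
            raise ValueError(f"registry must contain 12 direct features, got {n_direct}")
        for alias, target in self.aliases.items():
            if target not in names:
                raise ValueError(f"alias target {target!r} not in registry")

    # -- lookup -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, name: str) -> bool:
        return name in {f.name for f in self.features} or name in self.aliases

    def __getitem__(self, name: str) -> FeatureDef:
        canonical = self.resolve(name)
        for f in self.features:
            if f.name == canonical:
                return f
        raise KeyError(name)

    def resolve(self, name: str) -> str:
        """Map a (possibly variant) spelling to the canonical registry name."""
        if name in self.aliases:
            return self.aliases[name]
        if name in {f.name for f in self.features}:
            return name
        raise KeyError(f"unknown feature name: {name!r}")

    def index(self, name: str) -> int:
        return self.names.index(self.resolve(name))

    # -- subsets ----------------------------------------------------------
    def stage_names(self, stage: str) -> list[str]:
        """Feature names for a stage filter: 'all', 'full_test' or 'early_minutes'."""
        if stage == "all":
            return self.names
        if stage not in ("full_test", "early_minutes"):
            raise ValueError(f"unknown stage filter: {stage!r}")
        return [f.name for f in self.features if f.stage == stage]

    def direct_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "direct"]

    def calculated_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "calculated"]

    def vat_dependent_names(self) -> list[str]:
        return [f.name for f in self.features if f.requires_vat]


DEFAULT_REGISTRY = FeatureRegistry()


def resolve_name(name: str) -> str:
    """Resolve ``name`` against the default registry (aliases included)."""
    return DEFAULT_REGISTRY.resolve(name)
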