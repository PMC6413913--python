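"""Breath-by-breath CPET recording container.

A recording holds one subject's breath table (one row per breath) plus the
minimal metadata needed by feature extraction: body mass (for per-kg
features) and warm-up duration (minute-wise features are anchored at the end
of the warm-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import DataValidationError, SchemaError

__all__ = ["BREATH_COLUMNS", "CpetRecording"]

#: Canonical breath-table columns (the CSV dialect written by the simulator).
BREATH_COLUMNS: tuple[str, ...] = (
    "t_s",
    "vo2_ml_min",
    "vco2_ml_min",
    "ve_l_min",
    "rf_per_min",
    "vt_l",
    "hr_bpm",
    "speed_kmh",
    "grade_pct",
)


@dataclass
class CpetRecording:
    """One subject's breath-by-breath incremental CPET.

    Parameters
    ----------
    subject_id : str
        Identifier used in cohort manifests and file names.
    mass_kg : float
        Body mass; required for per-kg features.
    warmup_s : float
        Duration of the low-intensity warm-up that precedes the incremental
        ramp.  Breaths with ``t_s >= warmup_s`` form the incremental phase.
    breaths : pandas.DataFrame
        Table with columns :data:`BREATH_COLUMNS`, one row per breath,
        strictly increasing ``t_s``.
    meta : dict
        Free-form provenance (protocol schedule, simulation seeds, ...).
    """

    subject_id: str
    mass_kg: float
    warmup_s: float
    breaths: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in BREATH_COLUMNS if c not in self.breaths.columns]
        if missing:
            raise SchemaError(f"breath table missing required column(s): {', '.join(missing)}")
        if self.mass_kg <= 0:
            raise DataValidationError("mass_kg must be positive")
        t = self.breaths["t_s"].to_numpy(dtype=float)
        if len(t) == 0:
            raise DataValidationError("breath table is empty")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(bad[0]) + 1
            raise DataValidationError(f"breath times not strictly increasing at row {row}")

    # ------------------------------------------------------------------
    @property
    def n_breaths(self) -> int:
        return len(self.breaths)

    @property
    def duration_s(self) -> float:
        return float(self.breaths["t_s"].iloc[-1])

    def incremental(self) -> pd.DataFrame:
        """Breaths of the incremental phase (warm-up excluded)."""
        return self.breaths[self.breaths["t_s"] >= self.warmup_s].reset_index(drop=True)

    def respiratory_rate(self) -> pd.Series:
        """Respiratory rate [breaths/min] derived from breath timestamps.

        Distinct from the cart's ``rf_per_min`` channel: this is 60 over the
        inter-breath interval (the first breath inherits the second's value).
        """
        t = self.breaths["t_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        rr = 60.0 / dt
        rr = np.concatenate([[rr[0]], rr]) if rr.size else np.array([np.nan])
        return pd.Series(rr, index=self.breaths.index, name="rr_per_min")
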