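"""Readers and writers for every on-disk artifact.

All files are plain text: breath tables and cohort manifests are CSV with
'.' decimal separator and UTF-8 encoding (bit-exact fixtures across
platforms), equations and partitions are JSON.  Breath CSVs carry their
subject metadata in leading ``#`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import DataValidationError, SchemaError
from .network import FeatureNetwork, Partition
from .recording import BREATH_COLUMNS, CpetRecording
from .selection import PredictorEquation
from .simulate import Cohort

__all__ = [
    "RunConfig",
    "read_breath_table",
    "write_breath_table",
    "read_equation",
    "write_equation",
    "reference_equations",
    "write_cohort",
    "read_cohort_features",
    "write_network",
    "write_partition",
    "read_feature_matrix",
    "write_feature_matrix",
]


# ===========================================================================
# Run configuration
# ===========================================================================
class RunConfig(BaseModel):
    """Validated configuration of the end-to-end pipeline.

    Every output artifact embeds ``config_hash()`` so a changed configuration
    is always visible in provenance.
    """

    seed: int = 0
    n_subjects: int = Field(88, ge=10)
    train_frac: float = 0.40
    test_frac: float = 0.30
    validation_frac: float = 0.30
    n_runs: int = Field(1000, ge=1)
    n_outer: int = Field(100, ge=1)
    termination_drop: float = Field(0.02, gt=0)
    absolute_drop: bool = False
    consensus_threshold: float = Field(0.5, gt=0, le=1)
    strata: int = Field(3, ge=1)
    stage: Literal["all", "full_test", "early_minutes"] = "all"
    smoothing_window: int = Field(10, ge=1)
    top_fraction: float = Field(0.30, gt=0, le=1)
    weighted_network: bool = True
    global_standardize: bool = False
    outcomes: list[str] = Field(default_factory=lambda: ["pp_w", "mp_w"])

    @field_validator("outcomes")
    @classmethod
    def _known_outcomes(cls, v):
        from .selection import OUTCOMES

        bad = [o for o in v if o not in OUTCOMES]
        if bad:
            raise ValueError(f"unknown outcome tag(s): {bad}")
        return v

    @model_validator(mode="after")
    def _fractions(self):
        total = self.train_frac + self.test_frac + self.validation_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("train/test/validation fractions must sum to 1")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls(**data)
        except Exception as exc:  # pydantic/yaml errors -> schema error
            raise SchemaError(f"invalid config {path}: {exc}") from exc


# ===========================================================================
# Breath tables
# ===========================================================================
def write_breath_table(recording: CpetRecording, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# subject_id: {recording.subject_id}",
        f"# mass_kg: {recording.mass_kg!r}",
        f"# warmup_s: {recording.warmup_s!r}",
    ]
    csv = recording.breaths[list(BREATH_COLUMNS)].to_csv(index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + csv, encoding="utf-8")


def _meta_float(meta: dict[str, str], key: str, default: float) -> float:
    raw = meta.get(key)
    if raw is None:
        return default
    try:
        return float(raw)
    except ValueError as exc:
        raise SchemaError(f"breath table metadata {key!r} is not a number: {raw!r}") from exc


def read_breath_table(path: str | Path) -> CpetRecording:
    """Parse a breath CSV (leading ``#`` comment lines hold metadata).

    Raises :class:`SchemaError` naming any missing required column and
    :class:`DataValidationError` (with the row number) for non-monotone
    breath times.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    missing = [c for c in BREATH_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: breath table missing required column(s): {', '.join(missing)}"
        )
    return CpetRecording(
        subject_id=meta.get("subject_id", path.stem),
        mass_kg=_meta_float(meta, "mass_kg", 70.0),
        warmup_s=_meta_float(meta, "warmup_s", 0.0),
        breaths=frame,
        meta={k: v for k, v in meta.items()
              if k not in ("subject_id", "mass_kg", "warmup_s")},
    )


# ===========================================================================
# Equations
# ===========================================================================
def write_equation(equation: PredictorEquation, path: str | Path) -> None:
    Path(path).write_text(equation.to_json() + "\n", encoding="utf-8")


def read_equation(path: str | Path) -> PredictorEquation:
    try:
        return PredictorEquation.from_json(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid equation JSON {path}: {exc}") from exc


def reference_equations() -> dict[str, PredictorEquation]:
    """The packaged peak-power (6-term) and mean-power (4-term) reference
    prediction equations.  Coefficients act on standardized features, so
    evaluating either equation at the all-zero vector returns its intercept
    (638.4 W for PP, 476.8 W for MP)."""
    from importlib import resources

    out = {}
    for outcome, fname in (("pp_w", "equation_pp_reference.json"),
                           ("mp_w", "equation_mp_reference.json")):
        text = resources.files("aeropower.data").joinpath(fname).read_text(encoding="utf-8")
        out[outcome] = PredictorEquation.from_json(text)
    return out


# ===========================================================================
# Cohorts and feature matrices
# ===========================================================================
def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write one breath CSV per subject plus manifest and truth files."""
    out = Path(out_dir)
    breaths = out / "breaths"
    breaths.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_breath_table(rec, breaths / f"{rec.subject_id}.csv")
    manifest = cohort.manifest()
    manifest.to_csv(out / "manifest.csv", lineterminator="\n")
    (out / "truth.json").write_text(
        json.dumps(cohort.truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_cohort_features(in_dir: str | Path, **extract_kwargs):
    """Read a written cohort's breath tables and extract its feature matrix."""
    from .features import extract_feature_matrix

    in_dir = Path(in_dir)
    breaths = in_dir / "breaths" if (in_dir / "breaths").is_dir() else in_dir
    recs = [read_breath_table(p) for p in sorted(breaths.glob("*.csv"))]
    if not recs:
        raise DataValidationError(f"no breath tables found under {in_dir}")
    return extract_feature_matrix(recs, **extract_kwargs)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path,
                         provenance: dict | None = None) -> None:
    path = Path(path)
    matrix.to_csv(path, lineterminator="\n")
    if provenance is not None:
        path.with_suffix(".provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


# ===========================================================================
# Networks and partitions
# ===========================================================================
def write_network(net: FeatureNetwork, path: str | Path) -> None:
    """Edge list as TSV: feature_a, feature_b, weight."""
    lines = ["feature_a\tfeature_b\tweight"]
    for a, b, w in net.edges():
        lines.append(f"{a}\t{b}\t{w!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_partition(partition: Partition, path: str | Path,
                    provenance: dict | None = None) -> None:
    payload = partition.to_dict()
    if provenance:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
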