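"""Greedy stability-selection regression of anaerobic power on aerobic features.

The procedure, end to end:

1. split the cohort 40/30/30 into train / test / validation, stratified on
   VO2max tertiles so every fitness level appears in every subset;
2. on the train subset, forward-select features one at a time, each step
   adding the candidate whose OLS fit minimizes the train sum of squared
   prediction error; monitor the Spearman correlation on the test subset;
   stop when the added predictor's adjusted R^2 falls more than 2%
   (relative) below the current predictor's, keeping the pre-drop model;
3. repeat the selection over many (default 1000) random re-splits of the
   calibration pool (train + test) and vote: features selected in at least
   half the runs form the consensus set;
4. refit OLS on the whole calibration pool with the consensus features — the
   resulting linear equation ("the predictor") is applied to the held-out
   validation subset;
5. wrap the whole thing in an outer loop (default 100 repeats) over fresh
   40/30/30 splits and report the mean and SD of the validation Spearman
   correlation, RMSE, and percent error.

The greedy inner loop is the hot path (a full protocol runs ~10^5 OLS
fits), so candidate evaluation works on Gram matrices with Schur-complement
updates rather than refitting from scratch; tests cross-check the
coefficients against scikit-learn's ``LinearRegression``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    DataValidationError,
    MissingFeatureError,
    RankDeficiencyError,
    SchemaError,
    StratificationError,
    UndefinedAdjustmentError,
)
from .features import FeatureStandardizer
from .registry import DEFAULT_REGISTRY

__all__ = [
    "OUTCOMES",
    "PredictorEquation",
    "SplitSpec",
    "SelectionRun",
    "StabilityResult",
    "EvaluationMetrics",
    "ProtocolConfig",
    "ProtocolResult",
    "split_stratified",
    "adjusted_r2",
    "greedy_select",
    "stability_select",
    "fit_consensus",
    "predict",
    "evaluate",
    "run_full_protocol",
    "GreedyStabilityRegressor",
]

log = logging.getLogger(__name__)

#: Supported outcome tags.
OUTCOMES = ("pp_w", "mp_w", "pp_w_per_kg", "mp_w_per_kg", "fatigue_pct")

#: Feature used for stratified splitting (VO2max tertiles).
STRATIFY_FEATURE = "max VO2"


# ===========================================================================
# Equation
# ===========================================================================
@dataclass
class PredictorEquation:
    """A fitted linear predictor: outcome = intercept + sum(coef * feature).

    Coefficients act on *standardized* feature values; ``scaler`` (feature ->
    {mean, sd}) is carried along so the equation can be applied to raw
    feature vectors.  Serializes losslessly to/from JSON.
    """

    outcome: str
    intercept: float
    terms: list[tuple[str, float]]
    scaler: dict[str, dict[str, float]] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise SchemaError(f"unknown outcome tag: {self.outcome!r}")
        names = [t[0] for t in self.terms]
        if len(names) != len(set(names)):
            raise SchemaError("equation features must be unique")
        self.terms = [(str(f), float(c)) for f, c in self.terms]

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.terms]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, c in self.terms], dtype=float)

    # -- evaluation -----------------------------------------------------
    def predict(self, X, *, standardized: bool = True) -> np.ndarray:
        """Evaluate the equation on one or many feature vectors.

        ``X`` may be a mapping (one subject), a pandas Series/DataFrame, or
        a 2-D array ordered like ``self.features``.  With
        ``standardized=False`` the carried scaler is applied first.
        """
        if isinstance(X, dict):
            X = pd.Series(X)
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.features if f not in X.columns]
            if missing:
                raise MissingFeatureError(missing)
            V = X[self.features].to_numpy(dtype=float)
        else:
            V = np.atleast_2d(np.asarray(X, dtype=float))
            if V.shape[1] != len(self.terms):
                raise MissingFeatureError(
                    [f for f in self.features[V.shape[1]:]]
                )
        if not standardized:
            if self.scaler is None:
                raise SchemaError("equation carries no scaler; cannot accept raw features")
            mean = np.array([self.scaler[f]["mean"] for f in self.features])
            sd = np.array([self.scaler[f]["sd"] for f in self.features])
            V = (V - mean) / sd
        out = self.intercept + V @ self.coefficients
        return out if out.size > 1 else out  # ndarray either way

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "intercept": self.intercept,
            "terms": [{"feature": f, "coef": c} for f, c in self.terms],
            "scaler": self.scaler,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorEquation":
        try:
            terms = [(t["feature"], t["coef"]) for t in d["terms"]]
            return cls(
                outcome=d["outcome"],
                intercept=float(d["intercept"]),
                terms=terms,
                scaler=d.get("scaler"),
                provenance=d.get("provenance", {}),
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed equation object: {exc}") from exc

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PredictorEquation":
        return cls.from_dict(json.loads(text))


def predict(equation: PredictorEquation, vector) -> np.ndarray:
    """Functional wrapper around :meth:`PredictorEquation.predict`."""
    return equation.predict(vector)


# ===========================================================================
# Splitting
# ===========================================================================
@dataclass
class SplitSpec:
    """Stratified 40/30/30 split specification."""

    fractions: tuple[float, float, float] = (0.40, 0.30, 0.30)
    strata: int = 3
    seed: int | np.random.SeedSequence | np.random.Generator = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DataValidationError("split fractions must sum to 1")
        if self.strata < 1:
            raise DataValidationError("strata must be >= 1")


def _largest_remainder(n: int, fractions: Sequence[float]) -> np.ndarray:
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = n - base.sum()
    order = np.argsort(-rem, kind="stable")
    for g in order[:short]:
        base[g] += 1
    return base


def split_stratified(
    n: int,
    stratify_values: np.ndarray | None,
    spec: SplitSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test/validation index split.

    Subjects are binned into ``spec.strata`` quantile groups of
    ``stratify_values`` (VO2max in the standard protocol) and each stratum
    is allocated to the three subsets so that global sizes follow
    largest-remainder rounding of the fractions and, within each stratum,
    the allocation deviates from the global fractions by at most one
    subject.

    Raises
    ------
    StratificationError
        When ``n`` is too small to populate every stratum; callers may
        retry with ``strata=1`` (the fallback flag lives with the caller).
    """
    if n < 10:
        raise DataValidationError(f"need n >= 10 to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    targets = _largest_remainder(n, spec.fractions)

    if stratify_values is None or spec.strata == 1:
        strata_members = [np.arange(n)]
    else:
        v = np.asarray(stratify_values, dtype=float)
        if len(v) != n:
            raise DataValidationError("stratify_values length mismatch")
        qs = np.quantile(v, np.linspace(0, 1, spec.strata + 1)[1:-1])
        bins = np.searchsorted(qs, v, side="right")
        strata_members = [np.nonzero(bins == s)[0] for s in range(spec.strata)]
        if any(len(m) == 0 for m in strata_members):
            raise StratificationError(
                f"cannot populate {spec.strata} strata with n = {n}; retry with strata = 1"
            )

    remaining = targets.astype(int).copy()
    parts: list[list[int]] = [[], [], []]
    for members in strata_members:
        members = rng.permutation(members)
        m = len(members)
        raw = np.asarray(spec.fractions) * m
        base = np.floor(raw).astype(int)
        base = np.minimum(base, remaining)
        extra = m - base.sum()
        rem = raw - np.floor(raw)
        order = np.argsort(-rem, kind="stable")
        alloc = base.copy()
        gi = 0
        while extra > 0:
            g = order[gi % 3]
            if remaining[g] - alloc[g] > 0:
                alloc[g] += 1
                extra -= 1
            gi += 1
            if gi > 12:  # all preferred groups saturated: fill any open group
                open_g = np.nonzero(remaining - alloc > 0)[0]
                for g in open_g[: extra]:
                    alloc[g] += 1
                extra -= min(extra, len(open_g))
                if len(open_g) == 0:
                    break
        pos = 0
        for g in range(3):
            parts[g].extend(members[pos: pos + alloc[g]].tolist())
            pos += alloc[g]
        remaining -= alloc
    train, test, val = (np.sort(np.array(p, dtype=int)) for p in parts)
    return train, test, val


# ===========================================================================
# Adjusted R^2 and greedy selection
# ===========================================================================
def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination, 1 - (1-R^2)(n-1)/(n-p-1)."""
    if n <= p + 1:
        raise UndefinedAdjustmentError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class SelectionRun:
    """Trace of one greedy forward-selection run."""

    features: list[str]
    adjusted_r2_path: list[float]
    test_spearman_path: list[float]
    train_sse_path: list[float]
    stop_reason: str
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks on ties."""
    ra = rankdata(a)
    rb = rankdata(b)
    sa = ra.std()
    sb = rb.std()
    if sa <= 0 or sb <= 0:
        return float("nan")
    rho = ((ra - ra.mean()) @ (rb - rb.mean())) / (len(a) * sa * sb)
    return float(np.clip(rho, -1.0, 1.0))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{i + 1}" for i in range(X.shape[1])]


def greedy_select(
    X_train,
    y_train,
    X_test=None,
    y_test=None,
    *,
    outcome: str = "pp_w",
    termination_drop: float = 0.02,
    absolute_drop: bool = False,
    max_features: int | None = None,
    collinear_tol: float = 1e-10,
    feature_names: Sequence[str] | None = None,
) -> tuple[SelectionRun, PredictorEquation]:
    """Greedy forward feature selection by train prediction error.

    Each iteration fits OLS of the outcome on the current features plus each
    remaining candidate and adds the candidate minimizing the train sum of
    squared prediction error (ties broken by lower registry/column index).
    The test-subset Spearman correlation is recorded per step (monitoring
    only; it does not feed back into selection).  The loop stops when the
    added predictor's adjusted R^2 is more than ``termination_drop``
    (relative, or absolute with ``absolute_drop``) below the current
    predictor's — returning the pre-drop model — or on a perfect fit, an
    exhausted candidate pool, or the sample-size limit.

    Collinear candidates producing singular normal equations are skipped
    with a log entry.
    """
    Xtr, names = _as_matrix(X_train)
    if feature_names is not None:
        names = [str(f) for f in feature_names]
    ytr = np.asarray(y_train, dtype=float)
    n, p_all = Xtr.shape
    if n < 3:
        raise DataValidationError("need at least 3 training rows")
    have_test = X_test is not None and y_test is not None
    if have_test:
        Xte, _ = _as_matrix(X_test)
        yte = np.asarray(y_test, dtype=float)
        X1te = np.hstack([np.ones((len(yte), 1)), Xte])

    ones = np.ones((n, 1))
    X1 = np.hstack([ones, Xtr])
    G = X1.T @ X1
    gy = X1.T @ ytr
    yy = float(ytr @ ytr)

    sel: list[int] = [0]  # column 0 is the intercept
    Ainv = np.array([[1.0 / n]])
    beta = Ainv @ gy[sel]
    sse = max(yy - float(beta @ gy[sel]), 0.0)
    sst = sse  # intercept-only SSE is the total sum of squares
    adj_cur = 0.0

    cand = list(range(1, p_all + 1))
    if max_features is None:
        max_features = p_all
    run = SelectionRun([], [], [], [], stop_reason="exhausted")

    while cand and len(sel) - 1 < max_features:
        p_new = len(sel)  # number of features after adding one
        if n <= p_new + 1:
            run.stop_reason = "sample_size"
            break
        idx = np.array(cand)
        B = G[np.ix_(sel, idx)]
        AinvB = Ainv @ B
        s = G[idx, idx] - np.einsum("ij,ij->j", B, AinvB)
        r = gy[idx] - beta @ B
        diag = np.maximum(G[idx, idx], 1.0)
        valid = s > collinear_tol * diag
        if not valid.any():
            for j in idx:
                run.skipped.append((names[j - 1], "collinear"))
            run.stop_reason = "exhausted"
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(valid, (r * r) / np.where(valid, s, 1.0), -np.inf)
        best = int(np.argmax(delta))  # argmax keeps the first (lowest index) on ties
        j = int(idx[best])
        sse_new = max(sse - float(delta[best]), 0.0)
        r2_new = 1.0 - sse_new / sst if sst > 0 else 1.0
        adj_new = adjusted_r2(r2_new, n, p_new)

        stop_drop = (
            adj_new < adj_cur - termination_drop
            if absolute_drop
            else adj_new < (1.0 - termination_drop) * adj_cur
        )
        if stop_drop and run.features:
            run.stop_reason = "adjusted_r2_drop"
            break

        # accept the candidate; bordered symmetric inverse update via Schur
        b_j = G[sel, j]
        Ainv_b = Ainv @ b_j
        s_j = float(G[j, j] - b_j @ Ainv_b)
        sel.append(j)
        cand.remove(j)
        k = len(sel)
        new = np.empty((k, k))
        new[: k - 1, : k - 1] = Ainv + np.outer(Ainv_b, Ainv_b) / s_j
        new[: k - 1, k - 1] = -Ainv_b / s_j
        new[k - 1, : k - 1] = -Ainv_b / s_j
        new[k - 1, k - 1] = 1.0 / s_j
        Ainv = new
        beta = Ainv @ gy[sel]
        sse = sse_new
        adj_cur = adj_new
        run.features.append(names[j - 1])
        run.adjusted_r2_path.append(adj_new)
        run.train_sse_path.append(sse)
        if have_test:
            pred = X1te[:, sel] @ beta
            run.test_spearman_path.append(_spearman(pred, yte))
        else:
            run.test_spearman_path.append(float("nan"))

        if sse <= 1e-12 * max(sst, 1.0):
            run.stop_reason = "perfect_fit"
            break
    else:
        if not cand:
            run.stop_reason = "exhausted"
        else:
            run.stop_reason = "max_features"

    # refit the final coefficients directly (the incremental Gram inverse can
    # drift in heavily overfit runs; one lstsq per run is cheap)
    beta, *_ = np.linalg.lstsq(X1[:, sel], ytr, rcond=None)
    terms = list(zip(run.features, beta[1:].tolist()))
    eq = PredictorEquation(
        outcome=outcome,
        intercept=float(beta[0]),
        terms=terms,
        provenance={"stop_reason": run.stop_reason, "n_train": n},
    )
    return run, eq


# ===========================================================================
# Stability voting
# ===========================================================================
@dataclass
class StabilityResult:
    """Per-feature selection frequencies over repeated random re-splits."""

    frequencies: dict[str, float]
    consensus: list[str]
    n_runs: int
    mean_first_rank: dict[str, float] = field(default_factory=dict)


def stability_select(
    X_cal,
    y_cal,
    *,
    n_runs: int = 1000,
    threshold: float = 0.5,
    train_frac: float = 0.40,
    test_frac: float = 0.30,
    strata: int = 3,
    stratify_values: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
    outcome: str = "pp_w",
    **greedy_kwargs,
) -> StabilityResult:
    """Run the greedy selection over ``n_runs`` random calibration re-splits.

    The calibration pool is re-split into train and test at the protocol's
    40:30 ratio (stratified on VO2max tertiles when available) with an
    independent seeded stream per run.  A feature's frequency is the
    fraction of runs selecting it; the consensus set keeps features with
    frequency >= ``threshold``, ordered by frequency (ties by earlier mean
    first-selection position, then column order).
    """
    X, names = _as_matrix(X_cal)
    y = np.asarray(y_cal, dtype=float)
    n = len(y)
    tr = train_frac / (train_frac + test_frac)
    spec_fracs = (tr, 1.0 - tr, 0.0)
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    streams = ss.spawn(n_runs)

    counts = np.zeros(len(names))
    rank_sums = np.zeros(len(names))
    name_idx = {f: i for i, f in enumerate(names)}
    for stream in streams:
        spec = SplitSpec(fractions=spec_fracs, strata=strata, seed=stream)
        try:
            itr, ite, _ = split_stratified(n, stratify_values, spec)
        except StratificationError:
            spec = SplitSpec(fractions=spec_fracs, strata=1, seed=stream)
            itr, ite, _ = split_stratified(n, None, spec)
        run, _ = greedy_select(
            X[itr], y[itr], X[ite], y[ite], outcome=outcome,
            feature_names=names, **greedy_kwargs
        )
        for pos, f in enumerate(run.features):
            k = name_idx[f]
            counts[k] += 1
            rank_sums[k] += pos

    freq = counts / n_runs
    frequencies = {f: float(freq[i]) for i, f in enumerate(names)}
    mean_rank = {
        f: (rank_sums[i] / counts[i] if counts[i] else math.inf)
        for i, f in enumerate(names)
    }
    consensus = [f for f in names if frequencies[f] >= threshold]
    consensus.sort(key=lambda f: (-frequencies[f], mean_rank[f], names.index(f)))
    return StabilityResult(
        frequencies=frequencies,
        consensus=consensus,
        n_runs=n_runs,
        mean_first_rank={f: (float(mean_rank[f]) if math.isfinite(mean_rank[f]) else float("inf"))
                         for f in names},
    )


def fit_consensus(
    X_cal,
    y_cal,
    consensus: Sequence[str],
    *,
    outcome: str = "pp_w",
    scaler: FeatureStandardizer | None = None,
    provenance: dict | None = None,
) -> PredictorEquation:
    """Ordinary least squares on the calibration pool with the consensus set."""
    if not consensus:
        raise DataValidationError("consensus feature set is empty")
    X, names = _as_matrix(X_cal)
    y = np.asarray(y_cal, dtype=float)
    cols = [names.index(f) for f in consensus]
    D = np.hstack([np.ones((len(y), 1)), X[:, cols]])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the columns whose removal restores full rank
        offending = []
        keep = [0]
        for k, f in zip(range(1, D.shape[1]), consensus):
            if np.linalg.matrix_rank(D[:, keep + [k]]) > len(keep):
                keep.append(k)
            else:
                offending.append(f)
        raise RankDeficiencyError(offending)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    sc = scaler.params_ if scaler is not None else None
    if sc is not None:
        sc = {f: sc[f] for f in consensus if f in sc}
    return PredictorEquation(
        outcome=outcome,
        intercept=float(beta[0]),
        terms=list(zip(list(consensus), beta[1:].tolist())),
        scaler=sc,
        provenance=provenance or {},
    )


# ===========================================================================
# Evaluation
# ===========================================================================
@dataclass
class EvaluationMetrics:
    """Validation metrics: Spearman r, RMSE, percent-error mean +/- SD."""

    spearman_r: float
    rmse: float
    pct_err_mean: float
    pct_err_sd: float
    n: int
    spearman_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "spearman_r": self.spearman_r,
            "rmse": self.rmse,
            "pct_err_mean": self.pct_err_mean,
            "pct_err_sd": self.pct_err_sd,
            "n": self.n,
            "spearman_defined": self.spearman_defined,
        }


def evaluate(y_true, y_pred) -> EvaluationMetrics:
    """Compare predictions with observations.

    Spearman uses average ranks on ties and is flagged undefined for
    constant predictions; RMSE is sqrt(mean squared error); percent error is
    100*|pred - obs|/obs per subject (observations <= 0 are excluded from
    the percent error with a log entry) reported as mean +/- SD.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) < 3:
        raise DataValidationError("need at least 3 labeled rows to evaluate")
    rho = _spearman(p, y)
    defined = not math.isnan(rho)
    rmse = float(np.sqrt(np.mean((p - y) ** 2)))
    pos = y > 0
    if not pos.all():
        log.info("excluding %d non-positive observations from percent error", int((~pos).sum()))
    if pos.any():
        pe = 100.0 * np.abs(p[pos] - y[pos]) / y[pos]
        pe_mean, pe_sd = float(pe.mean()), float(pe.std(ddof=1)) if len(pe) > 1 else 0.0
    else:
        pe_mean = pe_sd = float("nan")
    return EvaluationMetrics(
        spearman_r=rho if defined else float("nan"),
        rmse=rmse,
        pct_err_mean=pe_mean,
        pct_err_sd=pe_sd,
        n=len(y),
        spearman_defined=defined,
    )


# ===========================================================================
# Full protocol
# ===========================================================================
@dataclass
class ProtocolConfig:
    """Configuration of the full repeated-validation protocol."""

    n_outer: int = 100
    n_runs: int = 1000
    fractions: tuple[float, float, float] = (0.40, 0.30, 0.30)
    strata: int = 3
    consensus_threshold: float = 0.5
    termination_drop: float = 0.02
    absolute_drop: bool = False
    stage: str = "all"  # 'all' | 'full_test' | 'early_minutes'
    global_standardize: bool = False  # standardize globally before splitting
    seed: int = 0
    outcome: str = "pp_w"
    max_features: int | None = None


@dataclass
class ProtocolResult:
    """Per-repeat validation metrics plus aggregates and consensus votes."""

    per_repeat: list[EvaluationMetrics]
    consensus_sets: list[list[str]]
    equations: list[PredictorEquation]
    config: ProtocolConfig

    @property
    def spearman_values(self) -> np.ndarray:
        return np.array([m.spearman_r for m in self.per_repeat])

    @property
    def spearman_mean(self) -> float:
        return float(np.nanmean(self.spearman_values))

    @property
    def spearman_sd(self) -> float:
        return float(np.nanstd(self.spearman_values, ddof=1))

    @property
    def rmse_mean(self) -> float:
        return float(np.nanmean([m.rmse for m in self.per_repeat]))

    @property
    def pct_err_mean(self) -> float:
        return float(np.nanmean([m.pct_err_mean for m in self.per_repeat]))

    @property
    def pct_err_sd(self) -> float:
        return float(np.nanmean([m.pct_err_sd for m in self.per_repeat]))

    def feature_votes(self) -> dict[str, float]:
        """Fraction of outer repeats whose consensus contains each feature."""
        votes: dict[str, float] = {}
        for s in self.consensus_sets:
            for f in s:
                votes[f] = votes.get(f, 0.0) + 1.0
        return {f: v / len(self.consensus_sets) for f, v in sorted(
            votes.items(), key=lambda kv: -kv[1])}

    def to_dict(self) -> dict:
        return {
            "outcome": self.config.outcome,
            "stage": self.config.stage,
            "n_outer": self.config.n_outer,
            "n_runs": self.config.n_runs,
            "spearman_mean": self.spearman_mean,
            "spearman_sd": self.spearman_sd,
            "rmse_mean": self.rmse_mean,
            "pct_err_mean": self.pct_err_mean,
            "pct_err_sd": self.pct_err_sd,
            "feature_votes": self.feature_votes(),
            "per_repeat": [m.to_dict() for m in self.per_repeat],
        }


def run_full_protocol(features: pd.DataFrame, y, config: ProtocolConfig) -> ProtocolResult:
    """Outer repeated-validation loop of the selection procedure.

    Each of ``config.n_outer`` repeats draws a fresh stratified 40/30/30
    split, standardizes on the calibration pool (or globally with
    ``global_standardize``), votes features over ``config.n_runs`` greedy runs,
    refits the consensus equation on the calibration pool, and scores it on
    the held-out validation subset.
    """
    if config.stage != "all":
        keep = [c for c in features.columns if c in DEFAULT_REGISTRY
                and DEFAULT_REGISTRY[c].stage == config.stage]
        if not keep:
            raise DataValidationError(f"no features for stage {config.stage!r}")
        features = features[keep]
    y = np.asarray(y, dtype=float)
    n = len(y)
    stratify = (
        features[STRATIFY_FEATURE].to_numpy()
        if STRATIFY_FEATURE in features.columns
        else None
    )

    if config.global_standardize:
        features_all_z, global_scaler = _std(features)

    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_outer)
    per_repeat, consensus_sets, equations = [], [], []
    for rep, stream in enumerate(streams):
        s_split, s_runs = stream.spawn(2)
        spec = SplitSpec(fractions=config.fractions, strata=config.strata, seed=s_split)
        try:
            itr, ite, iva = split_stratified(n, stratify, spec)
        except StratificationError:
            spec = SplitSpec(fractions=config.fractions, strata=1, seed=s_split)
            itr, ite, iva = split_stratified(n, None, spec)
        ical = np.sort(np.concatenate([itr, ite]))

        if config.global_standardize:
            Z_cal = features_all_z.iloc[ical]
            Z_val = features_all_z.iloc[iva]
            scaler = global_scaler
        else:
            Z_cal_raw = features.iloc[ical]
            Z_cal, scaler = _std(Z_cal_raw)
            Z_val = scaler.transform(features.iloc[iva])

        stab = stability_select(
            Z_cal,
            y[ical],
            n_runs=config.n_runs,
            threshold=config.consensus_threshold,
            train_frac=config.fractions[0],
            test_frac=config.fractions[1],
            strata=config.strata,
            stratify_values=stratify[ical] if stratify is not None else None,
            seed=s_runs,
            outcome=config.outcome,
            termination_drop=config.termination_drop,
            absolute_drop=config.absolute_drop,
            max_features=config.max_features,
        )
        consensus = stab.consensus or _top_fallback(stab)
        eq = fit_consensus(
            Z_cal, y[ical], consensus, outcome=config.outcome, scaler=scaler,
            provenance={"repeat": rep, "n_runs": config.n_runs},
        )
        pred = eq.predict(Z_val)
        per_repeat.append(evaluate(y[iva], pred))
        consensus_sets.append(consensus)
        equations.append(eq)
    return ProtocolResult(per_repeat, consensus_sets, equations, config)


def _top_fallback(stab: StabilityResult) -> list[str]:
    """If no feature clears the consensus threshold, keep the single most
    frequent one so the protocol still yields an equation."""
    best = max(stab.frequencies, key=lambda f: stab.frequencies[f])
    return [best]


def _std(frame: pd.DataFrame):
    scaler = FeatureStandardizer().fit(frame)
    return scaler.transform(frame), scaler


# ===========================================================================
# scikit-learn estimator
# ===========================================================================
class GreedyStabilityRegressor(BaseEstimator, RegressorMixin):
    """Greedy stability-selection linear regressor (scikit-learn API).

    ``fit(X, y)`` treats the supplied rows as the calibration pool: it
    standardizes the features, votes them over ``n_runs`` stratified
    train/test re-splits of the greedy forward selection, and refits an OLS
    equation on the consensus set.  ``predict(X)`` applies the fitted
    equation to raw (unstandardized) feature rows.

    Parameters mirror the protocol defaults: 1000 voting runs, consensus at
    50% frequency, termination on a 2% relative adjusted-R^2 drop, 40:30
    train:test re-splits stratified on VO2max tertiles.

    Attributes (after fit): ``equation_``, ``selected_features_``,
    ``frequencies_``, ``intercept_``, ``coef_``, ``scaler_``.
    """

    def __init__(
        self,
        n_runs: int = 1000,
        consensus_threshold: float = 0.5,
        termination_drop: float = 0.02,
        absolute_drop: bool = False,
        train_frac: float = 0.40,
        test_frac: float = 0.30,
        strata: int = 3,
        stratify_on: str | None = STRATIFY_FEATURE,
        outcome: str = "pp_w",
        max_features: int | None = None,
        random_state: int | None = None,
    ):
        self.n_runs = n_runs
        self.consensus_threshold = consensus_threshold
        self.termination_drop = termination_drop
        self.absolute_drop = absolute_drop
        self.train_frac = train_frac
        self.test_frac = test_frac
        self.strata = strata
        self.stratify_on = stratify_on
        self.outcome = outcome
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = FeatureStandardizer._as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise DataValidationError("X and y length mismatch")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        Z, scaler = _std(X)
        stratify = (
            X[self.stratify_on].to_numpy()
            if self.stratify_on and self.stratify_on in X.columns
            else None
        )
        stab = stability_select(
            Z, y,
            n_runs=self.n_runs,
            threshold=self.consensus_threshold,
            train_frac=self.train_frac,
            test_frac=self.test_frac,
            strata=self.strata,
            stratify_values=stratify,
            seed=0 if self.random_state is None else self.random_state,
            outcome=self.outcome,
            termination_drop=self.termination_drop,
            absolute_drop=self.absolute_drop,
            max_features=self.max_features,
        )
        consensus = stab.consensus or _top_fallback(stab)
        self.stability_ = stab
        self.frequencies_ = stab.frequencies
        self.selected_features_ = list(consensus)
        self.scaler_ = scaler
        self.equation_ = fit_consensus(
            Z, y, consensus, outcome=self.outcome, scaler=scaler,
            provenance={"n_runs": self.n_runs, "seed": self.random_state},
        )
        self.intercept_ = self.equation_.intercept
        self.coef_ = self.equation_.coefficients
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "equation_")
        X = FeatureStandardizer._as_frame(X)
        return self.equation_.predict(X, standardized=False)
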