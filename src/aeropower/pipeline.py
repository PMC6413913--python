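"""End-to-end pipeline: simulate -> extract -> train -> cluster -> report.

The pipeline is deterministic given its :class:`~aeropower.io.RunConfig`:
re-running the same configuration produces byte-identical JSON and markdown
reports (they contain no timestamps; timing goes to the log only).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from .io import (
    RunConfig,
    write_cohort,
    write_equation,
    write_feature_matrix,
    write_network,
    write_partition,
)
from .network import ModularityClustering
from .selection import ProtocolConfig, fit_consensus, run_full_protocol, stability_select
from .features import FeatureStandardizer
from .simulate import simulate_cohort

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_pipeline(config: RunConfig, out_dir: str | Path, *, write_breaths: bool = True) -> dict:
    """Execute the full study flow and emit a report bundle.

    Stages: cohort simulation, feature extraction, greedy stability-selection
    training (one model per requested outcome, each with its repeated
    validation protocol), and correlation-network clustering.  Artifacts
    (cohort CSVs, feature matrix, per-outcome equation JSON, network edge
    list, partition JSON, ``report.json`` + ``report.md``) are written under
    ``out_dir``; the returned dict equals the JSON report.

    Any stage failure propagates with the stage recorded in the exception
    message; partial outputs written so far are left on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"config": config.model_dump(), "config_hash": chash}

    try:
        with _stage("simulate"):
            cohort = simulate_cohort(config.n_subjects, seed=config.seed)
            if write_breaths:
                write_cohort(cohort, out / "cohort")
        report["cohort"] = {
            "n": cohort.n,
            "n_female": sum(1 for p in cohort.profiles if p.sex == "female"),
            "n_male": sum(1 for p in cohort.profiles if p.sex == "male"),
            "outcome_means": {k: round(float(v), 4) for k, v in
                              cohort.outcomes.mean().items()},
        }

        with _stage("extract"):
            features = cohort.features
            write_feature_matrix(
                features, out / "features.csv",
                provenance={"config_hash": chash,
                            "smoothing_window": config.smoothing_window},
            )

        report["models"] = {}
        for outcome in config.outcomes:
            with _stage(f"train[{outcome}]"):
                pconf = ProtocolConfig(
                    n_outer=config.n_outer,
                    n_runs=config.n_runs,
                    fractions=(config.train_frac, config.test_frac,
                               config.validation_frac),
                    strata=config.strata,
                    consensus_threshold=config.consensus_threshold,
                    termination_drop=config.termination_drop,
                    absolute_drop=config.absolute_drop,
                    stage=config.stage,
                    global_standardize=config.global_standardize,
                    seed=config.seed,
                    outcome=outcome,
                )
                result = run_full_protocol(features, cohort.outcomes[outcome], pconf)
                # final published-style equation: stability vote + refit on the
                # full cohort
                scaler = FeatureStandardizer().fit(features)
                Z = scaler.transform(features)
                stab = stability_select(
                    Z, cohort.outcomes[outcome].to_numpy(),
                    n_runs=config.n_runs,
                    threshold=config.consensus_threshold,
                    strata=config.strata,
                    stratify_values=features["max VO2"].to_numpy(),
                    seed=config.seed,
                    outcome=outcome,
                    termination_drop=config.termination_drop,
                    absolute_drop=config.absolute_drop,
                )
                consensus = stab.consensus or [
                    max(stab.frequencies, key=lambda f: stab.frequencies[f])
                ]
                equation = fit_consensus(
                    Z, cohort.outcomes[outcome].to_numpy(), consensus,
                    outcome=outcome, scaler=scaler,
                    provenance={"config_hash": chash, "seed": config.seed,
                                "n_runs": config.n_runs, "n_outer": config.n_outer},
                )
                write_equation(equation, out / f"model_{outcome}.json")
                summary = result.to_dict()
                summary.pop("per_repeat")
                report["models"][outcome] = {
                    "equation": equation.to_dict(),
                    "metrics": summary,
                }

        with _stage("cluster"):
            clust = ModularityClustering(
                top_fraction=config.top_fraction, weighted=config.weighted_network
            ).fit(features)
            write_network(clust.network_, out / "network_edges.tsv")
            write_partition(clust.partition_, out / "partition.json",
                            provenance={"config_hash": chash})
        report["clustering"] = {
            "n_groups": clust.partition_.n_groups,
            "Q": clust.modularity_,
            "groups": clust.partition_.groups(),
        }
    except Exception as exc:
        raise type(exc)(f"[pipeline stage failure] {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "report.md").write_text(_markdown_report(report), encoding="utf-8")
    return report


def _markdown_report(report: dict) -> str:
    """Markdown summary mirroring the standard equation/metrics table layout."""
    lines = [
        "# aeropower pipeline report",
        "",
        f"- config hash: `{report['config_hash']}`",
        f"- cohort: n = {report['cohort']['n']} "
        f"({report['cohort']['n_female']} female / {report['cohort']['n_male']} male)",
        "",
        "| Category | Regression equation | Spearman r (SD) | RMSE | Mean ± SD of % error |",
        "|---|---|---|---|---|",
    ]
    for outcome, model in report.get("models", {}).items():
        eq = model["equation"]
        terms = " ".join(
            f"{'+' if t['coef'] >= 0 else '-'} {abs(t['coef']):.1f}*{t['feature']}"
            for t in eq["terms"]
        )
        m = model["metrics"]
        lines.append(
            f"| {outcome} | {eq['intercept']:.1f} {terms} | "
            f"{m['spearman_mean']:.3f} ({m['spearman_sd']:.3f}) | "
            f"{m['rmse_mean']:.1f} | {m['pct_err_mean']:.1f} ± {m['pct_err_sd']:.1f} |"
        )
    lines += [
        "",
        f"## Feature-network clustering",
        "",
        f"- modularity Q = {report['clustering']['Q']:.4f}, "
        f"{report['clustering']['n_groups']} groups",
    ]
    for i, group in enumerate(report["clustering"]["groups"], start=1):
        lines.append(f"- group {i}: {', '.join(group)}")
    return "\n".join(lines) + "\n"
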