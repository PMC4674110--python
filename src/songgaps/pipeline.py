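"""End-to-end pipeline driver: segment -> syntax -> coupling (-> change).

Every artifact embeds the config hash and seed; rerunning with the same
configuration and inputs is byte-identical for all non-timestamp content
(no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as sgio
from . import stats
from .lmm import MixedModelResult

log = logging.getLogger("songgaps")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    labels_dir: str
    out_dir: str
    labels_dir_b: str | None = None  # second condition for change analyses
    change_mode: str = "age"  # or "context"; recorded in the report
    audio: bool = False
    threshold_frac: float = 0.1
    alpha: float = 0.05
    min_occurrences: int = 10
    min_instances: int = 5
    max_context_order: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_occurrences < 1 or self.min_instances < 1:
            raise ValueError("filters must be >= 1")


def _result_rows(name: str, fit: MixedModelResult, term: str) -> list[dict]:
    c = fit.coef(term)
    return [
        {
            "analysis": name,
            "term": term,
            "estimate": c["estimate"],
            "se": c["se"],
            "F": c["F"],
            "df_num": c["df_num"],
            "df_den": c["df_den"],
            "p": c["p"],
        }
    ]


def _branch_point_report(analysis: stats.CorpusAnalysis) -> dict:
    out = {}
    for bird, bps in sorted(analysis.branch_points.items()):
        out[bird] = [
            {
                "context": bp.context,
                "targets": [
                    {"label": t, "count": c, "p": p} for t, c, p in bp.targets
                ],
                "n_occurrences": bp.n_occurrences,
                "n_terminations": bp.n_terminations,
                "classification": bp.classification,
                "split": bp.split,
                "lrt": (
                    None
                    if bp.lrt is None
                    else {"G": bp.lrt.g, "df": bp.lrt.df, "p": bp.lrt.pvalue}
                ),
            }
            for bp in bps
        ]
    return out


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts under
    ``config.out_dir``.  Returns the run report (also written as JSON)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = sgio.provenance(dataclasses.asdict(config), config.seed)
    report: dict = {"provenance": prov, "stages": {}}
    results: list[dict] = []

    def analyze(labels_dir, condition):
        _stage(f"segment[{condition}]")
        try:
            events = sgio.load_events(
                labels_dir,
                audio=config.audio,
                threshold_frac=config.threshold_frac,
                condition=condition,
            )
        except Exception as exc:
            raise RuntimeError(f"segment stage failed: {exc}") from exc
        _stage(f"syntax[{condition}]")
        try:
            analysis = stats.analyze_corpus(
                events,
                alpha=config.alpha,
                min_occurrences=config.min_occurrences,
                min_instances=config.min_instances,
                max_context_order=config.max_context_order,
            )
        except Exception as exc:
            raise RuntimeError(f"syntax stage failed: {exc}") from exc
        report["stages"][f"counts_{condition}"] = {
            "n_events": int(len(events)),
            "n_branch_points": int(
                sum(len(v) for v in analysis.branch_points.values())
            ),
            "n_coupling_rows": int(len(analysis.coupling)),
        }
        return analysis

    analysis_a = analyze(config.labels_dir, "A")
    (out / "branch_points_A.json").write_text(
        json.dumps({**prov, "branch_points": _branch_point_report(analysis_a)},
                   sort_keys=True, indent=1)
    )
    analysis_a.coupling.to_csv(out / "coupling_table_A.csv", index=False)

    _stage("couple")
    branch_rows = analysis_a.coupling[
        analysis_a.coupling["transition_type"] == "branch"
    ]
    try:
        gaps = branch_rows["median_gap_ms"].to_numpy()
        screen = stats.screen_normality(gaps) if len(gaps) >= 3 else None
        fit = stats.fit_coupling_model(branch_rows)
        results += _result_rows("coupling_p_vs_log10_gap", fit, "p")
        report["stages"]["couple"] = {
            "n_rows": int(len(branch_rows)),
            "slope": fit.coef("p")["estimate"],
            "shapiro_raw_p": None if screen is None else screen.pvalue,
            "shapiro_log10_p": None if screen is None else screen.log_pvalue,
        }
        if {"branch", "stereotyped"} <= set(
            analysis_a.coupling["transition_type"]
        ):
            fit_types = stats.compare_transition_types(analysis_a.coupling)
            results += _result_rows(
                "branch_vs_stereotyped", fit_types, "branch_minus_stereotyped"
            )
        if "log10_amp" in branch_rows.columns and branch_rows["log10_amp"].notna().all():
            _resid_rows, fit_amp, fit_resid = stats.residualize_amplitude(branch_rows)
            results += _result_rows("gap_vs_amplitude", fit_amp, "log10_amp")
            results += _result_rows("coupling_amp_residualized", fit_resid, "p")
    except Exception as exc:
        raise RuntimeError(f"couple stage failed: {exc}") from exc

    if config.labels_dir_b is not None:
        analysis_b = analyze(config.labels_dir_b, "B")
        analysis_b.coupling.to_csv(out / "coupling_table_B.csv", index=False)
        _stage("change")
        try:
            change_df, stereo_df = stats.build_change_table(
                analysis_a, analysis_b, alpha=config.alpha,
                min_instances=config.min_instances,
            )
            change_df.to_csv(out / "change_table.csv", index=False)
            fit_log, fit_pct = stats.change_coupling_analysis(change_df)
            results += _result_rows(
                f"change_{config.change_mode}_log10", fit_log, "delta_p"
            )
            results += _result_rows(
                f"change_{config.change_mode}_pct", fit_pct, "delta_p"
            )
            report["stages"]["change"] = {
                "mode": config.change_mode,
                "n_change_rows": int(len(change_df)),
                "n_stereotyped_rows": int(len(stereo_df)),
                "categories": change_df["category"].value_counts().to_dict(),
            }
            if len(stereo_df) and change_df["category"].nunique() >= 1:
                contrast = stats.category_contrast(change_df, stereo_df)
                contrast.lsmeans.to_csv(out / "category_lsmeans.csv", index=False)
                contrast.tukey.to_csv(out / "category_tukey.csv", index=False)
                report["stages"]["change"]["omnibus"] = contrast.omnibus
        except Exception as exc:
            raise RuntimeError(f"change stage failed: {exc}") from exc

    res_df = pd.DataFrame(results)
    res_df.to_csv(out / "results.csv", index=False, float_format="%.10g")
    report["results"] = results
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1,
                                                default=float))
    return report
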