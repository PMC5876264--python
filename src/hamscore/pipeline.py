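"""Umbrella pipeline: score -> summarize -> evaluate, with report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import HamscoreError, ValidationError
from .evaluation import EvaluationResult, evaluate
from .io import Exclusion, load_records, write_scored_records
from .rubric import InjuryRecord, Rubric, load_rubric, score_injury
from .summary import CohortSummary, round_half_up, summarize_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    input_path: Path
    output_dir: Path
    rubric_path: Optional[Path] = None
    threshold: int = 10
    report_formats: tuple[str, ...] = ("json", "md")

    def __post_init__(self):
        if self.threshold < 1:
            raise ValidationError("threshold must be >= 1", field="threshold")
        unknown = set(self.report_formats) - {"json", "md"}
        if unknown:
            raise ValidationError(f"unknown report format(s) {sorted(unknown)}")


@dataclass
class PipelineResult:
    records: list[InjuryRecord]
    analyzed: list[InjuryRecord]
    exclusions: list[Exclusion]
    n_mri_negative: int
    summary: CohortSummary
    evaluation: Optional[EvaluationResult]
    outputs: dict[str, Path]


def _stage(name: str):
    """Re-raise module errors with a stage label for pipeline diagnostics."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, HamscoreError):
                exc.args = (f"[{name}] {exc}",)
            return False

    return _ctx()


def _fit_line(scores: np.ndarray, rts: np.ndarray) -> pd.DataFrame:
    """OLS fit of rts on score, with a 95% CI band over the score range."""
    X = sm.add_constant(scores.astype(float))
    fit = sm.OLS(rts.astype(float), X).fit()
    grid = np.linspace(scores.min(), scores.max(), 50)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    return pd.DataFrame(
        {
            "score": grid,
            "fit": pred["mean"].to_numpy(),
            "ci_low": pred["mean_ci_lower"].to_numpy(),
            "ci_high": pred["mean_ci_upper"].to_numpy(),
        }
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read, score, summarize and evaluate a record CSV; write the bundle.

    Deterministic given the input file; no stage mutates its input.  The
    analysis cohort is the MRI-positive records with a documented RTS; the
    exclusion accounting (input = analyzed + excluded, itemized) is written
    to ``exclusions.json``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    with _stage("read"):
        rubric = load_rubric(config.rubric_path)
        result = load_records(config.input_path)
    records = result.records

    with _stage("score"):
        scores = [score_injury(r, rubric) for r in records]
    path = outdir / "scored_records.csv"
    write_scored_records(records, scores, path)
    outputs["scored_records"] = path

    analyzed = [
        r for r in records if r.mri_positive and r.rts_days is not None
    ]
    n_negative = sum(1 for r in records if not r.mri_positive)
    n_no_rts = sum(1 for r in records if r.mri_positive and r.rts_days is None)
    log.info(
        "flow: %d input rows -> %d analyzed (%d MRI-negative, %d without RTS, %d invalid)",
        result.n_input, len(analyzed), n_negative, n_no_rts, len(result.exclusions),
    )

    with _stage("summarize"):
        summary = summarize_cohort(analyzed, rubric=rubric)
    if "json" in config.report_formats:
        path = outdir / "summary.json"
        path.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
        outputs["summary_json"] = path
    if "md" in config.report_formats:
        path = outdir / "summary.md"
        path.write_text(summary.to_markdown() + "\n")
        outputs["summary_md"] = path

    evaluation: Optional[EvaluationResult] = None
    if len(analyzed) >= 5:
        with _stage("evaluate"):
            totals = np.array([score_injury(r, rubric).total for r in analyzed])
            rts = np.array([float(r.rts_days) for r in analyzed])
            evaluation = evaluate(totals, rts, config.threshold)
        if "json" in config.report_formats:
            path = outdir / "evaluation.json"
            path.write_text(json.dumps(evaluation.to_dict(), indent=2) + "\n")
            outputs["evaluation_json"] = path
        if "md" in config.report_formats:
            path = outdir / "evaluation.md"
            path.write_text(_evaluation_markdown(evaluation) + "\n")
            outputs["evaluation_md"] = path

        # plot-ready data: scatter + fit, dichotomized groups, per-muscle-count means
        with _stage("plot-data"):
            scatter = pd.DataFrame({"score": totals, "rts_days": rts})
            path = outdir / "fig_scatter.csv"
            scatter.to_csv(path, index=False)
            outputs["fig_scatter"] = path

            path = outdir / "fig_fit.csv"
            _fit_line(totals, rts).to_csv(path, index=False)
            outputs["fig_fit"] = path

            groups = pd.DataFrame(
                {
                    "group": np.where(
                        totals >= config.threshold,
                        f">={config.threshold}",
                        f"<{config.threshold}",
                    ),
                    "rts_days": rts,
                }
            )
            path = outdir / "fig_groups.csv"
            groups.to_csv(path, index=False)
            outputs["fig_groups"] = path

            per_count = (
                pd.DataFrame(
                    {"n_muscles": [r.n_muscles for r in analyzed], "rts_days": rts}
                )
                .groupby("n_muscles")["rts_days"]
                .agg(n="size", mean_rts="mean", sd_rts=lambda v: v.std(ddof=1))
                .reset_index()
            )
            path = outdir / "fig_muscle_counts.csv"
            per_count.to_csv(path, index=False)
            outputs["fig_muscle_counts"] = path

    accounting = {
        "n_input": result.n_input,
        "n_records": len(records),
        "n_analyzed": len(analyzed),
        "n_mri_negative": n_negative,
        "n_without_rts": n_no_rts,
        "n_invalid": len(result.exclusions),
        "exclusions": [
            {"row": e.row, "athlete_id": e.athlete_id, "reason": e.reason}
            for e in result.exclusions
        ],
    }
    path = outdir / "exclusions.json"
    path.write_text(json.dumps(accounting, indent=2) + "\n")
    outputs["exclusions"] = path

    return PipelineResult(
        records=records,
        analyzed=analyzed,
        exclusions=result.exclusions,
        n_mri_negative=n_negative,
        summary=summary,
        evaluation=evaluation,
        outputs=outputs,
    )


def _evaluation_markdown(ev: EvaluationResult) -> str:
    d = ev.to_dict()
    r1 = round_half_up
    lines = [
        "# Score vs RTS evaluation",
        "",
        f"- n = {d['n']}",
        f"- Pearson r = {round_half_up(d['pearson_r'], 3)} (p = {round_half_up(d['pearson_p'], 3)})",
        f"- Spearman rho = {round_half_up(d['spearman_rho'], 3)} (p = {round_half_up(d['spearman_p'], 3)})",
        f"- Variance explained = {r1(d['variance_explained_pct'])}%",
        "",
        "## Normality (Lilliefors-corrected KS)",
        "",
    ]
    for var, ks in d["ks_normality"].items():
        lines.append(
            f"- {var}: D = {round_half_up(ks['statistic'], 3)}, p = {round_half_up(ks['p'], 3)}"
        )
    lines += ["", f"## Groups at threshold {d['threshold']}", ""]
    for label, g in (("below", d["group_below"]), ("at_or_above", d["group_at_or_above"])):
        if g is None:
            lines.append(f"- {label}: empty")
        else:
            sd = round_half_up(g["sd_rts"], 2) if g["sd_rts"] is not None else "n/a"
            lines.append(
                f"- {label}: n = {g['n']}, mean RTS = {r1(g['mean_rts'])}, "
                f"median = {r1(g['median_rts'])}, SD = {sd}"
            )
    if d["mean_difference_days"] is not None:
        lines.append(f"- mean difference = {r1(d['mean_difference_days'])} days")
    if d["difference_ci95"] is not None:
        lo, hi = d["difference_ci95"]
        lines.append(f"- 95% CI of difference = ({r1(lo)}, {r1(hi)})")
    if d["effect_size_d"] is not None:
        lines.append(f"- Cohen's d = {round_half_up(d['effect_size_d'], 2)}")
    for note in d["notes"]:
        lines.append(f"> note: {note}")
    return "\n".join(lines)
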