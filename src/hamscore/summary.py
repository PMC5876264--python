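"""Cohort description: category counts with percentages and continuous summaries."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .rubric import ComponentScores, InjuryRecord, Rubric, default_rubric

__all__ = [
    "round_half_up",
    "CategoryShare",
    "ContinuousSummary",
    "CohortSummary",
    "summarize_categorical",
    "summarize_continuous",
    "summarize_cohort",
]

log = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (5 rounds away from zero), as printed reports do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoryShare:
    category: str
    count: int
    percent: float  # of this variable's own total, one decimal, half-up


@dataclass(frozen=True)
class ContinuousSummary:
    n: int
    mean: float
    ci95: tuple[float, float]  # t-based CI of the mean
    median: float
    iqr: float  # Q3 - Q1, linear-interpolation quartiles
    sd: float  # sample SD, n-1 denominator
    min: float
    max: float


def summarize_categorical(
    counts: Iterable[tuple[str, int]]
) -> list[CategoryShare]:
    """Percentages against the supplied counts' own total.

    The denominator is never assumed to be a fixed cohort size; it is the
    sum of the counts handed in.  Percents are rounded half-up to one
    decimal.
    """
    items = [(str(c), int(n)) for c, n in counts]
    if any(n < 0 for _, n in items):
        raise ValidationError("counts must be non-negative")
    total = sum(n for _, n in items)
    if total == 0:
        raise ValidationError("at least one count must be positive")
    return [
        CategoryShare(c, n, round_half_up(100.0 * n / total, 1))
        for c, n in items
    ]


def summarize_continuous(values: Sequence[float]) -> ContinuousSummary:
    """Mean with 95% t-CI, median, IQR (Q3-Q1), sample SD, min, max."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValidationError("summarize_continuous needs at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return ContinuousSummary(
        n=n,
        mean=mean,
        ci95=(mean - half, mean + half),
        median=float(med),
        iqr=float(q3 - q1),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )


# Bin labels used for the categorical rendering of the two size variables.
TRANSVERSE_BIN_EDGES = [(0.0, 25.0, "<25%"), (25.0, 50.0, "25-<50%"),
                        (50.0, 75.0, "50-<75%"), (75.0, None, ">=75%")]
SAGITTAL_BIN_EDGES = [(0.0, 5.0, "<5 cm"), (5.0, 10.0, "5-<10 cm"),
                      (10.0, None, ">=10 cm")]


def _bin_label(x: float, edges) -> str:
    for lo, hi, label in edges:
        if x >= lo and (hi is None or x < hi):
            return label
    raise ValidationError(f"value {x} outside binning domain")


@dataclass
class CohortSummary:
    """Counts/percentages per categorical variable and continuous summaries."""

    categorical: dict[str, list[CategoryShare]]
    continuous: dict[str, ContinuousSummary]
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "categorical": {
                var: [
                    {"category": s.category, "count": s.count, "percent": s.percent}
                    for s in shares
                ]
                for var, shares in self.categorical.items()
            },
            "continuous": {
                var: {
                    "n": c.n,
                    "mean": c.mean,
                    "ci95": list(c.ci95),
                    "median": c.median,
                    "iqr": c.iqr,
                    "sd": c.sd,
                    "min": c.min,
                    "max": c.max,
                }
                for var, c in self.continuous.items()
            },
            "warnings": list(self.warnings),
        }

    def to_markdown(self) -> str:
        lines: list[str] = ["# Cohort summary", ""]
        for var, shares in self.categorical.items():
            lines += [f"## {var}", "", "| category | n | % |", "|---|---|---|"]
            lines += [
                f"| {s.category} | {s.count} | {s.percent} |" for s in shares
            ]
            lines.append("")
        if self.continuous:
            lines += ["## Continuous variables", ""]
            header = "| statistic | " + " | ".join(self.continuous) + " |"
            lines += [header, "|" + "---|" * (len(self.continuous) + 1)]

            def row(label, fn):
                cells = " | ".join(fn(c) for c in self.continuous.values())
                return f"| {label} | {cells} |"

            r1 = round_half_up
            lines += [
                row("Mean (95% CI)", lambda c: f"{r1(c.mean)} ({r1(c.ci95[0])}-{r1(c.ci95[1])})"),
                row("Median (IQR)", lambda c: f"{r1(c.median)} ({r1(c.iqr)})"),
                row("SD", lambda c: f"{round_half_up(c.sd, 2)}"),
                row("Minimum", lambda c: f"{r1(c.min)}"),
                row("Maximum", lambda c: f"{r1(c.max)}"),
                "",
            ]
        for w in self.warnings:
            lines.append(f"> warning: {w}")
        return "\n".join(lines)


def summarize_cohort(
    records: Sequence[InjuryRecord],
    scores: Optional[Sequence[ComponentScores]] = None,
    rubric: Optional[Rubric] = None,
) -> CohortSummary:
    """Describe a cohort of MRI-positive records.

    Produces the categorical tables (muscle count, primary muscle, location,
    transverse and sagittal bins) and the continuous summaries of the total
    score and, where available, RTS days.  Different variables may have
    different denominators (missing data); a warning is emitted when they
    disagree, rather than asserting a single cohort N.
    """
    from .rubric import score_injury  # local to avoid cycle at import time

    if rubric is None:
        rubric = default_rubric()
    positives = [r for r in records if r.mri_positive]
    if scores is None:
        scores = [score_injury(r, rubric) for r in positives]
    elif len(scores) != len(positives):
        raise ValidationError("scores must align with the MRI-positive records")

    def counted(pairs: Iterable[str]) -> list[tuple[str, int]]:
        out: dict[str, int] = {}
        for k in pairs:
            out[k] = out.get(k, 0) + 1
        return sorted(out.items())

    categorical = {}
    categorical["n_muscles"] = summarize_categorical(
        counted(str(r.n_muscles) for r in positives)
    )
    categorical["primary_muscle"] = summarize_categorical(
        counted(r.primary_muscle.value for r in positives if r.primary_muscle)
    )
    categorical["location"] = summarize_categorical(
        counted(r.location.value for r in positives if r.location)
    )
    categorical["transverse_bin"] = summarize_categorical(
        counted(_bin_label(r.transverse_pct, TRANSVERSE_BIN_EDGES) for r in positives)
    )
    categorical["sagittal_bin"] = summarize_categorical(
        counted(_bin_label(r.sagittal_extent_cm, SAGITTAL_BIN_EDGES) for r in positives)
    )

    warns: list[str] = []
    totals = {var: sum(s.count for s in shares) for var, shares in categorical.items()}
    if len(set(totals.values())) > 1:
        msg = f"categorical denominators disagree across variables: {totals}"
        warns.append(msg)
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)

    continuous = {"total_score": summarize_continuous([s.total for s in scores])}
    rts = [r.rts_days for r in positives if r.rts_days is not None]
    if len(rts) >= 2:
        continuous["rts_days"] = summarize_continuous(rts)
    return CohortSummary(categorical=categorical, continuous=continuous, warnings=warns)
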