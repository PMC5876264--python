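"""Statistical evaluation of the total score against return-to-sport time.

Covers the analysis pipeline applied to the scored cohort: normality checks
(Lilliefors-corrected Kolmogorov-Smirnov), Pearson and Spearman correlation
with variance explained, and a dichotomized group comparison (score below
vs at-or-above a threshold, default 10) with Welch CI and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import ValidationError, ZeroVarianceError

__all__ = [
    "CorrelationResult",
    "GroupStats",
    "GroupComparison",
    "KSResult",
    "EvaluationResult",
    "variance_explained_pct",
    "correlate",
    "cohens_d",
    "dichotomize_and_compare",
    "ks_normality",
    "evaluate",
]


def variance_explained_pct(pearson_r: float) -> float:
    """Squared Pearson correlation as a percentage (100 * r**2)."""
    if not -1.0 <= pearson_r <= 1.0:
        raise ValidationError(f"correlation {pearson_r!r} outside [-1, 1]")
    return 100.0 * pearson_r * pearson_r


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    variance_explained_pct: float


def _as_float_arrays(score, rts) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(score, dtype=float)
    b = np.asarray(rts, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("score and rts must be 1-d vectors of equal length")
    return a, b


def correlate(score: Sequence[float], rts: Sequence[float]) -> CorrelationResult:
    """Pearson on raw values, Spearman on mid-ranks, and variance explained.

    Both coefficients are always computed and reported side by side; the
    variance explained is 100 * pearson_r**2.  Two-sided p-values.
    """
    a, b = _as_float_arrays(score, rts)
    if a.size < 3:
        raise ValidationError("correlate needs n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    pr = stats.pearsonr(a, b)
    sr = stats.spearmanr(a, b)
    return CorrelationResult(
        n=int(a.size),
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        variance_explained_pct=variance_explained_pct(float(pr.statistic)),
    )


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    median: float
    sd: Optional[float]  # None when n < 2

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GroupStats":
        return cls(
            n=int(values.size),
            mean=float(values.mean()),
            median=float(np.median(values)),
            sd=float(values.std(ddof=1)) if values.size >= 2 else None,
        )


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized mean difference (a minus b) over the pooled SD."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("cohens_d needs n >= 2 in each group")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        raise ZeroVarianceError("pooled SD is zero; Cohen's d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class GroupComparison:
    """Partition by score threshold plus the between-group comparison.

    The partition (``below``/``at_or_above``) is always present; the
    comparison fields are ``None`` when a group is empty or degenerate, with
    the reason recorded in ``notes``.
    """

    threshold: int
    below: Optional[GroupStats]
    at_or_above: Optional[GroupStats]
    mean_difference: Optional[float]  # at_or_above minus below
    ci95: Optional[tuple[float, float]]  # Welch CI of the difference
    welch_t: Optional[float]
    welch_p: Optional[float]
    effect_size_d: Optional[float]
    notes: tuple[str, ...] = ()


def dichotomize_and_compare(
    score: Sequence[float], rts: Sequence[float], threshold: int = 10
) -> GroupComparison:
    """Split at ``score < threshold`` vs ``score >= threshold`` and compare RTS.

    Returns per-group n/mean/median/SD, the mean difference (at-or-above
    minus below), a Welch-t 95% CI of the difference, and Cohen's d with the
    pooled SD.  Degenerate cases (empty group, zero pooled SD) leave the
    affected fields ``None`` instead of returning infinities.
    """
    a, b = _as_float_arrays(score, rts)
    mask = a >= threshold
    lo, hi = b[~mask], b[mask]
    notes: list[str] = []
    below = GroupStats.from_values(lo) if lo.size else None
    above = GroupStats.from_values(hi) if hi.size else None
    diff = ci = t = p = d = None
    if lo.size == 0 or hi.size == 0:
        notes.append("a group is empty; comparison not performed")
    else:
        diff = float(hi.mean() - lo.mean())
        if lo.size >= 2 and hi.size >= 2:
            res = stats.ttest_ind(hi, lo, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            interval = res.confidence_interval(0.95)
            ci = (float(interval.low), float(interval.high))
            if not np.isfinite(t):
                t = p = ci = None
                notes.append("Welch comparison degenerate (zero variance)")
            try:
                d = cohens_d(hi, lo)
            except ZeroVarianceError as exc:
                notes.append(str(exc))
        else:
            notes.append("a group has n < 2; CI and effect size not computed")
    return GroupComparison(
        threshold=int(threshold),
        below=below,
        at_or_above=above,
        mean_difference=diff,
        ci95=ci,
        welch_t=t,
        welch_p=p,
        effect_size_d=d,
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float


def ks_normality(values: Sequence[float]) -> KSResult:
    """One-sample KS against a normal with estimated mean/SD (Lilliefors p)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ValidationError("ks_normality needs n >= 5")
    if np.ptp(arr) == 0:
        raise ZeroVarianceError("normality test undefined for a constant vector")
    stat, p = lilliefors(arr, dist="norm")
    return KSResult(statistic=float(stat), pvalue=float(p))


@dataclass(frozen=True)
class EvaluationResult:
    n: int
    correlation: CorrelationResult
    ks_normality: dict[str, KSResult]
    comparison: GroupComparison

    def to_dict(self) -> dict:
        c = self.correlation
        cmp = self.comparison

        def group(g: Optional[GroupStats]):
            if g is None:
                return None
            return {"n": g.n, "mean_rts": g.mean, "median_rts": g.median, "sd_rts": g.sd}

        return {
            "n": self.n,
            "pearson_r": c.pearson_r,
            "pearson_p": c.pearson_p,
            "spearman_rho": c.spearman_rho,
            "spearman_p": c.spearman_p,
            "variance_explained_pct": c.variance_explained_pct,
            "ks_normality": {
                k: {"statistic": v.statistic, "p": v.pvalue}
                for k, v in self.ks_normality.items()
            },
            "threshold": cmp.threshold,
            "group_below": group(cmp.below),
            "group_at_or_above": group(cmp.at_or_above),
            "mean_difference_days": cmp.mean_difference,
            "difference_ci95": list(cmp.ci95) if cmp.ci95 else None,
            "welch_t": cmp.welch_t,
            "welch_p": cmp.welch_p,
            "effect_size_d": cmp.effect_size_d,
            "notes": list(cmp.notes),
        }


def evaluate(
    score: Sequence[float], rts: Sequence[float], threshold: int = 10
) -> EvaluationResult:
    """Run the full analysis: normality, correlations, dichotomized comparison."""
    a, b = _as_float_arrays(score, rts)
    return EvaluationResult(
        n=int(a.size),
        correlation=correlate(a, b),
        ks_normality={
            "total_score": ks_normality(a),
            "rts_days": ks_normality(b),
        },
        comparison=dichotomize_and_compare(a, b, threshold),
    )
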