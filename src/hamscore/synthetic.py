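"""Synthetic injury cohorts with the marginal structure the analysis assumes.

Categorical MRI variables are sampled independently from configurable
marginals (defaults: the observed category frequencies of the reference
cohort, normalized), age from a discrete uniform over the observed range,
and RTS days from a linear-in-score Gaussian model whose intercept, slope
and noise SD are moment-matched to target RTS mean/SD and score-RTS
correlation via :func:`calibrate_rts_model`.

The generator samples the components independently because only marginals
are reported for the reference cohort; a joint table can be emulated by
supplying custom marginals per stratum and concatenating cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rubric import (
    InjuryRecord,
    Location,
    Muscle,
    Rubric,
    default_rubric,
    score_injury,
)

__all__ = [
    "RtsModel",
    "SyntheticConfig",
    "calibrate_rts_model",
    "analytic_score_moments",
    "generate_frame",
    "generate_cohort",
]

# Default marginals: observed category counts, normalized per variable.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "n_muscles": {"1": 89 / 111, "2": 21 / 111, "3": 1 / 111},
    "primary_muscle": {
        Muscle.BICEPS_FEMORIS_LONG_HEAD.value: 89 / 110,
        Muscle.SEMIMEMBRANOSUS.value: 17 / 110,
        Muscle.SEMITENDINOSUS.value: 3 / 110,
        Muscle.BICEPS_FEMORIS_SHORT_HEAD.value: 1 / 110,
    },
    "location": {"proximal": 21 / 111, "middle": 46 / 111, "distal": 44 / 111},
    "transverse_bin": {"<25": 76 / 109, "25-<50": 18 / 109, "50-<75": 10 / 109, ">=75": 5 / 109},
    "sagittal_bin": {"<5": 16 / 110, "5-<10": 37 / 110, ">=10": 57 / 110},
}

# Value ranges backing each size bin: sampled uniformly within, and the
# midpoint is used as the bin's representative for analytic moments.
TRANSVERSE_BIN_RANGES = {"<25": (0.0, 25.0), "25-<50": (25.0, 50.0),
                         "50-<75": (50.0, 75.0), ">=75": (75.0, 100.0)}
SAGITTAL_BIN_RANGES = {"<5": (1.0, 5.0), "5-<10": (5.0, 10.0), ">=10": (10.0, 18.0)}

# Default calibration targets: RTS mean, RTS SD (days) and score-RTS Pearson r.
DEFAULT_RTS_TARGETS = (22.65, 11.03, 0.205)


@dataclass(frozen=True)
class RtsModel:
    """RTS = alpha + beta * total_score + Normal(0, sigma), floored and rounded."""

    alpha: float
    beta: float
    sigma: float
    floor: float = 1.0
    round_days: bool = True

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0", field="sigma")
        if self.floor < 1:
            raise ValidationError("floor must be >= 1 day", field="floor")


def calibrate_rts_model(
    score_mean: float,
    score_sd: float,
    target_rts_mean: float,
    target_rts_sd: float,
    target_r: float,
) -> RtsModel:
    """Moment-match the linear RTS model to target moments and correlation.

    Closed form: ``beta = r * sd_rts / sd_score``,
    ``sigma = sd_rts * sqrt(1 - r**2)``,
    ``alpha = mean_rts - beta * mean_score``.
    """
    if score_sd <= 0:
        raise ValidationError("score_sd must be > 0", field="score_sd")
    if target_rts_sd <= 0:
        raise ValidationError("target_rts_sd must be > 0", field="target_rts_sd")
    if abs(target_r) >= 1:
        raise ValidationError("|target_r| must be < 1", field="target_r")
    beta = target_r * target_rts_sd / score_sd
    sigma = target_rts_sd * math.sqrt(1.0 - target_r**2)
    alpha = target_rts_mean - beta * score_mean
    return RtsModel(alpha=alpha, beta=beta, sigma=sigma)


def _validate_marginal(name: str, marginal: Mapping[str, float]) -> None:
    if any(p < 0 for p in marginal.values()):
        raise ValidationError(f"{name}: negative probability", field=name)
    if abs(sum(marginal.values()) - 1.0) > 1e-9:
        raise ValidationError(f"{name}: probabilities must sum to 1", field=name)


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 110
    seed: int = 0
    marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    age_low: int = 18
    age_high: int = 39  # inclusive bound of the discrete-uniform age model
    rts_model: Optional[RtsModel] = None  # None -> calibrated at generation
    rts_targets: tuple[float, float, float] = DEFAULT_RTS_TARGETS

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1", field="n")
        if set(self.marginals) != set(DEFAULT_MARGINALS):
            raise ValidationError(
                f"marginals must define exactly {sorted(DEFAULT_MARGINALS)}",
                field="marginals",
            )
        for name, marginal in self.marginals.items():
            _validate_marginal(name, marginal)
        if not (18 <= self.age_low <= self.age_high <= 50):
            raise ValidationError("age range must lie within 18-50", field="age_low")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        d = json.loads(Path(path).read_text())
        if "rts_model" in d and d["rts_model"] is not None:
            d["rts_model"] = RtsModel(**d["rts_model"])
        if "rts_targets" in d:
            d["rts_targets"] = tuple(d["rts_targets"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _bin_midpoint(ranges: Mapping[str, tuple[float, float]], label: str) -> float:
    lo, hi = ranges[label]
    return (lo + hi) / 2.0


def analytic_score_moments(
    config: SyntheticConfig, rubric: Optional[Rubric] = None
) -> tuple[float, float]:
    """Exact mean and SD of the total score under the config's marginals.

    Components are independent by construction, so the total's mean and
    variance are sums of per-component means and variances.  Each category
    is pushed through the rubric via a representative value, so the moments
    follow a swapped-in rubric too.
    """
    if rubric is None:
        rubric = default_rubric()
    config.validate()

    def moments(dist: Sequence[tuple[float, float]]) -> tuple[float, float]:
        mean = sum(p * s for s, p in dist)
        var = sum(p * (s - mean) ** 2 for s, p in dist)
        return mean, var

    ages = range(config.age_low, config.age_high + 1)
    p_age = 1.0 / len(ages)
    parts = []

    def rec(age=25, n_m=1, loc="middle", tr=0.0, sag=6.0):
        return InjuryRecord(
            athlete_id="cal",
            age=age,
            mri_positive=True,
            n_muscles=n_m,
            primary_muscle=Muscle.BICEPS_FEMORIS_LONG_HEAD,
            location=Location(loc),
            transverse_pct=tr,
            sagittal_extent_cm=sag,
        )

    parts.append(moments([(score_injury(rec(age=a), rubric).age_score, p_age) for a in ages]))
    parts.append(moments([
        (score_injury(rec(n_m=int(k)), rubric).muscles_score, p)
        for k, p in config.marginals["n_muscles"].items()
    ]))
    parts.append(moments([
        (score_injury(rec(loc=k), rubric).location_score, p)
        for k, p in config.marginals["location"].items()
    ]))
    parts.append(moments([
        (score_injury(rec(tr=_bin_midpoint(TRANSVERSE_BIN_RANGES, k)), rubric).transverse_score, p)
        for k, p in config.marginals["transverse_bin"].items()
    ]))
    parts.append(moments([
        (score_injury(rec(sag=_bin_midpoint(SAGITTAL_BIN_RANGES, k)), rubric).sagittal_score, p)
        for k, p in config.marginals["sagittal_bin"].items()
    ]))
    mean = sum(m for m, _ in parts)
    var = sum(v for _, v in parts)
    return mean, math.sqrt(var)


def resolved_rts_model(
    config: SyntheticConfig, rubric: Optional[Rubric] = None
) -> RtsModel:
    """The config's RTS model, calibrating from analytic score moments if unset."""
    if config.rts_model is not None:
        return config.rts_model
    mean, sd = analytic_score_moments(config, rubric)
    return calibrate_rts_model(mean, sd, *config.rts_targets)


# Sub-stream order is part of the reproducibility contract: editing one
# variable's marginal must not perturb the draws of the others.
_STREAMS = ("age", "n_muscles", "primary_muscle", "location",
            "transverse", "sagittal", "noise")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _choice(rng, marginal: Mapping[str, float], n: int) -> np.ndarray:
    labels = list(marginal)
    probs = np.asarray([marginal[k] for k in labels], dtype=float)
    return rng.choice(np.asarray(labels, dtype=object), size=n, p=probs / probs.sum())


def generate_frame(
    config: SyntheticConfig, rubric: Optional[Rubric] = None
) -> pd.DataFrame:
    """Sample a cohort as a DataFrame (includes the unfloored ``rts_raw``)."""
    config.validate()
    if rubric is None:
        rubric = default_rubric()
    rngs = _rngs(config.seed)
    n = config.n

    age = rngs["age"].integers(config.age_low, config.age_high + 1, size=n)
    n_muscles = _choice(rngs["n_muscles"], config.marginals["n_muscles"], n).astype(int)
    primary = _choice(rngs["primary_muscle"], config.marginals["primary_muscle"], n)
    location = _choice(rngs["location"], config.marginals["location"], n)
    tr_bin = _choice(rngs["transverse"], config.marginals["transverse_bin"], n)
    sag_bin = _choice(rngs["sagittal"], config.marginals["sagittal_bin"], n)

    tr_lo, tr_hi = np.array([TRANSVERSE_BIN_RANGES[b] for b in tr_bin]).T
    transverse = rngs["transverse"].uniform(tr_lo, tr_hi)
    sag_lo, sag_hi = np.array([SAGITTAL_BIN_RANGES[b] for b in sag_bin]).T
    sagittal = rngs["sagittal"].uniform(sag_lo, sag_hi)

    totals = np.empty(n, dtype=int)
    for i in range(n):
        totals[i] = score_injury(
            InjuryRecord(
                athlete_id=f"syn-{i:06d}",
                age=int(age[i]),
                mri_positive=True,
                n_muscles=int(n_muscles[i]),
                primary_muscle=Muscle(primary[i]),
                location=Location(location[i]),
                transverse_pct=float(transverse[i]),
                sagittal_extent_cm=float(sagittal[i]),
            ),
            rubric,
        ).total

    model = resolved_rts_model(config, rubric)
    raw = model.alpha + model.beta * totals + rngs["noise"].normal(0.0, model.sigma, n)
    floored = np.maximum(raw, model.floor)
    rts = np.rint(floored).astype(int) if model.round_days else floored

    return pd.DataFrame(
        {
            "athlete_id": [f"syn-{i:06d}" for i in range(n)],
            "age": age,
            "n_muscles": n_muscles,
            "primary_muscle": primary,
            "location": location,
            "transverse_pct": transverse,
            "sagittal_extent_cm": sagittal,
            "total_score": totals,
            "rts_raw": raw,
            "rts_days": rts,
        }
    )


def generate_cohort(
    config: SyntheticConfig, rubric: Optional[Rubric] = None
) -> list[InjuryRecord]:
    """Sample ``config.n`` MRI-positive records; reproducible from ``config.seed``."""
    frame = generate_frame(config, rubric)
    return [
        InjuryRecord(
            athlete_id=row.athlete_id,
            age=int(row.age),
            mri_positive=True,
            n_muscles=int(row.n_muscles),
            primary_muscle=Muscle(row.primary_muscle),
            location=Location(row.location),
            insertion_involved=False,
            transverse_pct=float(row.transverse_pct),
            retraction_cm=0.0,
            sagittal_extent_cm=float(row.sagittal_extent_cm),
            rts_days=int(row.rts_days),
        )
        for row in frame.itertuples(index=False)
    ]
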