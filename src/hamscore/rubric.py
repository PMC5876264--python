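"""Severity rubric for MRI-graded acute hamstring injury.

The rubric is additive: seven components (athlete age, number of muscles
involved, injury location along the muscle, insertional involvement,
transverse cross-sectional percentage, tendon/muscle retraction, and
craniocaudal sagittal extent) are each mapped to integer points through
declarative bins, and the total is their sum.

The rubric is data, not code: :func:`default_rubric` builds the shipped
grid, and any variant can be loaded from a JSON config with the same shape
(see :meth:`Rubric.from_dict`), e.g. for sensitivity analyses with
alternative bin boundaries.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

from .errors import ValidationError

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "Muscle",
    "Location",
    "InjuryRecord",
    "NumericBin",
    "Rubric",
    "ComponentScores",
    "ScoreRange",
    "default_rubric",
    "load_rubric",
    "score_injury",
    "enumerate_score_range",
]

#: Study eligibility bounds on athlete age (whole years, inclusive).
AGE_MIN = 18
AGE_MAX = 50


class Muscle(str, Enum):
    """Hamstring-complex muscles."""

    BICEPS_FEMORIS_LONG_HEAD = "biceps_femoris_long_head"
    BICEPS_FEMORIS_SHORT_HEAD = "biceps_femoris_short_head"
    SEMIMEMBRANOSUS = "semimembranosus"
    SEMITENDINOSUS = "semitendinosus"


class Location(str, Enum):
    """Injury location along the craniocaudal extent of the muscle."""

    PROXIMAL = "proximal"
    MIDDLE = "middle"
    DISTAL = "distal"


@dataclass(frozen=True)
class InjuryRecord:
    """One athlete's structured MRI reading plus the return-to-sport outcome.

    ``rts_days`` may be ``None``: the outcome is unknown at scoring time.
    MRI-negative records carry zero/absent injury descriptors and remain
    scoreable (the age component still applies).
    """

    athlete_id: str
    age: float
    mri_positive: bool
    n_muscles: int = 0
    primary_muscle: Optional[Muscle] = None
    location: Optional[Location] = None
    insertion_involved: bool = False
    transverse_pct: float = 0.0
    retraction_cm: float = 0.0
    sagittal_extent_cm: float = 0.0
    rts_days: Optional[int] = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise ValidationError(
                f"age {self.age!r} outside study eligibility "
                f"{AGE_MIN}-{AGE_MAX} years",
                field="age",
            )
        if not (0.0 <= self.transverse_pct <= 100.0):
            raise ValidationError(
                f"transverse_pct {self.transverse_pct!r} outside [0, 100]",
                field="transverse_pct",
            )
        if self.retraction_cm < 0:
            raise ValidationError(
                f"retraction_cm {self.retraction_cm!r} is negative",
                field="retraction_cm",
            )
        if self.sagittal_extent_cm < 0:
            raise ValidationError(
                f"sagittal_extent_cm {self.sagittal_extent_cm!r} is negative",
                field="sagittal_extent_cm",
            )
        if not (0 <= self.n_muscles <= 4):
            raise ValidationError(
                f"n_muscles {self.n_muscles!r} outside 0-4", field="n_muscles"
            )
        if self.rts_days is not None and self.rts_days < 1:
            raise ValidationError(
                f"rts_days {self.rts_days!r} must be a positive number of days",
                field="rts_days",
            )
        if self.mri_positive:
            if self.n_muscles < 1:
                raise ValidationError(
                    "MRI-positive record must involve at least one muscle",
                    field="n_muscles",
                )
            if self.location is None:
                raise ValidationError(
                    "MRI-positive record must have a location", field="location"
                )
            if self.sagittal_extent_cm <= 0:
                raise ValidationError(
                    "MRI-positive record must have sagittal_extent_cm > 0",
                    field="sagittal_extent_cm",
                )
        else:
            if self.n_muscles != 0:
                raise ValidationError(
                    "MRI-negative record must have n_muscles = 0",
                    field="n_muscles",
                )
            for name in (
                "transverse_pct",
                "retraction_cm",
                "sagittal_extent_cm",
            ):
                if getattr(self, name) != 0:
                    raise ValidationError(
                        f"MRI-negative record must have {name} = 0", field=name
                    )
            if self.primary_muscle is not None or self.location is not None:
                raise ValidationError(
                    "MRI-negative record must not name a muscle or location",
                    field="primary_muscle",
                )
            if self.insertion_involved:
                raise ValidationError(
                    "MRI-negative record cannot involve an insertion",
                    field="insertion_involved",
                )


@dataclass(frozen=True)
class NumericBin:
    """One interval → points entry of a numeric rubric component.

    ``lower``/``upper`` of ``None`` mean unbounded.  The default convention
    is lower-inclusive, upper-exclusive; a degenerate bin (``lower == upper``
    with both ends inclusive) encodes "exactly this value", used for the
    zero rows of the retraction and sagittal components.
    """

    points: int
    lower: Optional[float] = None
    upper: Optional[float] = None
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def contains(self, x: float) -> bool:
        if self.lower is not None:
            if x < self.lower or (x == self.lower and not self.lower_inclusive):
                return False
        if self.upper is not None:
            if x > self.upper or (x == self.upper and not self.upper_inclusive):
                return False
        return True

    def representative(self, minimum: Optional[float] = None) -> Optional[float]:
        """A value inside the bin, at least ``minimum``; ``None`` if none exists."""
        lo = self.lower if self.lower is not None else (minimum if minimum is not None else 0.0)
        candidates = [lo]
        if self.lower is not None and not self.lower_inclusive:
            if self.upper is not None:
                candidates = [(self.lower + self.upper) / 2.0]
            else:
                candidates = [self.lower + 1.0]
        if minimum is not None:
            candidates = [max(c, minimum) for c in candidates]
        for c in candidates:
            if self.contains(c):
                return c
        return None

    def to_dict(self) -> dict:
        return {
            "points": self.points,
            "lower": self.lower,
            "upper": self.upper,
            "lower_inclusive": self.lower_inclusive,
            "upper_inclusive": self.upper_inclusive,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NumericBin":
        return cls(
            points=int(d["points"]),
            lower=d.get("lower"),
            upper=d.get("upper"),
            lower_inclusive=bool(d.get("lower_inclusive", True)),
            upper_inclusive=bool(d.get("upper_inclusive", False)),
        )


def _lookup(bins: Sequence[NumericBin], x: float, component: str) -> int:
    for b in bins:
        if b.contains(x):
            return b.points
    raise ValidationError(
        f"value {x!r} not covered by any {component} bin", field=component
    )


#: Domains over which bin coverage is checked (sampled grids).
_COVERAGE_DOMAINS = {
    "age_years": (AGE_MIN, AGE_MAX),
    "n_muscles": (0, 4),
    "transverse_pct": (0.0, 100.0),
    "retraction_cm": (0.0, 30.0),
    "sagittal_cm": (0.0, 60.0),
}

_NUMERIC_COMPONENTS = (
    "age_years",
    "n_muscles",
    "transverse_pct",
    "retraction_cm",
    "sagittal_cm",
)
_CATEGORICAL_COMPONENTS = ("location", "insertion")


@dataclass(frozen=True)
class Rubric:
    """Declarative bin/point definitions for the seven score components."""

    age_years: tuple[NumericBin, ...]
    n_muscles: tuple[NumericBin, ...]
    location: Mapping[str, int]
    insertion: Mapping[str, int]  # keys "no"/"yes"
    transverse_pct: tuple[NumericBin, ...]
    retraction_cm: tuple[NumericBin, ...]
    sagittal_cm: tuple[NumericBin, ...]

    def validate(self) -> None:
        """Check points range, and disjoint/covering bins on a sampled grid."""
        for name in _NUMERIC_COMPONENTS:
            bins: Sequence[NumericBin] = getattr(self, name)
            for b in bins:
                if not (0 <= b.points <= 3) or b.points != int(b.points):
                    raise ValidationError(
                        f"{name}: points must be integers in 0-3, got {b.points}",
                        field=name,
                    )
            lo, hi = _COVERAGE_DOMAINS[name]
            steps = 400
            grid = [lo + (hi - lo) * i / steps for i in range(steps + 1)]
            grid += [b.lower for b in bins if b.lower is not None]
            grid += [b.upper for b in bins if b.upper is not None]
            for x in grid:
                if x is None or not (lo <= x <= hi):
                    continue
                hits = sum(b.contains(x) for b in bins)
                if hits != 1:
                    raise ValidationError(
                        f"{name}: value {x} matched {hits} bins "
                        "(bins must be disjoint and cover the domain)",
                        field=name,
                    )
        for name in _CATEGORICAL_COMPONENTS:
            mapping: Mapping[str, int] = getattr(self, name)
            if not mapping:
                raise ValidationError(f"{name}: empty mapping", field=name)
            for label, pts in mapping.items():
                if not (0 <= pts <= 3) or pts != int(pts):
                    raise ValidationError(
                        f"{name}[{label}]: points must be integers in 0-3",
                        field=name,
                    )
        if set(self.insertion) != {"no", "yes"}:
            raise ValidationError(
                "insertion component must have exactly the labels 'no' and 'yes'",
                field="insertion",
            )

    def component_maxima(self) -> dict[str, int]:
        out = {}
        for name in _NUMERIC_COMPONENTS:
            out[name] = max(b.points for b in getattr(self, name))
        for name in _CATEGORICAL_COMPONENTS:
            out[name] = max(getattr(self, name).values())
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {}
        for name in _NUMERIC_COMPONENTS:
            d[name] = [b.to_dict() for b in getattr(self, name)]
        for name in _CATEGORICAL_COMPONENTS:
            d[name] = dict(getattr(self, name))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Rubric":
        kwargs: dict = {}
        for name in _NUMERIC_COMPONENTS:
            kwargs[name] = tuple(NumericBin.from_dict(b) for b in d[name])
        for name in _CATEGORICAL_COMPONENTS:
            kwargs[name] = {str(k): int(v) for k, v in d[name].items()}
        rubric = cls(**kwargs)
        rubric.validate()
        return rubric

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Rubric":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ComponentScores:
    """Per-component points and their sum for one record."""

    age_score: int
    muscles_score: int
    location_score: int
    insertion_score: int
    transverse_score: int
    retraction_score: int
    sagittal_score: int
    total: int

    _COMPONENT_FIELDS = (
        "age_score",
        "muscles_score",
        "location_score",
        "insertion_score",
        "transverse_score",
        "retraction_score",
        "sagittal_score",
    )

    @classmethod
    def from_components(cls, *components: int) -> "ComponentScores":
        if len(components) != 7:
            raise ValueError("expected exactly seven component scores")
        return cls(*components, total=sum(components))

    def as_tuple(self) -> tuple[int, ...]:
        """The seven component scores, in declaration order (total excluded)."""
        return tuple(getattr(self, f) for f in self._COMPONENT_FIELDS)


class ScoreRange(tuple):
    """(min_total, max_total) achievable under a rubric."""

    __slots__ = ()

    def __new__(cls, min_total: int, max_total: int):
        return super().__new__(cls, (min_total, max_total))

    @property
    def min_total(self) -> int:
        return self[0]

    @property
    def max_total(self) -> int:
        return self[1]


def default_rubric() -> Rubric:
    """The shipped scoring grid.

    Age: <=25 -> 1, 26-31 -> 2, >=32 -> 3.  Muscles: count, capped at 3.
    Location: proximal 1, middle 2, distal 3.  Insertion: yes -> 2.
    Transverse %: [0,25) 0, [25,50) 1, [50,75) 2, >=75 3.
    Retraction cm: 0 -> 0, (0,2) -> 1, >=2 -> 2.
    Sagittal cm: 0 -> 0, (0,5) -> 1, [5,10) -> 2, >=10 -> 3.
    """
    zero = NumericBin(points=0, lower=0.0, upper=0.0, upper_inclusive=True)
    rubric = Rubric(
        age_years=(
            NumericBin(points=1, lower=AGE_MIN, upper=26),
            NumericBin(points=2, lower=26, upper=32),
            NumericBin(points=3, lower=32, upper=None),
        ),
        n_muscles=(
            NumericBin(points=0, lower=0, upper=1),
            NumericBin(points=1, lower=1, upper=2),
            NumericBin(points=2, lower=2, upper=3),
            NumericBin(points=3, lower=3, upper=None),
        ),
        location={"proximal": 1, "middle": 2, "distal": 3},
        insertion={"no": 0, "yes": 2},
        transverse_pct=(
            NumericBin(points=0, lower=0.0, upper=25.0),
            NumericBin(points=1, lower=25.0, upper=50.0),
            NumericBin(points=2, lower=50.0, upper=75.0),
            NumericBin(points=3, lower=75.0, upper=None),
        ),
        retraction_cm=(
            zero,
            NumericBin(points=1, lower=0.0, upper=2.0, lower_inclusive=False),
            NumericBin(points=2, lower=2.0, upper=None),
        ),
        sagittal_cm=(
            zero,
            NumericBin(points=1, lower=0.0, upper=5.0, lower_inclusive=False),
            NumericBin(points=2, lower=5.0, upper=10.0),
            NumericBin(points=3, lower=10.0, upper=None),
        ),
    )
    rubric.validate()
    return rubric


def load_rubric(path: str | Path | None = None) -> Rubric:
    """Load a rubric config, or return the default when ``path`` is None."""
    if path is None:
        return default_rubric()
    return Rubric.load(path)


def score_injury(record: InjuryRecord, rubric: Rubric | None = None) -> ComponentScores:
    """Score one record by bin lookup.

    MRI-negative records score 0 on all injury components and retain the
    age score.  Raises :class:`ValidationError` when the record violates an
    invariant (e.g. age outside eligibility, transverse outside [0, 100]).
    """
    if rubric is None:
        rubric = default_rubric()
    record.validate()
    age_score = _lookup(rubric.age_years, math.floor(record.age), "age_years")
    if not record.mri_positive:
        return ComponentScores.from_components(age_score, 0, 0, 0, 0, 0, 0)
    location = record.location.value if isinstance(record.location, Location) else str(record.location)
    if location not in rubric.location:
        raise ValidationError(f"unknown location {location!r}", field="location")
    return ComponentScores.from_components(
        age_score,
        _lookup(rubric.n_muscles, record.n_muscles, "n_muscles"),
        rubric.location[location],
        rubric.insertion["yes" if record.insertion_involved else "no"],
        _lookup(rubric.transverse_pct, record.transverse_pct, "transverse_pct"),
        _lookup(rubric.retraction_cm, record.retraction_cm, "retraction_cm"),
        _lookup(rubric.sagittal_cm, record.sagittal_extent_cm, "sagittal_cm"),
    )


def _representative_records(
    rubric: Rubric, mri_positive: bool
) -> Iterator[InjuryRecord]:
    """One record per combination of component bins, honouring invariants."""
    age_reps = [
        r
        for r in (b.representative(minimum=AGE_MIN) for b in rubric.age_years)
        if r is not None and r <= AGE_MAX
    ]
    if not mri_positive:
        for age in age_reps:
            yield InjuryRecord(athlete_id="enum", age=age, mri_positive=False)
        return
    muscle_reps = [
        r
        for r in (b.representative(minimum=1) for b in rubric.n_muscles)
        if r is not None and 1 <= r <= 4 and float(r).is_integer()
    ]
    transverse_reps = [
        r
        for r in (b.representative(minimum=0.0) for b in rubric.transverse_pct)
        if r is not None and r <= 100.0
    ]
    retraction_reps = [
        r
        for r in (b.representative(minimum=0.0) for b in rubric.retraction_cm)
        if r is not None
    ]
    # sagittal extent must be strictly positive on an MRI-positive record
    sagittal_reps = []
    for b in rubric.sagittal_cm:
        r = b.representative(minimum=0.0)
        if r is not None and r <= 0:
            r = b.representative(minimum=1e-6)
        if r is not None and r > 0:
            sagittal_reps.append(r)
    for age, n_m, loc, ins, tr, ret, sag in itertools.product(
        age_reps,
        muscle_reps,
        rubric.location.keys(),
        (False, True),
        transverse_reps,
        retraction_reps,
        sagittal_reps,
    ):
        yield InjuryRecord(
            athlete_id="enum",
            age=age,
            mri_positive=True,
            n_muscles=int(n_m),
            primary_muscle=Muscle.BICEPS_FEMORIS_LONG_HEAD,
            location=Location(loc),
            insertion_involved=ins,
            transverse_pct=tr,
            retraction_cm=ret,
            sagittal_extent_cm=sag,
        )


def enumerate_score_range(rubric: Rubric, mri_positive: bool) -> ScoreRange:
    """Brute-force the achievable (min, max) total over all bin combinations.

    Enumerates one representative value per bin for every component,
    respecting the record invariants for the given ``mri_positive`` flag
    (age within eligibility; positive scans need >=1 muscle, a location and
    a positive sagittal extent), scores each combination, and returns the
    extremes.
    """
    totals = [
        score_injury(rec, rubric).total
        for rec in _representative_records(rubric, mri_positive)
    ]
    if not totals:
        raise ValidationError("rubric admits no valid records")
    return ScoreRange(min(totals), max(totals))
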