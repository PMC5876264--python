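import pytest

from hamscore.rubric import InjuryRecord, Location, Muscle, default_rubric
from hamscore.synthetic import SyntheticConfig, generate_frame


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture
def make_record():
    """Factory for valid MRI-positive records with overridable fields."""

    def _make(**kwargs):
        base = dict(
            athlete_id="r1",
            age=24,
            mri_positive=True,
            n_muscles=1,
            primary_muscle=Muscle.BICEPS_FEMORIS_LONG_HEAD,
            location=Location.MIDDLE,
            insertion_involved=False,
            transverse_pct=30.0,
            retraction_cm=0.0,
            sagittal_extent_cm=12.0,
            rts_days=None,
        )
        base.update(kwargs)
        return InjuryRecord(**base)

    return _make


@pytest.fixture(scope="session")
def big_frame():
    """A 100k default-calibration cohort, shared by the stochastic checks."""
    return generate_frame(SyntheticConfig(n=100_000, seed=20260905))
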