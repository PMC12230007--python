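import dataclasses

import pytest

import icscore as ic


@pytest.fixture(scope="session")
def thresholds() -> ic.ThresholdConfig:
    """The packaged synthetic example threshold configuration."""
    return ic.example_threshold_config()


@pytest.fixture(scope="session")
def norm_fixture() -> ic.NormTable:
    """A tiny hand-written norm table used by the lookup tests."""
    return ic.NormTable(entries=(
        ic.NormBand("F", 60, 64, 12, -0.5, 5.0),
        ic.NormBand("F", 65, 69, 11, -1.5, 4.0),
        ic.NormBand("M", 60, 64, 14, -2.5, 4.0),
    ))


@pytest.fixture(scope="session")
def default_cohort() -> ic.CohortTable:
    """The reference synthetic cohort: n=43, 3 dropouts, null effects."""
    return ic.generate_cohort(ic.default_cohort_config(seed=20240101))


@pytest.fixture(scope="session")
def balanced_config() -> ic.CohortConfig:
    """Reference config without dropout (complete balanced data)."""
    return dataclasses.replace(ic.default_cohort_config(seed=1), dropout_n=0)


def favourable_record(**overrides) -> ic.AssessmentRecord:
    """A record passing every scoring sub-rule under the example thresholds."""
    base = dict(
        participant_id="P001", timepoint=0, age=62.0, sex="F",
        education="high", hgs=20.0, bmi=24.5, weight_loss_3mo=0.0,
        appetite_loss=False, wears_glasses=False, vision_difficulty=False,
        uses_hearing_aid=False, hearing_difficulty=False, tug=9.0,
        chair_stand=14, sit_reach=3.0, balance=25.0, gds15=0, moca=28,
    )
    base.update(overrides)
    return ic.AssessmentRecord(**base)
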