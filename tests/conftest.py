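import datetime

import pytest

from nlcsp import NoduleObservation, ParticipantCovariates

BASE_DATE = datetime.date(2025, 7, 1)


@pytest.fixture
def cov() -> ParticipantCovariates:
    return ParticipantCovariates(
        age=62, sex="male", family_history_lung_cancer=False, emphysema=False
    )


@pytest.fixture
def make_obs():
    """Factory for observations with sensible defaults, overridable per test."""

    def _make(**overrides) -> NoduleObservation:
        fields = dict(
            nodule_id="N1",
            scan_date=BASE_DATE,
            composition="solid",
            long_axis_mm=5.5,
            short_axis_mm=4.5,
            lobe="RUL",
        )
        fields.update(overrides)
        return NoduleObservation(**fields)

    return _make
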