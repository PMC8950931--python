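import json
from pathlib import Path

import pytest

from pqtpp import (
    DEFAULT_CONFIG,
    FIXTURE_NAMES,
    default_growth_reference,
    load_fixture,
)
from pqtpp.model import (
    AgeRange,
    DosageForm,
    DoseMode,
    FormulationProduct,
    PosologyRule,
    QualitativeAssertions,
    Strength,
)


def make_unknown_product() -> FormulationProduct:
    """A record whose label carries no usable information: every attribute grey."""
    return FormulationProduct(
        medicine_name="mystery",
        dosage_form=DosageForm(category="unknown"),
        strengths=[Strength(amount_mg=1)],
        posology=[
            PosologyRule(
                age_window=AgeRange(min_months=0, max_months=144),
                dose_mode=DoseMode.fixed_mg,
                dose_low=1,
                dose_high=1,
                frequency_per_day=1,
            )
        ],
        assertions=QualitativeAssertions(registration_unknown=True),
    )

EXPECTED_PATH = Path(__file__).parent / "expected" / "table_scores.json"


@pytest.fixture(scope="session")
def growth():
    return default_growth_reference()


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def expected_scores():
    return json.loads(EXPECTED_PATH.read_text())


@pytest.fixture(scope="session")
def products():
    return {name: load_fixture(name) for name in FIXTURE_NAMES}
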