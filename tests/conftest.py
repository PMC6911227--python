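import pandas as pd
import pytest

from phemap import (
    Vocabulary,
    build_fixture_bundle,
    build_map,
    icd9_direct_map,
)


@pytest.fixture(scope="session")
def bundle():
    return build_fixture_bundle()


@pytest.fixture(scope="session")
def map10cm(bundle):
    return build_map(bundle, Vocabulary.ICD10CM)


@pytest.fixture(scope="session")
def map10(bundle):
    return build_map(bundle, Vocabulary.ICD10)


@pytest.fixture(scope="session")
def map9(bundle):
    return icd9_direct_map(bundle)


def make_events(rows):
    """rows of (patient_id, date, vocabulary, code) -> event table."""
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "vocabulary", "code"]
    )
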