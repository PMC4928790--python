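import numpy as np
import pytest

from docoutcome import build_basis, load_fixture_cohort, patients_from_tables
from docoutcome.cohort import PrimaryClass, classify_outcome


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_patients(fixture_cohort):
    return patients_from_tables(fixture_cohort)


@pytest.fixture(scope="session")
def basis():
    return build_basis()


def outcome_groups(patients):
    """Map patient ids onto the two primary outcome classes."""
    groups = {"emerged": [], "remaining": []}
    for p in patients:
        key = ("emerged"
               if classify_outcome(p).primary_class is PrimaryClass.EMERGED
               else "remaining")
        groups[key].append(p.id)
    return {k: tuple(v) for k, v in groups.items()}
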