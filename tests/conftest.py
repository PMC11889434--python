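import pytest

from rorscreen import (
    SafetyReport,
    default_drug_dictionary,
    default_event_terms,
)


@pytest.fixture(scope="session")
def drug_dict():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def term_set():
    return default_event_terms()


def make_report(case_id, version=1, drugs=(), events=("Nausea",), **kwargs):
    """Terse report builder: drugs as bare ingredient names (role PS)."""
    return SafetyReport(
        case_id=case_id,
        version_key=version,
        drugs=frozenset((d, "PS") if isinstance(d, str) else d for d in drugs),
        events=frozenset(events),
        **kwargs,
    )


@pytest.fixture
def toy_reports():
    """Six reports: two name drug D (one with the composite event), four do
    not (one with the event) -> table (1, 1, 1, 3) for D."""
    return [
        make_report("C1", drugs=["D"], events=["Thyroid cancer"]),
        make_report("C2", drugs=["D"], events=["Nausea"]),
        make_report("C3", drugs=["X"], events=["Papillary thyroid cancer"]),
        make_report("C4", drugs=["X"], events=["Headache"]),
        make_report("C5", drugs=["Y"], events=["Rash"]),
        make_report("C6", drugs=["Y", "X"], events=["Fatigue"]),
    ]
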