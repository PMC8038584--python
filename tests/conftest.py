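import pytest

from abgkit import BloodGasPanel, ReferenceRanges, parse_case, printed_cases


@pytest.fixture(scope="session")
def ranges():
    return ReferenceRanges()


@pytest.fixture(scope="session")
def cases_by_id():
    return {case.case_id: case for case in printed_cases()}


@pytest.fixture(scope="session")
def panels_by_id(cases_by_id):
    out = {}
    for case_id, case in cases_by_id.items():
        _, panel = parse_case(case.record, where=case_id)
        out[case_id] = panel
    return out


@pytest.fixture
def normal_panel():
    """A fully normal panel: every value inside its reference interval."""
    return BloodGasPanel(ph=7.4, paco2=40, hco3=24, sbe=0, ag=11, albumin=40)
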