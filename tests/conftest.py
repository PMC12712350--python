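import datetime as dt

import pytest

from fqvigil.report_model import (
    CaseReport,
    DrugMention,
    ReactionMention,
)
from fqvigil.synthetic_reports import default_dictionary


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


def make_case(
    case_id="C1",
    receive_date=dt.date(2020, 1, 1),
    sex="female",
    age_years=40.0,
    country="US",
    reporter="consumer",
    outcomes=("other_serious",),
    indications=("urinary tract infection",),
    drugs=None,
    reactions=None,
):
    """Minimal valid case with overridable fields."""
    if drugs is None:
        drugs = [
            DrugMention(
                "ciprofloxacin", "suspect", frozenset({"J01MA02"}),
                dt.date(2019, 12, 25),
            )
        ]
    if reactions is None:
        reactions = [ReactionMention("anxiety", dt.date(2019, 12, 27))]
    return CaseReport(
        case_id=case_id,
        receive_date=receive_date,
        sex=sex,
        age_years=age_years,
        country=country,
        reporter=reporter,
        outcomes=frozenset(outcomes),
        indications=frozenset(indications),
        drugs=list(drugs),
        reactions=list(reactions),
    )


@pytest.fixture
def case_factory():
    return make_case
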