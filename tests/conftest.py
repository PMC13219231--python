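from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from dispro import Case, make_paper_shaped_fixture

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def mk_case(case_id: str, drug: str | None = None, event: str | None = None,
            events: tuple[str, ...] = (), receipt: date = date(2020, 6, 1),
            sex: str = "M", age: float | None = 60.0,
            country: str | None = "US",
            outcome: str | None = "Hospitalization-initial or prolonged",
            pair: bool = True) -> Case:
    """Hand-built consolidated case for contingency/summary tests."""
    evs = set(events)
    if event:
        evs.add(event)
    drugs = frozenset({drug}) if drug else frozenset()
    pairs = frozenset((drug, e) for e in evs) if (drug and pair) \
        else frozenset()
    return Case(case_id=case_id, n_versions=1,
                latest_primary_id=case_id + "1",
                receipt_date_latest=receipt, date_precision="day",
                suspect_drugs=drugs, events=frozenset(evs),
                drug_event_pairs=pairs, all_pts=frozenset(evs),
                sex=sex, age_years=age, reporter_country=country,
                outcome_category=outcome)


@pytest.fixture(scope="session")
def paper_fixture():
    """The bundled ~500-case study-shaped synthetic universe."""
    return make_paper_shaped_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_cases(paper_fixture):
    from dispro import deduplicate
    rs, _ = paper_fixture
    return deduplicate(rs)


@pytest.fixture(scope="session")
def fixture_filtered(fixture_cases):
    from dispro import apply_inclusion_filters
    return apply_inclusion_filters(fixture_cases)
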