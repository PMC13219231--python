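"""Case consolidation (version union semantics, tie-breaks) and the
inclusion filters (date window, suspect role, event list)."""

from datetime import date

import pytest

from dispro import (InclusionConfig, ReportSet, apply_inclusion_filters,
                    deduplicate)
from dispro.io_faers import DemoRow, DrugRow, OutcRow, ReacRow


def version(pid, case_id, n, receipt, drug=None, role="PS", events=(),
            sex="M", outcomes=("HO",)):
    demo = DemoRow(primary_id=pid, case_id=case_id, case_version=n,
                   receipt_date=receipt, date_precision="day", sex=sex,
                   age_value=60.0, age_unit="YR", reporter_country="US")
    drugs = [DrugRow(pid, 1, role, drug)] if drug else []
    reacs = [ReacRow(pid, e) for e in events]
    outc = [OutcRow(pid, c) for c in outcomes]
    return demo, drugs, reacs, outc


def build(versions) -> ReportSet:
    rs = ReportSet()
    for demo, drugs, reacs, outc in versions:
        rs.demo.append(demo)
        rs.drugs.extend(drugs)
        rs.reactions.extend(reacs)
        rs.outcomes.extend(outc)
    return rs


class TestDeduplicate:
    def test_two_versions_one_case_latest_demographics(self):
        rs = build([
            version("C11", "C1", 1, date(2018, 1, 1), "INVOKANA",
                    events=("Toe amputation",), sex="M"),
            version("C12", "C1", 2, date(2018, 6, 1), "INVOKANA",
                    events=("Toe amputation",), sex="F"),
        ])
        cases = deduplicate(rs)
        assert len(cases) == 1
        assert cases[0].sex == "F"
        assert cases[0].receipt_date_latest == date(2018, 6, 1)
        assert cases[0].latest_primary_id == "C12"

    def test_union_semantics_followup_lacking_event_keeps_pair(self):
        rs = build([
            version("C11", "C1", 1, date(2018, 1, 1), "canagliflozin",
                    events=("Toe amputation",)),
            version("C12", "C1", 2, date(2018, 6, 1), "canagliflozin",
                    events=("Pyrexia",)),  # follow-up drops the event
        ])
        case = deduplicate(rs)[0]
        assert ("canagliflozin", "Toe amputation") in case.drug_event_pairs
        assert "Toe amputation" in case.events

    def test_three_distinct_case_ids_three_cases(self):
        rs = build([version(f"C{i}1", f"C{i}", 1, date(2019, 1, 1),
                            "JARDIANCE", events=("Osteomyelitis",))
                    for i in range(3)])
        assert len(deduplicate(rs)) == 3

    def test_tie_break_by_receipt_date_then_primary_id(self):
        rs = build([
            version("A", "C1", 1, date(2018, 1, 1), sex="M"),
            version("B", "C1", 1, date(2018, 3, 1), sex="F"),
        ])
        assert deduplicate(rs)[0].sex == "F"
        rs = build([
            version("A", "C1", 1, date(2018, 1, 1), sex="M"),
            version("B", "C1", 1, date(2018, 1, 1), sex="F"),
        ])
        assert deduplicate(rs)[0].latest_primary_id == "B"

    def test_consolidation_is_idempotent(self):
        rs = build([
            version("C11", "C1", 1, date(2018, 1, 1), "INVOKANA",
                    events=("Toe amputation",)),
            version("C12", "C1", 2, date(2018, 6, 1), "INVOKANA"),
            version("C21", "C2", 1, date(2019, 1, 1), "FARXIGA",
                    events=("Fournier's gangrene",)),
        ])
        once = deduplicate(rs)
        # keep only the surviving latest versions and consolidate again
        keep = {c.latest_primary_id for c in once}
        again = deduplicate(ReportSet(
            demo=[d for d in rs.demo if d.primary_id in keep],
            drugs=[d for d in rs.drugs if d.primary_id in keep],
            reactions=[r for r in rs.reactions if r.primary_id in keep],
            outcomes=[o for o in rs.outcomes if o.primary_id in keep]))
        assert [c.case_id for c in again] == [c.case_id for c in once]
        assert [(c.sex, c.receipt_date_latest, c.latest_primary_id)
                for c in again] == \
            [(c.sex, c.receipt_date_latest, c.latest_primary_id)
             for c in once]

    def test_monotone_growth_under_new_versions(self):
        base = [version("C11", "C1", 1, date(2018, 1, 1), "INVOKANA",
                        events=("Toe amputation", "Osteomyelitis"))]
        extra = version("C12", "C1", 2, date(2018, 6, 1), "INVOKANA",
                        events=("Pyrexia",))
        before = deduplicate(build(base))[0].drug_event_pairs
        after = deduplicate(build(base + [extra]))[0].drug_event_pairs
        assert before <= after

    def test_version_unit_skips_consolidation(self):
        rs = build([
            version("C11", "C1", 1, date(2018, 1, 1), "INVOKANA",
                    events=("Toe amputation",)),
            version("C12", "C1", 2, date(2018, 6, 1), "INVOKANA",
                    events=("Toe amputation",)),
        ])
        assert len(deduplicate(rs, unit="version")) == 2

    def test_missing_case_id_strict_raises_lenient_drops(self):
        rs = build([version("C11", "", 1, date(2018, 1, 1), "INVOKANA",
                            events=("Toe amputation",))])
        with pytest.raises(ValueError, match="case_id"):
            deduplicate(rs, mode="strict")
        assert deduplicate(rs, mode="lenient") == []


class TestInclusionFilters:
    def make_cases(self):
        rs = build([
            # concomitant role only -> background
            version("A1", "A", 1, date(2018, 1, 1), "INVOKANA", role="C",
                    events=("Toe amputation",)),
            # before the window -> excluded from both
            version("B1", "B", 1, date(2012, 12, 1), "INVOKANA",
                    events=("Toe amputation",)),
            # suspect drug but no listed event -> background
            version("D1", "D", 1, date(2019, 1, 1), "JARDIANCE",
                    events=("Pyrexia",)),
            # qualifies
            version("E1", "E", 1, date(2019, 1, 1), "JARDIANCE",
                    events=("Fournier's gangrene",)),
            # no drug row at all -> still counts in the background
            version("F1", "F", 1, date(2019, 1, 1)),
        ])
        return deduplicate(rs)

    def test_filter_disposition(self):
        fr = apply_inclusion_filters(self.make_cases())
        assert [c.case_id for c in fr.included] == ["E"]
        assert {c.case_id for c in fr.background} == {"A", "D", "F"}
        assert [c.case_id for c in fr.out_of_window] == ["B"]

    def test_window_boundary_is_inclusive(self):
        cases = deduplicate(build([
            version("X1", "X", 1, date(2013, 3, 29), "INVOKANA",
                    events=("Toe amputation",)),
            version("Y1", "Y", 1, date(2013, 3, 28), "INVOKANA",
                    events=("Toe amputation",)),
        ]))
        fr = apply_inclusion_filters(cases)
        assert [c.case_id for c in fr.included] == ["X"]
        assert [c.case_id for c in fr.out_of_window] == ["Y"]

    def test_counts_reconcile_exactly(self, fixture_cases):
        fr = apply_inclusion_filters(fixture_cases)
        assert len(fr.included) + len(fr.background) + \
            len(fr.out_of_window) == len(fixture_cases)
        assert sum(fr.log.values()) == len(fixture_cases)
        assert fr.log["included"] == len(fr.included)

    def test_custom_window_and_drug_list(self):
        cases = self.make_cases()
        fr = apply_inclusion_filters(cases, InclusionConfig(
            window_start=date(2010, 1, 1),
            drugs_of_interest=("canagliflozin",)))
        assert {c.case_id for c in fr.included} == {"B"}

    def test_empty_input_gives_empty_outputs(self):
        fr = apply_inclusion_filters([])
        assert fr.included == [] and fr.background == [] and fr.log == {}
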