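"""Consolidation of report versions into cases and inclusion filtering.

A spontaneous-reporting case accumulates follow-up versions over time.
The analysis unit here is the consolidated *case*: demographics come
from the latest version (highest case_version, ties broken by latest
receipt date then lexicographically greatest primary_id), while
drug–event relationships are the UNION over all versions — a case
contributes a (drug, event) pair if at least one of its versions
reports the drug in a suspect role together with the event.  A
follow-up that drops a previously reported event therefore never
removes the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from .io_faers import ReportSet
from .vocabularies import (DrugDictionary, EventTermList, SGLT2_INHIBITORS,
                           worst_outcome)

DEFAULT_WINDOW_START = date(2013, 3, 29)  # first US approval of the class


@dataclass(frozen=True)
class Case:
    """One consolidated individual case safety report."""

    case_id: str
    n_versions: int
    latest_primary_id: str
    receipt_date_latest: date | None
    date_precision: str | None
    suspect_drugs: frozenset[str]          # generics ever in a suspect role
    events: frozenset[str]                 # matched event terms, canonical form
    drug_event_pairs: frozenset[tuple[str, str]]
    all_pts: frozenset[str]                # every PT across versions, verbatim
    sex: str
    age_years: float | None
    reporter_country: str | None
    outcome_category: str | None

    @property
    def report_year(self) -> int | None:
        return None if self.receipt_date_latest is None \
            else self.receipt_date_latest.year


@dataclass
class InclusionConfig:
    """Filter configuration for the analysis window and drugs of interest."""

    window_start: date = DEFAULT_WINDOW_START
    drugs_of_interest: tuple[str, ...] = SGLT2_INHIBITORS
    role_filter: tuple[str, ...] = ("PS",)
    unit: str = "case"  # "case" | "version"


@dataclass
class FilterResult:
    included: list[Case] = field(default_factory=list)
    background: list[Case] = field(default_factory=list)
    out_of_window: list[Case] = field(default_factory=list)
    #: rejection-reason → count; also counts "included"
    log: dict[str, int] = field(default_factory=dict)


def _build_case(case_id: str, versions: list[dict]) -> Case:
    latest = max(versions, key=lambda v: (
        v["demo"].case_version,
        v["demo"].receipt_date or date.min,
        v["demo"].primary_id))
    suspect: set[str] = set()
    events: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    pts: set[str] = set()
    codes: set[str] = set()
    for v in versions:
        suspect |= v["suspect"]
        events |= v["events"]
        pairs |= {(d, e) for d in v["suspect"] for e in v["events"]}
        pts |= v["pts"]
        codes |= v["outcomes"]
    demo = latest["demo"]
    return Case(
        case_id=case_id, n_versions=len(versions),
        latest_primary_id=demo.primary_id,
        receipt_date_latest=demo.receipt_date,
        date_precision=demo.date_precision,
        suspect_drugs=frozenset(suspect), events=frozenset(events),
        drug_event_pairs=frozenset(pairs), all_pts=frozenset(pts),
        sex=demo.sex, age_years=demo.age_years,
        reporter_country=demo.reporter_country,
        outcome_category=worst_outcome(codes))


def deduplicate(report_set: ReportSet,
                drug_dict: DrugDictionary | None = None,
                event_terms: EventTermList | None = None,
                role_filter: tuple[str, ...] = ("PS",),
                unit: str = "case",
                mode: str = "strict") -> list[Case]:
    """Consolidate report versions into one :class:`Case` per case_id.

    ``unit="version"`` skips consolidation and treats every report
    version as its own case (case_id := primary_id), preserving the
    alternative report-level counting convention.

    Drug mentions are resolved through ``drug_dict`` (package default if
    None) and only mentions whose role is in ``role_filter`` (default:
    primary suspect) define exposure.  Events are matched against
    ``event_terms`` (package default: the 12-term list).  The pair set
    is built per version — drug and event must co-occur in at least one
    version — then unioned across versions.
    """
    if unit not in {"case", "version"}:
        raise ValueError(f"unit must be 'case' or 'version', got {unit!r}")
    drug_dict = drug_dict or DrugDictionary.default()
    event_terms = event_terms or EventTermList.default()
    roles = set(role_filter)

    drugs_by_pid: dict[str, list] = {}
    for r in report_set.drugs:
        drugs_by_pid.setdefault(r.primary_id, []).append(r)
    reac_by_pid: dict[str, list] = {}
    for r in report_set.reactions:
        reac_by_pid.setdefault(r.primary_id, []).append(r)
    outc_by_pid: dict[str, list] = {}
    for r in report_set.outcomes:
        outc_by_pid.setdefault(r.primary_id, []).append(r)

    grouped: dict[str, list[dict]] = {}
    n_missing = 0
    for demo in report_set.demo:
        case_id = demo.primary_id if unit == "version" else demo.case_id
        if not case_id:
            if mode == "strict":
                raise ValueError(f"report {demo.primary_id} has no case_id")
            n_missing += 1
            continue
        pid = demo.primary_id
        suspect: set[str] = set()
        for d in drugs_by_pid.get(pid, []):
            if d.role_code in roles:
                suspect |= drug_dict.normalize(d.drug_name_verbatim)
        pts = {r.preferred_term for r in reac_by_pid.get(pid, [])}
        events = {event_terms.canonical(p) for p in pts}
        events.discard(None)
        grouped.setdefault(case_id, []).append({
            "demo": demo, "suspect": suspect, "events": events, "pts": pts,
            "outcomes": {o.outcome_code for o in outc_by_pid.get(pid, [])}})

    cases = [_build_case(cid, versions) for cid, versions in grouped.items()]
    cases.sort(key=lambda c: c.case_id)
    return cases


def apply_inclusion_filters(cases: list[Case],
                            config: InclusionConfig | None = None) -> FilterResult:
    """Split cases into included / background / out-of-window.

    Included: receipt date within the window AND at least one drug of
    interest in a suspect role AND at least one matched event term.
    Background: every other in-window case (these populate the c/d
    cells of the contingency tables).  Cases dated before the window
    start, or with no usable date, are excluded from both.  The log
    counts each case exactly once by its first failing reason, so the
    totals reconcile with the input size.
    """
    config = config or InclusionConfig()
    doi = set(config.drugs_of_interest)
    res = FilterResult()

    def bump(reason: str) -> None:
        res.log[reason] = res.log.get(reason, 0) + 1

    for case in cases:
        if case.receipt_date_latest is None:
            res.out_of_window.append(case)
            bump("missing_receipt_date")
        elif case.receipt_date_latest < config.window_start:
            res.out_of_window.append(case)
            bump("before_window_start")
        elif not (case.suspect_drugs & doi):
            res.background.append(case)
            bump("no_drug_of_interest_as_suspect")
        elif not case.events:
            res.background.append(case)
            bump("no_listed_event")
        else:
            res.included.append(case)
            bump("included")

    assert len(res.included) + len(res.background) + len(res.out_of_window) \
        == len(cases)
    return res
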