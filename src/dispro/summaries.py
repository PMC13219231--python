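"""Descriptive summary tables: per-drug demographics, outcomes, regions,
report years and event frequencies, plus the year trend of report counts.

Percentages are computed as round-half-up(100·count/denominator, 1
decimal) using exact decimal arithmetic, so 1437/2128 prints 67.5 and
never 67.4 from a binary-float artefact.  Within the sex, outcome,
region and year blocks counts sum to the number of cases (missing
values fall into an explicit Unknown label); the event block counts
cases per term and may exceed the case total because one case can carry
several of the listed events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .case_processing import Case
from .vocabularies import (EventTermList, OUTCOME_CATEGORIES, REGIONS,
                           RegionMap)


def percent(count: float, denom: float, digits: int = 1) -> float | None:
    """Round-half-up percentage; None when the denominator is zero."""
    if denom == 0:
        return None
    q = (Decimal(count) * 100) / Decimal(denom)
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


@dataclass
class SummaryTable:
    """Counts and percentages for one drug's case subset."""

    drug: str
    n_cases: int
    #: block name → list of (label, count, percent-or-None)
    blocks: dict[str, list[tuple[str, int, float | None]]] = field(
        default_factory=dict)
    age_mean: float | None = None
    age_sd: float | None = None
    age_n: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"drug": self.drug, "block": "total",
                 "label": "Number of cases", "count": self.n_cases,
                 "percent": None}]
        for block, entries in self.blocks.items():
            for label, count, pct in entries:
                rows.append({"drug": self.drug, "block": block,
                             "label": label, "count": count, "percent": pct})
        return pd.DataFrame(rows, columns=["drug", "block", "label", "count",
                                           "percent"])


def summarize(cases: list[Case], drug: str,
              region_map: RegionMap | None = None,
              event_terms: EventTermList | None = None) -> SummaryTable:
    """Build the descriptive table for cases with ``drug`` as a suspect.

    ``cases`` is normally the included set of the inclusion filter
    (drug of interest as suspect, at least one listed event); the
    function itself only selects on suspect exposure.
    """
    region_map = region_map or RegionMap.default()
    event_terms = event_terms or EventTermList.default()
    sel = [c for c in cases if drug in c.suspect_drugs]
    n = len(sel)
    table = SummaryTable(drug=drug, n_cases=n)
    if n == 0:
        return table

    def block_counts(labels, value_of):
        counts = {lbl: 0 for lbl in labels}
        for c in sel:
            counts[value_of(c)] += 1
        return [(lbl, counts[lbl], percent(counts[lbl], n)) for lbl in labels]

    table.blocks["sex"] = block_counts(
        ("Male", "Female", "Unknown"),
        lambda c: {"M": "Male", "F": "Female"}.get(c.sex, "Unknown"))
    table.blocks["outcome"] = block_counts(
        OUTCOME_CATEGORIES + ("Unknown",),
        lambda c: c.outcome_category or "Unknown")
    table.blocks["region"] = block_counts(
        REGIONS, lambda c: region_map.region(c.reporter_country))

    years = sorted({c.report_year for c in sel if c.report_year is not None})
    year_labels = [str(y) for y in years] + ["Unknown"]
    table.blocks["year"] = block_counts(
        tuple(year_labels),
        lambda c: str(c.report_year) if c.report_year is not None else "Unknown")
    if table.blocks["year"][-1][1] == 0:  # drop empty Unknown year bucket
        table.blocks["year"] = table.blocks["year"][:-1]

    table.blocks["event"] = [
        (term, cnt, percent(cnt, n))
        for term in event_terms
        for cnt in [sum(1 for c in sel if term in c.events)]]

    ages = np.array([c.age_years for c in sel if c.age_years is not None],
                    dtype=float)
    table.age_n = ages.size
    if ages.size:
        table.age_mean = float(ages.mean())
        table.age_sd = float(ages.std(ddof=1)) if ages.size > 1 else 0.0
    return table


def summaries_to_frame(tables: list[SummaryTable]) -> pd.DataFrame:
    frames = [t.to_frame() for t in tables]
    rows = [row for f in frames for row in f.to_dict("records")]
    return pd.DataFrame(rows, columns=["drug", "block", "label", "count",
                                       "percent"])


def year_trend(cases: list[Case], drugs,
               country: str | None = None) -> pd.DataFrame:
    """Report counts per (drug, calendar year) with percent of drug total.

    ``country`` optionally restricts to one reporter country (e.g. "US")
    to mirror single-country trend figures.  Years with zero reports are
    omitted; per drug the counts sum to that drug's case total within
    the selection.
    """
    rows = []
    for drug in drugs:
        sel = [c for c in cases if drug in c.suspect_drugs
               and c.report_year is not None
               and (country is None or (c.reporter_country or "").upper()
                    == country.upper())]
        total = len(sel)
        counts: dict[int, int] = {}
        for c in sel:
            counts[c.report_year] = counts.get(c.report_year, 0) + 1
        for year in sorted(counts):
            rows.append({"drug": drug, "year": year, "count": counts[year],
                         "percent": percent(counts[year], total)})
    return pd.DataFrame(rows, columns=["drug", "year", "count", "percent"])
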