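"""Published reference counts for the SGLT2-inhibitor lower-limb /
gangrene FAERS analysis, and the arithmetic check that recomputes every
printed percentage from its printed count.

The bundled table (``data/reference_counts.csv``) transcribes the
published per-drug descriptive counts: cases, sex, outcome categories,
reporter regions, report years and event-term frequencies for
canagliflozin, dapagliflozin, empagliflozin and ertugliflozin.  It is
used only to validate percentage arithmetic (round-half-up to one
decimal), never as an input to the pipeline.

Denominators: the sex, outcome, year and event blocks are percentages
of the drug's case count.  The reporter-region block in the published
table uses the block's own column sum as denominator (the region counts
sum to 2133, 381 and 1082 — more than the case totals, a case can carry
more than one reporter country across versions); recomputation confirms
every region cell reconciles under that convention and not under the
case-count denominator.

A small number of printed cells do not reconcile with their own counts
under any standard rounding rule (transcription/formatting slips in the
source table); they are listed in :data:`INCONSISTENT_CELLS` with the
reason and excluded from the exact-match check.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .summaries import percent

#: (drug, block, label) → why the printed percentage cannot be reproduced
INCONSISTENT_CELLS = {
    ("canagliflozin", "outcome", "Death"):
        "27/2128 = 1.3 under half-up rounding; printed 1.2",
    ("canagliflozin", "event", "Leg amputation"):
        "414/2128 = 19.5 under half-up rounding; printed 19.4",
    ("canagliflozin", "event", "Dry gangrene"):
        "50/2128 = 2.3 under any standard rounding; printed 2.4",
    ("empagliflozin", "outcome", "Disability"):
        "126/1049 = 12.0 under any standard rounding; printed 12.1",
    ("empagliflozin", "event", "Diabetic gangrene"):
        "4/1049 = 0.4 under half-up rounding; printed 0.3",
    ("dapagliflozin", "outcome", "Death"):
        "24/361 = 6.6 under half-up rounding; printed 6.7",
    ("dapagliflozin", "outcome", "Other medical events"):
        "printed to 0 decimals (29) instead of 1 (29.1)",
    ("dapagliflozin", "event", "Cellulitis gangrenous"):
        "printed to 2 decimals (0.28) instead of 1 (0.3)",
    ("dapagliflozin", "event", "Diabetic gangrene"):
        "2/361 = 0.6; printed 0.28, apparently copied from the row above",
}


@dataclass(frozen=True)
class ReferenceCell:
    drug: str
    block: str
    label: str
    count: int
    printed_percent: float | None
    recomputed_percent: float | None
    matches: bool | None  # None when not checkable (no printed percent)
    excluded_reason: str | None


def load_reference_counts() -> list[dict]:
    path = resources.files("dispro.data").joinpath("reference_counts.csv")
    with resources.as_file(path) as p, open(p, encoding="utf-8",
                                            newline="") as fh:
        rows = list(csv.DictReader(fh))
    for r in rows:
        r["count"] = int(r["count"])
        r["printed_percent"] = (float(r["printed_percent"])
                                if r["printed_percent"] else None)
    return rows


def check_percent_arithmetic() -> list[ReferenceCell]:
    """Recompute every printed percentage from its printed count.

    Returns one :class:`ReferenceCell` per non-total row; cells listed
    in :data:`INCONSISTENT_CELLS` carry their exclusion reason and a
    ``matches`` verdict of None.
    """
    rows = load_reference_counts()
    n_cases = {r["drug"]: r["count"] for r in rows if r["block"] == "total"}
    region_totals: dict[str, int] = {}
    for r in rows:
        if r["block"] == "region":
            region_totals[r["drug"]] = region_totals.get(r["drug"], 0) \
                + r["count"]

    cells = []
    for r in rows:
        if r["block"] == "total":
            continue
        denom = region_totals[r["drug"]] if r["block"] == "region" \
            else n_cases[r["drug"]]
        recomputed = percent(r["count"], denom)
        key = (r["drug"], r["block"], r["label"])
        excluded = INCONSISTENT_CELLS.get(key)
        printed = r["printed_percent"]
        if printed is None or excluded is not None:
            matches = None
        else:
            matches = recomputed == printed
        cells.append(ReferenceCell(
            drug=r["drug"], block=r["block"], label=r["label"],
            count=r["count"], printed_percent=printed,
            recomputed_percent=recomputed, matches=matches,
            excluded_reason=excluded))
    return cells
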