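"""Controlled vocabularies: drug-name normalization, the closed event-term
list, country→region and outcome-code→category maps.

Drug mentions in spontaneous reports are free text — brand names, typos,
fixed-dose combinations.  Normalization here is deliberately *exact*
(after lower-casing, whitespace collapsing and apostrophe unification):
a mention either matches a dictionary synonym and resolves to its
nonproprietary (USAN-style) generic constituents, or it resolves to
nothing and is excluded from drug-of-interest identification.  No fuzzy
matching: edit-distance heuristics would silently change counts.
"""

from __future__ import annotations

import csv
import re
from importlib import resources
from pathlib import Path

_WS = re.compile(r"\s+")


def normalize_text(s: str) -> str:
    """Lower-case, trim, collapse internal whitespace, unify apostrophes."""
    return _WS.sub(" ", s.strip().lower()).replace("’", "'")


def _data_path(name: str):
    return resources.files("dispro.data").joinpath(name)


class DrugDictionary:
    """Mapping from normalized synonym → set of generic constituent names.

    Combination products list one row per constituent; exposure to any
    constituent counts as exposure to that generic.  Every generic name
    maps to itself.
    """

    def __init__(self, entries: dict[str, frozenset[str]]):
        self.entries = dict(entries)
        # every generic maps to itself
        for generics in list(self.entries.values()):
            for g in generics:
                self.entries.setdefault(normalize_text(g), frozenset({g}))

    @classmethod
    def from_rows(cls, rows) -> "DrugDictionary":
        acc: dict[str, set[str]] = {}
        seen_pairs: set[tuple[str, str]] = set()
        for synonym, generic in rows:
            syn = normalize_text(synonym)
            gen = normalize_text(generic)
            if (syn, gen) in seen_pairs:
                raise ValueError(f"duplicate dictionary row: {synonym!r} -> "
                                 f"{generic!r}")
            seen_pairs.add((syn, gen))
            acc.setdefault(syn, set()).add(gen)
        return cls({k: frozenset(v) for k, v in acc.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or \
                    {"synonym", "generic"} - set(reader.fieldnames):
                raise ValueError(f"{Path(path).name}: expected columns "
                                 "synonym, generic")
            return cls.from_rows((r["synonym"], r["generic"]) for r in reader)

    @classmethod
    def default(cls) -> "DrugDictionary":
        """Dictionary bundled with the package: the 8 SGLT2-inhibitor
        generics plus brand names and fixed-dose combinations."""
        with resources.as_file(_data_path("drug_synonyms.csv")) as p:
            return cls.from_csv(p)

    def normalize(self, verbatim: str) -> frozenset[str]:
        """Resolve a free-text mention; empty set when unmatched."""
        return self.entries.get(normalize_text(verbatim), frozenset())

    def __contains__(self, verbatim: str) -> bool:
        return normalize_text(verbatim) in self.entries


#: generics of the studied oral antidiabetic class, in reporting order
SGLT2_INHIBITORS = ("canagliflozin", "dapagliflozin", "empagliflozin",
                    "ertugliflozin", "ipragliflozin", "tofogliflozin",
                    "luseogliflozin", "remogliflozin")


class EventTermList:
    """The closed list of adverse-event preferred terms under study.

    Matching is case-insensitive exact after whitespace/apostrophe
    normalization; a PT outside the list (e.g. bare "Gangrene") never
    matches.
    """

    def __init__(self, terms: list[str]):
        self.terms = list(terms)  # display form, fixed order
        self._lookup = {normalize_text(t): t for t in terms}
        if len(self._lookup) != len(self.terms):
            raise ValueError("duplicate event terms after normalization")

    @classmethod
    def from_file(cls, path: str | Path) -> "EventTermList":
        with open(path, encoding="utf-8") as fh:
            terms = [line.strip() for line in fh if line.strip()]
        return cls(terms)

    @classmethod
    def default(cls) -> "EventTermList":
        """The 12 lower-limb / gangrene preferred terms."""
        with resources.as_file(_data_path("event_terms.txt")) as p:
            return cls.from_file(p)

    def canonical(self, preferred_term: str) -> str | None:
        """Canonical display form of a matching PT, else None."""
        return self._lookup.get(normalize_text(preferred_term))

    def match(self, preferred_term: str) -> bool:
        return self.canonical(preferred_term) is not None

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)


REGIONS = ("North America", "Europe", "Asia", "Oceania", "South America",
           "Africa", "Unknown")


class RegionMap:
    """Total map from reporter-country code to continent-level region."""

    def __init__(self, mapping: dict[str, str]):
        bad = set(mapping.values()) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region(s): {sorted(bad)}")
        self.mapping = {k.strip().upper(): v for k, v in mapping.items()}

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or \
                    {"country_code", "region"} - set(reader.fieldnames):
                raise ValueError(f"{Path(path).name}: expected columns "
                                 "country_code, region")
            return cls({r["country_code"]: r["region"] for r in reader})

    @classmethod
    def default(cls) -> "RegionMap":
        with resources.as_file(_data_path("region_map.csv")) as p:
            return cls.from_csv(p)

    def region(self, country: str | None) -> str:
        if not country:
            return "Unknown"
        return self.mapping.get(country.strip().upper(), "Unknown")


OUTCOME_CATEGORIES = ("Hospitalization-initial or prolonged", "Life-threatening",
                      "Disability", "Death", "Other medical events")

#: FAERS outcome code → descriptive category (CA, RI and OT all fold into
#: "Other medical events")
OUTCOME_CATEGORY_MAP = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization-initial or prolonged",
    "DS": "Disability",
    "CA": "Other medical events",
    "RI": "Other medical events",
    "OT": "Other medical events",
}

#: severity order used to assign one category per consolidated case
OUTCOME_PRECEDENCE = ("Death", "Life-threatening", "Disability",
                      "Hospitalization-initial or prolonged",
                      "Other medical events")


def map_outcome(code: str) -> str:
    """Outcome category for one code; unknown codes raise KeyError."""
    return OUTCOME_CATEGORY_MAP[code.strip().upper()]


def worst_outcome(codes) -> str | None:
    """Single category for a set of codes by severity precedence."""
    cats = {map_outcome(c) for c in codes}
    for cat in OUTCOME_PRECEDENCE:
        if cat in cats:
            return cat
    return None
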