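"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a FAERS extract — multiple submitted versions
per case, primary-suspect vs concomitant drug roles, free-text drug
names (generics, brands, typos), MedDRA-style preferred terms including
the 12 studied lower-limb/gangrene terms, outcome codes, demographics,
reporter countries and receipt dates — with drug–event association
strengths designed on the odds-ratio scale.

Event model.  Each case is first assigned at most one drug of interest
as primary suspect (categorical draw over the configured marginal
exposure probabilities; the remainder get a background suspect drug).
Each studied event term is then a Bernoulli draw whose odds equal
baseline-odds × θ(drug, event) when the case is exposed to the drug.
Because the multiplication happens on the odds scale, the case-level
cross-product ratio of the implied 2×2 table is exactly θ: the designed
parameter is the estimand of the reporting odds ratio, with no
approximation at any baseline rate.

Everything is driven by one ``numpy`` generator seeded from the config,
so equal configs produce byte-identical report sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .case_processing import DEFAULT_WINDOW_START
from .io_faers import DemoRow, DrugRow, OutcRow, ReacRow, ReportSet

#: PTs outside the studied list, used as filler reactions
OTHER_PTS = ("Pyrexia", "Nausea", "Headache", "Dizziness",
             "Urinary tract infection", "Ketoacidosis", "Dehydration",
             "Rash", "Fatigue", "Hypoglycaemia")

#: background suspect / concomitant drugs (verbatim pool, not in the
#: SGLT2-inhibitor dictionary except metformin-alone which maps to itself)
OTHER_DRUGS = ("LISINOPRIL", "ATORVASTATIN", "INSULIN GLARGINE",
               "OMEPRAZOLE", "ASPIRIN", "LEVOTHYROXINE", "AMLODIPINE",
               "GLIMEPIRIDE", "SERTRALINE", "IBUPROFEN")

DEFAULT_COUNTRIES = {"US": 0.70, "GB": 0.05, "DE": 0.04, "FR": 0.03,
                     "JP": 0.05, "CA": 0.04, "AU": 0.03, "BR": 0.02,
                     "ZA": 0.01, "": 0.03}
DEFAULT_OUTCOMES = {"HO": 0.42, "OT": 0.28, "DS": 0.15, "LT": 0.06,
                    "DE": 0.04, "RI": 0.03, "CA": 0.02}
DEFAULT_SEX = {"M": 0.62, "F": 0.35, "UNK": 0.03}


class DrugSpec(BaseModel):
    """One drug of interest: marginal exposure and its free-text synonyms."""

    name: str
    exposure_prob: float = Field(ge=0.0, le=1.0)
    synonyms: tuple[str, ...] = ()
    ps_prob: float = Field(default=1.0, ge=0.0, le=1.0)

    @property
    def name_pool(self) -> tuple[str, ...]:
        return (self.name,) + tuple(self.synonyms)


class EventSpec(BaseModel):
    term: str
    baseline_prob: float = Field(gt=0.0, lt=1.0)


class SyntheticConfig(BaseModel):
    """Full description of one synthetic reporting universe."""

    n_cases: int = Field(gt=0)
    seed: int = 0
    drugs: tuple[DrugSpec, ...]
    events: tuple[EventSpec, ...]
    #: designed odds ratio per (drug name, event term); missing pairs are 1
    theta: dict[str, dict[str, float]] = {}
    followup_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    noise: float = Field(default=0.0, ge=0.0, le=1.0)  # P(unmatched typo)
    concomitant_max: int = Field(default=0, ge=0)
    other_pt_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    sex_probs: dict[str, float] = DEFAULT_SEX
    age_mean: float = 58.0
    age_sd: float = 10.0
    country_probs: dict[str, float] = DEFAULT_COUNTRIES
    outcome_probs: dict[str, float] = DEFAULT_OUTCOMES
    date_start: date = date(2013, 4, 1)
    date_end: date = date(2024, 12, 31)

    @field_validator("theta")
    @classmethod
    def _theta_positive(cls, v):
        for per_event in v.values():
            for theta in per_event.values():
                if theta <= 0:
                    raise ValueError("theta must be > 0")
        return v

    @model_validator(mode="after")
    def _checks(self):
        if sum(d.exposure_prob for d in self.drugs) > 1.0 + 1e-12:
            raise ValueError("summed exposure probabilities exceed 1")
        if self.date_end < self.date_start:
            raise ValueError("date_end precedes date_start")
        for probs in (self.sex_probs, self.country_probs, self.outcome_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("probability table does not sum to 1")
        return self

    def theta_for(self, drug: str, event: str) -> float:
        return self.theta.get(drug, {}).get(event, 1.0)


@dataclass
class GroundTruth:
    """Designed parameters and realized case-level indicators."""

    config: SyntheticConfig
    case_ids: list[str]
    exposure: list[str | None]       # drug-of-interest name or None
    events: list[set[str]]           # realized studied events per case
    in_window: list[bool]

    def realized_table(self, drug: str, event: str,
                       window_only: bool = True) -> tuple[int, int, int, int]:
        """Case-level (a, b, c, d) from the true exposure/event indicators."""
        a = b = c = d = 0
        for exp, evs, ok in zip(self.exposure, self.events, self.in_window):
            if window_only and not ok:
                continue
            if exp == drug:
                if event in evs:
                    a += 1
                else:
                    b += 1
            elif event in evs:
                c += 1
            else:
                d += 1
        return a, b, c, d

    def to_json(self, path) -> None:
        payload = {
            "config": json.loads(self.config.model_dump_json()),
            "theta": {d.name: {e.term: self.config.theta_for(d.name, e.term)
                               for e in self.config.events}
                      for d in self.config.drugs},
            "realized_tables": {
                f"{d.name}|{e.term}": self.realized_table(d.name, e.term)
                for d in self.config.drugs for e in self.config.events},
            "n_cases": len(self.case_ids),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _typo(name: str, rng: np.random.Generator) -> str:
    """Corrupt a drug name so it no longer matches any dictionary synonym."""
    if len(name) > 4:
        i = int(rng.integers(1, len(name) - 1))
        out = name[:i] + name[i + 1:]
    else:
        out = name + "X"
    return out + "~"  # tilde guarantees no dictionary hit


def generate(config: SyntheticConfig) -> tuple[ReportSet, GroundTruth]:
    """Sample one report set plus its ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_drugs = len(config.drugs)
    n_events = len(config.events)

    # exposure: categorical over drugs of interest, remainder unexposed
    cum = np.cumsum([d.exposure_prob for d in config.drugs])
    u = rng.random(n)
    drug_idx = np.searchsorted(cum, u)  # n_drugs == unexposed

    # events: odds-multiplicative Bernoulli matrix
    base_odds = np.array([e.baseline_prob / (1.0 - e.baseline_prob)
                          for e in config.events])
    theta_rows = np.ones((n_drugs + 1, n_events))
    for i, d in enumerate(config.drugs):
        for j, e in enumerate(config.events):
            theta_rows[i, j] = config.theta_for(d.name, e.term)
    odds = base_odds[None, :] * theta_rows[drug_idx, :]
    event_mat = rng.random((n, n_events)) < odds / (1.0 + odds)

    sex_labels = list(config.sex_probs)
    sexes = rng.choice(sex_labels, size=n, p=list(config.sex_probs.values()))
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 18, 95)
    country_labels = list(config.country_probs)
    countries = rng.choice(country_labels, size=n,
                           p=list(config.country_probs.values()))
    outcome_labels = list(config.outcome_probs)
    span = (config.date_end - config.date_start).days
    day_offsets = rng.integers(0, span + 1, size=n)
    followups = rng.random(n) < config.followup_rate

    rs = ReportSet()
    case_ids, exposures, event_sets, in_window = [], [], [], []

    for i in range(n):
        case_id = str(10000001 + i)
        exposed = drug_idx[i] < n_drugs
        spec = config.drugs[drug_idx[i]] if exposed else None
        evs = {config.events[j].term for j in range(n_events) if event_mat[i, j]}
        receipt = config.date_start + timedelta(days=int(day_offsets[i]))

        # suspect drug verbatim name
        if exposed:
            pool = spec.name_pool
            verbatim = str(pool[rng.integers(0, len(pool))]).upper()
            if rng.random() < config.noise:
                verbatim = _typo(verbatim, rng)
            role = "PS" if rng.random() < spec.ps_prob else "SS"
        else:
            verbatim = OTHER_DRUGS[rng.integers(0, len(OTHER_DRUGS))]
            role = "PS"

        reactions = sorted(evs)
        if rng.random() < config.other_pt_rate or not reactions:
            reactions = reactions + [OTHER_PTS[rng.integers(0, len(OTHER_PTS))]]

        n_versions = 2 if followups[i] else 1
        for version in range(1, n_versions + 1):
            pid = f"{case_id}{version}"
            v_receipt = receipt if version == 1 else \
                receipt + timedelta(days=int(rng.integers(30, 400)))
            rs.demo.append(DemoRow(
                primary_id=pid, case_id=case_id, case_version=version,
                receipt_date=v_receipt, date_precision="day",
                age_value=round(float(ages[i]), 0), age_unit="YR",
                sex=str(sexes[i]),
                reporter_country=str(countries[i]) or None))
            rs.drugs.append(DrugRow(primary_id=pid, drug_seq=1,
                                    role_code=role,
                                    drug_name_verbatim=verbatim))
            seq = 2
            if config.concomitant_max:
                k = int(rng.integers(0, config.concomitant_max + 1))
                # distinct names: one drug row per product and report
                for j in rng.choice(len(OTHER_DRUGS), size=k, replace=False):
                    rs.drugs.append(DrugRow(
                        primary_id=pid, drug_seq=seq, role_code="C",
                        drug_name_verbatim=OTHER_DRUGS[int(j)]))
                    seq += 1
            v_reactions = reactions
            if version == 2 and len(reactions) > 1 and rng.random() < 0.5:
                # follow-up drops one previously reported event: exercises
                # the union semantics of case consolidation
                drop = int(rng.integers(0, len(reactions)))
                v_reactions = reactions[:drop] + reactions[drop + 1:]
            for pt in v_reactions:
                emit = pt.upper() if rng.random() < 0.1 else pt
                rs.reactions.append(ReacRow(primary_id=pid, preferred_term=emit))
            code = outcome_labels[rng.choice(
                len(outcome_labels), p=list(config.outcome_probs.values()))]
            rs.outcomes.append(OutcRow(primary_id=pid, outcome_code=code))

        case_ids.append(case_id)
        exposures.append(spec.name if exposed else None)
        event_sets.append(evs)
        in_window.append(receipt >= DEFAULT_WINDOW_START)

    truth = GroundTruth(config=config, case_ids=case_ids, exposure=exposures,
                        events=event_sets, in_window=in_window)
    return rs, truth


def make_paper_shaped_fixture(seed: int = 0) -> tuple[ReportSet, GroundTruth]:
    """A small (~500-case) universe shaped like the studied extract.

    Four SGLT2-inhibitor drugs with very unequal reporting volumes, the
    12 studied event terms with strong designed associations for the
    dominant drug, brand-name and typo mentions, follow-up versions,
    multi-event cases and receipt dates extending before the 2013-03-29
    window start (so the window filter always has work to do).
    """
    from .vocabularies import EventTermList

    terms = list(EventTermList.default())
    drugs = (
        DrugSpec(name="canagliflozin", exposure_prob=0.28,
                 synonyms=("INVOKANA", "Invokamet")),
        DrugSpec(name="empagliflozin", exposure_prob=0.14,
                 synonyms=("JARDIANCE", "Synjardy")),
        DrugSpec(name="dapagliflozin", exposure_prob=0.06,
                 synonyms=("FARXIGA", "Forxiga")),
        DrugSpec(name="ertugliflozin", exposure_prob=0.006,
                 synonyms=("STEGLATRO",)),
    )
    theta = {
        "canagliflozin": {"Toe amputation": 40.0, "Amputation": 30.0,
                          "Fournier's gangrene": 15.0, "Osteomyelitis": 12.0,
                          "Diabetic foot": 8.0},
        "empagliflozin": {"Fournier's gangrene": 35.0, "Toe amputation": 6.0},
        "dapagliflozin": {"Fournier's gangrene": 12.0, "Toe amputation": 3.0},
    }
    config = SyntheticConfig(
        n_cases=500, seed=seed,
        drugs=drugs,
        events=tuple(EventSpec(term=t, baseline_prob=0.02) for t in terms),
        theta=theta, followup_rate=0.3, noise=0.05, concomitant_max=2,
        other_pt_rate=0.5,
        date_start=date(2012, 6, 1), date_end=date(2024, 12, 31))
    return generate(config)
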