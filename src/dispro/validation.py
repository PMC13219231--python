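"""Simulation-based calibration checks for the full pipeline.

These run the generator's designed universes through the *entire*
analysis path (report set → consolidation → inclusion filter → 2×2
table → ROR/CI) and measure frequentist operating characteristics:

* null coverage — with designed odds ratio θ = 1, the 95% Wald CI
  should cover 1 in ≈95% of replicates;
* parameter recovery — with θ = 10 the estimated ROR should concentrate
  around 10, since the generator's odds-multiplicative event model makes
  θ exactly the case-level cross-product ratio.

Design sizes default to all-positive expected cells (the Wald interval
is only calibrated away from zero counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

from .case_processing import InclusionConfig, apply_inclusion_filters, deduplicate
from .disproportionality import DisproportionalityResult, build_contingency, \
    compute_ror
from .synthetic import DrugSpec, EventSpec, SyntheticConfig, generate
from .vocabularies import DrugDictionary, EventTermList

_DRUG = "canagliflozin"
_EVENT = "Toe amputation"
_SEED_MOD = 2**31


@dataclass
class PairEstimate:
    ror: float
    ci_low: float
    ci_high: float
    table: tuple[int, int, int, int]


def _single_pair_config(theta: float, n_cases: int, seed: int,
                        exposure: float, baseline: float) -> SyntheticConfig:
    return SyntheticConfig(
        n_cases=n_cases, seed=seed % _SEED_MOD,
        drugs=(DrugSpec(name=_DRUG, exposure_prob=exposure),),
        events=(EventSpec(term=_EVENT, baseline_prob=baseline),),
        theta={_DRUG: {_EVENT: theta}},
        followup_rate=0.0, noise=0.0, concomitant_max=0, other_pt_rate=0.0,
        date_start=date(2013, 4, 1), date_end=date(2024, 12, 31))


def estimate_single_pair(theta: float, n_cases: int, seed: int,
                         exposure: float, baseline: float,
                         drug_dict: DrugDictionary | None = None,
                         event_terms: EventTermList | None = None,
                         ) -> PairEstimate:
    """One replicate: generate a universe, run the pipeline, estimate ROR."""
    drug_dict = drug_dict or DrugDictionary.default()
    event_terms = event_terms or EventTermList.default()
    rs, _ = generate(_single_pair_config(theta, n_cases, seed,
                                         exposure, baseline))
    cases = deduplicate(rs, drug_dict, event_terms)
    fr = apply_inclusion_filters(cases, InclusionConfig(
        drugs_of_interest=(_DRUG,)))
    table = build_contingency(fr.included, fr.background, _DRUG, _EVENT)
    res: DisproportionalityResult = compute_ror(table, drug=_DRUG,
                                                event=_EVENT)
    return PairEstimate(ror=res.ror, ci_low=res.ci_low, ci_high=res.ci_high,
                        table=(table.a, table.b, table.c, table.d))


def replicate_estimates(theta: float, n_cases: int, n_replicates: int,
                        seed: int, exposure: float,
                        baseline: float) -> list[PairEstimate]:
    ddict = DrugDictionary.default()
    terms = EventTermList.default()
    return [estimate_single_pair(theta, n_cases, seed + 1000 * i,
                                 exposure, baseline, ddict, terms)
            for i in range(n_replicates)]


def null_coverage(n_cases: int = 5000, n_replicates: int = 200,
                  seed: int = 1, exposure: float = 0.15,
                  baseline: float = 0.08) -> float:
    """Fraction of θ=1 replicates whose 95% CI covers 1."""
    estimates = replicate_estimates(1.0, n_cases, n_replicates, seed,
                                    exposure, baseline)
    return sum(1 for e in estimates if e.ci_low <= 1.0 <= e.ci_high) \
        / len(estimates)


def recovery_median_ror(theta: float = 10.0, n_cases: int = 20000,
                        n_replicates: int = 50, seed: int = 1,
                        exposure: float = 0.1,
                        baseline: float = 0.01) -> float:
    """Median estimated ROR across θ-design replicates."""
    estimates = replicate_estimates(theta, n_cases, n_replicates, seed,
                                    exposure, baseline)
    rors = sorted(e.ror for e in estimates)
    m = len(rors)
    return rors[m // 2] if m % 2 else 0.5 * (rors[m // 2 - 1] + rors[m // 2])
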