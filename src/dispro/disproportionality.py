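"""Reporting-odds-ratio disproportionality analysis.

For each drug–event pair the case universe (included ∪ background) is
cross-classified into the 2×2 table

    a  — cases reporting the event with the drug as suspect,
    b  — cases with the drug as suspect, without the event,
    c  — cases reporting the event with any other drug,
    d  — cases with neither,

and the reporting odds ratio ROR = a·d / (b·c) is computed with a Wald
confidence interval on the log scale,

    ln ROR ± z_{1−α/2} · sqrt(1/a + 1/b + 1/c + 1/d).

A zero cell makes the ROR or its variance degenerate; under the
``haldane_if_zero`` policy (default) 0.5 is added to ALL four cells of
an affected table (Haldane–Anscombe) and the correction is recorded on
the result.  Tables with all cells positive are never touched.

A pair is flagged as a disproportionality signal when ROR exceeds the
threshold (default 2.00) AND the lower CI bound exceeds its threshold
(default 1.00), both strict inequalities.  No multiple-testing
adjustment is applied by default; a Bonferroni hook is provided for
users who want one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd
from scipy.stats import norm

from .case_processing import Case


class DegenerateTableError(ValueError):
    """The drug has no exposed cases (a + b = 0): no table can be formed."""


class ZeroCellError(ValueError):
    """A zero cell under correction policy 'none'."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SignalCriteria:
    """Signal rule: ROR > ror_threshold and CI lower bound > ci_low_threshold
    (strict inequalities)."""

    ror_threshold: float = 2.0
    ci_low_threshold: float = 1.0

    def __post_init__(self):
        if self.ror_threshold <= 0 or self.ci_low_threshold <= 0:
            raise ValueError("signal thresholds must be positive")


@dataclass(frozen=True)
class DisproportionalityResult:
    drug: str
    event: str
    table: ContingencyTable | None
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    alpha: float
    correction_applied: bool
    signal: bool
    status: str = "ok"  # "ok" | "no_exposure"


def build_contingency(included: list[Case], background: list[Case],
                      drug: str, event: str) -> ContingencyTable:
    """Count the four cells over the union of included and background cases.

    Cell a requires the (drug, event) pair to have co-occurred in at
    least one version of the case; exposure (a + b) counts any case
    with the drug in a suspect role.
    """
    a = b = c = d = 0
    for cases in (included, background):
        for case in cases:
            exposed = drug in case.suspect_drugs
            if exposed and (drug, event) in case.drug_event_pairs:
                a += 1
            elif exposed:
                b += 1
            elif event in case.events:
                c += 1
            else:
                d += 1
    if a + b == 0:
        raise DegenerateTableError(
            f"no case exposed to {drug!r}: cannot form a 2x2 table")
    return ContingencyTable(a, b, c, d)


def compute_ror(table: ContingencyTable, alpha: float = 0.05,
                correction_policy: str = "haldane_if_zero",
                criteria: SignalCriteria | None = None,
                drug: str = "", event: str = "") -> DisproportionalityResult:
    """ROR with a log-scale Wald CI and the signal decision for one table."""
    if correction_policy not in {"none", "haldane_if_zero"}:
        raise ValueError(f"unknown correction policy {correction_policy!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    criteria = criteria or SignalCriteria()

    corrected = table.has_zero() and correction_policy == "haldane_if_zero"
    if table.has_zero() and correction_policy == "none":
        raise ZeroCellError(f"zero cell in {table} with correction policy 'none'")
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (table.a + shift, table.b + shift,
                  table.c + shift, table.d + shift)

    ror = (a * d) / (b * c)
    z = norm.ppf(1.0 - alpha / 2.0)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)

    result = DisproportionalityResult(
        drug=drug, event=event, table=table, ror=ror,
        ci_low=ci_low, ci_high=ci_high, alpha=alpha,
        correction_applied=corrected, signal=False)
    return replace(result, signal=classify_signal(result, criteria))


def classify_signal(result: DisproportionalityResult,
                    criteria: SignalCriteria | None = None) -> bool:
    """Apply the signal rule (strict inequalities on ROR and CI lower bound)."""
    criteria = criteria or SignalCriteria()
    if result.ror is None or result.ci_low is None:
        return False
    return (result.ror > criteria.ror_threshold
            and result.ci_low > criteria.ci_low_threshold)


def screen(included: list[Case], background: list[Case],
           drugs, events, criteria: SignalCriteria | None = None,
           alpha: float = 0.05,
           correction_policy: str = "haldane_if_zero",
           n_comparisons: int | None = None) -> list[DisproportionalityResult]:
    """Batch RORs over the drug × event grid, in the given order.

    Pairs whose drug has no exposed case are reported with status
    ``"no_exposure"`` and no numbers rather than raised, so a sparse
    drug never aborts a screen.  ``n_comparisons`` enables an optional
    Bonferroni adjustment (alpha / n_comparisons) for users who want
    multiplicity control; the default applies none.
    """
    criteria = criteria or SignalCriteria()
    eff_alpha = alpha if not n_comparisons else alpha / n_comparisons
    results = []
    for drug in drugs:
        exposed = any(drug in c.suspect_drugs for c in included) or \
            any(drug in c.suspect_drugs for c in background)
        for event in events:
            if not exposed:
                results.append(DisproportionalityResult(
                    drug=drug, event=event, table=None, ror=None,
                    ci_low=None, ci_high=None, alpha=eff_alpha,
                    correction_applied=False, signal=False,
                    status="no_exposure"))
                continue
            table = build_contingency(included, background, drug, event)
            results.append(compute_ror(table, alpha=eff_alpha,
                                       correction_policy=correction_policy,
                                       criteria=criteria, drug=drug,
                                       event=event))
    return results


def results_to_frame(results: list[DisproportionalityResult]) -> pd.DataFrame:
    """Flatten screen results to the export table."""
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "drug": r.drug, "event": r.event,
            "a": t.a if t else None, "b": t.b if t else None,
            "c": t.c if t else None, "d": t.d if t else None,
            "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "alpha": r.alpha, "correction_applied": r.correction_applied,
            "signal": r.signal, "status": r.status})
    return pd.DataFrame(rows, columns=["drug", "event", "a", "b", "c", "d",
                                       "ror", "ci_low", "ci_high", "alpha",
                                       "correction_applied", "signal",
                                       "status"])
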