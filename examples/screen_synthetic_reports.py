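"""Screen a synthetic reporting universe for disproportionality signals.

Generates the bundled study-shaped fixture (~500 cases, four SGLT2
inhibitors, the 12 lower-limb/gangrene preferred terms, follow-up
versions, brand names and typos), consolidates report versions into
cases, applies the inclusion filters, and prints the reporting odds
ratio for every drug-event pair flagged as a signal (ROR > 2 and lower
95% CI bound > 1).
"""

from dispro import (EventTermList, SGLT2_INHIBITORS, apply_inclusion_filters,
                    deduplicate, make_paper_shaped_fixture, results_to_frame,
                    screen)

report_set, truth = make_paper_shaped_fixture(seed=1)
print(f"report versions: {len(report_set.demo)}  "
      f"cases: {len(truth.case_ids)}")

cases = deduplicate(report_set)
filtered = apply_inclusion_filters(cases)
print(f"included: {len(filtered.included)}  "
      f"background: {len(filtered.background)}  "
      f"out of window: {len(filtered.out_of_window)}")

results = screen(filtered.included, filtered.background,
                 SGLT2_INHIBITORS[:4], list(EventTermList.default()))
df = results_to_frame(results)
signals = df[df.signal][["drug", "event", "a", "ror", "ci_low", "ci_high"]]
print("\nsignalled drug-event pairs "
      "(a = exposed cases with the event; CI is the 95% Wald interval):")
print(signals.round(2).to_string(index=False))
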