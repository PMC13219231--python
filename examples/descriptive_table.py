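"""Per-drug descriptive summary and year trend on a synthetic universe.

Prints the canagliflozin block of the descriptive table (sex, outcome
severity, reporter region, report year, event frequencies) with counts
and round-half-up percentages, then the per-year report counts.  Event
percentages can sum past 100 because one case may carry several of the
listed events.
"""

from dispro import (apply_inclusion_filters, deduplicate,
                    make_paper_shaped_fixture, summarize, year_trend)

report_set, _ = make_paper_shaped_fixture(seed=1)
filtered = apply_inclusion_filters(deduplicate(report_set))

table = summarize(filtered.included, "canagliflozin")
print(f"canagliflozin: {table.n_cases} cases, mean age "
      f"{table.age_mean:.0f} ({table.age_sd:.0f}) over {table.age_n} "
      "cases with known age\n")
for block in ("sex", "outcome", "region", "event"):
    print(block)
    for label, count, pct in table.blocks[block]:
        if count:
            print(f"  {label:<40} {count:>4} ({pct})")

print("\nreports per year (count, % of the drug's total):")
trend = year_trend(filtered.included, ["canagliflozin"])
print(trend.to_string(index=False))
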