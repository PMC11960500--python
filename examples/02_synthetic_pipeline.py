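"""Full signal-detection pipeline on a synthetic FAERS-like corpus.

Generates a corpus with one implanted drug-event association (relative risk
50 for ARIA-E), ingests and deduplicates it, builds PT-level contingency
tables and computes all four disproportionality statistics, then applies
the five-way joint signal criteria.
"""

from faersignal import SyntheticConfig, build_dataset, build_tables, generate
from faersignal.signals import (compute_statistics_table, decisions_to_frame,
                                evaluate_criteria)
from faersignal.disprop import SignalStatistics
from faersignal.synthetic import default_pt_soc_map

config = SyntheticConfig(n_background_reports=30_000, n_focal_reports=500,
                         implanted_rr={"ARIA-E": 50.0}, seed=1)
dataset = build_dataset(generate(config), ("aducanumab", "aduhelm"),
                        default_pt_soc_map())
print(f"cases: {dataset.meta['n_cases']} "
      f"(focal {dataset.meta['n_focal_cases']}), "
      f"events: {dataset.meta['n_events']}")

tables = [(t, tab) for t, tab in
          build_tables(dataset.events, dataset.focal_case_ids, level="PT",
                       unit="event")
          if tab.a > 0]
stats = compute_statistics_table(tables, seed=1)
decisions = evaluate_criteria(
    [(r.term, int(r.a),
      SignalStatistics(r.ror, r.ror_low, r.ror_high, r.prr, r.chi2, r.ic,
                       r.ic_minus_2sd, r.ebgm, r.ebgm05, r.rr))
     for r in stats.itertuples()])
frame = decisions_to_frame(decisions)
significant = frame[frame["significant"]]
print(f"\nsignificant signals ({len(significant)} of {len(frame)} terms):")
print(significant[["term", "a", "ror", "ror_low", "ror_high", "prr", "ic",
                   "ebgm05"]].round(2).to_string(index=False))
print("\nThe implanted term should be flagged with its ROR 95% CI covering")
print("the true relative risk of 50; background terms stay unflagged.")
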