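"""Demographic summary and time-to-onset analysis.

The published-count record set reproduces the printed percentages exactly;
the calibrated generator then shows the same summaries computed end-to-end
from simulated raw tables, including the binned time-to-onset distribution.
"""

from faersignal import build_dataset, compute_onset, generate, published, \
    summarize_demographics
from faersignal.synthetic import aducanumab_profile, default_pt_soc_map

frame = summarize_demographics(published.demographic_records())
sex = frame[frame["section"] == "sex"]
print("sex distribution from the published counts:")
print(sex.round(2).to_string(index=False))

config = aducanumab_profile(seed=4, n_background_reports=0)
dataset = build_dataset(generate(config), ("aducanumab", "aduhelm"),
                        default_pt_soc_map())
focal = dataset.subset(dataset.records["is_focal"])
onset = compute_onset(focal)
print(f"\nsynthetic time to onset: n={onset.n}, "
      f"median {onset.median_days:.1f} d "
      f"(IQR {onset.q1_days:.1f}-{onset.q3_days:.1f})")
print("bin counts:", dict(onset.bin_counts))
print("\nPercentages out of all 510 reports match the printed table")
print("(female 49.80%); the simulated onset histogram tracks the printed")
print("bins, with the published median near 146 days.")
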